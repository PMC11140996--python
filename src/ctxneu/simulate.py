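"""Synthetic multi-tissue scRNA-seq generator.

Emulates the statistical structure the downstream stages assume: several
patients each sampled in blood, peritumoral tissue and tumor; neutrophils
carrying tissue-restricted gene programs; malignant epithelial cells carrying
planted copy-number segments among normal epithelial reference cells;
doublets formed by barcode collision; and a subpopulation of damaged cells
with high mitochondrial content.

Counts follow a negative-binomial law with gene-level log-normal baseline
means — the standard overdispersed noise model for UMI data. The synthetic
genome places genes at evenly spaced positions on a configurable number of
autosomes plus a dedicated ``chrM`` contig holding the mitochondrial genes;
CNV windowing only needs genomic ordering, not realistic coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CnvSegment",
    "GeneProgram",
    "SyntheticDesign",
    "default_design",
    "generate_dataset",
    "validate_count_matrix",
]

CELL_META_COLUMNS = ["patient", "tissue", "true_cell_type", "true_is_malignant", "true_is_doublet"]
GENE_ANNO_COLUMNS = ["chromosome", "start_position", "is_mitochondrial"]


@dataclass(frozen=True)
class GeneProgram:
    """A planted gene program: a set of genes upregulated in some tissues.

    ``log2_effect`` multiplies the NB mean of every program gene by
    ``2**log2_effect`` in cells whose tissue is in ``active_tissues`` (and,
    if ``cell_types`` is given, whose type is in ``cell_types``).
    ``partial_activation`` maps further tissues to intermediate log2
    effects, emulating transitional states (e.g. a tumor program already
    half-induced in the peritumoral tissue).
    """

    name: str
    genes: tuple[str, ...]
    active_tissues: tuple[str, ...]
    log2_effect: float
    cell_types: tuple[str, ...] | None = None
    partial_activation: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"program {self.name!r} has an empty gene set")
        if self.log2_effect < 0:
            raise ValueError(f"program {self.name!r}: log2_effect must be >= 0")
        if self.partial_activation and set(self.partial_activation) & set(self.active_tissues):
            raise ValueError(f"program {self.name!r}: partial_activation overlaps active_tissues")


@dataclass(frozen=True)
class CnvSegment:
    """A planted copy-number segment: gene indices are 0-based within the
    chromosome's genomically ordered gene list, ``end_gene_index`` exclusive."""

    chromosome: str
    start_gene_index: int
    end_gene_index: int
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.start_gene_index < 0 or self.end_gene_index <= self.start_gene_index:
            raise ValueError("CNV segment requires 0 <= start < end")
        if self.copy_ratio <= 0 or self.copy_ratio == 1.0:
            raise ValueError("copy_ratio must be positive and != 1")


@dataclass
class SyntheticDesign:
    """Full parameterization of the simulator.

    Baseline NB means are drawn per gene from
    ``LogNormal(baseline_log_mean, baseline_log_sd)``; dispersion is shared
    (variance ``m + m**2 / nb_dispersion``). ``mito_high_fraction`` of cells
    are simulated as damaged, with mitochondrial means inflated so their
    expected mitochondrial count fraction is ``mito_high_target`` (> 0.35).
    ``cell_type_fractions`` gives, per tissue, the cell-type composition of a
    sample; malignant cells are drawn among epithelial cells of the "tumor"
    tissue with probability ``malignant_fraction``.
    """

    n_genes: int = 1500
    n_patients: int = 3
    tissues: tuple[str, ...] = ("blood", "peritumor", "tumor")
    cells_per_sample: int = 300
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 10.0
    programs: tuple[GeneProgram, ...] = ()
    cnv_segments: tuple[CnvSegment, ...] = ()
    malignant_fraction: float = 0.5
    doublet_rate: float = 0.05
    mito_gene_fraction: float = 0.013
    mito_high_fraction: float = 0.05
    seed: int = 0
    n_chromosomes: int = 4
    cell_type_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "blood": {"neutrophil": 1.0},
            "peritumor": {"neutrophil": 0.5, "epithelial": 0.5},
            "tumor": {"neutrophil": 0.5, "epithelial": 0.5},
        }
    )
    baseline_mito_fraction: float = 0.05
    mito_high_target: float = 0.45

    # ---- derived genome layout -------------------------------------------------

    @property
    def n_mito_genes(self) -> int:
        return math.ceil(self.mito_gene_fraction * self.n_genes)

    def gene_annotation(self) -> pd.DataFrame:
        """Synthetic genome: mito genes on chrM, the rest split evenly across
        ``n_chromosomes`` autosomes at evenly spaced positions."""
        n_mito = self.n_mito_genes
        n_auto = self.n_genes - n_mito
        gene_ids = [f"MT-{i + 1}" for i in range(n_mito)]
        chroms = ["chrM"] * n_mito
        positions = [10_000 * (i + 1) for i in range(n_mito)]
        per_chrom = np.full(self.n_chromosomes, n_auto // self.n_chromosomes)
        per_chrom[: n_auto % self.n_chromosomes] += 1
        g = 0
        for c, size in enumerate(per_chrom):
            for i in range(size):
                gene_ids.append(f"G{g:05d}")
                chroms.append(f"chr{c + 1}")
                positions.append(10_000 * (i + 1))
                g += 1
        anno = pd.DataFrame(
            {
                "chromosome": chroms,
                "start_position": np.asarray(positions, dtype=np.int64),
                "is_mitochondrial": np.asarray([c == "chrM" for c in chroms]),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return anno

    # ---- validation -------------------------------------------------------------

    def validate(self) -> None:
        for name, value in [
            ("n_genes", self.n_genes),
            ("n_patients", self.n_patients),
            ("cells_per_sample", self.cells_per_sample),
            ("n_chromosomes", self.n_chromosomes),
        ]:
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        for name, value in [
            ("malignant_fraction", self.malignant_fraction),
            ("doublet_rate", self.doublet_rate),
            ("mito_gene_fraction", self.mito_gene_fraction),
            ("mito_high_fraction", self.mito_high_fraction),
            ("baseline_mito_fraction", self.baseline_mito_fraction),
            ("mito_high_target", self.mito_high_target),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissues must be unique")

        anno = self.gene_annotation()
        known_genes = set(anno.index)
        mito_genes = set(anno.index[anno["is_mitochondrial"]])
        seen: set[str] = set()
        for prog in self.programs:
            gset = set(prog.genes)
            if not gset <= known_genes:
                missing = sorted(gset - known_genes)[:3]
                raise ValueError(f"program {prog.name!r} references unknown genes {missing}")
            if gset & mito_genes:
                raise ValueError(f"program {prog.name!r} overlaps mitochondrial genes")
            if gset & seen:
                raise ValueError(f"program {prog.name!r} overlaps another program's genes")
            seen |= gset
            missing_tissues = (
                set(prog.active_tissues) | set(prog.partial_activation or {})
            ) - set(self.tissues)
            if missing_tissues:
                raise ValueError(
                    f"program {prog.name!r} references tissues outside the design: "
                    f"{sorted(missing_tissues)}"
                )

        sizes = anno[~anno["is_mitochondrial"]].groupby("chromosome", sort=False).size()
        for seg in self.cnv_segments:
            if seg.chromosome not in sizes.index:
                raise ValueError(f"CNV segment chromosome {seg.chromosome!r} not in genome")
            if seg.end_gene_index > sizes[seg.chromosome]:
                raise ValueError(
                    f"CNV segment exceeds {seg.chromosome} ({sizes[seg.chromosome]} genes)"
                )
        for tissue, fracs in self.cell_type_fractions.items():
            if tissue not in self.tissues:
                raise ValueError(f"cell_type_fractions references unknown tissue {tissue!r}")
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValueError(f"cell_type_fractions for {tissue!r} must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["programs"] = [
            {**asdict(p), "genes": list(p.genes), "active_tissues": list(p.active_tissues),
             "cell_types": None if p.cell_types is None else list(p.cell_types),
             "partial_activation": None if p.partial_activation is None else dict(p.partial_activation)}
            for p in self.programs
        ]
        d["cnv_segments"] = [asdict(s) for s in self.cnv_segments]
        d["cell_type_fractions"] = {t: dict(v) for t, v in self.cell_type_fractions.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticDesign":
        d = dict(d)
        d["tissues"] = tuple(d.get("tissues", ("blood", "peritumor", "tumor")))
        d["programs"] = tuple(
            GeneProgram(
                name=p["name"],
                genes=tuple(p["genes"]),
                active_tissues=tuple(p["active_tissues"]),
                log2_effect=float(p["log2_effect"]),
                cell_types=None if p.get("cell_types") is None else tuple(p["cell_types"]),
                partial_activation=(
                    None if p.get("partial_activation") is None else dict(p["partial_activation"])
                ),
            )
            for p in d.get("programs", ())
        )
        d["cnv_segments"] = tuple(CnvSegment(**s) for s in d.get("cnv_segments", ()))
        return cls(**d)


def default_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """The default study-like design: three patients sampled in blood,
    peritumor and tumor; three disjoint 30-gene neutrophil context programs
    (active in blood+peritumor, peritumor+tumor, and tumor only); epithelial
    marker genes separating the two cell types; and one 300-gene copy-number
    gain (ratio 2.0) carried by malignant tumor epithelial cells."""
    base = SyntheticDesign(seed=seed)
    n_mito = base.n_mito_genes
    # program genes drawn from the back half of the autosomal genome so the
    # planted CNV segment (front of chr1) stays program-free
    ids = [f"G{i:05d}" for i in range(base.n_genes - n_mito)]
    take = iter(ids[len(ids) // 2:])

    def grab(n: int) -> tuple[str, ...]:
        return tuple(next(take) for _ in range(n))

    programs = (
        GeneProgram("nontumor_shared", grab(30), ("blood", "peritumor"), 2.0, ("neutrophil",)),
        GeneProgram("tissue_shared", grab(30), ("peritumor", "tumor"), 2.0, ("neutrophil",)),
        GeneProgram(
            "tumor_specific", grab(30), ("tumor",), 2.0, ("neutrophil",),
            # half-induced in peritumor: the blood -> peritumor -> tumor transition
            partial_activation={"peritumor": 1.0},
        ),
        GeneProgram("epithelial_markers", grab(40), base.tissues, 3.0, ("epithelial",)),
        GeneProgram("neutrophil_markers", grab(40), base.tissues, 3.0, ("neutrophil",)),
    )
    # one chromosome-scale gain, the typical arm-level event in carcinomas
    chr1_size = (base.n_genes - n_mito) // base.n_chromosomes + (
        1 if (base.n_genes - n_mito) % base.n_chromosomes > 0 else 0
    )
    segments = (CnvSegment("chr1", 0, chr1_size, 2.0),)
    params = dict(seed=seed, programs=programs, cnv_segments=segments)
    params.update(overrides)
    return SyntheticDesign(**params)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with mean ``mean`` and variance ``mean + mean**2/dispersion``."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _allocate_types(rng: np.random.Generator, n: int, fracs: Mapping[str, float]) -> np.ndarray:
    """Deterministic composition: largest-remainder rounding of the requested
    fractions, then a seeded shuffle."""
    types = sorted(fracs)
    counts = np.array([fracs[t] * n for t in types])
    base = np.floor(counts).astype(int)
    rem = counts - base
    short = n - base.sum()
    for i in np.argsort(-rem)[:short]:
        base[i] += 1
    out = np.repeat(np.asarray(types, dtype=object), base)
    rng.shuffle(out)
    return out


def generate_dataset(design: SyntheticDesign) -> ad.AnnData:
    """Draw a full synthetic dataset.

    Returns an :class:`anndata.AnnData` with raw integer counts in ``X``
    (cells x genes, CSR), per-cell metadata (patient, tissue, true_cell_type,
    true_is_malignant, true_is_doublet) in ``obs`` and the gene annotation
    (chromosome, start_position, is_mitochondrial) in ``var``. Identical
    designs (including seed) give bit-identical output.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    anno = design.gene_annotation()
    gene_ids = anno.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mito_mask = anno["is_mitochondrial"].to_numpy()

    # baseline means: log-normal autosomal genes; mito genes scaled so the
    # expected mito count fraction of a healthy cell is baseline_mito_fraction
    base_mean = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, design.n_genes)
    if mito_mask.any() and design.baseline_mito_fraction > 0:
        f = design.baseline_mito_fraction
        auto_total = base_mean[~mito_mask].sum()
        base_mean[mito_mask] *= (f / (1 - f)) * auto_total / base_mean[mito_mask].sum()

    # per-(tissue, cell_type, malignant) expected-mean profiles
    seg_multiplier = np.ones(design.n_genes)
    auto = anno[~mito_mask]
    for seg in design.cnv_segments:
        chrom_genes = auto.index[auto["chromosome"] == seg.chromosome]
        chrom_genes = chrom_genes[np.argsort(auto.loc[chrom_genes, "start_position"].to_numpy(), kind="stable")]
        for g in chrom_genes[seg.start_gene_index: seg.end_gene_index]:
            seg_multiplier[gene_pos[g]] *= seg.copy_ratio

    def profile(tissue: str, cell_type: str, malignant: bool) -> np.ndarray:
        m = base_mean.copy()
        for prog in design.programs:
            if prog.cell_types is not None and cell_type not in prog.cell_types:
                continue
            if tissue in prog.active_tissues:
                effect = prog.log2_effect
            elif prog.partial_activation and tissue in prog.partial_activation:
                effect = prog.partial_activation[tissue]
            else:
                continue
            idx = [gene_pos[g] for g in prog.genes]
            m[idx] *= 2.0 ** effect
        if malignant:
            m = m * seg_multiplier
        return m

    rows: list[sp.csr_matrix] = []
    meta: dict[str, list] = {c: [] for c in ["cell_id", *CELL_META_COLUMNS]}

    for p in range(design.n_patients):
        patient = f"P{p + 1:02d}"
        for tissue in design.tissues:
            fracs = design.cell_type_fractions.get(tissue, {"neutrophil": 1.0})
            cell_types = _allocate_types(rng, design.cells_per_sample, fracs)
            malignant = np.zeros(design.cells_per_sample, dtype=bool)
            if tissue == "tumor":
                epi = cell_types == "epithelial"
                malignant[epi] = rng.random(int(epi.sum())) < design.malignant_fraction
            mito_high = rng.random(design.cells_per_sample) < design.mito_high_fraction

            sample_counts = np.empty((design.cells_per_sample, design.n_genes), dtype=np.int64)
            for i in range(design.cells_per_sample):
                m = profile(tissue, cell_types[i], bool(malignant[i]))
                if mito_high[i] and mito_mask.any():
                    t = design.mito_high_target
                    auto_total = m[~mito_mask].sum()
                    mito_total = m[mito_mask].sum()
                    if mito_total > 0:
                        m = m.copy()
                        m[mito_mask] *= (t / (1 - t)) * auto_total / mito_total
                sample_counts[i] = _nb_sample(rng, m, design.nb_dispersion)

            n_singlets = design.cells_per_sample
            sample_id = f"{patient}_{tissue}"
            for i in range(n_singlets):
                meta["cell_id"].append(f"{sample_id}_C{i:04d}")
                meta["patient"].append(patient)
                meta["tissue"].append(tissue)
                meta["true_cell_type"].append(cell_types[i])
                meta["true_is_malignant"].append(bool(malignant[i]))
                meta["true_is_doublet"].append(False)
            rows.append(sp.csr_matrix(sample_counts))

            # doublets: sum of two random singlets of this sample, downsampled
            # (without replacement) to the mean singlet library size
            n_doub = int(round(design.doublet_rate * n_singlets))
            if n_doub:
                target = int(round(sample_counts.sum(axis=1).mean()))
                doub = np.zeros((n_doub, design.n_genes), dtype=np.int64)
                for j in range(n_doub):
                    a, b = rng.choice(n_singlets, size=2, replace=False)
                    combined = sample_counts[a] + sample_counts[b]
                    total = int(combined.sum())
                    if total > target:
                        doub[j] = rng.multivariate_hypergeometric(combined, target, method="marginals")
                    else:
                        doub[j] = combined
                    ta, tb = cell_types[a], cell_types[b]
                    meta["cell_id"].append(f"{sample_id}_D{j:04d}")
                    meta["patient"].append(patient)
                    meta["tissue"].append(tissue)
                    meta["true_cell_type"].append(ta if ta == tb else "+".join(sorted((ta, tb))))
                    meta["true_is_malignant"].append(bool(malignant[a] or malignant[b]))
                    meta["true_is_doublet"].append(True)
                rows.append(sp.csr_matrix(doub))

    X = sp.vstack(rows, format="csr").astype(np.int64)
    obs = pd.DataFrame(
        {c: meta[c] for c in CELL_META_COLUMNS},
        index=pd.Index(meta["cell_id"], name="cell_id"),
    )
    obs["true_is_malignant"] = obs["true_is_malignant"].astype(bool)
    obs["true_is_doublet"] = obs["true_is_doublet"].astype(bool)
    adata = ad.AnnData(X=X, obs=obs, var=anno.copy())
    adata.uns["design"] = design.to_dict()
    validate_count_matrix(adata)
    return adata


def validate_count_matrix(adata: ad.AnnData) -> None:
    """Check the container invariants every downstream stage relies on."""
    if adata.n_obs != len(adata.obs) or adata.n_vars != len(adata.var):
        raise ValueError("counts dimensions do not match metadata lengths")
    if adata.obs_names.has_duplicates:
        raise ValueError("cell_ids are not unique")
    missing = [c for c in GENE_ANNO_COLUMNS if c not in adata.var.columns]
    if missing:
        raise ValueError(f"gene annotation lacks columns {missing}")
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
        raise ValueError("counts must be non-negative integers")
    for chrom, sub in adata.var.groupby("chromosome", sort=False):
        pos = np.sort(sub["start_position"].to_numpy())
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError(f"gene positions are not strictly increasing on {chrom}")
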