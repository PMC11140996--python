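"""Context-dependent scores, gene-set scoring, and signature construction."""

import numpy as np
import pandas as pd
import pytest

from ctxneu.preprocess import log_normalize
from ctxneu.scores import build_context_scores, build_signature, score_gene_set
from ctxneu.simulate import GeneProgram, SyntheticDesign, generate_dataset

from conftest import make_adata

PLANTED = {
    "nontumor_activating": "nontumor_shared",
    "tissue_residing": "tissue_shared",
    "tumor_modifying": "tumor_specific",
}


def three_program_design(log2_effect=2.0, n_program_genes=30, cells=300, seed=61):
    ids = iter(f"G{i:05d}" for i in range(200))

    def grab(n):
        return tuple(next(ids) for _ in range(n))

    programs = (
        GeneProgram("nontumor_shared", grab(n_program_genes), ("blood", "peritumor"), log2_effect),
        GeneProgram("tissue_shared", grab(n_program_genes), ("peritumor", "tumor"), log2_effect),
        GeneProgram(
            "tumor_specific", grab(n_program_genes), ("tumor",), log2_effect,
            # half-induced in peritumor, emulating the blood->peritumor->tumor transition
            partial_activation={"peritumor": log2_effect / 2} if log2_effect else None,
        ),
    )
    return SyntheticDesign(
        n_genes=600,
        n_patients=1,
        cells_per_sample=cells,
        n_chromosomes=2,
        programs=programs,
        cell_type_fractions={t: {"neutrophil": 1.0} for t in ("blood", "peritumor", "tumor")},
        cnv_segments=(),
        doublet_rate=0.0,
        mito_high_fraction=0.0,
        seed=seed,
    )


@pytest.fixture(scope="module")
def three_program_scores():
    adata = generate_dataset(three_program_design())
    return adata, build_context_scores(adata)


def test_recovered_sets_lie_within_their_planted_programs(three_program_scores):
    adata, css = three_program_scores
    planted = {p["name"]: set(p["genes"]) for p in adata.uns["design"]["programs"]}
    for score_name, program in PLANTED.items():
        got = css.gene_sets()[score_name]
        assert len(got) <= 21
        assert set(got) <= planted[program]
        recovery = len(set(got) & planted[program]) / min(21, len(planted[program]))
        assert recovery >= 0.9


def test_mean_scores_order_by_context(three_program_scores):
    """Tumor-Modifying ranks tumor > peritumor > blood; Nontumor-Activating
    ranks blood >= peritumor > tumor (the qualitative violin-plot pattern)."""
    _, css = three_program_scores
    m = css.scores.groupby("context")[list(PLANTED)].mean()
    tm = m["tumor_modifying"]
    assert tm["tumor"] > tm["peritumor"] and tm["tumor"] > tm["blood"]
    nta = m["nontumor_activating"]
    assert nta["blood"] > nta["tumor"] and nta["peritumor"] > nta["tumor"]
    tr = m["tissue_residing"]
    assert tr["peritumor"] > tr["blood"] and tr["tumor"] > tr["blood"]


def test_null_design_yields_empty_or_flat_scores():
    from scipy import stats

    design = three_program_design(log2_effect=0.0, cells=150, seed=62)
    adata = generate_dataset(design)
    with pytest.warns(UserWarning, match="empty"):
        css = build_context_scores(adata)
    for name, genes in css.gene_sets().items():
        if not genes:
            assert np.all(css.scores[name].to_numpy() == 0.0)
        else:  # any surviving set must not separate the tissues
            groups = [
                css.scores.loc[css.scores["context"] == c, name] for c in ("blood", "peritumor", "tumor")
            ]
            assert stats.f_oneway(*groups).pvalue > 0.01


def test_reducing_top_n_gives_prefix_of_larger_set(three_program_scores):
    adata, css21 = three_program_scores
    css10 = build_context_scores(adata, top_n=10)
    for name in PLANTED:
        assert css10.gene_sets()[name] == css21.gene_sets()[name][:10]


def test_construction_invariant_to_cell_and_gene_order(three_program_scores):
    adata, css = three_program_scores
    rng = np.random.default_rng(0)
    cells = rng.permutation(adata.n_obs)
    genes = rng.permutation(adata.n_vars)
    shuffled = adata[cells, :][:, genes].copy()
    shuffled.layers.clear()
    css2 = build_context_scores(shuffled)
    assert css2.gene_sets() == css.gene_sets()


def test_pseudo_trajectory_monotone_tumor_modifying(three_program_scores):
    """Ordering cells blood -> peritumor -> tumor, the mean Tumor-Modifying
    score is non-decreasing across the ordered groups."""
    _, css = three_program_scores
    m = css.scores.groupby("context")["tumor_modifying"].mean()
    assert m["blood"] <= m["peritumor"] <= m["tumor"]


def test_missing_context_class_errors():
    adata = make_adata(np.ones((10, 5), int), tissue=["blood"] * 5 + ["tumor"] * 5)
    with pytest.raises(ValueError, match="peritumor"):
        build_context_scores(adata)


# ---- score_gene_set ---------------------------------------------------------


def test_score_is_mean_of_lognormalized_values():
    adata = make_adata(np.array([[10, 0, 30], [0, 0, 0]]))
    log_normalize(adata)
    L = adata.layers["lognorm"].toarray()
    s = score_gene_set(adata, ["G0000", "G0002"])
    assert s[0] == pytest.approx((L[0, 0] + L[0, 2]) / 2)
    assert s[1] == 0.0  # all-zero cell scores 0


def test_union_score_is_size_weighted_mean():
    rng = np.random.default_rng(4)
    adata = make_adata(rng.poisson(5, (20, 10)))
    a = [f"G{i:04d}" for i in range(0, 4)]
    b = [f"G{i:04d}" for i in range(4, 10)]
    su = score_gene_set(adata, a + b)
    sa, sb = score_gene_set(adata, a), score_gene_set(adata, b)
    np.testing.assert_allclose(su, (4 * sa + 6 * sb) / 10, atol=1e-12)


def test_missing_genes_dropped_with_warning():
    adata = make_adata(np.ones((3, 4), int))
    with pytest.warns(UserWarning, match="absent"):
        s = score_gene_set(adata, ["G0000", "NOPE"])
    assert s.shape == (3,)
    with pytest.raises(ValueError, match="no gene"):
        score_gene_set(adata, ["NOPE1", "NOPE2"])


# ---- build_signature --------------------------------------------------------


def signature_dataset(seed=71):
    """Tumor cells of two subtypes; an anchor-correlated module is planted by
    making 10 genes share the anchor's subtype-specific activation, and 12
    further genes are upregulated in the invasive (LI) subtype."""
    anchor_module = tuple(f"G{i:05d}" for i in range(11))  # anchor + 10 partners
    li_degs = tuple(f"G{i:05d}" for i in range(20, 32))
    design = SyntheticDesign(
        n_genes=400,
        n_patients=1,
        cells_per_sample=400,
        n_chromosomes=2,
        tissues=("tumor",),
        programs=(
            GeneProgram("anchor_module", anchor_module, ("tumor",), 2.0, ("epithelial_li",)),
            GeneProgram("li_up", li_degs, ("tumor",), 2.0, ("epithelial_li",)),
        ),
        cell_type_fractions={"tumor": {"epithelial_li": 0.5, "epithelial_lo": 0.5}},
        cnv_segments=(),
        malignant_fraction=0.0,
        doublet_rate=0.0,
        mito_high_fraction=0.0,
        seed=seed,
    )
    adata = generate_dataset(design)
    subtype = np.where(adata.obs["true_cell_type"] == "epithelial_li", "LI", "Lo")
    return adata, subtype, anchor_module, li_degs


def test_signature_recovers_planted_union():
    adata, subtype, anchor_module, li_degs = signature_dataset()
    sig = build_signature(adata, subtype, anchor_gene="G00000", corr_threshold=0.3)
    planted = set(anchor_module) | set(li_degs)
    recovered = len(planted & set(sig.genes)) / len(planted)
    assert recovered >= 0.9
    assert "G00000" in sig.genes


def test_unattainable_correlation_leaves_deg_arm_only():
    adata, subtype, _, li_degs = signature_dataset()
    sig = build_signature(adata, subtype, anchor_gene="G00000", corr_threshold=1.0)
    deg_table_genes = set(sig.genes) - {"G00000"}
    assert sig.construction["n_corr_genes"] == 0
    assert deg_table_genes  # DEG arm still contributes


def test_constant_anchor_warns_and_skips_correlation_arm():
    adata = make_adata(
        np.hstack([np.zeros((12, 1), int), np.random.default_rng(0).poisson(5, (12, 9))]),
        subtype=["LI"] * 6 + ["Lo"] * 6,
    )
    with pytest.warns(UserWarning, match="constant"):
        sig = build_signature(adata, "subtype", anchor_gene="G0000", corr_threshold=0.3)
    assert sig.construction["n_corr_genes"] == 0
    assert sig.genes[0] == "G0000"


def test_absent_anchor_errors():
    adata = make_adata(np.ones((6, 3), int), subtype=["LI"] * 3 + ["Lo"] * 3)
    with pytest.raises(ValueError, match="anchor"):
        build_signature(adata, "subtype", anchor_gene="KRT17")
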