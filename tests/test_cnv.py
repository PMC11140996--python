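"""Sliding-window CNV profiling: window arithmetic, oracle equivalence,
threshold semantics, and planted-gain recovery."""

import numpy as np
import pandas as pd
import pytest

from ctxneu.cnv import (
    cnv_profile,
    cnv_score_and_call,
    infer_malignant,
    relative_expression,
    sliding_windows,
)
from ctxneu.simulate import CnvSegment, SyntheticDesign, generate_dataset

from conftest import make_adata


def brute_force_scores(relative_matrix, retained, windows):
    """Independent double-loop recomputation of CNVi and the CNV score."""
    retained = list(retained)
    pos = {g: i for i, g in enumerate(retained)}
    n_cells = relative_matrix.shape[0]
    scores = np.zeros(n_cells)
    for c in range(n_cells):
        acc = 0.0
        for _, genes in windows:
            cnvi = 0.0
            for g in genes:
                cnvi += relative_matrix[c, pos[g]]
            cnvi /= len(genes)
            acc += cnvi * cnvi
        scores[c] = acc / len(windows)
    return scores


# ---- sliding_windows --------------------------------------------------------


def _anno(sizes):
    rows = []
    for chrom, n in sizes.items():
        for i in range(n):
            rows.append((f"{chrom}_g{i:04d}", chrom, (i + 1) * 100))
    return pd.DataFrame(
        {"chromosome": [r[1] for r in rows], "start_position": [r[2] for r in rows],
         "is_mitochondrial": False},
        index=pd.Index([r[0] for r in rows], name="gene_id"),
    )


@pytest.mark.parametrize(
    "sizes, window, expected",
    [
        ({"chr1": 250}, 100, 151),
        ({"chr1": 150, "chr2": 100}, 100, 52),
        ({"chr1": 40}, 100, 1),
        ({"chr1": 5}, 1, 5),
    ],
)
def test_window_counts(sizes, window, expected):
    anno = _anno(sizes)
    windows = sliding_windows(anno, anno.index, window_size=window)
    assert len(windows) == expected


def test_short_chromosome_collapses_to_single_full_window():
    anno = _anno({"chr1": 40})
    (chrom, genes), = sliding_windows(anno, anno.index, window_size=100)
    assert chrom == "chr1" and len(genes) == 40


def test_windows_are_contiguous_and_sorted_by_position():
    anno = _anno({"chr1": 120})
    shuffled = anno.sample(frac=1.0, random_state=0)
    windows = sliding_windows(shuffled, shuffled.index, window_size=100)
    for _, genes in windows:
        positions = anno.loc[genes, "start_position"].to_numpy()
        assert np.all(np.diff(positions) == 100)


# ---- relative_expression ----------------------------------------------------


def test_self_reference_centering_is_zero():
    """Identical cells referenced on themselves give an (almost) all-zero
    relative matrix."""
    counts = np.tile(np.arange(1, 31), (8, 1))
    adata = make_adata(counts)
    rel, retained = relative_expression(adata, adata.obs_names, expression_cutoff=0.1)
    assert np.abs(rel).max() < 1e-9
    assert len(retained) == 30


def test_low_expression_gene_dropped_at_cutoff():
    counts = np.full((20, 5), 20)
    counts[:, 0] = 0
    counts[0, 0] = 1  # mean normalized expression 0.05 at (nearly) equal libraries
    adata = make_adata(counts)
    rel, retained = relative_expression(adata, adata.obs_names, expression_cutoff=0.1)
    assert "G0000" not in retained and len(retained) == 4


def test_values_clipped_to_clip_parameter():
    counts = np.full((4, 30), 3)
    counts[0, 0] = 1_000_000  # one gene far above the reference in one cell
    adata = make_adata(counts)
    rel, _ = relative_expression(adata, adata.obs_names[1:], clip=3.0)
    assert rel.max() == pytest.approx(3.0)
    assert rel.min() >= -3.0


def test_chrM_genes_always_excluded():
    counts = np.full((6, 20), 10)
    mito = [True] * 5 + [False] * 15
    chrom = ["chrM"] * 5 + ["chr1"] * 15
    adata = make_adata(counts, chromosomes=chrom, mito=mito)
    _, retained = relative_expression(adata, adata.obs_names)
    assert retained == [f"G{i:04d}" for i in range(5, 20)]


def test_empty_reference_errors():
    adata = make_adata(np.ones((4, 10), int))
    with pytest.raises(ValueError, match="reference"):
        relative_expression(adata, [])


def test_no_gene_survives_cutoff_errors():
    adata = make_adata(np.zeros((4, 10), int))
    with pytest.raises(ValueError, match="cutoff"):
        relative_expression(adata, adata.obs_names, expression_cutoff=0.1)


# ---- cnv_profile / score ----------------------------------------------------


def test_cnvi_is_window_mean():
    rel = np.array([[0.2, 0.4, -0.6]])
    windows = [("chr1", ["g0", "g1"]), ("chr1", ["g1", "g2"])]
    prof = cnv_profile(rel, ["g0", "g1", "g2"], windows)
    assert prof.cnv_matrix[0, 0] == pytest.approx(0.3)
    assert prof.cnv_matrix[0, 1] == pytest.approx(-0.1)


def test_all_zero_relative_matrix_gives_zero_scores():
    rel = np.zeros((3, 4))
    windows = [("chr1", ["g0", "g1", "g2", "g3"])]
    prof = cnv_score_and_call(cnv_profile(rel, ["g0", "g1", "g2", "g3"], windows))
    assert np.all(prof.cnv_score == 0.0)
    assert not prof.is_malignant.any()


def test_score_closed_form_half_windows_at_0_3():
    """CNVi = 0.3 on half of the windows -> score 0.5 * 0.09 = 0.045 > 0.04."""
    rel = np.array([[0.3, 0.0]])
    windows = [("chr1", ["a"]), ("chr1", ["b"])]
    prof = cnv_score_and_call(cnv_profile(rel, ["a", "b"], windows), threshold=0.04)
    assert prof.cnv_score[0] == pytest.approx(0.045)
    assert prof.is_malignant[0]


def test_score_exactly_at_threshold_is_not_malignant():
    rel = np.array([[0.25, 0.0]])  # score = 0.0625 / 2 = 0.03125, exact in binary
    windows = [("chr1", ["a"]), ("chr1", ["b"])]
    prof = cnv_score_and_call(cnv_profile(rel, ["a", "b"], windows), threshold=0.03125)
    assert prof.cnv_score[0] == 0.03125
    assert not prof.is_malignant[0]  # strict "above"


def test_window_referencing_dropped_gene_errors():
    rel = np.zeros((2, 2))
    with pytest.raises(ValueError, match="not retained"):
        cnv_profile(rel, ["a", "b"], [("chr1", ["a", "zz"])])


def test_zero_windows_errors():
    rel = np.zeros((2, 2))
    with pytest.raises(ValueError, match="window"):
        cnv_profile(rel, ["a", "b"], [])


def test_pipeline_matches_brute_force_oracle():
    """50 cells x 500 genes: vectorized scores equal the double-loop oracle
    to 1e-12."""
    rng = np.random.default_rng(17)
    counts = rng.poisson(5.0, size=(50, 500))
    chrom = ["chr1"] * 300 + ["chr2"] * 200
    adata = make_adata(counts, chromosomes=chrom,
                       positions=list(range(1, 301)) + list(range(1, 201)))
    rel, retained = relative_expression(adata, adata.obs_names[:20])
    windows = sliding_windows(adata.var, retained, window_size=100)
    prof = cnv_score_and_call(cnv_profile(rel, retained, windows))
    expected = brute_force_scores(rel, retained, windows)
    assert np.max(np.abs(prof.cnv_score - expected)) < 1e-12


def test_score_invariant_to_window_order():
    rng = np.random.default_rng(3)
    rel = rng.normal(size=(5, 30))
    genes = [f"g{i}" for i in range(30)]
    windows = [("chr1", genes[i: i + 10]) for i in range(0, 21)]
    fwd = cnv_score_and_call(cnv_profile(rel, genes, windows)).cnv_score
    rev = cnv_score_and_call(cnv_profile(rel, genes, windows[::-1])).cnv_score
    np.testing.assert_allclose(fwd, rev, atol=1e-15)


def test_reference_invariance_to_duplicated_reference_cells():
    """Adding identical copies of reference cells does not change any CNVi."""
    rng = np.random.default_rng(5)
    counts = rng.poisson(8.0, size=(20, 120))
    base = make_adata(counts)
    rel1, retained = relative_expression(base, base.obs_names[:10])
    dup = np.vstack([counts, counts[:10]])
    bigger = make_adata(dup)
    ref2 = list(bigger.obs_names[:10]) + list(bigger.obs_names[20:])
    rel2, retained2 = relative_expression(bigger, ref2)
    assert retained == retained2
    np.testing.assert_allclose(rel1, rel2[:20], atol=1e-12)


def test_planted_gain_recovered_at_printed_threshold():
    """One copy_ratio=2.0 whole-chromosome gain (>= 300 genes), default NB
    noise: sensitivity and specificity >= 0.95 at threshold 0.04."""
    design = SyntheticDesign(
        n_patients=3,
        cells_per_sample=150,
        cnv_segments=(CnvSegment("chr1", 0, 370, 2.0),),
        doublet_rate=0.0,
        mito_high_fraction=0.0,
        seed=41,
    )
    adata = generate_dataset(design)
    epi = adata[adata.obs["true_cell_type"] == "epithelial"].copy()
    assert epi.n_obs >= 400
    ref = epi.obs_names[(epi.obs["tissue"] == "peritumor")]
    prof = infer_malignant(epi, ref, threshold=0.04)
    truth = epi.obs["true_is_malignant"].to_numpy()
    called = prof.is_malignant
    sensitivity = (truth & called).sum() / truth.sum()
    specificity = (~truth & ~called).sum() / (~truth).sum()
    assert sensitivity >= 0.95
    assert specificity >= 0.95
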