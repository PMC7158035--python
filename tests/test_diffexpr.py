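"""Size factors, BH, NB Wald test conventions, consensus rules."""

import numpy as np
import pandas as pd
import pytest

from sealmir.containers import CountMatrix, default_design, sample_id
from sealmir.diffexpr import (age_de, bh_adjust, nb_test, pairwise_tissue_de,
                              size_factors, tissue_consensus)
from sealmir.synthetic_data import simulate_count_table

TWO_GROUP = [("brain", a, r) for a in ("pup", "adult") for r in (1, 2, 3)]


def _cm_from_matrix(mat, design):
    cols = [sample_id(*d) for d in design]
    counts = pd.DataFrame(mat, index=[f"g{i}" for i in range(len(mat))],
                          columns=cols)
    samples = pd.DataFrame(
        [{"sample": sample_id(*d), "sample_type": d[0], "age": d[1],
          "replicate": d[2]} for d in design]).set_index("sample")
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# size factors


def test_identical_columns_give_unit_factors():
    counts = pd.DataFrame({"a": [10, 40, 5], "b": [10, 40, 5]})
    assert np.allclose(size_factors(counts), 1.0)


def test_doubled_column_gets_factor_two():
    base = np.array([10, 40, 5, 100, 7])
    counts = pd.DataFrame({"a": base, "b": 2 * base})
    sf = size_factors(counts)
    assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-9)


def test_equal_depth_libraries_near_unity():
    cm = simulate_count_table(400, TWO_GROUP, None, 1e4, 0.1, seed=3)
    sf = size_factors(cm.counts)
    assert (np.abs(sf - 1) < 0.05).all()


def test_no_allpositive_row_falls_back_with_warning():
    counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
    with pytest.warns(UserWarning, match="positive-subset"):
        size_factors(counts)


# ---------------------------------------------------------------------------
# BH


def test_bh_hand_computed_values():
    q = bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])


def test_bh_single_and_degenerate_cases():
    assert bh_adjust([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_nan_excluded_from_m():
    q = bh_adjust([0.01, np.nan, 0.02])
    assert np.isnan(q[1])
    assert np.allclose(q[[0, 2]], [0.02, 0.02])


def test_bh_matches_statsmodels_and_is_order_invariant():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    q = bh_adjust(p)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_sm)
    perm = rng.permutation(50)
    assert np.allclose(bh_adjust(p[perm]), q[perm])


# ---------------------------------------------------------------------------
# NB test


def test_identical_groups_give_zero_lfc():
    rng = np.random.default_rng(1)
    block = rng.poisson(50, size=(30, 3))
    cm = _cm_from_matrix(np.hstack([block, block]), TWO_GROUP)
    res = nb_test(cm, ("age",), ("age", "pup", "adult"))
    assert np.nanmax(np.abs(res["log2FC"])) < 1e-6


def test_swapping_contrast_flips_sign_exactly():
    cm = simulate_count_table(50, TWO_GROUP, None, 5e3, 0.1, seed=9)
    fwd = nb_test(cm, ("age",), ("age", "pup", "adult"))
    rev = nb_test(cm, ("age",), ("age", "adult", "pup"))
    assert np.allclose(fwd["log2FC"].dropna(), -rev["log2FC"].dropna())
    assert np.allclose(fwd["p"].dropna(), rev["p"].dropna())


def test_all_zero_strand_has_na_p_outside_bh():
    cm = simulate_count_table(20, TWO_GROUP, None, 5e3, 0.1, seed=2)
    cm.counts.iloc[0] = 0
    res = nb_test(cm, ("age",), ("age", "pup", "adult"))
    assert np.isnan(res["p"].iloc[0]) and np.isnan(res["q"].iloc[0])
    assert res["q"].iloc[1:].notna().all()


def test_planted_effect_detected_small():
    effects = {(f"s{i:04d}", "age", "adult"): 2.0 for i in range(10)}
    cm = simulate_count_table(200, TWO_GROUP, effects, 2e4, 0.1, seed=4)
    res = nb_test(cm, ("age",), ("age", "pup", "adult"))
    assert (res["q"].iloc[:10] <= 0.05).mean() >= 0.8
    assert res["log2FC"].iloc[:10].median() == pytest.approx(2.0, abs=0.5)


# ---------------------------------------------------------------------------
# consensus and age analyses


def _planted_cm(seed=6):
    effects = {("s0000", "sample_type", "brain"): 2.5,
               ("s0001", "sample_type", "brain"): 2.5,
               ("s0001", "sample_type", "heart"): 2.5}
    return simulate_count_table(120, default_design(), effects, 2e4, 0.1,
                                seed=seed)


def test_consensus_requires_all_three_comparisons():
    cm = _planted_cm()
    pw = pairwise_tissue_de(cm)
    calls = tissue_consensus(pw, cm)
    brain_up = set(calls[(calls["sample_type"] == "brain")
                         & (calls["direction"] == "up")]["strand"])
    assert "s0000" in brain_up      # single-tissue: called
    assert "s0001" not in brain_up  # two-tissue: heart comparison fails


def test_missing_contrast_is_named():
    cm = _planted_cm()
    pw = pairwise_tissue_de(cm)
    pw.pop(("brain", "heart"))
    with pytest.raises(ValueError, match="brain"):
        tissue_consensus(pw, cm)


def test_up_and_down_calls_are_exclusive():
    cm = _planted_cm(seed=8)
    calls = tissue_consensus(pairwise_tissue_de(cm), cm)
    dup = calls.groupby(["strand", "sample_type"])["direction"].nunique()
    assert (dup <= 1).all()


def test_triplet_filter_boundary_29_vs_30():
    from sealmir.pipeline import (boundary_count_matrix,
                                  significant_brain_up_pairwise)
    cm = boundary_count_matrix()
    pw = significant_brain_up_pairwise(cm.counts.index)
    calls = tissue_consensus(pw, cm)
    called = set(calls["strand"])
    assert "g30" in called, "triplet total of exactly 30 must be retained"
    assert "g29" not in called, "triplet total of 29 must be filtered"
    assert calls.attrs["n_filtered"] >= 1


def test_age_de_sign_convention_and_per_tissue():
    effects = {("s0000", "age@muscle", "adult"): 2.5}
    cm = simulate_count_table(100, default_design(), effects, 2e4, 0.1, 13)
    per = age_de(cm, scope="per_tissue")
    assert per["muscle"].loc["s0000", "significant"]
    assert per["muscle"].loc["s0000", "log2FC"] > 1.0  # up in adults
    others = [t for t in per if t != "muscle"]
    assert not any(per[t].loc["s0000", "significant"] for t in others)


def test_age_label_swap_flips_all_signs():
    cm = simulate_count_table(40, default_design(), None, 5e3, 0.1, 14)
    fwd = age_de(cm, scope="all_tissues")
    swapped = CountMatrix(cm.counts.copy(), cm.samples.copy())
    swapped.samples["age"] = swapped.samples["age"].map(
        {"pup": "adult", "adult": "pup"})
    rev = age_de(swapped, scope="all_tissues")
    assert np.allclose(fwd["log2FC"].dropna(), -rev["log2FC"].dropna())
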