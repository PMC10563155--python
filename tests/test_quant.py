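"""Filtering, mode normalization, imputation and replicate metrics."""

import numpy as np
import pandas as pd
import pytest

from acquant import quant
from acquant.quant import ImputationParams, QuantTable

from conftest import make_table

nan = float("nan")


# ---------------------------------------------------------------- filter
def six_row_fixture():
    # A, B pass; C contaminant; D one peptide; E never >= 2 replicates in a
    # condition; F fails two rules at once.
    return make_table(
        {"mock_rep1": [20, 21, 22, 23, 24, 25],
         "mock_rep2": [20, 21, 22, 23, nan, 25],
         "acet_rep1": [20, 21, 22, 23, 24, nan],
         "acet_rep2": [20, 21, 22, 23, nan, nan]},
        index=list("ABCDEF"),
        is_contaminant=[False, False, True, False, False, True],
        n_peptides=[5, 2, 5, 1, 5, 1],
    )


def test_filter_proteins_six_row_fixture():
    kept = quant.filter_proteins(six_row_fixture())
    assert list(kept.meta.index) == ["A", "B"]


def test_filter_removes_single_peptide_protein_observed_everywhere():
    table = make_table({"c_rep1": [20], "c_rep2": [20]}, n_peptides=[1])
    assert len(quant.filter_proteins(table)) == 0


def test_filter_removes_contaminant_with_many_peptides():
    table = make_table({"c_rep1": [20], "c_rep2": [20]}, n_peptides=[5],
                       is_contaminant=[True])
    assert len(quant.filter_proteins(table)) == 0


def test_filter_keeps_protein_quantified_in_one_condition_only():
    table = make_table({"a_rep1": [20], "a_rep2": [20], "b_rep1": [nan], "b_rep2": [nan]})
    assert len(quant.filter_proteins(table)) == 1


def test_filter_idempotent_and_never_grows():
    table = six_row_fixture()
    once = quant.filter_proteins(table)
    twice = quant.filter_proteins(once)
    assert len(once) <= len(table)
    assert list(twice.meta.index) == list(once.meta.index)


def test_filter_rejects_peptide_level():
    table = make_table({"c_rep1": [20], "c_rep2": [21]}, level="peptide")
    with pytest.raises(ValueError, match="protein-level"):
        quant.filter_proteins(table)


# ---------------------------------------------------------------- modes
def test_mode_of_constant_shift_is_exact(rng):
    base = rng.normal(22, 2, 200)
    table = make_table({"a_rep1": base, "a_rep2": base - 0.5})
    modes = quant.pairwise_ratio_modes(table)
    assert modes[("a_rep1", "a_rep2")] == pytest.approx(0.5, abs=1e-9)


def test_mode_of_identical_samples_is_zero(rng):
    base = rng.normal(22, 2, 100)
    table = make_table({"a_rep1": base, "a_rep2": base})
    assert quant.pairwise_ratio_modes(table)[("a_rep1", "a_rep2")] == 0.0


def test_mode_robust_to_outlier_minority(rng):
    base = rng.normal(0, 1, 500)
    shift = np.full(500, 1.2)
    shift[:50] = -3.0  # 10% of proteins move the other way
    table = make_table({"a_rep1": base + shift, "a_rep2": base})
    mode = quant.pairwise_ratio_modes(table)[("a_rep1", "a_rep2")]
    assert mode == pytest.approx(1.2, abs=0.1)


def test_mode_antisymmetry(rng):
    values = {f"s_rep{k}": rng.normal(20 + 0.3 * k, 1.5, 300) for k in range(1, 5)}
    table = make_table(values)
    reversed_table = make_table(dict(reversed(values.items())))
    modes = quant.pairwise_ratio_modes(table)
    flipped = quant.pairwise_ratio_modes(reversed_table)
    for (i, j), m in modes.items():
        assert flipped[(j, i)] == pytest.approx(-m, abs=0.02)


def test_mode_requires_shared_proteins():
    table = make_table({"a_rep1": [20, nan, 21], "a_rep2": [nan, 20, nan]})
    with pytest.raises(ValueError, match="share only"):
        quant.pairwise_ratio_modes(table)


def test_mode_warns_below_min_shared(rng):
    table = make_table({"a_rep1": rng.normal(20, 1, 5), "a_rep2": rng.normal(20, 1, 5)})
    with pytest.warns(UserWarning, match="unstable"):
        quant.pairwise_ratio_modes(table)


def test_mode_rejects_linear_table(rng):
    table = make_table({"a_rep1": [100.0, 200.0], "a_rep2": [100.0, 200.0]}, is_log2=False)
    with pytest.raises(ValueError, match="log2"):
        quant.pairwise_ratio_modes(table)


# ---------------------------------------------------------------- factors
def test_two_sample_factors_split_the_mode():
    res = quant.solve_normalization_factors({("a_rep1", "a_rep2"): 0.8})
    assert res.factors["a_rep1"] == pytest.approx(0.4)
    assert res.factors["a_rep2"] == pytest.approx(-0.4)
    assert res.factors.sum() == pytest.approx(0.0, abs=1e-12)


def test_consistent_modes_recovered_exactly():
    truth = {"s_rep1": 0.0, "s_rep2": 1.0, "s_rep3": -1.0}
    modes = {(i, j): truth[i] - truth[j]
             for n, i in enumerate(truth) for j in list(truth)[n + 1:]}
    res = quant.solve_normalization_factors(modes)
    for sample, f in truth.items():
        assert res.factors[sample] == pytest.approx(f, abs=1e-12)
    assert res.residual_sd == pytest.approx(0.0, abs=1e-9)


def test_zero_modes_give_zero_factors():
    modes = {("a_rep1", "a_rep2"): 0.0, ("a_rep1", "a_rep3"): 0.0,
             ("a_rep2", "a_rep3"): 0.0}
    assert np.allclose(quant.solve_normalization_factors(modes).factors, 0.0)


def test_disconnected_pairs_rejected():
    with pytest.raises(ValueError, match="connect"):
        quant.solve_normalization_factors(
            {("a_rep1", "a_rep2"): 0.1, ("b_rep1", "b_rep2"): 0.2})


def test_normalization_recovery_on_synthetic_table(rng):
    """Known per-sample shifts recovered within 0.05 log2 despite missingness."""
    n, shifts = 300, np.array([0.6, -0.2, 0.1, -0.5])
    base = rng.normal(22, 2, n)
    values = {f"s_rep{k + 1}": base + shifts[k] + rng.normal(0, 0.2, n)
              for k in range(4)}
    table = make_table(values)
    # ~15% missing at random
    masked = table.values.mask(rng.random(table.values.shape) < 0.15)
    table = QuantTable(table.meta, masked, "protein", is_log2=True)
    res = quant.solve_normalization_factors(quant.pairwise_ratio_modes(table))
    recovered = res.factors[table.samples].to_numpy()
    assert np.abs(recovered - (shifts - shifts.mean())).max() < 0.05


def test_normalization_idempotent(rng):
    values = {f"s_rep{k}": rng.normal(20 + 0.4 * k, 2, 400) for k in range(1, 4)}
    table = make_table(values)
    res = quant.solve_normalization_factors(quant.pairwise_ratio_modes(table))
    normalized = quant.normalize(table, res)
    res2 = quant.solve_normalization_factors(quant.pairwise_ratio_modes(normalized))
    assert np.abs(res2.factors).max() < 0.01


# ---------------------------------------------------------------- impute
def test_impute_no_missing_is_identity(rng):
    table = make_table({"a_rep1": [20.0, 21, 22, 23], "a_rep2": [19.0, 20, 21, 22]})
    out = quant.impute(table, rng=rng)
    pd.testing.assert_frame_equal(out.values, table.values)


def test_impute_moments_match_downshifted_gaussian():
    observed = np.random.default_rng(4).normal(20, 2, 1000)
    column = np.concatenate([observed, np.full(100_000, nan)])
    table = make_table({"a_rep1": column})
    out = quant.impute(table, ImputationParams(), rng=np.random.default_rng(9))
    imputed = out.values["a_rep1"].to_numpy()[1000:]
    med, sd = np.median(observed), np.std(observed, ddof=1)
    assert imputed.mean() == pytest.approx(med - 1.8 * sd, abs=0.01)
    assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, abs=0.01)


def test_impute_observed_cells_bit_identical_and_complete(rng):
    table = make_table({"a_rep1": [20.0, nan, 22, 23], "a_rep2": [19.0, 20, nan, 22]})
    out = quant.impute(table, rng=rng)
    mask = table.values.notna().to_numpy()
    assert np.array_equal(out.values.to_numpy()[mask], table.values.to_numpy()[mask])
    assert not out.values.isna().any().any()


def test_impute_deterministic_under_seed():
    table = make_table({"a_rep1": [20.0, nan, 22, 23, 21]})
    a = quant.impute(table, rng=np.random.default_rng(5))
    b = quant.impute(table, rng=np.random.default_rng(5))
    pd.testing.assert_frame_equal(a.values, b.values)


def test_impute_rejects_sparse_sample(rng):
    table = make_table({"a_rep1": [20.0, 21, nan, nan]})
    with pytest.raises(ValueError, match="observed values"):
        quant.impute(table, rng=rng)


def test_imputation_params_validation():
    with pytest.raises(ValueError):
        ImputationParams(width=0.0)
    with pytest.raises(ValueError):
        ImputationParams(downshift=-1.0)


# ---------------------------------------------------------------- ratios / CV / counts
def test_replicate_pair_ratios_identity_and_shift():
    a = make_table({"c_rep1": [20.0, 21], "c_rep2": [22.0, 23]})
    same = quant.replicate_pair_ratios(a, a)
    assert (same.to_numpy() == 0).all()
    b = make_table({"c_rep1": [18.0, 19], "c_rep2": [20.0, 21]})
    assert (quant.replicate_pair_ratios(a, b).to_numpy() == 2).all()


def test_replicate_pair_ratios_skip_missing_member():
    a = make_table({"c_rep1": [20.0], "c_rep2": [21.0]})
    b = make_table({"c_rep1": [nan], "c_rep2": [20.0]})
    ratios = quant.replicate_pair_ratios(a, b)
    assert np.isnan(ratios.loc["P1", "rep1"]) and ratios.loc["P1", "rep2"] == 1.0


def test_replicate_pair_ratios_across_conditions():
    table = make_table({"tag_rep1": [22.0], "tag_rep2": [23.0],
                        "untag_rep1": [20.0], "untag_rep2": [20.0]})
    ratios = quant.replicate_pair_ratios(table.select_condition("tag"),
                                         table.select_condition("untag"))
    assert ratios.loc["P1"].tolist() == [2.0, 3.0]


def test_median_ratio_rules():
    ratios = pd.DataFrame({"rep1": [1.0, 0.5, 3.0], "rep2": [1.0, 0.5, 3.0],
                           "rep3": [1.0, 1.5, 3.0]}, index=list("abc"))
    assert quant.median_ratio(ratios) == pytest.approx(1.0)
    # protein observed in only 2/3 pairs is excluded under the flag
    ratios.loc["b", "rep3"] = nan
    assert quant.median_ratio(ratios, require_all_replicates=True) == pytest.approx(2.0)


def test_protein_cv_values():
    table = make_table({"c_rep1": [100.0, 100], "c_rep2": [100.0, 90],
                        "c_rep3": [100.0, 110]}, is_log2=False)
    cv = quant.protein_cv(table, "c")
    assert cv["P1"] == pytest.approx(0.0)
    assert cv["P2"] == pytest.approx(0.1)


def test_protein_cv_excludes_single_observation():
    table = make_table({"c_rep1": [100.0], "c_rep2": [nan], "c_rep3": [nan]},
                       is_log2=False)
    assert "P1" not in quant.protein_cv(table, "c").index


def test_count_quantified():
    table = make_table(
        {"c_rep1": [20, 20, 20, 20], "c_rep2": [20, nan, 20, 20], "c_rep3": [20, nan, 20, 20]},
        is_contaminant=[False, False, True, False],
        is_ligand=[False, False, False, True])
    counts = quant.count_quantified(table)
    assert counts["c"] == 1  # P2 single-replicate, P3 contaminant, P4 ligand


def test_count_quantified_empty_table():
    table = make_table({"c_rep1": [], "c_rep2": []})
    assert quant.count_quantified(table)["c"] == 0


def test_count_quantified_all_observed():
    values = {f"c_rep{k}": [20.0] * 10 for k in (1, 2, 3)}
    assert quant.count_quantified(make_table(values))["c"] == 10


# ---------------------------------------------------------------- ligand report
def ligand_peptide_table():
    intensities = [100.0, 80, 60, 40, 20, 10, 5]
    values = {}
    for cond, scale in (("mock", 1.0), ("acet", 0.5)):
        for rep in (1, 2):
            values[f"{cond}_rep{rep}"] = [v * scale for v in intensities]
    return make_table(values, level="peptide", is_log2=False,
                      is_ligand=[True] * 6 + [False], protein_id="nanobody")


def test_ligand_report_reference_is_one_and_halved_is_half():
    report = quant.ligand_contamination_report(ligand_peptide_table(), "mock")
    assert report["mock"] == pytest.approx(1.0)
    assert report["acet"] == pytest.approx(0.5)


def test_ligand_report_top_one_uses_most_prominent_peptide():
    table = ligand_peptide_table()
    # halve only the most abundant ligand peptide in the treated arm
    for rep in (1, 2):
        table.values.loc["P1", f"acet_rep{rep}"] = 25.0
    report = quant.ligand_contamination_report(table, "mock", top_n=1)
    assert report["acet"] == pytest.approx(0.25)


def test_ligand_report_requires_peptide_level():
    table = make_table({"c_rep1": [20.0], "c_rep2": [20.0]})
    with pytest.raises(ValueError, match="peptide-level"):
        quant.ligand_contamination_report(table, "c")


# ---------------------------------------------------------------- rollup
def test_protein_intensity_sums_peptides():
    table = make_table({"c_rep1": [10.0, 20, 30], "c_rep2": [1.0, 2, nan]},
                       level="peptide", is_log2=False,
                       protein_id=["prot", "prot", "prot"])
    protein = quant.protein_intensity_from_peptides(table)
    assert protein.values.loc["prot", "c_rep1"] == 60.0
    assert protein.values.loc["prot", "c_rep2"] == 3.0
    assert protein.meta.loc["prot", "n_peptides"] == 3


def test_shared_peptides_dropped():
    table = make_table({"c_rep1": [10.0, 20], "c_rep2": [10.0, 20]},
                       level="peptide", is_log2=False,
                       protein_id=["a;b", "a"])
    protein = quant.protein_intensity_from_peptides(table)
    assert list(protein.meta.index) == ["a"]
    assert protein.values.loc["a", "c_rep1"] == 20.0


def test_all_missing_peptides_leave_protein_missing():
    table = make_table({"c_rep1": [nan, nan], "c_rep2": [10.0, 20]},
                       level="peptide", is_log2=False, protein_id=["a", "a"])
    protein = quant.protein_intensity_from_peptides(table)
    assert np.isnan(protein.values.loc["a", "c_rep1"])


# ---------------------------------------------------------------- table contract
def test_quant_table_rejects_nonpositive_linear():
    with pytest.raises(ValueError, match="positive"):
        make_table({"c_rep1": [0.0], "c_rep2": [1.0]}, is_log2=False)


def test_quant_table_rejects_bad_sample_name():
    meta = pd.DataFrame({"protein_id": ["a"], "n_peptides": [2],
                         "is_contaminant": [False], "is_ligand": [False]})
    with pytest.raises(ValueError, match="sample column"):
        QuantTable(meta, pd.DataFrame({"sampleX": [1.0]}), "protein")
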