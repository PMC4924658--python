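"""Merging and empirical-Bayes batch correction: recovery and invariants."""

import numpy as np
import pandas as pd
import pytest

from sigdriver import (BatchEffectModel, ExpressionCohort, SimulationConfig,
                       batch_mean_contrast, correct_batch_effects,
                       merge_on_shared_genes, simulate_multistudy_expression)
from sigdriver.exceptions import MergeError


def _toy_cohort(genes, values, studies, groups, prefix="S"):
    ids = [f"{prefix}{i}" for i in range(len(studies))]
    return ExpressionCohort(
        pd.DataFrame(values, index=genes, columns=ids),
        pd.DataFrame({"study": studies, "group": groups},
                     index=pd.Index(ids, name="sample_id")))


# -- merging -----------------------------------------------------------------

def test_merge_intersects_genes_sorted():
    a = _toy_cohort(["A", "B", "C"], np.zeros((3, 4)), ["s1"] * 4,
                    ["control", "control", "case", "case"], prefix="a")
    b = _toy_cohort(["B", "C", "D"], np.ones((3, 4)), ["s2"] * 4,
                    ["control", "control", "case", "case"], prefix="b")
    merged = merge_on_shared_genes([a, b])
    assert list(merged.gene_ids) == ["B", "C"]
    assert merged.n_samples == 8
    assert sorted(merged.batch.unique()) == ["s1", "s2"]


def test_merge_rejects_duplicate_sample_ids():
    a = _toy_cohort(["A", "B"], np.zeros((2, 4)), ["s1"] * 4,
                    ["control", "control", "case", "case"])
    b = _toy_cohort(["A", "B"], np.ones((2, 4)), ["s2"] * 4,
                    ["control", "control", "case", "case"])
    with pytest.raises(MergeError, match="duplicate"):
        merge_on_shared_genes([a, b])


def test_merge_rejects_empty_intersection():
    a = _toy_cohort(["A"], np.zeros((1, 4)), ["s1"] * 4,
                    ["control", "control", "case", "case"], prefix="a")
    b = _toy_cohort(["B"], np.ones((1, 4)), ["s2"] * 4,
                    ["control", "control", "case", "case"], prefix="b")
    with pytest.raises(MergeError, match="intersection"):
        merge_on_shared_genes([a, b])


def test_merge_recovers_shared_gene_count_from_generator():
    cohort, _ = simulate_multistudy_expression(
        SimulationConfig(n_genes=2000, seed=6))
    studies = cohort.split_by_study()
    # keep 1500 shared genes; give each study 250 private extras
    genes = list(cohort.gene_ids)
    shared = genes[:1500]
    subsets = [shared + genes[1500:1650], shared + genes[1650:1800],
               shared + genes[1800:1950]]
    trimmed = [c.subset(genes=sorted(set(g))) for c, g in zip(studies, subsets)]
    merged = merge_on_shared_genes(trimmed)
    assert merged.n_genes == 1500


# -- standardization ---------------------------------------------------------

def test_balanced_symmetric_design_gives_zero_group_effect():
    # two batches, equal group means everywhere -> beta = 0
    values = np.array([[1.0, 1.0, 1.0, 1.0, 3.0, 3.0, 3.0, 3.0]])
    cohort = _toy_cohort(["g1"], values, ["b1"] * 4 + ["b2"] * 4,
                         ["control", "case"] * 4)
    res = BatchEffectModel(cohort).fit()
    assert res.beta["g1"] == pytest.approx(0.0, abs=1e-10)


def test_constant_gene_is_floored_not_divided_by_zero():
    rngv = np.random.default_rng(0).normal(size=(1, 8))
    values = np.vstack([np.full(8, 5.0), rngv])
    cohort = _toy_cohort(["flat", "noisy"], values, ["b1"] * 4 + ["b2"] * 4,
                         ["control", "case"] * 4)
    res = BatchEffectModel(cohort).fit()
    assert "flat" in res.degenerate_genes
    assert np.isfinite(res.standardized.loc["flat"]).all()
    # the floor leaves only least-squares rounding noise in z
    assert np.allclose(res.standardized.loc["flat"], 0.0, atol=1e-4)


def test_group_effect_recovery_on_planted_signal(small_scenario, merged_cohort):
    _, truth = small_scenario
    res = BatchEffectModel(merged_cohort).fit()
    up = res.beta[truth.up_genes].mean()
    down = res.beta[truth.down_genes].mean()
    assert up == pytest.approx(1.5, abs=0.15)
    assert down == pytest.approx(-1.5, abs=0.15)


# -- shrinkage ---------------------------------------------------------------

def test_shrinkage_dominates_naive_estimator_under_null():
    cohort, _ = simulate_multistudy_expression(
        SimulationConfig(n_genes=2000, de_fraction=0.0, batch_shift_sd=0.0,
                         batch_scale_sd=0.0, seed=8))
    res = BatchEffectModel(cohort).fit()
    assert (res.gamma_star.abs().to_numpy().mean()
            < res.gamma_hat.abs().to_numpy().mean())


def test_planted_additive_shift_recovered_in_standardized_units():
    cohort, _ = simulate_multistudy_expression(
        SimulationConfig(n_genes=2000, n_studies=2,
                         controls_per_study=(10, 10),
                         cases_per_study=(10, 10), de_fraction=0.0,
                         batch_shift_sd=0.0, batch_scale_sd=0.0, seed=9))
    shifted = cohort.values.copy()
    mask = (cohort.batch == "study2").to_numpy()
    shifted.loc[:, mask] += 2.0
    cohort2 = ExpressionCohort(shifted, cohort.samples.copy())
    res = BatchEffectModel(cohort2).fit()
    # standardized truth: the shift splits into +1/-1 around the grand mean
    expected = (2.0 / res.sigma.to_numpy()) * 0.5
    recovered = res.gamma_star.loc["study2"].to_numpy()
    assert abs((recovered - expected).mean()) < 0.1


# -- correction --------------------------------------------------------------

def test_single_batch_correction_is_identity():
    cohort, _ = simulate_multistudy_expression(
        SimulationConfig(n_genes=50, n_studies=1, controls_per_study=(8,),
                         cases_per_study=(8,), seed=10))
    corrected = correct_batch_effects(cohort)
    assert np.allclose(corrected.values, cohort.values, atol=1e-8)


def test_planted_shift_removed_by_correction():
    cohort, _ = simulate_multistudy_expression(
        SimulationConfig(n_genes=2000, n_studies=2,
                         controls_per_study=(10, 10),
                         cases_per_study=(10, 10), batch_shift_sd=0.0,
                         batch_scale_sd=0.0, de_fraction=0.0, seed=11))
    shifted = cohort.values.copy()
    shifted.loc[:, (cohort.batch == "study2").to_numpy()] += 2.0
    cohort2 = ExpressionCohort(shifted, cohort.samples.copy())
    before = batch_mean_contrast(cohort2)
    after = batch_mean_contrast(correct_batch_effects(cohort2))
    assert before == pytest.approx(2.0, abs=0.1)
    assert after < 0.1


def test_batch_f_statistic_strictly_decreases():
    from scipy import stats

    def mean_batch_f(cohort):
        y = cohort.values.to_numpy()
        labels = cohort.batch.to_numpy()
        fs = []
        for row in y:
            groups = [row[labels == b] for b in np.unique(labels)]
            fs.append(stats.f_oneway(*groups).statistic)
        return float(np.mean(fs))

    for seed in range(20):
        cohort, _ = simulate_multistudy_expression(
            SimulationConfig(n_genes=100, batch_shift_sd=1.0, seed=seed))
        corrected = correct_batch_effects(cohort)
        assert mean_batch_f(corrected) < mean_batch_f(cohort)


def test_group_effect_preserved_through_correction(small_scenario,
                                                   merged_cohort):
    # the fitted case/control effect is re-added after adjustment, so the
    # planted +/-1.5 log2 signal survives correction
    _, truth = small_scenario
    corrected = correct_batch_effects(merged_cohort)

    def group_diff(c):
        return (c.values.loc[:, c.case_mask].mean(axis=1)
                - c.values.loc[:, ~c.case_mask].mean(axis=1))

    diff = group_diff(corrected)
    assert diff[truth.up_genes].mean() == pytest.approx(1.5, abs=0.15)
    assert diff[truth.down_genes].mean() == pytest.approx(-1.5, abs=0.15)
    # and no systematic shift is introduced across null genes
    null_genes = [g for g in merged_cohort.gene_ids if g not in truth.de_genes]
    delta = (diff - group_diff(merged_cohort))[null_genes]
    assert abs(delta.mean()) < 3 * delta.std(ddof=1) / np.sqrt(len(delta))


def test_correction_is_approximately_idempotent(merged_cohort):
    once = correct_batch_effects(merged_cohort)
    twice = correct_batch_effects(once)
    residual_once = batch_mean_contrast(once)
    # a second pass may not reintroduce batch signal
    assert batch_mean_contrast(twice) <= residual_once + 1e-6
    assert np.abs(twice.values.to_numpy() - once.values.to_numpy()).mean() \
        < 10 * max(residual_once, 1e-8)


def test_dimensions_conserved(merged_cohort):
    corrected = correct_batch_effects(merged_cohort)
    assert corrected.values.shape == merged_cohort.values.shape
    assert list(corrected.gene_ids) == list(merged_cohort.gene_ids)


def test_matches_reference_combat_implementation(merged_cohort):
    anndata = pytest.importorskip("anndata")
    sc = pytest.importorskip("scanpy")
    mine = BatchEffectModel(merged_cohort).fit(tol=1e-8).corrected()
    obs = merged_cohort.samples.rename(columns={"study": "batch"}).copy()
    obs["x"] = (obs["group"] == "case").astype(float)
    ad = anndata.AnnData(X=merged_cohort.values.to_numpy().T.copy(),
                         obs=obs[["batch", "x"]])
    ref = sc.pp.combat(ad, key="batch", covariates=["x"], inplace=False)
    assert np.abs(ref.T - mine.values.to_numpy()).max() < 1e-2
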