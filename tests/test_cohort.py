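"""Virtual cohort generation and the statistics pipeline."""

import numpy as np
import pytest
from scipy import stats

from cardiotwin import (CohortPriors, TruncNormal, cohort_summary,
                        grubbs_test, pearson_with_p, sample_cohort)
from cardiotwin.cohort import cohort_to_dataframe, _fast_observations


PRIORS = CohortPriors()


def test_truncated_normal_validation():
    with pytest.raises(ValueError):
        TruncNormal(0.0, -1.0)
    with pytest.raises(ValueError):
        TruncNormal(0.0, 1.0, lo=2.0, hi=1.0)


def test_sample_means_match_truncated_priors():
    patients = sample_cohort(PRIORS, n=1000, seed=1)
    for name, prior in (("c_myo", PRIORS.c_myo),
                        ("stiffness", PRIORS.stiffness),
                        ("sigma0", PRIORS.sigma0),
                        ("wk_aorta_C", PRIORS.wk_aorta_C)):
        vals = np.array([p.parameters[name] for p in patients])
        se = prior.sd / np.sqrt(len(vals))
        assert abs(vals.mean() - prior.truncated_mean) < 3 * se, name
        assert vals.min() >= prior.lo and vals.max() <= prior.hi


def test_cohort_deterministic_per_seed():
    a = sample_cohort(PRIORS, n=12, seed=7, observations="fast")
    b = sample_cohort(PRIORS, n=12, seed=7, observations="fast")
    for pa, pb in zip(a, b):
        assert pa.parameters == pb.parameters
        assert pa.covariates == pb.covariates
        assert pa.targets.m_qrsd == pb.targets.m_qrsd
    c = sample_cohort(PRIORS, n=12, seed=8)
    assert c[0].parameters != a[0].parameters


def test_zero_noise_observations_equal_forward_output():
    quiet = PRIORS.zero_noise()
    patients = sample_cohort(quiet, n=5, seed=3, observations="fast")
    for p in patients:
        obs = _fast_observations(p.parameters, p.covariates)
        assert p.targets.m_qrsd == pytest.approx(obs["m_qrsd"], abs=1e-12)
        assert p.targets.ef == pytest.approx(obs["ef"], abs=1e-12)


def test_configured_effect_sizes_are_realized():
    patients = sample_cohort(PRIORS, n=4000, seed=11)
    sigma = np.array([p.parameters["sigma0"] for p in patients])
    for name, rho in (("outcome_score", 0.77), ("ntprobnp", -0.5),
                      ("sbp_rest", 0.5)):
        cov = np.array([p.covariates[name] for p in patients])
        r, _ = pearson_with_p(sigma, cov)
        assert r == pytest.approx(rho, abs=0.05), name


def test_cohort_size_validation():
    with pytest.raises(ValueError):
        sample_cohort(PRIORS, n=0, seed=1)


# -- Pearson -----------------------------------------------------------------

def test_pearson_perfect_linear():
    x = np.arange(10.0)
    r, p = pearson_with_p(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p < 1e-30


def test_pearson_four_point_example():
    """Hand-computable case, cross-checked against the reference routine."""
    x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
    r, p = pearson_with_p(x, y)
    assert r == pytest.approx(0.6)
    r_ref, p_ref = stats.pearsonr(x, y)
    assert r == pytest.approx(r_ref)
    assert p == pytest.approx(p_ref)


def test_pearson_zero_variance_raises():
    with pytest.raises(ValueError, match="variance"):
        pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson_with_p([1.0, 2.0], [1.0, 2.0])


def test_pearson_type_one_error_calibration():
    """Independent data: p < alpha in ~alpha of seeded replicates."""
    rng = np.random.default_rng(17)
    n_rep, n = 500, 200
    hits = 0
    for _ in range(n_rep):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        hits += pearson_with_p(x, y)[1] < 0.05
    rate = hits / n_rep
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < 3.5 * se


# -- Grubbs ------------------------------------------------------------------

def test_grubbs_flags_gross_outlier():
    x = np.array([1.0, 1.1, 0.9, 8.0])
    idx, G = grubbs_test(x, alpha=0.05)
    assert idx == 3
    assert G == pytest.approx(np.max(np.abs(x - x.mean())) / x.std(ddof=1))


def test_grubbs_no_outlier_in_tight_sample():
    idx, _ = grubbs_test([1.0, 1.02, 0.98, 1.01, 0.99], alpha=0.05)
    assert idx is None


def test_grubbs_validation():
    with pytest.raises(ValueError):
        grubbs_test([1.0, 2.0])
    with pytest.raises(ValueError):
        grubbs_test([1.0, 1.0, 1.0])


def test_grubbs_false_flag_rate_near_alpha():
    rng = np.random.default_rng(23)
    n_rep = 1000
    flags = sum(grubbs_test(rng.standard_normal(40), alpha=0.05)[0]
                is not None for _ in range(n_rep))
    rate = flags / n_rep
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < 3.5 * se


# -- summaries ----------------------------------------------------------------

def test_summary_constant_and_two_value_columns():
    import pandas as pd

    df = pd.DataFrame({"const": [5.0, 5.0, 5.0], "pair": [1.0, 3.0, np.nan],
                       "label": ["a", "a", "b"]})
    summ = cohort_summary(df).set_index("field")
    assert summ.loc["const", "sd"] == 0.0
    assert summ.loc["pair", "mean"] == pytest.approx(2.0)
    assert summ.loc["pair", "sd"] == pytest.approx(np.sqrt(2.0))
    assert "a: 2" in summ.loc["label", "summary"]


def test_summary_reproduces_generator_means():
    patients = sample_cohort(PRIORS, n=1000, seed=5)
    df = cohort_to_dataframe(patients)
    summ = cohort_summary(df).set_index("field")
    for name, prior in (("true_c_myo", PRIORS.c_myo),
                        ("true_sigma0", PRIORS.sigma0)):
        se = prior.sd / np.sqrt(len(df))
        assert abs(summ.loc[name, "mean"] - prior.truncated_mean) < 3 * se


def test_empty_summary_raises():
    with pytest.raises(ValueError):
        cohort_summary([])


# -- end-to-end properties -----------------------------------------------------

def test_effect_size_recovery_within_fisher_interval():
    """At the study's sample size the estimated sigma0-outcome correlation
    falls inside the true-rho-centered 95% Fisher interval in >= 93% of
    seeded replicates."""
    rho, n, n_rep = 0.77, 39, 300
    z0 = np.arctanh(rho)
    half = 1.96 / np.sqrt(n - 3)
    inside = 0
    for rep in range(n_rep):
        patients = sample_cohort(PRIORS, n=n, seed=5000 + rep)
        s = np.array([p.parameters["sigma0"] for p in patients])
        o = np.array([p.covariates["outcome_score"] for p in patients])
        r, _ = pearson_with_p(s, o)
        inside += abs(np.arctanh(r) - z0) <= half
    assert inside / n_rep >= 0.93


def test_personalization_recovers_cohort_conductivities():
    """Noiseless virtual patients with full 3-D EP observations: the QRS
    personalization step recovers each patient's myocardial diffusivity and
    preserves the cohort ordering (scaled-down pipeline check)."""
    from cardiotwin import build_biventricular_mesh, generate_fibers
    from cardiotwin.cohort import patient_anatomy
    from cardiotwin.personalize import ClinicalTargets, EPPersonalization

    quiet = PRIORS.zero_noise()
    patients = sample_cohort(quiet, n=3, seed=21, observations="ep")
    truths, fitted = [], []
    for p in patients:
        cfg = patient_anatomy(p.parameters)
        mesh = build_biventricular_mesh(cfg, seed=21 + p.index)
        fib = generate_fibers(mesh)
        targets = ClinicalTargets(m_qrsd=p.targets.m_qrsd)
        model = EPPersonalization(targets, mesh, fib)
        res = model.fit()
        assert abs(res.residuals["qrsd_ms"]) <= 5.0
        truths.append(p.parameters["c_myo"])
        fitted.append(res.params.c_myo)
    truths, fitted = np.array(truths), np.array(fitted)
    assert np.all(np.abs(fitted - truths) / truths < 0.35)
    # the 5 ms QRS tolerance cannot rank-separate nearby diffusivities, but
    # the clearly fastest-conducting patient must be identified as such
    assert np.argmax(fitted) == np.argmax(truths)
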