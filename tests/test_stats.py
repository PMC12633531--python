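"""Cohort statistics: outliers, rank tests, co-occurrence, NB regression,
survival."""

import math

import numpy as np
import pandas as pd
import pytest

from kataegis_storm.datamodel import ClinicalRecord
from kataegis_storm.stats import (
    build_cohort_table,
    compare_groups,
    compare_many,
    driver_cooccurrence,
    flag_outliers,
    nb_burden_regression,
    percentage,
    survival_strata,
)
from tests.test_apobec import hypergeom_tail_ge


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

def test_equal_burdens_have_no_outliers():
    s = pd.Series([3, 3, 3, 3], index=list("abcd"))
    assert flag_outliers(s) == []


def test_single_pass_z_rule_on_hand_computed_cases():
    # (1,1,1,1,50): z(50) ~ 2.0 -> kept
    s5 = pd.Series([1, 1, 1, 1, 50], index=list("abcde"))
    z = (50 - s5.mean()) / s5.std(ddof=1)
    assert z < 3 and flag_outliers(s5) == []
    # 9 ones and a 50: z ~ 2.85 -> still kept (no iterative re-computation)
    s10 = pd.Series([1] * 9 + [50], index=[f"s{i}" for i in range(10)])
    assert flag_outliers(s10) == []


def test_constructed_single_outlier_is_excluded():
    s = pd.Series([1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 40],
                  index=[f"s{i}" for i in range(13)])
    z = (s - s.mean()) / s.std(ddof=1)
    assert (z > 3).sum() == 1
    assert flag_outliers(s) == ["s12"]


def test_cohort_table_flags_and_reasons():
    clin = [ClinicalRecord(f"s{i}", "AFR", 4) for i in range(12)] \
        + [ClinicalRecord("hyper", "EUR", 4)]
    counts = {f"s{i}": (i % 3) for i in range(12)}
    counts["hyper"] = 42
    table = build_cohort_table(counts, clin)
    assert bool(table.loc["hyper", "excluded_flag"])
    assert "z-score" in table.loc["hyper", "exclusion_reason"]
    assert bool(table.loc["s1", "positive"]) and not bool(table.loc["s0", "positive"])


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def test_identical_groups_p_one():
    assert compare_groups([1, 2, 3], [1, 2, 3])["p"] == 1.0


def test_exact_small_sample_p():
    # all 20 orderings of (1,2,3) vs (10,11,12): two-sided exact p = 0.1
    r = compare_groups([1, 2, 3], [10, 11, 12])
    assert r["method"] == "rank-sum-exact"
    assert r["p"] == pytest.approx(0.1)


def test_shift_alternative_power(rng):
    """One-sd shift at n=50/50 is detected essentially always."""
    hits = 0
    for _ in range(40):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        hits += compare_groups(a, b)["p"] < 0.05
    assert hits / 40 > 0.9


def test_paired_wilcoxon_and_bh_family():
    rng = np.random.default_rng(5)
    base = rng.normal(size=20)
    tests = {
        "shifted": (base + 1.0, base),
        "null": (base + rng.normal(0, 0.01, 20), base),
    }
    df = compare_many(tests, paired=True)
    assert set(df.test) == {"shifted", "null"}
    assert df.loc[df.test == "shifted", "p"].iloc[0] < 0.01
    assert (df.fdr >= df.p - 1e-12).all()


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        compare_groups([], [1.0])


# ---------------------------------------------------------------------------
# driver co-occurrence
# ---------------------------------------------------------------------------

def test_driver_fisher_matches_hypergeometric_oracle():
    # table [[10,5],[2,20]]
    samples = [f"p{i}" for i in range(37)]
    pos = {s: i < 15 for i, s in enumerate(samples)}
    mutated = [True] * 10 + [False] * 5 + [True] * 2 + [False] * 20
    presence = pd.DataFrame({"GENE": mutated}, index=samples)
    res = driver_cooccurrence(pos, presence)
    r = res.iloc[0]
    assert r.table == ((10, 5), (2, 20))
    from scipy.stats import fisher_exact
    _, expected = fisher_exact(((10, 5), (2, 20)), alternative="two-sided")
    assert r.p == pytest.approx(expected)
    # one-sided tail from first principles bounds the two-sided p
    assert r.p >= hypergeom_tail_ge(10, 5, 2, 20) - 1e-12


def test_uninformative_gene_flagged():
    samples = [f"p{i}" for i in range(10)]
    pos = {s: i < 5 for i, s in enumerate(samples)}
    presence = pd.DataFrame({"NEVER": [False] * 10}, index=samples)
    res = driver_cooccurrence(pos, presence)
    assert res.iloc[0].p == 1.0 and bool(res.iloc[0].uninformative)


def test_coupled_gene_detected_among_nulls(rng):
    n = 150
    samples = [f"p{i}" for i in range(n)]
    pos = rng.random(n) < 0.4
    genes = {}
    for g in range(10):
        genes[f"null{g}"] = rng.random(n) < 0.2
    # coupled gene: odds ratio ~ 8
    p_mut = np.where(pos, 0.55, 0.12)
    genes["COUPLED"] = rng.random(n) < p_mut
    presence = pd.DataFrame(genes, index=samples)
    res = driver_cooccurrence(dict(zip(samples, pos)), presence)
    res = res.set_index("gene")
    assert res.loc["COUPLED", "fdr"] < 0.05


# ---------------------------------------------------------------------------
# NB regression
# ---------------------------------------------------------------------------

def test_intercept_only_recovers_log_mean(rng):
    y = rng.poisson(3.0, size=400)
    df = pd.DataFrame({"kataegis_count": y, "dummy": rng.normal(size=400)})
    res = nb_burden_regression(df, ["dummy"])
    assert res.params["const"] == pytest.approx(math.log(y.mean()), abs=0.05)


def test_poisson_counts_give_near_zero_dispersion(rng):
    y = rng.poisson(4.0, size=600)
    df = pd.DataFrame({"kataegis_count": y, "x": rng.normal(size=600)})
    res = nb_burden_regression(df, ["x"])
    assert res.dispersion < 0.1


def test_log1p_transform_applied_to_skewed_covariates(rng):
    n = 300
    sv = rng.lognormal(3, 1, n)
    mu = np.exp(0.1 + 0.4 * np.log1p(sv))
    y = rng.poisson(mu)
    df = pd.DataFrame({"kataegis_count": y, "sv_burden": sv})
    res = nb_burden_regression(df, ["sv_burden"], log_transform=["sv_burden"])
    assert "log1p_sv_burden" in res.params.index
    assert res.params["log1p_sv_burden"] == pytest.approx(0.4, abs=0.15)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _cohort_frame(times, events, counts):
    n = len(times)
    return pd.DataFrame({
        "sample_id": [f"p{i}" for i in range(n)],
        "kataegis_count": counts,
        "positive": [c >= 1 for c in counts],
        "followup_days": times,
        "bcr_flag": [False] * n,
        "metastasis_flag": events,
    })


def test_km_matches_hand_product_limit():
    # 6 patients, one stratum with events at t=2 (2 at risk drop) and t=4
    df = _cohort_frame([2, 3, 4, 5, 6, 7],
                       [True, False, True, False, False, False],
                       [2, 2, 2, 0, 0, 0])
    out = survival_strata(df, mode="burden_gt_1", endpoint="met_only")
    km = out["strata"]["burden>1"]["km"]
    # S(2) = 1 - 1/3; S(4) = (2/3) * (1 - 1/1) = 0 for the burden>1 stratum
    assert km[2.0] == pytest.approx(2 / 3)
    assert km[4.0] == pytest.approx(0.0)
    for s in out["strata"].values():
        vals = list(s["km"].values())
        assert vals[0] <= 1.0 + 1e-12
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def test_identical_strata_logrank_p_one():
    times = [5, 10, 15, 20] * 2
    events = [True, False, True, False] * 2
    counts = [2, 2, 2, 2, 0, 0, 0, 0]
    df = _cohort_frame(times, events, counts)
    out = survival_strata(df, mode="burden_gt_1", endpoint="met_only")
    assert out["logrank_p"] == pytest.approx(1.0)


def test_zero_event_stratum_flagged():
    df = _cohort_frame([5, 10, 15, 20], [True, True, False, False], [2, 2, 0, 0])
    df.loc[2:, "metastasis_flag"] = False
    out = survival_strata(df, mode="burden_gt_1", endpoint="met_only")
    assert out["logrank_p"] is None or out["logrank_p"] > 0


def test_met_only_excludes_bcr_without_met():
    df = _cohort_frame([5, 10, 15, 20], [False, True, False, True], [2, 0, 2, 0])
    df.loc[0, "bcr_flag"] = True  # BCR, no metastasis -> excluded
    out = survival_strata(df, mode="burden_gt_1", endpoint="met_only")
    assert out["n"] == 3


def test_hazard_ratio_three_detected(rng):
    """Exponential survival with hazard ratio 3 at n=100/100: log-rank is
    significant in nearly every replicate."""
    hits = 0
    for _ in range(25):
        t_hi = rng.exponential(300, 100)
        t_lo = rng.exponential(900, 100)
        cens = 1500
        times = np.concatenate([np.minimum(t_hi, cens), np.minimum(t_lo, cens)])
        events = np.concatenate([t_hi < cens, t_lo < cens])
        counts = [2] * 100 + [0] * 100
        df = _cohort_frame(times, list(events), counts)
        out = survival_strata(df, mode="burden_gt_1", endpoint="met_only")
        hits += out["logrank_p"] < 0.01
    assert hits / 25 >= 0.95


def test_percentage_rounds_to_printed_precision():
    assert percentage(68, 166) == 41.0
    assert percentage(413, 831, 0) == 50
    with pytest.raises(ValueError):
        percentage(1, 0)
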