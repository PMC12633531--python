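"""Cohort assembly and comparative statistics.

Covers the burden table, the single-pass z-score outlier exclusion, Wilcoxon
group comparisons with BH adjustment, driver-gene co-occurrence Fisher tests,
the negative-binomial burden regression with log1p-transformed skewed
covariates, and Kaplan-Meier / log-rank survival stratification by kataegis
positivity or elevated burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def build_cohort_table(kataegis_counts: Dict[str, int],
                       clinical: Sequence,
                       covariates: Optional[pd.DataFrame] = None,
                       outlier_z: float = 3.0) -> pd.DataFrame:
    """Assemble the per-sample burden table and flag outliers.

    ``covariates`` (optional) is indexed by sample_id with columns such as
    sv_burden, tmb, chromothripsis_burden, pga, cn_gain, telomere_length.
    Positivity is defined before exclusion; excluded rows carry a reason.
    """
    rows = []
    for c in clinical:
        count = int(kataegis_counts.get(c.sample_id, 0))
        rows.append({
            "sample_id": c.sample_id, "kataegis_count": count,
            "positive": count >= 1, "ancestry": c.ancestry, "risk": c.risk,
            "isup_gg": c.isup_gg, "psa": c.psa, "age": c.age,
            "followup_days": c.followup_days, "bcr_flag": c.bcr_flag,
            "metastasis_flag": c.metastasis_flag,
        })
    df = pd.DataFrame(rows).set_index("sample_id", drop=False)
    if covariates is not None:
        df = df.join(covariates, how="left")
    df["excluded_flag"] = False
    df["exclusion_reason"] = ""
    outliers = flag_outliers(df["kataegis_count"], outlier_z)
    df.loc[outliers, "excluded_flag"] = True
    df.loc[outliers, "exclusion_reason"] = f"burden z-score > {outlier_z:g}"
    return df.sort_index()


def flag_outliers(burdens: pd.Series, z_threshold: float = 3.0) -> List[str]:
    """Samples whose burden z-score exceeds the threshold (single pass on the
    raw vector; no iterative re-computation).  Zero variance -> no outliers."""
    x = burdens.astype(float)
    if len(x) < 2:
        return []
    sd = float(x.std(ddof=1))
    if sd == 0:
        return []
    z = (x - x.mean()) / sd
    return list(x.index[z > z_threshold])


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   paired: bool = False) -> Dict[str, float]:
    """Two-sided Wilcoxon test between two groups.

    Rank-sum for independent groups, signed-rank when paired.  Exact
    small-sample p when both n <= 25 and the data are tie-free, else the
    normal approximation with continuity and tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.all(d == 0):
            return {"statistic": float("nan"), "p": 1.0, "method": "degenerate"}
        exact = len(a) <= 25 and len(np.unique(np.abs(d[d != 0]))) == len(d[d != 0])
        res = sps.wilcoxon(a, b, zero_method="wilcox", correction=not exact,
                           method="exact" if exact else "approx",
                           alternative="two-sided")
        return {"statistic": float(res.statistic), "p": float(res.pvalue),
                "method": "signed-rank-exact" if exact else "signed-rank-normal"}
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) <= 25 and len(b) <= 25 and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "method": "rank-sum-exact" if exact else "rank-sum-normal"}


def compare_many(tests: Dict[str, Tuple[Sequence[float], Sequence[float]]],
                 paired: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Run a family of two-group comparisons and BH-adjust across them."""
    rows = []
    for name, (a, b) in tests.items():
        r = compare_groups(a, b, paired=paired)
        rows.append({"test": name, **r})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], alpha=alpha, method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Driver co-occurrence
# ---------------------------------------------------------------------------

def driver_cooccurrence(positivity: Dict[str, bool],
                        driver_presence: pd.DataFrame,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sided Fisher tests of kataegis positivity x driver
    mutation, BH across genes.

    ``driver_presence`` is a boolean DataFrame indexed by sample with one
    column per gene.  Odds ratios use the Haldane 0.5 correction when a
    margin is zero; genes mutated in no sample get p = 1, flagged.
    """
    samples = [s for s in driver_presence.index if s in positivity]
    pos = np.array([positivity[s] for s in samples], dtype=bool)
    rows = []
    for gene in driver_presence.columns:
        mut = driver_presence.loc[samples, gene].astype(bool).to_numpy()
        a = int((pos & mut).sum())
        b = int((pos & ~mut).sum())
        c = int((~pos & mut).sum())
        d = int((~pos & ~mut).sum())
        if mut.sum() == 0:
            rows.append({"gene": gene, "table": ((a, b), (c, d)),
                         "odds_ratio": float("nan"), "p": 1.0,
                         "uninformative": True})
            continue
        _, p = sps.fisher_exact(((a, b), (c, d)), alternative="two-sided")
        if min(a + b, c + d, a + c, b + d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append({"gene": gene, "table": ((a, b), (c, d)),
                     "odds_ratio": float(odds), "p": float(p),
                     "uninformative": False})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], alpha=alpha, method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Negative binomial burden regression
# ---------------------------------------------------------------------------

@dataclass
class NbRegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    dispersion: float  # NB2 alpha: Var = mu + alpha * mu^2
    n_obs: int
    converged: bool


def _fit_ok(fit) -> bool:
    if fit.mle_retvals.get("converged", False):
        return True
    grad = fit.mle_retvals.get("gopt")
    return grad is not None and float(np.max(np.abs(grad))) < 1e-3


def nb_burden_regression(cohort: pd.DataFrame,
                         covariates: Sequence[str],
                         log_transform: Sequence[str] = (),
                         count_col: str = "kataegis_count") -> NbRegressionResult:
    """Negative binomial (NB2, log link) regression of kataegis burden.

    Skewed covariates listed in ``log_transform`` enter as log(1 + x) so
    zero burdens are tolerated; categorical ancestry/risk columns are
    dummy-coded.  Excluded samples and rows with missing covariates are
    dropped before fitting.
    """
    import statsmodels.api as sm

    df = cohort.copy()
    if "excluded_flag" in df.columns:
        df = df[~df["excluded_flag"]]
    cols = [count_col] + list(covariates)
    df = df[cols].dropna()
    if len(df) < len(covariates) + 2:
        raise ValueError("too few complete rows for the requested model")
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        elif c in log_transform:
            X[f"log1p_{c}"] = np.log1p(col.astype(float))
        else:
            X[c] = col.astype(float)
    X = sm.add_constant(X, has_constant="add")
    y = df[count_col].astype(float)
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    try:
        fit = model.fit(disp=False, maxiter=200)
    except Exception as exc:
        raise RuntimeError(f"negative binomial fit failed: {exc}") from exc
    if not _fit_ok(fit):
        # Poisson-like data pushes alpha to its boundary; a derivative-free
        # polish usually settles it
        fit = model.fit(disp=False, method="nm", maxiter=2000,
                        start_params=fit.params)
        if not _fit_ok(fit):
            raise RuntimeError(
                f"negative binomial fit did not converge: {fit.mle_retvals}")
    keep = [c for c in fit.params.index if c != "alpha"]
    ci = fit.conf_int()
    ci.columns = ["lo", "hi"]
    return NbRegressionResult(
        params=fit.params[keep], bse=fit.bse[keep], pvalues=fit.pvalues[keep],
        conf_int=ci.loc[keep], dispersion=float(fit.params["alpha"]),
        n_obs=int(fit.nobs), converged=True,
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def survival_strata(cohort: pd.DataFrame,
                    mode: str = "burden_gt_1",
                    endpoint: str = "met_only",
                    burden_split: int = 1) -> Dict[str, object]:
    """Kaplan-Meier curves and the two-group log-rank test.

    mode 'positivity' splits by kataegis presence; 'burden_gt_1' by count
    above/below ``burden_split``.  Endpoint 'bcr_or_met' uses BCR and/or
    metastasis; 'met_only' uses metastasis, with BCR-without-metastasis
    patients excluded.  Excluded (outlier) samples are dropped first.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = cohort.copy()
    if "excluded_flag" in df.columns:
        df = df[~df["excluded_flag"]]
    df = df[df["followup_days"].notna()]
    bcr = df["bcr_flag"].fillna(False).astype(bool)
    met = df["metastasis_flag"].fillna(False).astype(bool)
    if endpoint == "bcr_or_met":
        event = (bcr | met).astype(int)
    elif endpoint == "met_only":
        df = df[~(bcr & ~met)]
        event = df["metastasis_flag"].fillna(False).astype(bool).astype(int)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if mode == "positivity":
        stratum = df["positive"].astype(bool)
        labels = ("kataegis+", "kataegis-")
    elif mode == "burden_gt_1":
        stratum = df["kataegis_count"] > burden_split
        labels = (f"burden>{burden_split}", f"burden<={burden_split}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    t = df["followup_days"].astype(float)
    out: Dict[str, object] = {"mode": mode, "endpoint": endpoint,
                              "n": int(len(df)), "strata": {}}
    fitters = {}
    for flag, label in ((True, labels[0]), (False, labels[1])):
        mask = stratum == flag
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=event[mask], label=label)
        fitters[label] = kmf
        out["strata"][label] = {
            "n": int(mask.sum()), "n_events": int(event[mask].sum()),
            "km": kmf.survival_function_.iloc[:, 0].to_dict(),
        }
    if len(fitters) < 2 or any(s["n_events"] == 0 for s in out["strata"].values()):
        out["logrank_p"] = None
        out["note"] = "a stratum has zero endpoint events; p undefined"
        return out
    res = logrank_test(t[stratum], t[~stratum],
                       event_observed_A=event[stratum],
                       event_observed_B=event[~stratum])
    out["logrank_p"] = float(res.p_value)
    out["logrank_statistic"] = float(res.test_statistic)
    return out


def percentage(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded to the printed precision (e.g. 68/166 -> 41.0)."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, digits)
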