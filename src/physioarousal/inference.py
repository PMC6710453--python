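"""Dual-frame inference: t-tests with FDR correction and JZS Bayes factors.

Every (parameter, segment) analysis cell is tested twice: a one-sample t on
the baseline-change scores pooled over conditions (within-subject family)
and a pooled-variance two-sample t comparing the MS and DPS groups
(between-subject family).  p values are corrected over the joint family by
the Benjamini-Hochberg step-up false-discovery-rate procedure.

Alongside, each t statistic is converted to a default Bayes factor under the
Jeffreys-Zellner-Siow prior: a Cauchy prior with scale ``r`` on the
standardized effect size, equivalently a normal prior whose variance g
carries an inverse-gamma(1/2, r^2/2) hyperprior.  The Bayes factor is

    B10 = integral_0^inf (1+Ng)^(-1/2) (1 + t^2/((1+Ng) v))^(-(v+1)/2) pi(g) dg
          -----------------------------------------------------------------
                          (1 + t^2/v)^(-(v+1)/2)

with effective sample size N (n for one-sample designs, n1*n2/(n1+n2) for
two-sample) and df v, evaluated by adaptive quadrature on a mapped finite
interval.  B > 3 is read as moderate evidence for the alternative, B < 1/3
for the null, anything between as inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from statsmodels.stats.multitest import multipletests

from .design import analysis_cells
from .impute import ImputedStack, pool_rubin

__all__ = [
    "TestResult", "one_sample_test", "two_sample_test", "two_sample_from_stats",
    "jzs_bf_one_sample", "jzs_bf_two_sample", "fdr_adjust", "classify_evidence",
    "evidence_summary", "analyze_study", "sensitivity_mdes", "t_test_power",
    "BF_ALTERNATIVE", "BF_NULL",
]

BF_ALTERNATIVE = 3.0
BF_NULL = 1.0 / 3.0

DEFAULT_JZS_SCALE = 1.0


@dataclass
class TestResult:
    family: str       # "within" | "between"
    parameter: str
    segment: str
    estimate: float   # mean (difference), parameter units
    se: float
    t: float
    df: float
    p: float
    bf: float
    q: float = np.nan
    evidence: str = ""


# ---------------------------------------------------------------------------
# frequentist tests

def one_sample_test(scores) -> dict:
    """Mean, SE, t, df, two-sided p for one cell's change scores."""
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        return dict(estimate=np.nan, se=np.nan, t=np.nan, df=np.nan, p=np.nan, n=n)
    est = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(n))
    if se == 0:
        t = 0.0 if est == 0 else np.inf * np.sign(est)
    else:
        t = est / se
    p = float(2 * stats.t.sf(abs(t), n - 1)) if np.isfinite(t) else 0.0
    return dict(estimate=est, se=se, t=float(t), df=float(n - 1), p=p, n=n)


def two_sample_test(scores, labels, groups=("MS", "DPS")) -> dict:
    """Pooled-variance two-sample t (group1 - group2), df = n1 + n2 - 2."""
    x = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    ok = np.isfinite(x)
    a, b = x[ok & (lab == groups[0])], x[ok & (lab == groups[1])]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        return dict(estimate=np.nan, se=np.nan, t=np.nan, df=np.nan, p=np.nan,
                    n1=n1, n2=n2)
    return two_sample_from_stats(np.mean(a), np.std(a, ddof=1), n1,
                                 np.mean(b), np.std(b, ddof=1), n2)


def two_sample_from_stats(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> dict:
    """Pooled-variance two-sample t from summary statistics."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    est = float(mean1 - mean2)
    t = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return dict(estimate=est, se=se, t=float(t), df=float(df), p=p, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# JZS Bayes factors

def _jzs_b10(t: float, n_eff: float, df: float, scale: float) -> float:
    """Two-sided JZS Bayes factor by adaptive quadrature over g in (0, inf).

    The integration variable is mapped to u in (0, 1) via g = u/(1-u); the
    integrand is evaluated in log space for numerical range.  Failure to
    converge raises rather than silently falling back.
    """
    if n_eff < 1 or df < 1:
        raise ValueError("need effective sample size and df of at least 1")
    if scale <= 0:
        raise ValueError("prior scale must be positive")
    t2 = float(t) * float(t)
    log_r = np.log(scale)
    log_null = -(df + 1) / 2 * np.log1p(t2 / df)

    def integrand(u: float) -> float:
        g = u / (1.0 - u)
        if g <= 0:
            return 0.0
        log_f = (-0.5 * np.log1p(n_eff * g)
                 - (df + 1) / 2 * np.log1p(t2 / ((1.0 + n_eff * g) * df))
                 + log_r - 0.5 * np.log(2 * np.pi)
                 - 1.5 * np.log(g) - scale * scale / (2.0 * g)
                 - log_null)
        return np.exp(log_f) / (1.0 - u) ** 2

    val, err = integrate.quad(integrand, 0.0, 1.0, epsabs=0.0, epsrel=1e-10,
                              limit=300)
    if not np.isfinite(val) or val <= 0 or err > 1e-6 * val:
        raise RuntimeError(f"JZS quadrature failed to converge (t={t}, n={n_eff})")
    return float(val)


def jzs_bf_one_sample(t: float, n: int, scale: float = DEFAULT_JZS_SCALE) -> float:
    """One-sample/paired JZS Bayes factor (alternative over null), two-sided."""
    if n < 2:
        raise ValueError("one-sample Bayes factor requires n >= 2")
    return _jzs_b10(t, n, n - 1, scale)


def jzs_bf_two_sample(t: float, n1: int, n2: int,
                      scale: float = DEFAULT_JZS_SCALE) -> float:
    """Two-sample JZS Bayes factor with effective N = n1*n2/(n1+n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("two-sample Bayes factor requires n1, n2 >= 2")
    return _jzs_b10(t, n1 * n2 / (n1 + n2), n1 + n2 - 2, scale)


# ---------------------------------------------------------------------------
# multiplicity and evidence classification

def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """FDR q values over the test family.

    ``bh`` (default) is the Benjamini-Hochberg step-up procedure.  ``storey``
    additionally estimates the null proportion pi0 from the p-value histogram
    (an empirical-null flavor) and scales the BH q values by it.  NaN inputs
    propagate and do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return q
    q_ok = multipletests(p[ok], method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p[ok] > 0.5)) / 0.5) if ok.sum() else 1.0
        q_ok = np.minimum(q_ok * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method: {method}")
    q[ok] = q_ok
    return q


def classify_evidence(bf: float) -> str:
    """B > 3: 'alternative'; B < 1/3: 'null'; else 'inconclusive'."""
    if not np.isfinite(bf):
        return ""
    if bf > BF_ALTERNATIVE:
        return "alternative"
    if bf < BF_NULL:
        return "null"
    return "inconclusive"


def evidence_summary(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Family-level summary percentages and frequentist/Bayesian agreement.

    Percentages are over comparisons with a finite Bayes factor (or p value
    for the significance rates).  A disagreement is a comparison where the
    FDR-corrected significance call and the Bayes-factor alternative call
    conflict.
    """
    bf = results["bf"].to_numpy(dtype=float)
    ok_bf = np.isfinite(bf)
    n_bf = int(ok_bf.sum())
    out = {
        "n_comparisons": n_bf,
        "pct_alternative": 100.0 * np.sum(bf[ok_bf] > BF_ALTERNATIVE) / n_bf if n_bf else np.nan,
        "pct_null": 100.0 * np.sum(bf[ok_bf] < BF_NULL) / n_bf if n_bf else np.nan,
    }
    for col, key in (("p", "pct_significant_uncorrected"), ("q", "pct_significant_fdr")):
        if col in results:
            v = results[col].to_numpy(dtype=float)
            ok = np.isfinite(v)
            out[key] = 100.0 * np.sum(v[ok] < alpha) / ok.sum() if ok.any() else np.nan
        else:
            out[key] = np.nan
    if "q" in results:
        q = results["q"].to_numpy(dtype=float)
        both = np.isfinite(q) & ok_bf
        out["n_disagreements"] = int(np.sum((q[both] < alpha) != (bf[both] > BF_ALTERNATIVE)))
    return out


# ---------------------------------------------------------------------------
# study-level analysis over an imputed stack

def analyze_study(stack: ImputedStack | pd.DataFrame, condition: pd.Series,
                  scale: float = DEFAULT_JZS_SCALE,
                  fdr_method: str = "bh",
                  groups=("MS", "DPS")) -> pd.DataFrame:
    """Run both test families over every analysis cell and assemble results.

    ``stack`` is an :class:`ImputedStack` (tests run per imputation, then
    Rubin-pooled) or a single complete change-score DataFrame.  Bayes factors
    are computed from the pooled t with the full design's sample sizes; FDR
    correction spans the joint 2 x cells family.
    """
    datasets = stack.datasets if isinstance(stack, ImputedStack) else [stack]
    cols = datasets[0].columns
    n_total = len(datasets[0])
    lab = condition.loc[datasets[0].index].to_numpy()
    n1 = int(np.sum(lab == groups[0]))
    n2 = int(np.sum(lab == groups[1]))

    rows: list[TestResult] = []
    for col in cols:
        parameter, segment = col.split(":")
        per_imp = [one_sample_test(d[col]) for d in datasets]
        rows.append(_pooled_result("within", parameter, segment, per_imp,
                                   df_complete=n_total - 1,
                                   bf=lambda t: jzs_bf_one_sample(t, n_total, scale)))
        per_imp = [two_sample_test(d[col], lab, groups) for d in datasets]
        rows.append(_pooled_result("between", parameter, segment, per_imp,
                                   df_complete=n1 + n2 - 2,
                                   bf=lambda t: jzs_bf_two_sample(t, n1, n2, scale)))

    results = pd.DataFrame([vars(r) for r in rows])
    results["q"] = fdr_adjust(results["p"], method=fdr_method)
    results["evidence"] = [classify_evidence(b) for b in results["bf"]]
    return results


def _pooled_result(family: str, parameter: str, segment: str, per_imp: list[dict],
                   df_complete: float, bf) -> TestResult:
    ok = [r for r in per_imp if np.isfinite(r["t"])]
    if not ok:
        return TestResult(family, parameter, segment, np.nan, np.nan, np.nan,
                          np.nan, np.nan, np.nan)
    pooled = pool_rubin([r["estimate"] for r in ok], [r["se"] for r in ok],
                        df_complete=df_complete)
    t = pooled.estimate / pooled.se if pooled.se > 0 else 0.0
    df = pooled.df if np.isfinite(pooled.df) else df_complete
    p = float(2 * stats.t.sf(abs(t), df))
    return TestResult(family, parameter, segment, pooled.estimate, pooled.se,
                      float(t), float(df), p, bf(t))


# ---------------------------------------------------------------------------
# sensitivity (minimal detectable effect size)

def t_test_power(effect_size: float, alpha: float = 0.05, n: int | None = None,
                 n1: int | None = None, n2: int | None = None,
                 design: str = "within") -> float:
    """Two-tailed power of a t-test via the noncentral t distribution."""
    if design == "within":
        if n is None:
            raise ValueError("within design requires n")
        df, ncp = n - 1, effect_size * np.sqrt(n)
    elif design == "between":
        if n1 is None or n2 is None:
            raise ValueError("between design requires n1 and n2")
        df, ncp = n1 + n2 - 2, effect_size * np.sqrt(n1 * n2 / (n1 + n2))
    else:
        raise ValueError("design must be 'within' or 'between'")
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    val = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(val):  # extreme noncentrality overflows scipy's nct
        val = stats.norm.sf(t_crit - ncp) + stats.norm.cdf(-t_crit - ncp)
    return float(val)


def sensitivity_mdes(design: str = "within", alpha: float = 0.05,
                     power: float = 0.80, n: int | None = None,
                     n1: int | None = None, n2: int | None = None,
                     tol: float = 1e-4) -> float:
    """Minimal detectable effect size (dz within, Cohen d between).

    The smallest standardized effect whose two-tailed noncentral-t power
    reaches ``power`` at ``alpha``, root-found to ``tol``.
    """
    if not (0 < alpha < 1 and alpha < power < 1):
        raise ValueError("require 0 < alpha < power < 1")
    f = lambda es: t_test_power(es, alpha=alpha, n=n, n1=n1, n2=n2, design=design) - power
    return float(optimize.brentq(f, 1e-6, 10.0, xtol=tol))
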