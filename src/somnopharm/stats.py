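"""Group-level inference for within-subject drug designs.

The toolkit mirrors the standard sleep-pharmacology workflow: a one-way
repeated-measures ANOVA across treatment conditions with Greenhouse-Geisser
(GG) sphericity correction (fractional degrees of freedom), Dunnett-adjusted
many-to-one post hoc comparisons against the reference (saline) condition
gated on a significant main effect, paired t-tests (one- or two-tailed),
paired Cohen's d, Benjamini-Hochberg FDR adjustment, and noncentral-t power
and sample-size calculations for the paired test.

Conventions: paired Cohen's d is mean(diff)/sd(diff), which satisfies the
identity d = t/sqrt(n) for the paired t statistic. Incomplete designs (not
every animal received every dose) fall back to a REML mixed model with a
random animal intercept; that path is an approximation, the exact contract
is the complete-case sums-of-squares decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hypnogram import ParameterError, SomnopharmError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# paired t and effect size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedEffect:
    t: float
    df: int
    p: float
    d: float          # paired Cohen's d, sign = direction of (x - y)
    side: str


def cohens_d_paired(diffs: np.ndarray) -> float:
    """Paired Cohen's d: mean of within-subject differences over their SD."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ParameterError("paired Cohen's d needs at least 2 differences")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ParameterError("paired Cohen's d undefined: zero-variance differences")
    return float(diffs.mean() / sd)


def paired_t(x: np.ndarray, y: np.ndarray, side: str = "two-sided") -> PairedEffect:
    """Classical paired t-test of x vs y with paired Cohen's d.

    ``side`` is 'two-sided', 'greater' (x > y) or 'less'. Zero-variance
    differences make t undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ParameterError("paired t needs two equal-length samples of size >= 2")
    diffs = x - y
    if diffs.std(ddof=1) == 0:
        raise ParameterError(
            "paired t undefined: all within-subject differences are identical"
        )
    res = sps.ttest_rel(x, y, alternative=side)
    return PairedEffect(
        float(res.statistic), x.size - 1, float(res.pvalue), cohens_d_paired(diffs), side
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with GG correction / mixed-model fallback
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RMModelResult:
    F: float
    df1: float        # epsilon-corrected, possibly fractional
    df2: float
    p: float
    epsilon: float    # GG epsilon in [1/(k-1), 1]; NaN on the mixed-model path
    k: int
    n_complete: int
    n_total: int
    method: str       # 'rm_anova_gg' or 'mixedlm_reml'


def _as_wide(values) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        return values.astype(float)
    return pd.DataFrame(np.asarray(values, dtype=float))


def rm_anova_gg(values) -> RMModelResult:
    """Main effect of condition in an animal x condition matrix.

    ``values`` is a wide frame/array, one row per animal, one column per
    condition; NaN marks missing cells. With complete data this is a one-way
    repeated-measures ANOVA whose degrees of freedom are multiplied by the
    Greenhouse-Geisser epsilon estimated from the within-subject covariance,
    so reported dfs are fractional. With missing cells it becomes a REML
    mixed model with a random animal intercept and an approximate
    denominator df (n_obs - n_animals - (k-1)); exact agreement with any
    particular mixed-model implementation is not promised.
    """
    wide = _as_wide(values)
    k = wide.shape[1]
    if k < 2:
        raise ParameterError("repeated-measures ANOVA needs >= 2 conditions")
    if wide.notna().sum(axis=0).eq(0).any():
        raise ParameterError("a condition with no observations cannot be tested")
    complete = wide.dropna()
    n_total = int(wide.notna().any(axis=1).sum())
    usable = wide.loc[wide.notna().sum(axis=1) >= 2]
    if len(usable) < 3:
        raise SomnopharmError("need >= 3 animals with >= 2 conditions")
    if len(complete) == n_total:
        return _rm_anova_complete(complete)
    return _mixed_model(wide, n_total, len(complete))


def _rm_anova_complete(wide: pd.DataFrame) -> RMModelResult:
    import pingouin as pg

    n, k = wide.shape
    long = wide.stack().rename("value").reset_index()
    long.columns = ["animal", "condition", "value"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(
            data=long, dv="value", within="condition", subject="animal",
            correction=True, detailed=True,
        )
    row = aov.iloc[0]
    F = float(row["F"])
    if not math.isfinite(F):  # zero within-subject variance (identical columns)
        F = 0.0
    eps = 1.0 if k == 2 else float(row["eps"])
    if not math.isfinite(eps):
        eps = 1.0
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    p = float(sps.f.sf(F, df1, df2)) if F > 0 else 1.0
    return RMModelResult(F, df1, df2, p, eps, k, n, n, "rm_anova_gg")


def _mixed_model(wide: pd.DataFrame, n_total: int, n_complete: int) -> RMModelResult:
    import statsmodels.formula.api as smf

    long = wide.stack().rename("value").reset_index()
    long.columns = ["animal", "condition", "value"]
    long["condition"] = long["condition"].astype(str)
    k = wide.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("value ~ C(condition)", long, groups=long["animal"]).fit(reml=True)
    names = [nm for nm in fit.params.index if nm.startswith("C(condition)")]
    L = np.zeros((len(names), len(fit.params)))
    for i, nm in enumerate(names):
        L[i, list(fit.params.index).index(nm)] = 1.0
    wald = fit.wald_test(L, scalar=True)
    chi2 = float(np.squeeze(wald.statistic))
    df1 = float(len(names))
    df2 = float(len(long) - long["animal"].nunique() - len(names))
    F = chi2 / df1
    p = float(sps.f.sf(F, df1, df2))
    return RMModelResult(F, df1, df2, p, math.nan, k, n_complete, n_total, "mixedlm_reml")


# ---------------------------------------------------------------------------
# Dunnett many-to-one adjustment (paired statistics, rho = 1/2)
# ---------------------------------------------------------------------------

def dunnett_sf_two_sided(t: float, m: int, df: int) -> float:
    """P(max_i |T_i| >= t) for m equicorrelated (rho=1/2) t statistics.

    This is the classical Dunnett two-sided tail: comparison statistics that
    share the reference condition are equicorrelated at 1/2. Evaluated by
    double Gauss quadrature over the shared normal factor and the chi
    mixing variable of the multivariate t.
    """
    if m < 1 or df < 1:
        raise ParameterError("Dunnett adjustment needs m >= 1 comparisons, df >= 1")
    if t <= 0:
        return 1.0
    gh_x, gh_w = np.polynomial.hermite.hermgauss(80)
    g = gh_x * math.sqrt(2.0)             # nodes for N(0,1)
    wg = gh_w / math.sqrt(math.pi)
    # u = sqrt(chi2_df / df): integrate over quantiles of its distribution
    leg_x, leg_w = np.polynomial.legendre.leggauss(96)
    qs = 0.5 * (leg_x + 1.0)
    wq = 0.5 * leg_w
    u = np.sqrt(sps.chi2.ppf(qs, df) / df)
    c = t * u[:, None] * math.sqrt(2.0)   # (nq, 1) against g (ngh,)
    inner = sps.norm.cdf(c - g) - sps.norm.cdf(-c - g)
    prob_all = (wq * ((inner ** m) @ wg)).sum()
    return float(min(max(1.0 - prob_all, 0.0), 1.0))


def dunnett_vs_reference(
    values, ref, main_effect: RMModelResult | None = None, alpha: float = ALPHA
) -> pd.DataFrame:
    """Dunnett-adjusted paired comparisons of each condition against ``ref``.

    ``values`` is the animal x condition wide frame. Comparisons are run only
    when the repeated-measures main effect is significant at ``alpha``
    (computed here if ``main_effect`` is not supplied); otherwise every row is
    marked ``tested=False`` with NaN adjusted p. Each comparison uses the
    animals providing both conditions; the adjusted p is the two-sided
    max-|t| tail with m = k-1 comparisons and is never below the raw p.
    """
    wide = _as_wide(values)
    if ref not in wide.columns:
        raise ParameterError(f"reference condition {ref!r} not among columns")
    others = [c for c in wide.columns if c != ref]
    if not others:
        raise ParameterError("nothing to compare: only the reference condition present")
    if main_effect is None:
        main_effect = rm_anova_gg(wide)
    gate = main_effect.p < alpha
    m = len(others)
    rows = []
    for cond in others:
        pair = wide[[cond, ref]].dropna()
        n = len(pair)
        if not gate or n < 2:
            rows.append({"condition": cond, "n_pairs": n, "t": math.nan, "df": math.nan,
                         "p_raw": math.nan, "p_adj": math.nan, "d": math.nan,
                         "tested": False})
            continue
        try:
            eff = paired_t(pair[cond].to_numpy(), pair[ref].to_numpy(), side="two-sided")
        except ParameterError:
            rows.append({"condition": cond, "n_pairs": n, "t": math.nan, "df": n - 1,
                         "p_raw": math.nan, "p_adj": math.nan, "d": math.nan,
                         "tested": False})
            continue
        p_adj = eff.p if m == 1 else max(
            dunnett_sf_two_sided(abs(eff.t), m, eff.df), eff.p
        )
        rows.append({"condition": cond, "n_pairs": n, "t": eff.t, "df": eff.df,
                     "p_raw": eff.p, "p_adj": p_adj, "d": eff.d, "tested": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple testing and power
# ---------------------------------------------------------------------------

def bh_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags at ``q``, adjusted p)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, bool), pvals
    if np.isnan(pvals).any() or (pvals < 0).any() or (pvals > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def paired_t_power(d: float, n: int, alpha: float = ALPHA, side: str = "one-sided") -> float:
    """Power of the paired t-test at effect size ``d`` with ``n`` pairs.

    Uses the noncentral t distribution with ncp = d*sqrt(n) and df = n-1.
    """
    if n < 2:
        return 0.0
    df = n - 1
    ncp = d * math.sqrt(n)
    if side == "one-sided":
        crit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(crit, df, ncp))
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def paired_t_sample_size(
    d: float, alpha: float = ALPHA, power: float = 0.9, side: str = "one-sided",
    n_max: int = 10_000,
) -> int:
    """Smallest number of pairs giving the paired t-test at least ``power``."""
    if d <= 0:
        raise ParameterError("effect size d must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ParameterError("alpha and power must lie strictly in (0, 1)")
    for n in range(2, n_max + 1):
        if paired_t_power(d, n, alpha, side) >= power:
            return n
    raise SomnopharmError(f"requested power not attainable with n <= {n_max}")
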