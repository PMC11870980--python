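"""Group-comparison battery for HRF parameter tables.

Frequentist tests (pooled-variance Student's t, paired t, Levene,
Mann-Whitney U, Pearson r with Fisher-z interval) alongside the
default JZS Bayes factor for independent-samples t tests.  The
per-parameter pipeline mirrors the study protocol: Levene's test on
each parameter gates the choice between Student's t and Mann-Whitney
(alpha = 0.05), the Bayes factor is always computed from the pooled t
statistic, and no multiple-comparison correction is applied because
the parameters are strongly interdependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import ConfigurationError, DataError

__all__ = [
    "StatsConfig", "TestResult", "t_test_independent", "t_test_paired",
    "jzs_bf10", "mann_whitney_u", "levene_test", "pearson_r_ci",
    "dprime", "compare_groups",
]

#: largest combined sample for which the Mann-Whitney p is exact
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class StatsConfig:
    bf_prior_scale: float = 0.707
    alpha: float = 0.05            # Levene gate and t tests
    mw_alpha: float = 0.025        # two-tailed Mann-Whitney threshold
    multiple_comparison: str = "none"

    def __post_init__(self) -> None:
        if self.bf_prior_scale <= 0:
            raise ConfigurationError("bf_prior_scale must be positive")
        if self.multiple_comparison != "none":
            raise ConfigurationError("only multiple_comparison='none' is supported")


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float | None
    p_two_sided: float
    ci95: tuple[float, float] | None = None
    effect_size: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _as_sample(x, min_n: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < min_n:
        raise DataError(f"{name} needs at least {min_n} observations")
    if not np.all(np.isfinite(a)):
        raise DataError(f"{name} contains non-finite values")
    return a


def t_test_independent(x, y) -> TestResult:
    """Pooled-variance (Student's) two-sample t test, two-sided."""
    x = _as_sample(x, 2, "t_test_independent")
    y = _as_sample(y, 2, "t_test_independent")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if np.isclose(x.mean(), y.mean()):
            return TestResult("student_t", 0.0, df, 1.0)
        raise DataError("zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    d = (x.mean() - y.mean()) / math.sqrt(sp2)
    return TestResult("student_t", float(t), df, float(p),
                      effect_size={"cohen_d": float(d)})


def t_test_paired(x, y) -> TestResult:
    """Paired t test with the 95% CI of the mean difference.

    Two effect sizes are reported because conventions differ: ``d_z``
    standardizes by the SD of the differences, ``cohen_d`` by the
    pooled SD of the two conditions.
    """
    x = _as_sample(x, 2, "t_test_paired")
    y = _as_sample(y, 2, "t_test_paired")
    if x.size != y.size:
        raise DataError("paired samples must have equal length")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult("paired_t", 0.0, n - 1, 1.0, ci95=(0.0, 0.0))
        raise DataError("zero difference variance with nonzero mean difference")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    half = tcrit * sd / math.sqrt(n)
    pooled_sd = math.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
    eff = {"d_z": float(d.mean() / sd)}
    if pooled_sd > 0:
        eff["cohen_d"] = float(d.mean() / pooled_sd)
    return TestResult("paired_t", float(t), df, float(p),
                      ci95=(float(d.mean() - half), float(d.mean() + half)),
                      effect_size=eff)


def jzs_bf10(t: float, n1: int, n2: int, prior_scale: float = 0.707) -> float:
    """Default JZS Bayes factor for an independent-samples t test.

    Evidence for a group difference given the observed t statistic,
    under a Cauchy prior with the given scale on the standardized
    effect and Jeffreys prior on the variance (Zellner-Siow mixture of
    g priors).  Computed by adaptive quadrature of

        BF10 = int_0^inf (1+Ng)^(-1/2) (1 + t^2/((1+Ng) v))^(-(v+1)/2) pi(g) dg
               / (1 + t^2/v)^(-(v+1)/2)

    with N = n1 n2/(n1+n2), v = n1+n2-2 and pi(g) the
    inverse-gamma(1/2, prior_scale^2/2) density.  BF10 > 1 favors a
    difference, BF10 < 1 favors identical groups.
    """
    if not np.isfinite(t):
        raise DataError("t statistic must be finite")
    if n1 < 2 or n2 < 2:
        raise DataError("group sizes must be >= 2")
    if prior_scale <= 0:
        raise ConfigurationError("prior_scale must be positive")
    N = n1 * n2 / (n1 + n2)
    v = n1 + n2 - 2

    def integrand(g: float) -> float:
        like = (1 + N * g) ** -0.5 * (1 + t * t / ((1 + N * g) * v)) ** (-(v + 1) / 2)
        return like * stats.invgamma.pdf(g, 0.5, scale=prior_scale ** 2 / 2)

    numerator, _err = integrate.quad(integrand, 0.0, np.inf,
                                     epsrel=1e-8, epsabs=0.0, limit=200)
    denominator = (1 + t * t / v) ** (-(v + 1) / 2)
    return float(numerator / denominator)


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U test, two-sided.

    The p value is exact (full null distribution of U) for tie-free
    samples with n1 + n2 <= 12, and a tie-corrected normal
    approximation otherwise.  Both the U statistic of the first sample
    and the rank-sum W convention are reported.
    """
    x = _as_sample(x, 1, "mann_whitney_u")
    y = _as_sample(y, 1, "mann_whitney_u")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size <= EXACT_MW_LIMIT) and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    u = float(res.statistic)
    w = u + x.size * (x.size + 1) / 2.0  # rank sum of x
    return TestResult("mann_whitney_u", u, None, float(min(res.pvalue, 1.0)),
                      extra={"W": w, "exact": exact})


def levene_test(x, y, center: str = "mean") -> TestResult:
    """Levene's test for equality of spread between two groups."""
    x = _as_sample(x, 2, "levene_test")
    y = _as_sample(y, 2, "levene_test")
    if center not in ("mean", "median"):
        raise ConfigurationError("center must be 'mean' or 'median'")
    loc = np.mean if center == "mean" else np.median
    devs = [np.abs(x - loc(x)), np.abs(y - loc(y))]
    if all(np.allclose(d, 0) for d in devs):
        return TestResult("levene", 0.0, (1, x.size + y.size - 2), 1.0)
    stat, p = stats.levene(x, y, center=center)
    if not np.isfinite(stat):  # zero within-group deviation spread
        stat, p = 0.0, 1.0
    return TestResult("levene", float(stat), (1, x.size + y.size - 2), float(p))


def pearson_r_ci(x, y) -> TestResult:
    """Pearson correlation with t-based p and Fisher-z 95% CI."""
    x = _as_sample(x, 4, "pearson_r_ci")
    y = _as_sample(y, 4, "pearson_r_ci")
    if x.size != y.size:
        raise DataError("samples must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise DataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    n = x.size
    if abs(r) >= 1.0:
        ci = (float(r), float(r))
    else:
        z = math.atanh(r)
        half = 1.96 / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    return TestResult("pearson_r", float(r), n - 2, float(p), ci95=ci)


def dprime(n_hits: int, n_targets: int, n_fas: int, n_nontargets: int) -> float:
    """Signal-detection sensitivity z(HR) - z(FAR).

    Extreme rates are nudged off 0/1 by the 1/(2N) correction so the
    quantiles stay finite.
    """
    if n_targets < 1 or n_nontargets < 1:
        raise DataError("need at least one target and one non-target trial")
    if min(n_hits, n_fas) < 0 or n_hits > n_targets or n_fas > n_nontargets:
        raise DataError("counts out of range")

    def rate(k: int, n: int) -> float:
        r = k / n
        if r == 0.0:
            return 1.0 / (2 * n)
        if r == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return r

    return float(stats.norm.ppf(rate(n_hits, n_targets))
                 - stats.norm.ppf(rate(n_fas, n_nontargets)))


def compare_groups(table: pd.DataFrame, group_col: str = "group",
                   parameters: list[str] | None = None,
                   config: StatsConfig = StatsConfig()) -> pd.DataFrame:
    """Per-parameter two-group comparison report.

    For each parameter column: Levene's test decides between Student's
    t (spread not significantly different) and Mann-Whitney U; the JZS
    Bayes factor is computed from the pooled t statistic regardless of
    which frequentist test was gated in, matching the side-by-side
    frequentist/Bayesian reporting convention.  Raw p values, no
    multiplicity correction.
    """
    if group_col not in table.columns:
        raise DataError(f"missing group column {group_col!r}")
    groups = list(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups, found {len(groups)}")
    if parameters is None:
        parameters = [c for c in table.columns
                      if c != group_col
                      and pd.api.types.is_numeric_dtype(table[c])
                      and c not in ("subject",)]
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise DataError(f"missing parameter columns: {', '.join(missing)}")

    rows = []
    for param in parameters:
        sub = table[[group_col, param]].dropna()
        x = sub.loc[sub[group_col] == groups[0], param].to_numpy()
        y = sub.loc[sub[group_col] == groups[1], param].to_numpy()
        if min(x.size, y.size) < 2:
            # parameter undefined for nearly all of one group
            rows.append({"parameter": param, "test": "none",
                         "statistic": np.nan, "df": np.nan, "p": np.nan,
                         "t": np.nan, "t_p": np.nan, "bf10": np.nan,
                         "levene_p": np.nan, "n1": x.size, "n2": y.size})
            continue
        lev = levene_test(x, y)
        t_res = t_test_independent(x, y)
        bf = jzs_bf10(t_res.statistic, x.size, y.size, config.bf_prior_scale)
        if lev.p_two_sided < config.alpha:
            chosen = mann_whitney_u(x, y)
        else:
            chosen = t_res
        rows.append({
            "parameter": param,
            "test": chosen.test_name,
            "statistic": chosen.statistic,
            "df": chosen.df if chosen.df is not None else np.nan,
            "p": chosen.p_two_sided,
            "t": t_res.statistic,
            "t_p": t_res.p_two_sided,
            "bf10": bf,
            "levene_p": lev.p_two_sided,
            "n1": x.size,
            "n2": y.size,
        })
    return pd.DataFrame(rows)
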