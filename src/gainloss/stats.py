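"""Statistical engine for the crossover analysis.

Frequentist side: paired t-tests with Cohen's d (= t / sqrt(n) for a paired
design) and a 95% CI on the mean difference; two-way repeated-measures ANOVA
with partial eta-squared, Mauchly's sphericity test and the
Greenhouse-Geisser correction; exact binomial tests; polynomial
dose-response regression.

Bayesian side: the default two-sided JZS t-test.  Under H1 the standardised
effect delta has a Cauchy(0, r) prior (r = 0.707 by default, i.e. a 50%
prior probability that |delta| < 0.707); the Bayes factor is the ratio of
marginal likelihoods of the observed t statistic,

    BF10 = ∫ T_{n-1}(t; delta*sqrt(n)) Cauchy(delta; 0, r) d(delta)
           / T_{n-1}(t; 0),

evaluated by adaptive quadrature, and reported in the null-favouring
orientation BF01 = 1/BF10.  The posterior of delta is normalised on a dense
grid to give the posterior median and central 95% credible interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import integrate, stats
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class BayesConfig:
    prior_scale: float = 0.707  # Cauchy width r
    orientation: str = "BF01"   # null-favouring by default

    def __post_init__(self) -> None:
        if self.prior_scale <= 0:
            raise ValueError("prior scale must be positive")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    ci_low: float          # 95% CI of the mean difference
    ci_high: float
    bf01: float
    posterior_median: float
    cred_low: float        # 95% credible interval of the standardised effect
    cred_high: float
    n: int

    def to_row(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "d": self.cohens_d,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "BF01": self.bf01,
            "posterior": self.posterior_median,
            "cred_low": self.cred_low, "cred_high": self.cred_high,
        }


class DegenerateInputError(ValueError):
    pass


def paired_t(x, y, bayes: BayesConfig = BayesConfig()) -> TTestResult:
    """Paired t-test on complete cases with effect sizes and JZS Bayes factor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = (x - y)[keep]
    n = len(d)
    if n < 2:
        raise DegenerateInputError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance of differences")
    se = sd / np.sqrt(n)
    t = float(d.mean() / se)
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.ppf(0.975, df)
    med, lo, hi = posterior_effect(t, n, bayes.prior_scale)
    return TTestResult(
        t=t, df=df, p=p, cohens_d=t / np.sqrt(n),
        ci_low=float(d.mean() - tcrit * se), ci_high=float(d.mean() + tcrit * se),
        bf01=jzs_bf01(t, n, bayes.prior_scale),
        posterior_median=med, cred_low=lo, cred_high=hi, n=n,
    )


def _nct_logpdf(t: float, nu: int, nc: np.ndarray) -> np.ndarray:
    """Noncentral-t log-density at ``t`` over an array of noncentralities.

    Uses the scale-mixture representation T = (Z + nc) / W with
    W = sqrt(chi2_nu / nu), integrated over W in log space — stable for the
    large nu * nc products where the library density overflows.
    """
    nc = np.asarray(nc, dtype=float)
    sd_w = 1.0 / np.sqrt(2.0 * nu)
    w = np.linspace(max(1e-6, 1.0 - 12.0 * sd_w), 1.0 + 12.0 * sd_w, 4001)
    log_fw = (np.log(2.0) + 0.5 * nu * np.log(nu / 2.0) + (nu - 1.0) * np.log(w)
              - 0.5 * nu * w ** 2 - gammaln(nu / 2.0))
    z = w[:, None] * t - nc[None, :]
    log_phi = -0.5 * np.log(2.0 * np.pi) - 0.5 * z ** 2
    integrand = np.log(w)[:, None] + log_phi + log_fw[:, None]
    dw = w[1] - w[0]
    return logsumexp(integrand, axis=0) + np.log(dw)


def _nct_pdf(t: float, nu: int, nc: np.ndarray) -> np.ndarray:
    """Noncentral-t density, preferring the library implementation and
    falling back to the stable log-space mixture when it overflows."""
    try:
        with np.errstate(all="ignore"):
            out = stats.nct.pdf(t, nu, nc)
        if np.all(np.isfinite(out)):
            return np.atleast_1d(out)
    except (OverflowError, FloatingPointError):
        pass
    return np.exp(_nct_logpdf(t, nu, np.atleast_1d(nc)))


def jzs_bf10(t: float, n: int, prior_scale: float = 0.707) -> float:
    """Two-sided JZS Bayes factor (alternative over null) by quadrature."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if prior_scale <= 0:
        raise ValueError("prior scale must be positive")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return float(_nct_pdf(t, nu, delta * sqrt_n)[0]) * stats.cauchy.pdf(delta, 0.0, prior_scale)

    num, err = integrate.quad(integrand, -np.inf, np.inf, epsrel=1e-8, limit=400)
    if not np.isfinite(num) or num <= 0 or err > 1e-4 * max(num, 1e-12):
        raise ArithmeticError(
            f"marginal-likelihood quadrature unreliable (value {num}, abserr {err})"
        )
    return float(num / stats.t.pdf(t, nu))


def jzs_bf01(t: float, n: int, prior_scale: float = 0.707) -> float:
    """Null-favouring orientation: BF01 = 1 / BF10."""
    return 1.0 / jzs_bf10(t, n, prior_scale)


def posterior_effect(
    t: float, n: int, prior_scale: float = 0.707,
    grid_half_width: float = 6.0, grid_points: int = 10001,
) -> tuple[float, float, float]:
    """Posterior median and central 95% credible interval of the standardised
    effect delta, from the normalised posterior on a dense grid."""
    if n < 2:
        raise ValueError("n must be >= 2")
    grid = np.linspace(-grid_half_width, grid_half_width, grid_points)
    dens = _nct_pdf(t, n - 1, grid * np.sqrt(n)) * stats.cauchy.pdf(grid, 0.0, prior_scale)
    total = np.trapezoid(dens, grid)
    if not np.isfinite(total) or total <= 0:
        raise ArithmeticError("posterior normalisation failed")
    cdf = integrate.cumulative_trapezoid(dens / total, grid, initial=0.0)
    med, lo, hi = np.interp([0.5, 0.025, 0.975], cdf, grid)
    return float(med), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA

@dataclass
class AnovaEffect:
    source: str
    F: float
    df1: float
    df2: float
    p: float               # GG-corrected when correction applied
    p_uncorrected: float
    partial_eta_sq: float
    mauchly_p: float | None
    gg_epsilon: float | None
    gg_applied: bool


@dataclass
class AnovaResult:
    effects: list[AnovaEffect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])

    def __getitem__(self, source: str) -> AnovaEffect:
        for e in self.effects:
            if e.source == source:
                return e
        raise KeyError(source)


def rm_anova(data: pd.DataFrame, dv: str, within: list[str], subject: str) -> AnovaResult:
    """One- or two-way fully-within ANOVA on complete cases.

    Incomplete subjects (missing any cell of the within design) are dropped
    listwise; an unbalanced residue raises with the offending subjects named.
    Greenhouse-Geisser corrected p-values replace the uncorrected ones for
    effects whose Mauchly test is significant (p < 0.05); two-level factors
    trivially satisfy sphericity (epsilon = 1).
    """
    levels = {w: sorted(data[w].unique()) for w in within}
    n_cells = int(np.prod([len(v) for v in levels.values()]))
    counts = data.dropna(subset=[dv]).groupby(subject).size()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(data[subject]) - set(complete))
    sub = data[data[subject].isin(complete)]
    if sub.empty:
        raise ValueError(f"no complete-case subjects (dropped: {dropped})")
    cell_counts = sub.groupby([subject, *within]).size()
    if (cell_counts != 1).any():
        bad = sorted({i[0] for i in cell_counts[cell_counts != 1].index})
        raise ValueError(f"design not fully crossed for subjects {bad}")

    aov = pg.rm_anova(data=sub, dv=dv, within=within, subject=subject,
                      detailed=True, effsize="np2")
    # one-way detailed output has a single DF column plus an Error row
    error_df = None
    if "ddof1" not in aov.columns:
        error_df = float(aov.loc[aov.Source.isin(("Error", "Residual")), "DF"].iloc[0])
    effects = []
    for row in aov.itertuples(index=False):
        src = row.Source
        if src in ("Residual", "Error"):
            continue
        factors = [f.strip() for f in src.split("*")]
        k_levels = int(np.prod([len(levels[f]) for f in factors if f in levels]))
        mauchly_p = None
        eps = getattr(row, "eps", 1.0)
        if k_levels <= 2:
            eps = 1.0
        gg_applied = False
        if len(factors) == 1 and k_levels > 2:
            wide = sub.pivot_table(index=subject, columns=factors[0], values=dv)
            mauchly_p = float(pg.sphericity(sub, dv=dv, subject=subject, within=factors[0]).pval) \
                if len(within) == 1 else float(pg.sphericity(wide).pval)
            gg_applied = mauchly_p < 0.05
        elif k_levels > 2:
            gg_applied = False  # interaction: GG available via eps but no Mauchly test here
        F = float(row.F)
        p_unc = float(row.p_unc)
        if not np.isfinite(F) and float(row.SS) <= 1e-9 * max(1.0, float(aov.SS.sum())):
            F, p_unc = 0.0, 1.0  # no effect variance at all: degenerate 0/0
        p_gg = float(getattr(row, "p_GG_corr", p_unc))
        df1 = float(getattr(row, "ddof1", getattr(row, "DF", np.nan)))
        df2 = float(getattr(row, "ddof2", error_df if error_df is not None else np.nan))
        effects.append(AnovaEffect(
            source=src, F=F, df1=df1, df2=df2,
            p=p_gg if gg_applied else p_unc, p_uncorrected=p_unc,
            partial_eta_sq=float(row.np2),
            mauchly_p=mauchly_p,
            gg_epsilon=float(eps) if eps is not None else None,
            gg_applied=gg_applied,
        ))
    return AnovaResult(effects)


# ---------------------------------------------------------------------------
# Binomial test and dose-response regression

def binomial_two_sided(k: int, n: int, p0: float = 0.5, method: str = "minlike") -> float:
    """Exact two-sided binomial p-value.

    ``minlike`` sums the probabilities of all outcomes no more likely than the
    observed one; ``doubling`` doubles the smaller one-sided tail (capped at 1).
    """
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if method == "minlike":
        return float(stats.binomtest(k, n, p0).pvalue)
    if method == "doubling":
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2 * min(lower, upper)))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class RegressionResult:
    degree: int
    r_squared: float
    p: float              # overall F-test
    coefficients: np.ndarray


def dose_response(dose_per_kg, outcome_difference, degree: int = 1) -> RegressionResult:
    """Least-squares polynomial regression of a drug-minus-placebo difference
    on weight-adjusted dose (mg/kg); reports r-squared and the overall p."""
    x = np.asarray(dose_per_kg, dtype=float)
    y = np.asarray(outcome_difference, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(x) <= degree + 1:
        raise ValueError(f"need more than {degree + 1} points for degree {degree}")
    if np.ptp(y) == 0:  # constant outcome: nothing to explain
        return RegressionResult(degree=degree, r_squared=0.0, p=float("nan"),
                                coefficients=np.zeros(degree + 1))
    X = sm.add_constant(np.column_stack([x ** d for d in range(1, degree + 1)]))
    fit = sm.OLS(y, X).fit()
    return RegressionResult(degree=degree, r_squared=float(fit.rsquared),
                            p=float(fit.f_pvalue), coefficients=fit.params)
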