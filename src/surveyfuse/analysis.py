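"""Regression on fused data sets, Rubin-style pooling, and reports.

Each fused data set yields one weighted linear regression of the
outcome on the exposure and the demographic covariates; the m = 5
per-grid-value coefficients are combined with the multiple-imputation
rules (within-variance Wbar, between-variance B, total
T = Wbar + (1 + 1/m) B, Rubin's small-sample degrees of freedom) even
though the fused data sets come from a sensitivity grid rather than
from repeated stochastic imputation.  The module also drives the
parameter-recovery experiment against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import COVARIATE_SETS, build_design
from .fusion import FusedDataset, fuse
from .partial_correlation import partial_corr, rho_grid
from .survey import SurveyFrame


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class CoefficientEstimate:
    """The exposure coefficient from one fused-data regression."""

    exposure: str
    outcome: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    covariate_set: str
    rho: float
    n: int

    def __post_init__(self):
        if self.se < 0:
            raise AnalysisError("standard error must be >= 0")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-combined estimate over the m fused data sets."""

    exposure: str
    outcome: str
    q_bar: float
    w_bar: float
    b: float
    t: float
    df: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int
    covariate_set: str = "full"
    n: int = 0
    per_rho: tuple = ()


def fit_outcome_model(
    fused: FusedDataset,
    outcome: str,
    exposure: str,
    covariates,
    covariate_set: str = "full",
    robust: bool = False,
) -> CoefficientEstimate:
    """Weighted least squares of the outcome on the exposure and
    covariates; the reported coefficient is the exposure's.

    Weights are the adjusted concatenation weights carried by the fused
    data set.  Classical (model-based) variance by default; ``robust``
    switches to HC1 heteroskedasticity-robust errors.
    """
    df = fused.data
    for col in [outcome, exposure]:
        if col not in df.columns:
            raise AnalysisError(f"column {col!r} not in fused data")
    X = build_design(df, covariates, fused.codebook)
    Xfull = np.column_stack([df[exposure].to_numpy(float), X])
    y = df[outcome].to_numpy(float)
    w = df["fusion_weight"].to_numpy(float)
    ok = ~(np.isnan(y) | np.isnan(Xfull).any(axis=1))
    Xfull, y, w = Xfull[ok], y[ok], w[ok]
    if len(y) <= Xfull.shape[1]:
        raise AnalysisError("too few records for the regression design")
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise AnalysisError(
            f"rank-deficient design for ({exposure}, {outcome}); "
            f"check covariates {list(covariates)}"
        )
    model = sm.WLS(y, Xfull, weights=w)
    res = model.fit(cov_type="HC1") if robust else model.fit()
    ci = res.conf_int(alpha=0.05)
    return CoefficientEstimate(
        exposure=exposure,
        outcome=outcome,
        coefficient=float(res.params[0]),
        se=float(res.bse[0]),
        ci_low=float(ci[0][0]),
        ci_high=float(ci[0][1]),
        p_value=float(res.pvalues[0]),
        covariate_set=covariate_set,
        rho=fused.rho,
        n=int(len(y)),
    )


def pool_rubin(
    estimates: list[CoefficientEstimate], df_method: str = "rubin"
) -> PooledEstimate:
    """Combine m >= 2 per-fusion estimates with the multiple-imputation
    rules.

    Qbar = mean coefficient; Wbar = mean squared SE; B = sample variance
    of the coefficients; T = Wbar + (1 + 1/m) B;
    df = (m - 1) (1 + Wbar / ((1 + 1/m) B))^2 (Rubin 1987).  When B = 0
    (identical estimates) the reference distribution degenerates to the
    normal.  ``df_method="normal"`` forces normal quantiles throughout.
    """
    if len(estimates) < 2:
        raise AnalysisError("pooling needs m >= 2 estimates")
    pairs = {(e.exposure, e.outcome, e.covariate_set) for e in estimates}
    if len(pairs) != 1:
        raise AnalysisError(f"cannot pool mixed pairs: {sorted(pairs)}")
    m = len(estimates)
    q = np.array([e.coefficient for e in estimates])
    w = np.array([e.se**2 for e in estimates])
    q_bar = float(q.mean())
    w_bar = float(w.mean())
    b = float(q.var(ddof=1))
    t = w_bar + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(t))
    if b > 0 and df_method == "rubin":
        df = (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b)) ** 2
        crit = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(q_bar) / se, df) if se > 0 else (0.0 if q_bar else 1.0)
    else:
        df = float("inf")
        crit = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(q_bar) / se) if se > 0 else (0.0 if q_bar else 1.0)
    e0 = estimates[0]
    return PooledEstimate(
        exposure=e0.exposure,
        outcome=e0.outcome,
        q_bar=q_bar,
        w_bar=w_bar,
        b=b,
        t=float(t),
        df=float(df),
        se=se,
        ci_low=float(q_bar - crit * se),
        ci_high=float(q_bar + crit * se),
        p_value=float(min(p, 1.0)),
        m=m,
        covariate_set=e0.covariate_set,
        n=e0.n,
        per_rho=tuple(estimates),
    )


def run_pair_analysis(
    A: SurveyFrame,
    B: SurveyFrame,
    exposure: str,
    outcome: str,
    anchor: float,
    covariates=None,
    covariate_set: str = "full",
    fusion_covariates=None,
    rho_mode: str = "relative",
    scheme: str = "equal-share",
    stochastic: bool = False,
    seed: int | None = None,
    df_method: str = "rubin",
) -> PooledEstimate:
    """Grid -> 5 fusions -> 5 regressions -> one pooled estimate for a
    single (exposure, outcome) pair.

    ``covariate_set``/``covariates`` control the outcome regression;
    the fusion's conditional models always adjust for
    ``fusion_covariates`` (default: the full jointly observed set), so
    covariate-sensitivity variants reuse the same imputation.
    """
    if covariates is None:
        covariates = COVARIATE_SETS[covariate_set]
    if fusion_covariates is None:
        fusion_covariates = COVARIATE_SETS["full"]
    grid = rho_grid(anchor, rho_mode)
    fused_sets, _ = fuse(
        A, B, outcome, exposure, fusion_covariates, grid,
        scheme=scheme, stochastic=stochastic, seed=seed,
    )
    fits = [
        fit_outcome_model(f, outcome, exposure, covariates, covariate_set)
        for f in fused_sets
    ]
    return pool_rubin(fits, df_method=df_method)


def sensitivity_covariates(
    A: SurveyFrame,
    B: SurveyFrame,
    exposure: str,
    outcome: str,
    anchor: float,
    rho_mode: str = "relative",
    scheme: str = "equal-share",
    stochastic: bool = False,
    seed: int | None = None,
    df_method: str = "rubin",
) -> tuple[PooledEstimate, PooledEstimate, float]:
    """Full versus reduced regression covariates (the latter omitting
    urbanicity and region) on the *same* fused data sets; returns both
    pooled estimates and their difference (reduced minus full)."""
    grid = rho_grid(anchor, rho_mode)
    fused_sets, _ = fuse(
        A, B, outcome, exposure, COVARIATE_SETS["full"], grid,
        scheme=scheme, stochastic=stochastic, seed=seed,
    )
    pooled = {}
    for covset in ("full", "reduced"):
        fits = [
            fit_outcome_model(f, outcome, exposure, COVARIATE_SETS[covset], covset)
            for f in fused_sets
        ]
        pooled[covset] = pool_rubin(fits, df_method=df_method)
    return pooled["full"], pooled["reduced"], float(
        pooled["reduced"].q_bar - pooled["full"].q_bar
    )


# ------------------------------------------------------------------ reports


def make_report(pooled: list[PooledEstimate]) -> pd.DataFrame:
    """Per-outcome report rows: exposure, coefficient, 95% CI, P.

    Returns a tidy frame (one row per exposure-outcome pair) from which
    the per-outcome tables of the published layout are slices.
    """
    rows = [
        {
            "outcome": p.outcome,
            "exposure": p.exposure,
            "coefficient": p.q_bar,
            "ci_low": p.ci_low,
            "ci_high": p.ci_high,
            "p_value": p.p_value,
            "covariate_set": p.covariate_set,
            "m": p.m,
            "n": p.n,
        }
        for p in pooled
    ]
    cols = [
        "outcome", "exposure", "coefficient", "ci_low", "ci_high",
        "p_value", "covariate_set", "m", "n",
    ]
    return pd.DataFrame(rows, columns=cols)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable per-outcome tables (coefficient, 95% CI, P)."""
    if report.empty:
        return "(no estimates)\n"
    lines = []
    for outcome, grp in report.groupby("outcome", sort=False):
        lines.append(f"Outcome: {outcome}")
        lines.append(f"  {'Exposure':<26} {'Coef':>8}  {'95% CI':>18}  {'P':>7}")
        for _, r in grp.iterrows():
            p = "<.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
            lines.append(
                f"  {r.exposure:<26} {r.coefficient:>8.3f}  "
                f"[{r.ci_low:>7.3f}, {r.ci_high:>7.3f}]  {p:>7}"
            )
        lines.append("")
    return "\n".join(lines)


# -------------------------------------------------------- recovery experiment


@dataclass
class RecoveryReport:
    """Pooled-estimate recovery against generator truth over replications."""

    exposure: str
    outcome: str
    true_beta: float
    estimates: list[float] = field(default_factory=list)
    rel_bias: list[float] = field(default_factory=list)
    covered: list[bool] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        return float(np.mean(self.covered)) if self.covered else float("nan")

    @property
    def mean_estimate(self) -> float:
        return float(np.mean(self.estimates)) if self.estimates else float("nan")

    def frac_within_rel_bias(self, tol: float) -> float:
        return float(np.mean([abs(r) <= tol for r in self.rel_bias]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposure,
                "outcome": self.outcome,
                "true_beta": self.true_beta,
                "estimate": self.estimates,
                "rel_bias": self.rel_bias,
                "ci_covers_truth": self.covered,
            }
        )


def fused_partial_corr(fused: FusedDataset, covariates) -> float:
    """Sample partial correlation of Y and Z given X in a fused data set."""
    df = fused.data
    X = build_design(df, covariates, fused.codebook)
    y = df[fused.y_col].to_numpy(float)
    z = df[fused.z_col].to_numpy(float)
    ok = ~(np.isnan(y) | np.isnan(z))
    return partial_corr(y[ok], z[ok], X[ok])


def recovery_experiment(
    make_surveys,
    exposure: str,
    outcome: str,
    n_replications: int,
    seed: int = 0,
    anchor: float | None = None,
    anchor_scale: float = 1.0,
    **analysis_kwargs,
) -> RecoveryReport:
    """Repeatedly simulate, fuse, pool, and score against the truth.

    ``make_surveys(seed)`` must return ``(A, B, truth)``.  The anchor
    defaults to the generator's true partial correlation for the pair
    (optionally misspecified by ``anchor_scale``); per-replication seeds
    are derived from ``seed``.
    """
    report = None
    for r in range(n_replications):
        rep_seed = int(np.random.default_rng((seed, r)).integers(2**31 - 1))
        A, B, truth = make_surveys(rep_seed)
        true_beta = truth.true_beta[(exposure, outcome)]
        a = anchor if anchor is not None else truth.true_rho[(exposure, outcome)]
        a *= anchor_scale
        if report is None:
            report = RecoveryReport(exposure, outcome, true_beta)
        pooled = run_pair_analysis(
            A, B, exposure, outcome, a, seed=rep_seed, **analysis_kwargs
        )
        report.estimates.append(pooled.q_bar)
        denom = true_beta if true_beta != 0 else 1.0
        report.rel_bias.append((pooled.q_bar - true_beta) / denom)
        report.covered.append(pooled.ci_low <= true_beta <= pooled.ci_high)
    return report
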