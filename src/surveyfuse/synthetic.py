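"""Synthetic two-survey population with known exposure-outcome structure.

The generator emulates the study setting: a global online sample of gay
and bisexual men measured by two partially overlapping surveys — an
outcome file A (access to HIV services, anticipated income reduction,
PHQ-4 mental health, plus demographics, mirroring the COVID-19
Disparities Survey) and a donor file B (four 5-point Likert exposure
scales plus the same demographics, mirroring GMHR-4).

Mechanism: a Gaussian copula over latent traits.  Nine demographic
propensities, four exposure traits and seven outcome traits are jointly
Gaussian with a correlation matrix built so that the partial correlation
of each (outcome, exposure) pair given the demographic latents equals a
configured anchor value.  Demographics are thresholded at the reference
prevalences of the combined sample; Likert items arise as one common
trait plus independent item noise, with the noise share and the item
thresholds solved numerically so the discretised items reproduce the
instrument's reported scale means/SDs and Cronbach alphas.

Because the fusion engine's prediction step is conditional-Gaussian, the
``measurement="gaussian"`` mode (no discretisation) is the method's
exactly well-specified case, with closed-form ground truth recorded in a
:class:`TruthRecord` for parameter-recovery experiments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import REGRESSION_COVARIATES_FULL, build_design
from .partial_correlation import partial_corr
from .scales import DEFAULT_OUTCOME_CODINGS, DEFAULT_SCALES, ScaleDef, score_scale
from .survey import Codebook, SurveyFrame, VariableDef


class GeneratorError(ValueError):
    pass


# --------------------------------------------------------------- references
#
# Joint demographic tabulation of the two source surveys (combined N =
# 19,643; donor survey n = 6,189; outcome survey n = 13,454).  Counts are
# (total, donor_B, outcome_A); category rows may not sum to the column
# totals because of item non-response in the source data.

N_TOTAL = 19_643
N_FILE_B = 6_189   # donor survey (exposures): GMHR-4
N_FILE_A = 13_454  # outcome survey: COVID-19 Disparities

REFERENCE_DEMOGRAPHIC_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "age": {
        "<20": (1287, 537, 750),
        "20-29": (7234, 2687, 4547),
        "30-49": (9240, 2528, 6712),
        "50+": (1878, 433, 1445),
    },
    "econ_able": {
        "Not able to meet needs well": (11275, 3982, 7293),
        "Able to meet needs well": (8368, 2207, 6161),
    },
    "education_college": {
        "Did not complete college": (9031, 1553, 7478),
        "Completed college": (10612, 4636, 5976),
    },
    "in_relationship": {
        "Not in a relationship": (13918, 4516, 9402),
        "In a relationship": (5725, 1673, 4052),
    },
    "urban": {
        "Not in a city/urban area": (4070, 831, 3239),
        "Resides in a city/urban area": (15573, 5358, 10215),
    },
    "minority": {
        "Not a racial or ethnic minority": (16117, 4733, 11384),
        "Racial or ethnic minority": (3526, 1456, 2070),
    },
    "insurance": {
        "No": (5398, 1908, 3490),
        "Yes": (14245, 4281, 9964),
    },
    "region_south": {
        "Global North": (9741, 598, 9143),
        "Global South": (9671, 5563, 4108),
    },
    "hiv_positive": {
        "Not living with HIV": (17194, 5173, 12021),
        "Living with HIV": (2449, 1016, 1433),
    },
}

EXPOSURES = (
    "community_engagement",
    "provider_comfort",
    "sexual_stigma",
    "provider_discrimination",
)
OUTCOMES = (
    "hiv_testing",
    "condoms",
    "prep",
    "provider_access",
    "art_refills",
    "income_reduction",
    "phq4",
)
DEMOGRAPHICS = tuple(REFERENCE_DEMOGRAPHIC_COUNTS)

#: Default generator-truth anchors: the donor-survey proxy partial
#: correlations reported for each (exposure, outcome) pair.
DEFAULT_ANCHORS: dict[tuple[str, str], float] = {}
for _expo, _row in {
    "community_engagement": (0.08, 0.05, 0.13, 0.11, 0.11, 0.02, -0.06),
    "provider_comfort": (0.21, 0.19, 0.25, 0.26, 0.26, -0.17, -0.15),
    "sexual_stigma": (-0.15, -0.19, -0.21, -0.21, -0.18, 0.17, 0.15),
    "provider_discrimination": (-0.07, -0.08, -0.06, -0.05, -0.04, 0.09, 0.10),
}.items():
    for _out, _rho in zip(OUTCOMES, _row):
        DEFAULT_ANCHORS[(_expo, _out)] = _rho

#: Reported scale score means/SDs used to calibrate item thresholds.
SCALE_CALIBRATION = {
    "community_engagement": (1.32, 0.43),
    "provider_comfort": (2.98, 1.25),
    "sexual_stigma": (3.53, 0.61),
    "provider_discrimination": (1.14, 0.39),
}

#: (mean, SD, support) targets for the single-item outcome marginals.
#: Targets outside the feasible moment region of the support (possible
#: because the source coding is not printed) are fit by bounded least
#: squares and land on the feasible boundary.
OUTCOME_CALIBRATION: dict[str, tuple[float, float, tuple[int, ...]]] = {
    "hiv_testing": (3.7, 0.43, tuple(range(1, 6))),
    "condoms": (4.6, 0.9, tuple(range(1, 6))),
    "prep": (3.2, 1.4, tuple(range(1, 6))),
    "provider_access": (2.4, 0.8, tuple(range(1, 5))),
    "art_refills": (2.1, 1.2, (1, 2)),
    "income_reduction": (2.4, 3.6, tuple(range(0, 11))),
}
#: PHQ-4 items: 0..3 each; item marginals chosen so the total has mean
#: 4.7 (the reported sample mean) and SD near 3, with inter-item
#: correlation 0.45 (alpha ~ 0.77, typical for the instrument).
PHQ4_ITEM_CALIBRATION = (1.175, 0.98, (0, 1, 2, 3))
PHQ4_ITEM_CORR = 0.45


def reference_prevalences() -> dict[str, object]:
    """Category probabilities implied by the reference counts (conditional
    on response, so rows with item non-response still normalise to 1)."""
    out: dict[str, object] = {}
    for var, cats in REFERENCE_DEMOGRAPHIC_COUNTS.items():
        totals = np.array([c[0] for c in cats.values()], float)
        probs = totals / totals.sum()
        if var == "age":
            out[var] = tuple(probs)
        else:
            out[var] = float(probs[1])  # probability of the coded-1 level
    return out


# ------------------------------------------------------------------- config


@dataclass
class SplitSpec:
    """How to partition the population into outcome file A and donor file B.

    ``composition_drift`` maps demographic names to assignment log-odds:
    a record's probability of landing in file A is
    sigmoid(eta + sum(drift[d] * x_d)), with the intercept eta solved so
    the expected A-share equals ``frac_A``.  Zero drift (the default) is
    the fusion method's ideal case of two simple random samples from one
    population; nonzero drift reproduces the real surveys' composition
    differences (e.g. the donor survey's much larger Global-South share),
    which violate that assumption.
    """

    frac_A: float = N_FILE_A / N_TOTAL
    composition_drift: dict[str, float] = field(default_factory=dict)
    exact: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.frac_A < 1.0:
            raise GeneratorError(f"frac_A must be in (0, 1), got {self.frac_A}")
        for k, v in self.composition_drift.items():
            if not np.isfinite(v):
                raise GeneratorError(f"drift for {k!r} is not finite")


def drift_for_target_shares(
    pop_share: float, share_A: float, share_B: float
) -> tuple[float, float]:
    """Invert the logistic assignment model for one binary demographic.

    Given the population prevalence of the demographic and the target
    within-file prevalences, return ``(frac_A, delta)`` — the file-A
    fraction consistent with the three shares and the assignment
    log-odds to put in ``composition_drift``.
    """
    if not min(share_A, share_B) < pop_share < max(share_A, share_B):
        raise GeneratorError("pop_share must lie between the two file shares")
    frac_A = (pop_share - share_B) / (share_A - share_B)
    p1 = frac_A * share_A / pop_share          # P(A | x=1)
    p0 = frac_A * (1 - share_A) / (1 - pop_share)  # P(A | x=0)
    logit = lambda p: np.log(p / (1 - p))
    return float(frac_A), float(logit(p1) - logit(p0))


@dataclass
class PopulationConfig:
    """Configuration of the joint synthetic population.

    ``target_anchors`` are the generator's ground-truth partial
    correlations rho_{outcome, exposure | demographics} on the latent
    scale.  ``exposure_loading`` / ``outcome_loading`` set how strongly
    each trait loads on each demographic latent (uniform scalar or a
    per-(trait, demographic) map).  ``latent_corr``, if given, overrides
    the structural construction with an explicit correlation matrix in
    the canonical order (demographics, exposures, outcomes).
    """

    n_population: int = N_TOTAL
    measurement: str = "likert"  # "likert" | "gaussian"
    target_anchors: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    exposure_loading: float | Mapping = 0.1
    outcome_loading: float | Mapping = 0.1
    latent_corr: np.ndarray | None = None
    scale_defs: dict[str, ScaleDef] = field(default_factory=lambda: dict(DEFAULT_SCALES))
    scale_calibration: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SCALE_CALIBRATION)
    )
    outcome_calibration: dict[str, tuple] = field(
        default_factory=lambda: dict(OUTCOME_CALIBRATION)
    )
    proxy_reliability: float = 1.0
    na_outcomes_for_hiv_negative: bool = True
    compute_truth: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_population < 1:
            raise GeneratorError("n_population must be >= 1")
        if self.measurement not in ("likert", "gaussian"):
            raise GeneratorError(f"unknown measurement mode {self.measurement!r}")
        for pair, rho in self.target_anchors.items():
            if not abs(rho) < 1:
                raise GeneratorError(f"|anchor| must be < 1 for {pair}")

    def canonical_dict(self) -> dict:
        d = {
            "n_population": self.n_population,
            "measurement": self.measurement,
            "target_anchors": {f"{e}|{o}": r for (e, o), r in sorted(self.target_anchors.items())},
            "exposure_loading": self.exposure_loading
            if np.isscalar(self.exposure_loading)
            else {k: dict(v) for k, v in self.exposure_loading.items()},
            "outcome_loading": self.outcome_loading
            if np.isscalar(self.outcome_loading)
            else {k: dict(v) for k, v in self.outcome_loading.items()},
            "latent_corr": None if self.latent_corr is None else np.asarray(self.latent_corr).tolist(),
            "proxy_reliability": self.proxy_reliability,
            "seed": self.seed,
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class TruthRecord:
    """Generator ground truth for recovery experiments.

    ``true_beta`` / ``true_rho`` are on the analysis scale, conditioned
    on the full regression covariate set: closed-form from the latent
    correlation matrix in gaussian mode, a whole-population fit of the
    realised (discretised) variables in likert mode.  ``latent_beta`` /
    ``latent_rho`` are always the closed-form values given all
    demographic latents.
    """

    true_beta: dict[tuple[str, str], float]
    true_rho: dict[tuple[str, str], float]
    latent_beta: dict[tuple[str, str], float]
    latent_rho: dict[tuple[str, str], float]
    config_hash: str = ""
    seed: int = 0


# ------------------------------------------------- latent correlation matrix


def _loading_matrix(spec, traits, value_default) -> np.ndarray:
    q = len(DEMOGRAPHICS)
    if np.isscalar(spec):
        return np.full((len(traits), q), float(spec))
    M = np.full((len(traits), q), float(value_default))
    for t, row in spec.items():
        for d, v in row.items():
            M[traits.index(t), DEMOGRAPHICS.index(d)] = float(v)
    return M


def build_latent_correlation(config: PopulationConfig) -> np.ndarray:
    """Assemble the (9+4+7) latent correlation matrix from the structural
    parameters, or validate a user-supplied one.  Non-PSD matrices are
    rejected with the offending eigenvalue."""
    if config.latent_corr is not None:
        S = np.asarray(config.latent_corr, float)
    else:
        A = _loading_matrix(config.exposure_loading, list(EXPOSURES), 0.1)
        Bm = _loading_matrix(config.outcome_loading, list(OUTCOMES), 0.1)
        lam2 = 1.0 - (A ** 2).sum(axis=1)
        if (lam2 <= 0).any():
            raise GeneratorError("exposure demographic loadings leave no residual variance")
        lam = np.sqrt(lam2)
        bnorm2 = (Bm ** 2).sum(axis=1)
        C = np.zeros((len(OUTCOMES), len(EXPOSURES)))
        for (e, o), rho in config.target_anchors.items():
            C[OUTCOMES.index(o), EXPOSURES.index(e)] = rho * np.sqrt(1.0 - bnorm2[OUTCOMES.index(o)])
        s2 = 1.0 - bnorm2 - (C ** 2).sum(axis=1)
        if (s2 < -1e-12).any():
            k = int(np.argmin(s2))
            raise GeneratorError(
                f"anchors for outcome {OUTCOMES[k]!r} imply negative residual variance"
            )
        q = len(DEMOGRAPHICS)
        p = q + len(EXPOSURES) + len(OUTCOMES)
        S = np.eye(p)
        iT = slice(q, q + len(EXPOSURES))
        iO = slice(q + len(EXPOSURES), p)
        S[iT, :q] = A
        S[:q, iT] = A.T
        S[iO, :q] = Bm
        S[:q, iO] = Bm.T
        S[iT, iT] = A @ A.T + np.diag(lam2)
        S[iO, iO] = Bm @ Bm.T + C @ C.T + np.diag(np.maximum(s2, 0.0))
        OT = Bm @ A.T + C * lam[None, :]
        S[iO, iT] = OT
        S[iT, iO] = OT.T
    if not np.allclose(np.diag(S), 1.0):
        raise GeneratorError("latent correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(S)
    if w[0] < -1e-10:
        raise GeneratorError(
            f"latent correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {w[0]:.3e})"
        )
    return S


def _latent_index(name: str) -> int:
    if name in DEMOGRAPHICS:
        return DEMOGRAPHICS.index(name)
    if name in EXPOSURES:
        return len(DEMOGRAPHICS) + EXPOSURES.index(name)
    return len(DEMOGRAPHICS) + len(EXPOSURES) + OUTCOMES.index(name)


def analytic_truth(
    S: np.ndarray, exposure: str, outcome: str, covariates: tuple[str, ...]
) -> tuple[float, float]:
    """Closed-form (beta, partial rho) of outcome on exposure given the
    named demographic latents, from the latent correlation matrix."""
    iy = _latent_index(outcome)
    iz = _latent_index(exposure)
    ix = [_latent_index(c) for c in covariates]
    sub = np.ix_([iy, iz], [iy, iz])
    Syz = S[sub]
    Sxz = S[np.ix_(ix, [iy, iz])]
    Sxx = S[np.ix_(ix, ix)]
    cond = Syz - Sxz.T @ np.linalg.solve(Sxx, Sxz)
    rho = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
    beta = cond[0, 1] / cond[1, 1]
    return float(beta), float(rho)


# --------------------------------------------------------------- calibration


def discretized_normal_probs(support: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Cell probabilities of a latent N(mu, sigma^2) cut at the midpoints
    of an integer support (open-ended end cells)."""
    support = np.asarray(support, float)
    edges = (support[:-1] + support[1:]) / 2.0
    cum = stats.norm.cdf((edges - mu) / sigma)
    return np.diff(np.concatenate([[0.0], cum, [1.0]]))


def fit_marginal(support, mean, sd) -> np.ndarray:
    """Solve (mu, sigma) of the discretised normal so the cell
    probabilities best match the target mean and SD (bounded least
    squares; exact when the target is feasible)."""
    support = np.asarray(support, float)

    def resid(theta):
        p = discretized_normal_probs(support, theta[0], np.exp(theta[1]))
        m = (p * support).sum()
        v = (p * (support - m) ** 2).sum()
        return [m - mean, np.sqrt(max(v, 0.0)) - sd]

    lo, hi = support[0], support[-1]
    sol = optimize.least_squares(
        resid,
        x0=[np.clip(mean, lo, hi), np.log(max(sd, 0.05))],
        bounds=([lo - 30.0, np.log(1e-3)], [hi + 30.0, np.log(50.0)]),
    )
    return discretized_normal_probs(support, sol.x[0], np.exp(sol.x[1]))


def cuts_from_probs(probs: np.ndarray) -> np.ndarray:
    """Standard-normal thresholds reproducing the cell probabilities."""
    cum = np.cumsum(probs)[:-1]
    return stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def _discrete_corr(cuts: np.ndarray, values: np.ndarray, r: float) -> float:
    """Pearson correlation of two equicorrelated latent-normal variables
    after thresholding both with the same cuts."""
    big = 9.0
    edges = np.concatenate([[-big], cuts, [big]])
    L = len(values)
    mv = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    grid = np.array([[edges[i], edges[j]] for i in range(L + 1) for j in range(L + 1)])
    cdf = mv.cdf(grid).reshape(L + 1, L + 1)
    cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    cell = np.clip(cell, 0.0, None)
    p = cell.sum(axis=1)
    m = (p * values).sum()
    v = (p * (values - m) ** 2).sum()
    exy = (cell * np.outer(values, values)).sum()
    return (exy - m * m) / v if v > 0 else 0.0


def latent_share_for_alpha(alpha: float, k: int, cuts, values) -> float:
    """Common-trait variance share w such that k thresholded items with
    pairwise latent correlation w have the target Cronbach alpha.

    For exchangeable items alpha = k * r_d / (1 + (k-1) * r_d) with r_d
    the discrete inter-item correlation, so the target r_d is inverted
    first, then the latent correlation matched by root finding on the
    thresholded-bivariate-normal correlation.
    """
    r_d = alpha / (k - alpha * (k - 1))
    if not 0 < r_d < 1:
        raise GeneratorError(f"alpha={alpha} with k={k} items is not attainable")
    cuts = np.asarray(cuts, float)
    values = np.asarray(values, float)
    f = lambda w: _discrete_corr(cuts, values, w) - r_d
    hi = 0.999
    if f(hi) < 0:
        raise GeneratorError(f"alpha={alpha} unreachable after discretisation")
    return float(optimize.brentq(f, 1e-6, hi, xtol=1e-4))


def calibrate_scale(scale: ScaleDef, mean: float, sd: float, alpha: float):
    """Item thresholds and common-trait share for one Likert scale.

    The item marginal is solved so the scale score (item mean) has the
    target mean and SD: item mean = score mean, item variance =
    k * SD^2 / (1 + (k-1) * r_d).
    """
    k = scale.n_items
    r_d = alpha / (k - alpha * (k - 1))
    item_var = k * sd ** 2 / (1.0 + (k - 1) * r_d)
    support = np.arange(scale.item_range[0], scale.item_range[1] + 1)
    probs = fit_marginal(support, mean, np.sqrt(item_var))
    cuts = cuts_from_probs(probs)
    w = latent_share_for_alpha(alpha, k, cuts, support)
    return cuts, support, w


# ---------------------------------------------------------------- generation


def _threshold_items(
    trait: np.ndarray, n_items: int, w: float, cuts: np.ndarray, values: np.ndarray, rng
) -> np.ndarray:
    noise = rng.standard_normal((len(trait), n_items))
    latent = np.sqrt(w) * trait[:, None] + np.sqrt(1.0 - w) * noise
    idx = np.searchsorted(cuts, latent)
    return values[idx]


def _population_codebook(config: PopulationConfig) -> Codebook:
    cb = Codebook()
    prev = reference_prevalences()
    for d in DEMOGRAPHICS:
        if config.measurement == "gaussian":
            cb.variables[d] = VariableDef(d, "demographic")
        elif d == "age":
            cb.variables[d] = VariableDef(
                d, "demographic", levels=(0, 1, 2, 3),
                labels=tuple(REFERENCE_DEMOGRAPHIC_COUNTS["age"]),
            )
        else:
            cb.variables[d] = VariableDef(
                d, "demographic", levels=(0, 1),
                labels=tuple(REFERENCE_DEMOGRAPHIC_COUNTS[d]),
            )
    if config.measurement == "likert":
        for sname, sdef in config.scale_defs.items():
            lo, hi = sdef.item_range
            for item in sdef.item_names:
                cb.variables[item] = VariableDef(
                    item, "exposure_item", levels=tuple(range(lo, hi + 1))
                )
            cb.scales[sname] = {
                "items": list(sdef.item_names),
                "item_range": list(sdef.item_range),
                "reported_alpha": sdef.reported_alpha,
            }
    for e in EXPOSURES:
        cb.variables[e] = VariableDef(e, "exposure_score")
    for o in OUTCOMES:
        if config.measurement == "likert" and o in config.outcome_calibration:
            support = tuple(int(v) for v in config.outcome_calibration[o][2])
            cb.variables[o] = VariableDef(o, "outcome", levels=support)
        else:
            cb.variables[o] = VariableDef(o, "outcome")
    if config.measurement == "likert":
        for i in range(1, 5):
            cb.variables[f"phq_{i}"] = VariableDef(f"phq_{i}", "outcome_item", levels=(0, 1, 2, 3))
        for o, coding in DEFAULT_OUTCOME_CODINGS.items():
            cb.outcome_codings[o] = {
                "map": dict(coding.mapping),
                "missing_codes": list(coding.missing_codes),
            }
    for o in OUTCOMES:
        cb.variables[f"proxy_{o}"] = VariableDef(f"proxy_{o}", "proxy")
    _ = prev
    return cb


def generate_population(config: PopulationConfig) -> tuple[SurveyFrame, TruthRecord]:
    """Draw the joint population and its ground-truth record.

    Returns a :class:`SurveyFrame` with one row per individual holding
    all demographics, exposure items and scores, outcomes and proxy
    measures, plus a :class:`TruthRecord` for recovery tests.
    """
    S = build_latent_correlation(config)
    rng = np.random.default_rng(config.seed)
    n, q = config.n_population, len(DEMOGRAPHICS)
    L = np.linalg.cholesky(S + 1e-12 * np.eye(S.shape[0]))
    U = rng.standard_normal((n, S.shape[0])) @ L.T
    D = U[:, :q]
    T = U[:, q : q + len(EXPOSURES)]
    O = U[:, q + len(EXPOSURES) :]

    data: dict[str, np.ndarray] = {}
    prev = reference_prevalences()

    # demographics
    if config.measurement == "gaussian":
        for i, d in enumerate(DEMOGRAPHICS):
            data[d] = D[:, i]
    else:
        for i, d in enumerate(DEMOGRAPHICS):
            if d == "age":
                cuts = stats.norm.ppf(np.cumsum(prev["age"])[:-1])
                data[d] = np.searchsorted(cuts, D[:, i]).astype(int)
            else:
                tau = stats.norm.ppf(1.0 - prev[d])
                data[d] = (D[:, i] > tau).astype(int)

    # exposures
    if config.measurement == "gaussian":
        for j, e in enumerate(EXPOSURES):
            data[e] = T[:, j]
    else:
        for j, e in enumerate(EXPOSURES):
            sdef = config.scale_defs[e]
            mean, sd = config.scale_calibration[e]
            cuts, support, w = calibrate_scale(sdef, mean, sd, sdef.reported_alpha)
            items = _threshold_items(T[:, j], sdef.n_items, w, cuts, support.astype(float), rng)
            for c, item in enumerate(sdef.item_names):
                data[item] = items[:, c].astype(int)
            data[e] = score_scale(items, sdef)

    # outcomes
    hiv_neg = None
    if config.measurement == "likert" and config.na_outcomes_for_hiv_negative:
        hiv_neg = data["hiv_positive"] == 0
    for k, o in enumerate(OUTCOMES):
        if config.measurement == "gaussian":
            data[o] = O[:, k]
        elif o == "phq4":
            m, s, support = PHQ4_ITEM_CALIBRATION
            probs = fit_marginal(support, m, s)
            cuts = cuts_from_probs(probs)
            items = _threshold_items(
                O[:, k], 4, PHQ4_ITEM_CORR, cuts, np.asarray(support, float), rng
            )
            for c in range(4):
                data[f"phq_{c + 1}"] = items[:, c].astype(int)
            data[o] = items.sum(axis=1)
        else:
            mean, sd, support = config.outcome_calibration[o]
            support = np.asarray(support, float)
            probs = fit_marginal(support, mean, sd)
            cuts = cuts_from_probs(probs)
            vals = support[np.searchsorted(cuts, O[:, k])]
            if hiv_neg is not None and o in ("provider_access", "art_refills"):
                vals = vals.astype(float)
                vals[hiv_neg] = np.nan
            data[o] = vals

    # proxy measures of the outcome constructs, observed in the donor file
    rel = config.proxy_reliability
    for k, o in enumerate(OUTCOMES):
        data[f"proxy_{o}"] = np.sqrt(rel) * O[:, k] + np.sqrt(1.0 - rel) * rng.standard_normal(n)

    frame = SurveyFrame(
        data=pd.DataFrame(data), codebook=_population_codebook(config), name="population"
    )
    truth = _compute_truth(config, S, frame)
    return frame, truth


def _compute_truth(config, S, frame) -> TruthRecord:
    latent_beta, latent_rho = {}, {}
    true_beta, true_rho = {}, {}
    pairs = sorted(config.target_anchors)
    for e, o in pairs:
        latent_beta[(e, o)], latent_rho[(e, o)] = analytic_truth(S, e, o, DEMOGRAPHICS)
    if config.compute_truth:
        for e, o in pairs:
            if config.measurement == "gaussian":
                true_beta[(e, o)], true_rho[(e, o)] = analytic_truth(
                    S, e, o, tuple(REGRESSION_COVARIATES_FULL)
                )
            else:
                X = build_design(frame.data, REGRESSION_COVARIATES_FULL, frame.codebook)
                y = frame.data[o].to_numpy(float)
                z = frame.data[e].to_numpy(float)
                ok = ~(np.isnan(y) | np.isnan(z) | np.isnan(X).any(axis=1))
                Xc = np.column_stack([z[ok], X[ok]])
                coef, *_ = np.linalg.lstsq(Xc, y[ok], rcond=None)
                true_beta[(e, o)] = float(coef[0])
                true_rho[(e, o)] = partial_corr(y[ok], z[ok], X[ok])
    return TruthRecord(
        true_beta=true_beta,
        true_rho=true_rho,
        latent_beta=latent_beta,
        latent_rho=latent_rho,
        config_hash=config.config_hash(),
        seed=config.seed,
    )


# -------------------------------------------------------------------- split


def split_surveys(
    population: SurveyFrame, spec: SplitSpec
) -> tuple[SurveyFrame, SurveyFrame]:
    """Partition the population into outcome file A and donor file B.

    A retains demographics + outcomes (exposure items, scores and proxies
    masked — removed, not blanked); B retains demographics + exposure
    items/scores + proxies (outcomes masked).  The partition is
    exhaustive and disjoint.
    """
    n = len(population)
    if n == 0:
        raise GeneratorError("population is empty")
    eta0 = np.log(spec.frac_A / (1 - spec.frac_A))
    if spec.composition_drift:
        shift = np.zeros(n)
        for d, delta in spec.composition_drift.items():
            if d not in population.data.columns:
                raise GeneratorError(f"drift names unknown demographic {d!r}")
            shift += delta * population.data[d].to_numpy(float)

        def mean_p(eta):
            return float(np.mean(1.0 / (1.0 + np.exp(-(eta + shift))))) - spec.frac_A

        eta = optimize.brentq(mean_p, eta0 - 30, eta0 + 30)
        p_A = 1.0 / (1.0 + np.exp(-(eta + shift)))
    else:
        p_A = np.full(n, spec.frac_A)

    rng = np.random.default_rng(spec.seed)
    if spec.exact:
        n_A = int(round(spec.frac_A * n))
        if not 0 < n_A < n:
            raise GeneratorError("frac_A produces an empty file")
        idx_A = rng.choice(n, size=n_A, replace=False, p=p_A / p_A.sum())
        in_A = np.zeros(n, bool)
        in_A[idx_A] = True
    else:
        in_A = rng.random(n) < p_A
        if in_A.all() or not in_A.any():
            raise GeneratorError("frac_A produces an empty file")

    A = SurveyFrame(
        data=population.data.loc[in_A].reset_index(drop=True),
        codebook=population.codebook,
        name="file_A",
    ).drop_roles("exposure_item", "exposure_score", "proxy")
    B = SurveyFrame(
        data=population.data.loc[~in_A].reset_index(drop=True),
        codebook=population.codebook,
        name="file_B",
    ).drop_roles("outcome", "outcome_item")
    return A, B


# ----------------------------------------------------------------- fixtures


def write_fixture(
    frames: Mapping[str, SurveyFrame], out_dir: str | Path
) -> dict[str, Path]:
    """Write each survey frame as CSV + YAML codebook; round-trips
    losslessly through :func:`load_fixture`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in frames.items():
        csv_path = out_dir / f"{name}.csv"
        frame.save(csv_path)
        paths[name] = csv_path
    return paths


def load_fixture(out_dir: str | Path, names=("file_A", "file_B")) -> dict[str, SurveyFrame]:
    out_dir = Path(out_dir)
    return {n: SurveyFrame.load(out_dir / f"{n}.csv", name=n) for n in names}


def default_study_fixture(seed: int = 0, out_dir: str | Path | None = None):
    """The default calibrated two-survey fixture: 19,643 individuals split
    13,454 (outcome file) / 6,189 (donor file)."""
    config = PopulationConfig(n_population=N_TOTAL, seed=seed)
    pop, truth = generate_population(config)
    A, B = split_surveys(pop, SplitSpec(frac_A=N_FILE_A / N_TOTAL, seed=seed + 1))
    if out_dir is not None:
        write_fixture({"file_A": A, "file_B": B}, out_dir)
    return A, B, truth
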