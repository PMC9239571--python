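"""Anchor partial correlations and the 5-value sensitivity grid.

The fusion method requires a prespecified partial correlation
rho_{Y,Z|X} between the never-jointly-observed outcome Y and exposure Z
given the shared demographics X.  That quantity is unidentifiable from
the two files, so it is anchored by a proxy-measure estimate computed
inside the donor survey — the partial correlation of each exposure with
the donor-survey measure judged closest to each outcome, adjusting for
the jointly observed demographics — and then varied over a 5-value grid
(the anchor, +/-5% and +/-10%) for sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ANCHOR_COVARIATES, build_design
from .survey import SurveyFrame


class PartialCorrError(ValueError):
    pass


def partial_corr(y, z, X) -> float:
    """Partial correlation of y and z given covariates X.

    Computed by correlating the least-squares residuals of y ~ X and
    z ~ X.  X must include an intercept column.  Symmetric in (y, z) and
    invariant to affine rescaling of y, z, or any covariate.

    Raises
    ------
    PartialCorrError
        if either residual vector is (numerically) constant, making the
        correlation undefined, or if there are too few observations.
    """
    y = np.asarray(y, float).ravel()
    z = np.asarray(z, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if len(y) != n or len(z) != n:
        raise PartialCorrError("y, z and X must have the same number of rows")
    if n < np.linalg.matrix_rank(X) + 3:
        raise PartialCorrError(f"need at least rank(X)+3 = {k + 3} observations")
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rz = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
    sy = np.sqrt(ry @ ry)
    sz = np.sqrt(rz @ rz)
    scale = max(np.abs(y).max(), np.abs(z).max(), 1.0)
    if sy <= 1e-12 * scale * np.sqrt(n) or sz <= 1e-12 * scale * np.sqrt(n):
        raise PartialCorrError("constant residuals: partial correlation undefined")
    return float(np.clip((ry @ rz) / (sy * sz), -1.0, 1.0))


#: Default proxy map: the donor survey carries a proxy measurement of
#: each outcome construct, named ``proxy_<outcome>``.
def default_proxy_map(exposures, outcomes) -> dict[tuple[str, str], str]:
    return {(e, o): f"proxy_{o}" for e in exposures for o in outcomes}


def anchor_estimates(
    donor: SurveyFrame,
    proxies: dict[tuple[str, str], str],
    covariates=ANCHOR_COVARIATES,
    max_abs: float = 0.999,
) -> dict[tuple[str, str], float]:
    """Anchor rho for every analyzed (exposure, outcome) pair, estimated
    in the donor survey with listwise deletion per pair.

    Anchors with |rho| >= ``max_abs`` (e.g. a proxy identical to the
    exposure) are rejected as outside the admissible range for fusion.
    """
    covariates = [c for c in covariates if c in donor.data.columns]
    anchors: dict[tuple[str, str], float] = {}
    for (exposure, outcome), proxy in proxies.items():
        if proxy not in donor.data.columns:
            raise PartialCorrError(
                f"proxy column {proxy!r} for pair ({exposure}, {outcome}) "
                f"missing from donor survey"
            )
        if exposure not in donor.data.columns:
            raise PartialCorrError(f"exposure column {exposure!r} missing from donor survey")
        sub = donor.data[[exposure, proxy] + covariates].dropna()
        X = build_design(sub, covariates, donor.codebook)
        rho = partial_corr(sub[exposure], sub[proxy], X)
        if abs(rho) >= max_abs:
            raise PartialCorrError(
                f"anchor for ({exposure}, {outcome}) is {rho:.3f}: degenerate "
                f"proxy, outside the admissible range for fusion"
            )
        anchors[(exposure, outcome)] = rho
    return anchors


@dataclass(frozen=True)
class RhoGrid:
    """The 5-value sensitivity grid around an anchor partial correlation."""

    anchor: float
    values: tuple[float, float, float, float, float]
    interpretation: str = "relative"

    def __post_init__(self):
        if len(self.values) != 5:
            raise PartialCorrError("grid must have exactly 5 values")
        if any(not -1 < v < 1 for v in self.values):
            raise PartialCorrError("grid values must lie in (-1, 1)")

    def __iter__(self):
        return iter(self.values)


def rho_grid(anchor: float, interpretation: str = "relative") -> RhoGrid:
    """Build the sensitivity grid: the anchor, +/-5% and +/-10%.

    ``relative`` reads the percentages as multiplicative perturbations
    (anchor * {0.90, 0.95, 1, 1.05, 1.10}); ``absolute`` as
    percentage-point shifts (anchor + {-0.10, ..., +0.10}).  Values are
    clamped into (-0.999, 0.999); the grid is sorted with the anchor
    central.
    """
    if not abs(anchor) < 1:
        raise PartialCorrError(f"|anchor| must be < 1, got {anchor}")
    if interpretation == "relative":
        vals = [anchor * f for f in (0.90, 0.95, 1.0, 1.05, 1.10)]
    elif interpretation == "absolute":
        vals = [anchor + d for d in (-0.10, -0.05, 0.0, 0.05, 0.10)]
    else:
        raise PartialCorrError(f"unknown interpretation {interpretation!r}")
    vals = sorted(float(np.clip(v, -0.999, 0.999)) for v in vals)
    return RhoGrid(anchor=float(anchor), values=tuple(vals), interpretation=interpretation)
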