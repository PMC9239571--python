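"""File concatenation with adjusted weights: the core fusion computation.

The two survey files are stacked into one (outcome file A contributes
observed Y, donor file B observed Z, both contribute the jointly
observed demographics X) with per-record weights adjusted so each file
carries its intended share of the total.  Y is regressed on X within A
and Z on X within B; a prespecified partial correlation rho_{Y,Z|X}
then yields conditional-Gaussian predictions of the missing variable
for every record.  Each recipient is matched to the donor with the
closest predicted value (1-D nearest neighbour, donors reusable), and
the donor's *observed* value is imputed — a hot deck, so imputations
are always realised data values.  One fused data set is produced per
value of the sensitivity grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .design import build_design, design_column_names
from .partial_correlation import RhoGrid
from .survey import Codebook, SurveyFrame, check_shared_covariates


class FusionError(ValueError):
    pass


WEIGHT_SCHEMES = ("equal-share", "proportional")


@dataclass
class StackedFile:
    """Concatenated A+B records with adjusted weights.

    ``origin`` is "A" (observed Y, missing Z) or "B" (observed Z,
    missing Y).  ``X`` is the shared design matrix (intercept first).
    """

    data: pd.DataFrame
    X: np.ndarray
    x_names: list[str]
    y_col: str
    z_col: str
    codebook: Codebook
    scheme: str = "equal-share"

    @property
    def origin(self) -> np.ndarray:
        return self.data["origin"].to_numpy()

    @property
    def is_A(self) -> np.ndarray:
        return self.origin == "A"

    @property
    def weights(self) -> np.ndarray:
        return self.data["fusion_weight"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.y_col].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        return self.data[self.z_col].to_numpy(float)


@dataclass
class ConditionalModels:
    """Weighted least-squares fits of Y on X (within A) and Z on X
    (within B), with weighted RMS residual scales."""

    beta_y: np.ndarray
    sigma_y: float
    beta_z: np.ndarray
    sigma_z: float
    n_A: int = 0
    n_B: int = 0
    r2_y: float = float("nan")
    r2_z: float = float("nan")


@dataclass
class FusedDataset:
    """A complete rectangular data set (no missing Y or Z) for one rho."""

    data: pd.DataFrame
    rho: float
    y_col: str
    z_col: str
    codebook: Codebook

    def __len__(self):
        return len(self.data)


# ------------------------------------------------------------ concatenation


def concatenate_with_weights(
    A: SurveyFrame,
    B: SurveyFrame,
    y_col: str,
    z_col: str,
    covariates,
    scheme: str = "equal-share",
) -> StackedFile:
    """Stack the outcome file A (observed ``y_col``) and donor file B
    (observed ``z_col``) with adjusted weights.

    ``equal-share`` gives each record of file F weight
    (n_A + n_B) / (2 n_F), so each file carries half the total weight
    regardless of its size; ``proportional`` leaves all weights at 1.
    Both files must share the demographic codebook exactly.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise FusionError(f"unknown weight scheme {scheme!r}")
    shared = check_shared_covariates(A, B)
    missing = [c for c in covariates if c not in shared]
    if missing:
        raise FusionError(f"covariates {missing} not jointly observed in both files")
    if y_col not in A.data.columns:
        raise FusionError(f"outcome {y_col!r} not in file {A.name}")
    if z_col not in B.data.columns:
        raise FusionError(f"exposure {z_col!r} not in file {B.name}")

    a = A.data.dropna(subset=[y_col])[list(covariates) + [y_col]].copy()
    b = B.data.dropna(subset=[z_col])[list(covariates) + [z_col]].copy()
    a = a.dropna(subset=list(covariates))
    b = b.dropna(subset=list(covariates))
    n_A, n_B = len(a), len(b)
    if n_A == 0 or n_B == 0:
        raise FusionError("a file has no complete records for this pair")
    a["origin"] = "A"
    b["origin"] = "B"
    a[z_col] = np.nan
    b[y_col] = np.nan
    n = n_A + n_B
    if scheme == "equal-share":
        a["fusion_weight"] = n / (2.0 * n_A)
        b["fusion_weight"] = n / (2.0 * n_B)
    else:
        a["fusion_weight"] = 1.0
        b["fusion_weight"] = 1.0
    stacked = pd.concat([a, b], ignore_index=True)

    codebook = A.codebook.subset([c for c in covariates] + [y_col])
    X = build_design(stacked, covariates, codebook)
    names = design_column_names(stacked, covariates, codebook)
    return StackedFile(
        data=stacked,
        X=X,
        x_names=names,
        y_col=y_col,
        z_col=z_col,
        codebook=codebook,
        scheme=scheme,
    )


# ------------------------------------------------------- conditional models


def _wls(X, y, w):
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < X.shape[1]:
        raise FusionError(_collinear_message(X))
    resid = y - X @ coef
    sigma = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
    ybar = np.sum(w * y) / np.sum(w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - np.sum(w * resid**2) / tss if tss > 0 else float("nan")
    return coef, sigma, float(r2)


def _collinear_message(X):
    _, R, piv = sla.qr(X, pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag[0] > 0 else 0
    bad = sorted(piv[rank:])
    return f"rank-deficient design: columns {list(bad)} are collinear"


def fit_conditional_models(stacked: StackedFile) -> ConditionalModels:
    """Fit Y ~ X on the A rows and Z ~ X on the B rows by weighted least
    squares; residual scale is the weighted RMS residual."""
    isA = stacked.is_A
    X, w = stacked.X, stacked.weights
    for mask, label in ((isA, "A"), (~isA, "B")):
        if mask.sum() <= X.shape[1]:
            raise FusionError(f"file {label} has too few records for the X design")
    beta_y, sigma_y, r2_y = _wls(X[isA], stacked.y[isA], w[isA])
    beta_z, sigma_z, r2_z = _wls(X[~isA], stacked.z[~isA], w[~isA])
    return ConditionalModels(
        beta_y=beta_y,
        sigma_y=sigma_y,
        beta_z=beta_z,
        sigma_z=sigma_z,
        n_A=int(isA.sum()),
        n_B=int((~isA).sum()),
        r2_y=r2_y,
        r2_z=r2_z,
    )


# ---------------------------------------------------------------- prediction


def predict_joint(
    stacked: StackedFile,
    models: ConditionalModels,
    rho: float,
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict Z and Y for every record under the prespecified rho.

    On rows where the other variable is observed, the prediction is the
    conditional-Gaussian mean: for an A row,
    Zhat = x'beta_Z + rho * (sigma_Z / sigma_Y) * (y - x'beta_Y),
    and symmetrically Yhat on B rows conditions on the observed z.  On
    rows where it is not observed, the prediction is the marginal
    regression mean x'beta (it exists solely as the matching
    coordinate).  With ``stochastic=True`` a residual draw of scale
    sigma * sqrt(1 - rho^2) is added to the conditioned predictions
    (stochastic regression imputation before matching).
    """
    if not -1 < rho < 1:
        raise FusionError(f"rho must be in (-1, 1), got {rho}")
    if rho != 0 and (models.sigma_y == 0 or models.sigma_z == 0):
        raise FusionError("zero residual scale with rho != 0: conditioning undefined")
    X = stacked.X
    isA = stacked.is_A
    mz = X @ models.beta_z
    my = X @ models.beta_y
    zhat = mz.copy()
    yhat = my.copy()
    if models.sigma_y > 0:
        zhat[isA] = mz[isA] + rho * (models.sigma_z / models.sigma_y) * (
            stacked.y[isA] - my[isA]
        )
    if models.sigma_z > 0:
        yhat[~isA] = my[~isA] + rho * (models.sigma_y / models.sigma_z) * (
            stacked.z[~isA] - mz[~isA]
        )
    if stochastic:
        if rng is None:
            raise FusionError("stochastic prediction requires an rng")
        scale = np.sqrt(max(1.0 - rho**2, 0.0))
        zhat[isA] += models.sigma_z * scale * rng.standard_normal(isA.sum())
        yhat[~isA] += models.sigma_y * scale * rng.standard_normal((~isA).sum())
    return zhat, yhat


# ------------------------------------------------------------------ matching


def nearest_donor(recipient_vals: np.ndarray, donor_vals: np.ndarray) -> np.ndarray:
    """Index (into ``donor_vals``) of the nearest donor for each
    recipient, by absolute difference; ties broken by the lowest donor
    index.  Equivalent to argmin over the full distance matrix."""
    recipient_vals = np.asarray(recipient_vals, float)
    donor_vals = np.asarray(donor_vals, float)
    if donor_vals.size == 0:
        raise FusionError("empty donor pool")
    order = np.argsort(donor_vals, kind="stable")
    sv = donor_vals[order]
    uv, first = np.unique(sv, return_index=True)
    min_idx = order[first]  # lowest original index per unique value
    pos = np.searchsorted(uv, recipient_vals)
    pos = np.clip(pos, 0, len(uv) - 1)
    left = np.clip(pos - 1, 0, len(uv) - 1)
    d_right = np.abs(uv[pos] - recipient_vals)
    d_left = np.abs(recipient_vals - uv[left])
    use_left = (pos > 0) & (
        (d_left < d_right) | ((d_left == d_right) & (min_idx[left] < min_idx[pos]))
    )
    choice = np.where(use_left, left, pos)
    return min_idx[choice]


def match_and_impute(
    stacked: StackedFile, zhat: np.ndarray, yhat: np.ndarray, rho: float
) -> FusedDataset:
    """Impute the missing block on each side by nearest-predicted-value
    hot deck: every A row receives the observed Z of the B row with the
    closest predicted Z (donors reusable), and symmetrically for Y."""
    isA = stacked.is_A
    idx_A = np.flatnonzero(isA)
    idx_B = np.flatnonzero(~isA)
    if idx_A.size == 0 or idx_B.size == 0:
        raise FusionError("empty donor pool for one direction")
    out = stacked.data.copy()
    z = stacked.z
    y = stacked.y

    donors_for_A = idx_B[nearest_donor(zhat[idx_A], zhat[idx_B])]
    donors_for_B = idx_A[nearest_donor(yhat[idx_B], yhat[idx_A])]

    z_full = z.copy()
    z_full[idx_A] = z[donors_for_A]
    y_full = y.copy()
    y_full[idx_B] = y[donors_for_B]
    out[stacked.z_col] = z_full
    out[stacked.y_col] = y_full
    donor_id = np.full(len(out), -1, dtype=int)
    donor_id[idx_A] = donors_for_A
    donor_id[idx_B] = donors_for_B
    out["donor_id"] = donor_id
    return FusedDataset(
        data=out, rho=float(rho), y_col=stacked.y_col, z_col=stacked.z_col,
        codebook=stacked.codebook,
    )


# ---------------------------------------------------------------- full pass


def fuse(
    A: SurveyFrame,
    B: SurveyFrame,
    y_col: str,
    z_col: str,
    covariates,
    grid: RhoGrid,
    scheme: str = "equal-share",
    stochastic: bool = False,
    seed: int | None = None,
) -> tuple[list[FusedDataset], ConditionalModels]:
    """Run the whole fusion once per grid value.

    The conditional models are fitted once on the stacked file and
    shared across the grid; output is deterministic given inputs (and
    seed, in stochastic mode).
    """
    stacked = concatenate_with_weights(A, B, y_col, z_col, covariates, scheme)
    models = fit_conditional_models(stacked)
    fused = []
    for i, rho in enumerate(grid):
        rng = np.random.default_rng((seed or 0, i)) if stochastic else None
        zhat, yhat = predict_joint(stacked, models, rho, stochastic=stochastic, rng=rng)
        fused.append(match_and_impute(stacked, zhat, yhat, rho))
    return fused, models
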