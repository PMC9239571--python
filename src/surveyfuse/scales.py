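"""Likert-scale scoring, reliability, and outcome codings.

The four exposure scales (community engagement, comfort with provider,
sexual stigma, provider discrimination) are scored as the mean of their
5-point items; internal consistency is summarised by Cronbach's alpha.
The PHQ-4 mental-health screener is the sum of four 0-3 items with the
standard >=3 psychological-distress cutoff.  Outcome codings map the
survey response labels (access Likert levels, income-reduction percent
bands, HIV-provider and ART-refill access categories) onto the numeric
scores used by the fusion regressions, with "Not applicable" treated as
missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import Codebook


class ScaleError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleDef:
    """Definition of a multi-item Likert scale scored as the item mean."""

    name: str
    item_names: tuple[str, ...]
    item_range: tuple[int, int] = (1, 5)
    reported_alpha: float | None = None

    def __post_init__(self):
        if len(self.item_names) < 2:
            raise ScaleError(f"scale {self.name!r} needs >=2 items")
        if self.item_range[0] >= self.item_range[1]:
            raise ScaleError(f"scale {self.name!r}: item_range min must be < max")

    @property
    def n_items(self) -> int:
        return len(self.item_names)


@dataclass(frozen=True)
class OutcomeCoding:
    """Category -> numeric map for one outcome variable.

    ``missing_codes`` (e.g. "Not applicable") map to NaN and are excluded
    from that outcome's fusion and regression.
    """

    name: str
    mapping: dict
    missing_codes: tuple = ("Not applicable",)

    def __post_init__(self):
        values = list(self.mapping.values())
        if len(set(values)) != len(values):
            raise ScaleError(f"coding for {self.name!r} is not injective")


# --------------------------------------------------------------------- scoring


def score_scale(items, scale: ScaleDef, max_missing_frac: float = 0.5) -> np.ndarray:
    """Score a scale as the per-row mean of its non-missing items.

    Parameters
    ----------
    items : array-like of shape (n_rows, n_items), NaN marking missing.
    scale : the scale definition (used for range validation).
    max_missing_frac : rows with strictly more than this fraction of items
        missing receive a missing (NaN) score.

    Raises
    ------
    ScaleError
        if any non-missing item value falls outside ``scale.item_range``,
        naming the offending row and column.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != scale.n_items:
        raise ScaleError(
            f"{scale.name}: expected {scale.n_items} items, got {arr.shape[1]}"
        )
    lo, hi = scale.item_range
    with np.errstate(invalid="ignore"):
        bad = (~np.isnan(arr)) & ((arr < lo) | (arr > hi))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ScaleError(
            f"{scale.name}: item value {arr[r, c]} out of range [{lo}, {hi}] "
            f"at row {r}, item {scale.item_names[c]!r}"
        )
    n_missing = np.isnan(arr).sum(axis=1)
    score = np.nanmean(np.where(np.isnan(arr), np.nan, arr), axis=1)
    score[n_missing == scale.n_items] = np.nan
    score[n_missing > max_missing_frac * scale.n_items] = np.nan
    return score


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances) / var(total)).

    Uses sample (n-1) variances.  Alpha is at most 1 but may be negative.

    Raises
    ------
    ScaleError
        for <2 items, <3 rows, or zero total-score variance (alpha
        undefined).
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ScaleError("cronbach_alpha needs a 2-D matrix with >=2 items")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n, k = arr.shape
    if n < 3:
        raise ScaleError("cronbach_alpha needs >=3 complete rows")
    item_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ScaleError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def score_phq4(items) -> tuple[np.ndarray, np.ndarray]:
    """Score the PHQ-4: total = sum of four 0-3 items; distress flag for
    totals >= 3.

    Returns ``(total, flag)`` arrays; accepts a single 4-vector or an
    (n, 4) matrix.
    """
    arr = np.asarray(items, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.shape[1] != 4:
        raise ScaleError("PHQ-4 has exactly 4 items")
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= 3))
    if not valid.all():
        r, c = np.argwhere(~valid)[0]
        raise ScaleError(f"PHQ-4 item value {arr[r, c]} out of range 0..3 at row {r}")
    total = arr.sum(axis=1)
    flag = total >= 3
    if single:
        return total[0], bool(flag[0])
    return total, flag


PHQ4_DISTRESS_CUTOFF = 3


# ------------------------------------------------------------------- codings


def apply_outcome_coding(frame: pd.DataFrame, codings: dict[str, OutcomeCoding]) -> pd.DataFrame:
    """Replace labelled outcome columns with their numeric codes.

    Unmapped categories (not declared missing) raise :class:`ScaleError`
    naming the category and column.  Values already equal to a numeric
    code pass through unchanged.
    """
    out = frame.copy()
    for name, coding in codings.items():
        if name not in out.columns:
            continue
        col = out[name]
        numeric_codes = set(coding.mapping.values())

        def encode(v, coding=coding, numeric_codes=numeric_codes, name=name):
            if pd.isna(v):
                return np.nan
            if v in coding.missing_codes:
                return np.nan
            if v in coding.mapping:
                return float(coding.mapping[v])
            if isinstance(v, (int, float, np.integer, np.floating)) and float(v) in {
                float(c) for c in numeric_codes
            }:
                return float(v)
            raise ScaleError(f"unmapped category {v!r} in outcome column {name!r}")

        out[name] = col.map(encode).astype(float)
    return out


# ------------------------------------------------------- default definitions

#: The four exposure scales, with the reliabilities reported for the
#: source instrument.
DEFAULT_SCALES: dict[str, ScaleDef] = {
    "community_engagement": ScaleDef(
        "community_engagement",
        tuple(f"engage_{i}" for i in range(1, 11)),
        (1, 5),
        reported_alpha=0.72,
    ),
    "provider_comfort": ScaleDef(
        "provider_comfort",
        tuple(f"comfort_{i}" for i in range(1, 4)),
        (1, 5),
        reported_alpha=0.85,
    ),
    "sexual_stigma": ScaleDef(
        "sexual_stigma",
        tuple(f"stigma_{i}" for i in range(1, 8)),
        (1, 5),
        reported_alpha=0.82,
    ),
    "provider_discrimination": ScaleDef(
        "provider_discrimination",
        tuple(f"discrim_{i}" for i in range(1, 7)),
        (1, 5),
        reported_alpha=0.87,
    ),
}

#: Income-reduction bands, "0%".."100%" in 10-point increments -> 0..10.
INCOME_CODING = OutcomeCoding(
    "income_reduction",
    {f"{10 * i}%": i for i in range(11)},
    missing_codes=("Not applicable",),
)

#: Access-to-services 5-point Likert: higher = more access, so that
#: enabling exposures carry positive regression coefficients.
ACCESS_LIKERT_CODING = {
    "Definitely no": 1,
    "Probably no": 2,
    "Unsure": 3,
    "Probably yes": 4,
    "Definitely yes": 5,
}

#: HIV-provider access: ordered from no access (clinic closed) to full
#: in-person access.  The numeric map is a declared default, configurable
#: through the codebook; the source instrument does not print one.
PROVIDER_ACCESS_CODING = OutcomeCoding(
    "provider_access",
    {
        "No, because it is closed": 1,
        "No, because of reduced hours": 2,
        "Yes, via telemedicine": 3,
        "Yes, in person": 4,
    },
)

#: ART-refill access: ordered, "Not applicable" missing.
ART_REFILL_CODING = OutcomeCoding(
    "art_refills",
    {
        "I cannot access or refill my HIV medicine": 1,
        "I can access or refill my HIV medicine, but access is burdensome or complicated": 2,
    },
)

DEFAULT_OUTCOME_CODINGS: dict[str, OutcomeCoding] = {
    "income_reduction": INCOME_CODING,
    "provider_access": PROVIDER_ACCESS_CODING,
    "art_refills": ART_REFILL_CODING,
    **{
        name: OutcomeCoding(name, dict(ACCESS_LIKERT_CODING))
        for name in ("hiv_testing", "condoms", "prep")
    },
}


def scales_from_codebook(codebook: Codebook) -> dict[str, ScaleDef]:
    """Parse the ``scales:`` codebook section into :class:`ScaleDef` objects."""
    out = {}
    for name, d in codebook.scales.items():
        out[name] = ScaleDef(
            name=name,
            item_names=tuple(d["items"]),
            item_range=tuple(d.get("item_range", (1, 5))),
            reported_alpha=d.get("reported_alpha"),
        )
    return out


def codings_from_codebook(codebook: Codebook) -> dict[str, OutcomeCoding]:
    out = {}
    for name, d in codebook.outcome_codings.items():
        out[name] = OutcomeCoding(
            name=name,
            mapping=dict(d["map"]),
            missing_codes=tuple(d.get("missing_codes", ("Not applicable",))),
        )
    return out
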