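"""Covariate sets and design-matrix construction shared across stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Covariates of the outcome regressions (and of the fusion engine's
#: conditional models): the jointly observed demographics named in the
#: analysis plan.
REGRESSION_COVARIATES_FULL = [
    "econ_able",
    "education_college",
    "in_relationship",
    "urban",
    "minority",
    "insurance",
    "region_south",
]

#: Sensitivity-analysis set: the same exclusive of urbanicity and region.
REGRESSION_COVARIATES_REDUCED = [
    c for c in REGRESSION_COVARIATES_FULL if c not in ("urban", "region_south")
]

#: Adjustment set for the proxy-based anchor estimation, which uses the
#: jointly observed characteristics (age band, relationship status,
#: minority status, financial ability, health coverage, HIV status,
#: region standing in for country of residence).
ANCHOR_COVARIATES = [
    "age",
    "in_relationship",
    "minority",
    "econ_able",
    "insurance",
    "hiv_positive",
    "region_south",
]

COVARIATE_SETS = {
    "full": REGRESSION_COVARIATES_FULL,
    "reduced": REGRESSION_COVARIATES_REDUCED,
    "anchor": ANCHOR_COVARIATES,
}


def build_design(
    df: pd.DataFrame, covariates, codebook=None, intercept: bool = True
) -> np.ndarray:
    """Design matrix for the named covariates.

    Variables declared in the codebook with more than two levels are
    reference-coded into indicator columns (first level omitted); binary
    and continuous variables enter as-is.
    """
    cols = []
    if intercept:
        cols.append(np.ones(len(df)))
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not in data")
        x = df[name]
        levels = None
        if codebook is not None and name in codebook:
            levels = codebook[name].levels
        if levels is not None and len(levels) > 2:
            for lev in levels[1:]:
                cols.append((x == lev).to_numpy(float))
        else:
            cols.append(x.to_numpy(float))
    return np.column_stack(cols)


def design_column_names(df, covariates, codebook=None, intercept=True) -> list[str]:
    names = ["const"] if intercept else []
    for name in covariates:
        levels = codebook[name].levels if (codebook is not None and name in codebook) else None
        if levels is not None and len(levels) > 2:
            names += [f"{name}=={lev}" for lev in levels[1:]]
        else:
            names.append(name)
    return names
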