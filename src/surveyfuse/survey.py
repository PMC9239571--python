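"""Survey containers: rectangular data + a codebook of variable roles.

A :class:`SurveyFrame` couples a pandas DataFrame with a :class:`Codebook`
describing each column's role in the fusion analysis (jointly observed
demographic, exposure item, outcome, proxy measure, ...), its admissible
levels and its numeric coding.  Frames round-trip losslessly through
CSV + YAML so that fixtures on disk and in-memory objects are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: Recognised variable roles.
ROLES = (
    "demographic",
    "exposure_item",
    "exposure_score",
    "outcome",
    "outcome_item",
    "proxy",
    "weight",
    "id",
)


class CodebookError(ValueError):
    """A survey file and its codebook disagree."""


@dataclass(frozen=True)
class VariableDef:
    """One codebook entry.

    Parameters
    ----------
    name : column name in the data file.
    role : one of :data:`ROLES`.
    levels : admissible values for categorical/Likert variables; ``None``
        for unconstrained continuous variables.
    labels : optional human-readable labels, parallel to ``levels``.
    missing_codes : raw values to be treated as missing on load.
    """

    name: str
    role: str
    levels: tuple | None = None
    labels: tuple | None = None
    missing_codes: tuple = ()

    def __post_init__(self):
        if self.role not in ROLES:
            raise CodebookError(f"unknown role {self.role!r} for {self.name!r}")

    def to_dict(self) -> dict:
        d = {"role": self.role}
        if self.levels is not None:
            d["levels"] = list(self.levels)
        if self.labels is not None:
            d["labels"] = list(self.labels)
        if self.missing_codes:
            d["missing_codes"] = list(self.missing_codes)
        return d

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "VariableDef":
        return cls(
            name=name,
            role=d["role"],
            levels=tuple(d["levels"]) if d.get("levels") is not None else None,
            labels=tuple(d["labels"]) if d.get("labels") is not None else None,
            missing_codes=tuple(d.get("missing_codes", ())),
        )


@dataclass
class Codebook:
    """Mapping of variable name -> :class:`VariableDef`, plus free-form
    sections for scale definitions and outcome codings (consumed by
    :mod:`surveyfuse.scales`)."""

    variables: dict[str, VariableDef] = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    outcome_codings: dict = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def __getitem__(self, name: str) -> VariableDef:
        return self.variables[name]

    def names_by_role(self, *roles: str) -> list[str]:
        return [v.name for v in self.variables.values() if v.role in roles]

    def subset(self, names: Iterable[str]) -> "Codebook":
        names = list(names)
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise CodebookError(f"codebook has no entry for {missing}")
        return Codebook(
            variables={n: self.variables[n] for n in names},
            scales=self.scales,
            outcome_codings=self.outcome_codings,
        )

    def to_dict(self) -> dict:
        return {
            "variables": {n: v.to_dict() for n, v in self.variables.items()},
            "scales": self.scales,
            "outcome_codings": self.outcome_codings,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        return cls(
            variables={
                n: VariableDef.from_dict(n, v) for n, v in d.get("variables", {}).items()
            },
            scales=dict(d.get("scales", {})),
            outcome_codings=dict(d.get("outcome_codings", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SurveyFrame:
    """A survey file: records x variables, with role tags and optional
    per-record weights."""

    data: pd.DataFrame
    codebook: Codebook
    name: str = "survey"

    def __post_init__(self):
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        """Check the data against the codebook; raise :class:`CodebookError`
        naming the first offending column."""
        for col in self.data.columns:
            if col not in self.codebook:
                raise CodebookError(
                    f"{self.name}: column {col!r} in data but absent from codebook"
                )
        for name, var in self.codebook.variables.items():
            if name not in self.data.columns:
                raise CodebookError(
                    f"{self.name}: codebook variable {name!r} missing from data"
                )
            if var.levels is not None:
                col = self.data[name]
                observed = col.dropna().unique()
                allowed = set(var.levels) | set(var.missing_codes)
                bad = [v for v in observed if v not in allowed]
                if bad:
                    row = int(self.data.index[col == bad[0]][0])
                    raise CodebookError(
                        f"{self.name}: value {bad[0]!r} in column {name!r} "
                        f"(first at row {row}) outside declared levels"
                    )

    def columns_by_role(self, *roles: str) -> list[str]:
        return [c for c in self.data.columns if self.codebook[c].role in roles]

    @property
    def weights(self) -> np.ndarray:
        wcols = self.columns_by_role("weight")
        if wcols:
            return self.data[wcols[0]].to_numpy(float)
        return np.ones(len(self.data))

    def drop_roles(self, *roles: str) -> "SurveyFrame":
        """Return a copy with all columns of the given roles removed from
        both the data and the codebook (masked, not blanked)."""
        keep = [c for c in self.data.columns if self.codebook[c].role not in roles]
        return SurveyFrame(
            data=self.data[keep].copy(),
            codebook=self.codebook.subset(keep),
            name=self.name,
        )

    # ------------------------------------------------------------------ I/O
    def save(self, csv_path: str | Path, codebook_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False)
        if codebook_path is None:
            codebook_path = csv_path.with_suffix(".codebook.yaml")
        self.codebook.save(codebook_path)

    @classmethod
    def load(
        cls,
        csv_path: str | Path,
        codebook_path: str | Path | None = None,
        name: str | None = None,
    ) -> "SurveyFrame":
        csv_path = Path(csv_path)
        if codebook_path is None:
            codebook_path = csv_path.with_suffix(".codebook.yaml")
        codebook = Codebook.load(codebook_path)
        data = pd.read_csv(csv_path)
        return cls(data=data, codebook=codebook, name=name or csv_path.stem)


def check_shared_covariates(a: SurveyFrame, b: SurveyFrame) -> list[str]:
    """Names of jointly observed (demographic) variables shared by both files.

    Raises :class:`CodebookError` listing any demographic present in one
    file but not the other, or coded with different level sets.
    """
    da = set(a.columns_by_role("demographic"))
    db = set(b.columns_by_role("demographic"))
    if da != db:
        raise CodebookError(
            f"demographic codebooks differ: only in {a.name}: {sorted(da - db)}; "
            f"only in {b.name}: {sorted(db - da)}"
        )
    discrepant = [
        n for n in sorted(da) if a.codebook[n].levels != b.codebook[n].levels
    ]
    if discrepant:
        raise CodebookError(f"level sets differ between files for: {discrepant}")
    return sorted(da)
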