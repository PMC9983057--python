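"""Longitudinal survival panels with monotone death/censoring structure.

The data model follows the ordering ``O = (L_j, A_j, C_{j+1}, Y_{j+1})`` for
treatment intervals ``j = 0..J-1``: covariates are measured at the start of the
interval, a binary treatment is assigned during it, and censoring/survival
status is updated at its end.  ``Y_0 = 1`` and ``C_0 = 0`` for everyone, the
survival indicator is monotone non-increasing, the censoring indicator is
absorbing, and every variable after death or censoring is missing-coded (NaN)
and excluded from all downstream fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelData",
    "PanelSchema",
    "PanelValidationError",
    "SchemaError",
    "read_panel",
    "write_panel",
]


class PanelValidationError(ValueError):
    """A structural invariant of the panel is violated."""


class SchemaError(ValueError):
    """The file does not match the declared column schema."""


@dataclass(frozen=True)
class PanelSchema:
    """Column mapping for long-format CSV I/O.

    One row per subject-interval; the row at time ``j`` carries ``L_j``,
    ``A_j`` and, in the ``censor``/``outcome`` columns, ``C_{j+1}`` and
    ``Y_{j+1}``.  Rows after death or censoring may be absent or missing-coded.
    """

    covariates: Sequence[str]
    lstar: str = "lstar"
    id: str = "id"
    time: str = "time"
    treatment: str = "A"
    censor: str = "C"
    outcome: str = "Y"

    def __post_init__(self) -> None:
        if self.lstar not in self.covariates:
            raise SchemaError(
                f"l-star column {self.lstar!r} must be among the covariates"
            )


@dataclass
class PanelData:
    """Subjects x intervals arrays for a longitudinal survival panel.

    Attributes
    ----------
    covariates : mapping of name -> float array of shape (n, J)
        Time-varying covariates; NaN after death or censoring.  Baseline
        covariates are stored tiled across intervals.
    lstar : str
        Name of the indication indicator column ``L*_j`` used by
        intervention families.
    A : (n, J) array
        Binary treatment, NaN off the risk set.  ``A_{-1} = 0`` by convention.
    C : (n, J+1) array
        Censoring indicator, ``C_0 = 0``, monotone non-decreasing once 1.
    Y : (n, J+1) array
        Survival indicator, ``Y_0 = 1``, monotone non-increasing; NaN once
        censored.
    """

    covariates: Mapping[str, np.ndarray]
    lstar: str
    A: np.ndarray
    C: np.ndarray
    Y: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.covariates = {
            k: np.asarray(v, dtype=float) for k, v in self.covariates.items()
        }
        if self.validate:
            self._check()

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def J(self) -> int:
        return self.A.shape[1]

    def _check(self) -> None:
        n, J = self.A.shape
        if self.Y.shape != (n, J + 1) or self.C.shape != (n, J + 1):
            raise PanelValidationError(
                f"Y and C must have shape (n, J+1)=({n}, {J + 1})"
            )
        if self.lstar not in self.covariates:
            raise SchemaError(f"designated l-star column {self.lstar!r} missing")
        for name, arr in self.covariates.items():
            if arr.shape != (n, J):
                raise PanelValidationError(
                    f"covariate {name!r} has shape {arr.shape}, expected {(n, J)}"
                )
        if not np.all(self.Y[:, 0] == 1):
            i = int(np.flatnonzero(self.Y[:, 0] != 1)[0])
            raise PanelValidationError(f"Y_0 != 1 for subject {i}")
        if not np.all(self.C[:, 0] == 0):
            i = int(np.flatnonzero(self.C[:, 0] != 0)[0])
            raise PanelValidationError(f"C_0 != 0 for subject {i}")
        # monotone survival: no 0 -> 1 revival among observed values
        for j in range(J):
            dead = self.Y[:, j] == 0
            revived = dead & (self.Y[:, j + 1] == 1)
            if np.any(revived):
                i = int(np.flatnonzero(revived)[0])
                raise PanelValidationError(
                    f"survival indicator revives 0->1 for subject {i} at interval {j + 1}"
                )
            uncens = dead & (self.C[:, j] == 1) & (self.C[:, j + 1] == 0)
            dropped = (self.C[:, j] == 1) & (self.C[:, j + 1] == 0)
            if np.any(dropped):
                i = int(np.flatnonzero(dropped)[0])
                raise PanelValidationError(
                    f"censoring indicator drops 1->0 for subject {i} at interval {j + 1}"
                )
            del uncens

    # ------------------------------------------------------------------ masks
    def at_risk(self, j: int) -> np.ndarray:
        """Boolean mask of subjects alive and uncensored entering interval j."""
        if not 0 <= j <= self.J - 1:
            raise IndexError(f"interval {j} out of range [0, {self.J - 1}]")
        return (self.Y[:, j] == 1) & (self.C[:, j] == 0)

    def at_risk_index(self, j: int) -> np.ndarray:
        """Indices of subjects with ``Y_j = 1`` and ``C_j = 0``."""
        return np.flatnonzero(self.at_risk(j))

    def frame(self, j: int) -> dict[str, np.ndarray]:
        """Interval-j history row: covariates plus treatment and its lag.

        This is the documented accessor contract consumed by intervention
        ``h`` functions and model formulas: keys are the covariate names at
        interval ``j``, one-interval covariate lags as ``"<name>_lag"``
        (zeros at j=0), plus ``"A"`` (treatment at j) and ``"Alag"``
        (treatment at j-1, zero at j=0).
        """
        cols = {k: v[:, j] for k, v in self.covariates.items()}
        for k, v in self.covariates.items():
            cols[f"{k}_lag"] = v[:, j - 1] if j > 0 else np.zeros(self.n)
        cols["A"] = self.A[:, j]
        cols["Alag"] = self.A[:, j - 1] if j > 0 else np.zeros(self.n)
        return cols

    def subset(self, idx: np.ndarray) -> "PanelData":
        """Row-gather (duplicates allowed; used by bootstrap and splits)."""
        return PanelData(
            covariates={k: v[idx] for k, v in self.covariates.items()},
            lstar=self.lstar,
            A=self.A[idx],
            C=self.C[idx],
            Y=self.Y[idx],
            validate=False,
        )

    def copy(self) -> "PanelData":
        return self.subset(np.arange(self.n))


def read_panel(path, schema: PanelSchema) -> PanelData:
    """Read a long-format delimited file into a validated :class:`PanelData`.

    Rows after death or censoring may be absent from the file or present with
    missing values; both are accepted and normalised to the NaN coding.
    """
    df = pd.read_csv(path)
    required = [schema.id, schema.time, schema.treatment, schema.censor,
                schema.outcome, *schema.covariates]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    ids = df[schema.id].to_numpy()
    uniq, inv = np.unique(ids, return_inverse=True)
    n = len(uniq)
    J = int(df[schema.time].max()) + 1
    t = df[schema.time].to_numpy(dtype=int)
    if t.min() < 0:
        raise SchemaError("negative time index")

    cov = {c: np.full((n, J), np.nan) for c in schema.covariates}
    A = np.full((n, J), np.nan)
    C = np.zeros((n, J + 1))
    Y = np.full((n, J + 1), np.nan)
    Y[:, 0] = 1.0
    for c in schema.covariates:
        cov[c][inv, t] = df[c].to_numpy(dtype=float)
    A[inv, t] = df[schema.treatment].to_numpy(dtype=float)
    Cnext = np.full((n, J), np.nan)
    Ynext = np.full((n, J), np.nan)
    Cnext[inv, t] = df[schema.censor].to_numpy(dtype=float)
    Ynext[inv, t] = df[schema.outcome].to_numpy(dtype=float)
    # propagate the absorbing states over absent rows
    for j in range(J):
        C[:, j + 1] = np.where(np.isnan(Cnext[:, j]), np.maximum(C[:, j], 0),
                               Cnext[:, j])
        C[:, j + 1] = np.where(C[:, j] == 1, 1.0, C[:, j + 1])
        # absent rows keep the absorbing death state; present values are
        # taken as-is so that revivals are caught by validation
        absent = np.isnan(Ynext[:, j])
        Y[:, j + 1] = np.where(absent & (Y[:, j] == 0), 0.0, Ynext[:, j])
        Y[:, j + 1] = np.where(C[:, j + 1] == 1, np.nan, Y[:, j + 1])
    return PanelData(covariates=cov, lstar=schema.lstar, A=A, C=C, Y=Y)


def write_panel(panel: PanelData, path, schema: PanelSchema | None = None) -> None:
    """Write a panel to long CSV (one row per subject-interval at risk)."""
    if schema is None:
        schema = PanelSchema(covariates=list(panel.covariates), lstar=panel.lstar)
    rows = []
    for j in range(panel.J):
        mask = panel.at_risk(j)
        idx = np.flatnonzero(mask)
        block = {schema.id: idx, schema.time: j}
        for c in schema.covariates:
            block[c] = panel.covariates[c][idx, j]
        block[schema.treatment] = panel.A[idx, j]
        block[schema.censor] = panel.C[idx, j + 1]
        block[schema.outcome] = panel.Y[idx, j + 1]
        rows.append(pd.DataFrame(block))
    out = pd.concat(rows, ignore_index=True).sort_values(
        [schema.id, schema.time], kind="stable"
    )
    out.to_csv(path, index=False)
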