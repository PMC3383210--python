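"""Activity tables, descriptor matrices and packaged reference data.

The package models inhibitory potency as pIC50 = -log10(IC50 in mol/L),
i.e. ``9 - log10(IC50 in nM)``.  Three small reference tables ship with the
package and can be loaded by name:

``table1``
    31 cinnamoyl pyrrolidine MMP-2 inhibitors with IC50 (nM) and pIC50.
``table2``
    Observed vs. predicted pIC50 for the five external-test compounds.
``eq1_stats`` / ``eq2_stats``
    The published statistic blocks of the auxiliary (n=31) and real (n=26)
    PLS models, used for algebraic consistency checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "ActivityTable",
    "DescriptorTable",
    "ObservedPredictedTable",
    "ic50_to_pic50",
    "softness_from_orbitals",
    "format_pic50",
    "load_activity_table",
    "load_observed_predicted",
    "load_descriptor_table",
    "load_model_stats",
    "write_activity_table",
    "write_observed_predicted",
    "fixture_path",
]

_FIXTURE_NAMES = {
    "table1": "table1.csv",
    "table2": "table2.csv",
    "eq1_stats": "eq1_stats.json",
    "eq2_stats": "eq2_stats.json",
}

#: IC50 unit -> factor converting to mol/L
_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "mM": 1e-3, "M": 1.0}

# printed tables agree with recomputation to this absolute tolerance
_PRINT_TOL = 5e-4


def fixture_path(name: str) -> Path:
    """Return the on-disk path of a packaged fixture (``table1`` etc.)."""
    if name not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURE_NAMES)}")
    return Path(str(resources.files("opspls") / "fixtures" / _FIXTURE_NAMES[name]))


def ic50_to_pic50(ic50, unit: str = "nM"):
    """Convert IC50 to pIC50 (= -log10 of the molar concentration).

    Parameters
    ----------
    ic50 : float or array-like
        Half-maximal inhibitory concentration, strictly positive.
    unit : str
        Concentration unit of the input ("nM" default; also "uM", "mM", "M").

    For nanomolar input this is ``9 - log10(ic50)``.
    """
    try:
        factor = _UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(f"unknown IC50 unit {unit!r}") from None
    arr = np.asarray(ic50, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("IC50 must be finite and > 0")
    out = -np.log10(arr * factor)
    return float(out) if np.isscalar(ic50) or out.ndim == 0 else out


def softness_from_orbitals(e_lumo: float, e_homo: float) -> float:
    """Molecular softness 1/GAP with GAP = E_LUMO - E_HOMO.

    Softness is the reciprocal of the frontier-orbital energy gap; softer
    molecules (small gap) are generally more reactive.
    """
    gap = e_lumo - e_homo
    if gap == 0:
        raise ValueError("zero HOMO-LUMO gap: softness undefined")
    return 1.0 / gap


def format_pic50(value: float, decimals: int = 3) -> str:
    """Format a pIC50 for display: fixed decimals, half-away-from-zero."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompoundRecord:
    """A single compound: id, optional substituents, IC50 (nM) and pIC50."""

    id: str
    pic50: float
    ic50_nM: Optional[float] = None
    r1: Optional[str] = None
    r2: Optional[str] = None
    r3: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.ic50_nM is not None:
            if self.ic50_nM <= 0:
                raise ValueError(f"{self.id}: IC50 must be > 0")
            expected = ic50_to_pic50(self.ic50_nM)
            if abs(self.pic50 - expected) > _PRINT_TOL:
                raise ValueError(
                    f"{self.id}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50_nM} nM (expected {expected:.4f})"
                )


@dataclass
class ActivityTable:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    records: list[CompoundRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("activity table is empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        for r in self.records:
            if r.id == compound_id:
                return r
        raise KeyError(compound_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def pic50(self) -> np.ndarray:
        return np.array([r.pic50 for r in self.records], dtype=float)

    def subset(self, ids: Sequence[str]) -> "ActivityTable":
        """Rows for ``ids``, in the given order."""
        return ActivityTable([self[i] for i in ids])

    def drop(self, ids: Sequence[str]) -> "ActivityTable":
        """All rows except ``ids`` (order preserved)."""
        drop = set(ids)
        missing = drop - set(self.ids)
        if missing:
            raise KeyError(f"ids not in table: {sorted(missing)}")
        return ActivityTable([r for r in self.records if r.id not in drop])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "r1": [r.r1 for r in self.records],
                "r2": [r.r2 for r in self.records],
                "r3": [r.r3 for r in self.records],
                "ic50_nM": [r.ic50_nM for r in self.records],
                "pic50": [r.pic50 for r in self.records],
            }
        )


@dataclass
class DescriptorTable:
    """Compounds x molecular descriptors matrix with row/column labels."""

    ids: list[str]
    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.names = list(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.names)} names"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate compound ids")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate descriptor names")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.names)

    def select(self, names: Sequence[str]) -> "DescriptorTable":
        """Column subset, in the given order."""
        idx = [self.names.index(n) for n in names]
        return DescriptorTable(self.ids, list(names), self.values[:, idx])

    def rows(self, ids: Sequence[str]) -> "DescriptorTable":
        """Row subset, in the given order."""
        pos = {cid: k for k, cid in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return DescriptorTable(list(ids), self.names, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DescriptorTable":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))


@dataclass
class ObservedPredictedTable:
    """Observed vs predicted activities; residual = observed - predicted."""

    ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    residual: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if len(self.ids) != len(self.observed) or len(self.ids) != len(self.predicted):
            raise ValueError("ids/observed/predicted length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids")
        computed = self.observed - self.predicted
        if self.residual is None:
            self.residual = computed
        else:
            self.residual = np.asarray(self.residual, dtype=float)
            if np.any(np.abs(self.residual - computed) > _PRINT_TOL):
                raise ValueError("stated residuals inconsistent with observed - predicted")
            self.residual = computed

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "observed": self.observed,
                "predicted": self.predicted,
                "residual": self.residual,
            }
        )


def _resolve(source: Union[str, Path]) -> Path:
    if isinstance(source, str) and source in _FIXTURE_NAMES:
        return fixture_path(source)
    return Path(source)


def load_activity_table(source: Union[str, Path]) -> ActivityTable:
    """Read an activity table from CSV (or the packaged fixture ``table1``).

    Requires an ``id`` column plus ``ic50_nM`` and/or ``pic50``; pIC50 is
    filled from IC50 where absent.
    """
    df = pd.read_csv(_resolve(source))
    if "id" not in df.columns:
        raise ValueError("activity CSV must have an 'id' column")
    has_ic50 = "ic50_nM" in df.columns
    has_pic50 = "pic50" in df.columns
    if not has_ic50 and not has_pic50:
        raise ValueError("activity CSV needs an 'ic50_nM' and/or 'pic50' column")
    records = []
    for _, row in df.iterrows():
        ic50 = float(row["ic50_nM"]) if has_ic50 and pd.notna(row["ic50_nM"]) else None
        if has_pic50 and pd.notna(row["pic50"]):
            pic50 = float(row["pic50"])
        elif ic50 is not None:
            pic50 = ic50_to_pic50(ic50)
        else:
            raise ValueError(f"{row['id']}: neither IC50 nor pIC50 given")
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                pic50=pic50,
                ic50_nM=ic50,
                r1=_opt_str(row.get("r1")),
                r2=_opt_str(row.get("r2")),
                r3=_opt_str(row.get("r3")),
            )
        )
    return ActivityTable(records)


def _opt_str(v) -> Optional[str]:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else str(v)


def load_observed_predicted(source: Union[str, Path]) -> ObservedPredictedTable:
    """Read an observed/predicted CSV (or the packaged fixture ``table2``)."""
    df = pd.read_csv(_resolve(source))
    for col in ("id", "observed", "predicted"):
        if col not in df.columns:
            raise ValueError(f"observed/predicted CSV must have a {col!r} column")
    return ObservedPredictedTable(
        ids=[str(i) for i in df["id"]],
        observed=df["observed"].to_numpy(float),
        predicted=df["predicted"].to_numpy(float),
        residual=df["residual"].to_numpy(float) if "residual" in df.columns else None,
    )


def load_descriptor_table(source: Union[str, Path]) -> DescriptorTable:
    """Read a compounds x descriptors CSV (first column = compound id)."""
    return DescriptorTable.from_csv(_resolve(source))


def load_model_stats(source: Union[str, Path]) -> dict:
    """Load a published statistic block (``eq1_stats``/``eq2_stats`` or a path)."""
    with open(_resolve(source)) as fh:
        return json.load(fh)


def write_activity_table(table: ActivityTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_observed_predicted(table: ObservedPredictedTable, path) -> None:
    table.to_frame().to_csv(path, index=False)
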