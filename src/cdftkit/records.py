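"""Molecule energy records and their delimited-table I/O.

A :class:`MoleculeEnergyRecord` carries the frontier-orbital energies of the
neutral N-electron molecule (HOMO, LUMO), optionally the SOMO of its radical
anion (the HOMO of the N+1 system), and optionally the ground-state total
energies of the N−1, N and N+1 electron systems.  These are the only inputs
the KID diagnostics and the global reactivity descriptors need.

The on-disk schema is a delimited table (comma or tab) with header columns

    id, label, eps_homo, eps_lumo, eps_somo_anion, e_gs_nm1, e_gs_n, e_gs_np1, unit

where ``unit`` is ``eV`` or ``hartree`` per row (default eV) and blank cells
mean "absent".  Energies are converted to eV on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import pandas as pd

from .exceptions import SchemaError, ValidationError
from .units import hartree_to_ev

__all__ = [
    "MoleculeEnergyRecord",
    "read_energy_records",
    "write_energy_records",
    "ENERGY_COLUMNS",
]

#: energy-bearing columns of the delimited schema, in canonical order
ENERGY_COLUMNS = (
    "eps_homo",
    "eps_lumo",
    "eps_somo_anion",
    "e_gs_nm1",
    "e_gs_n",
    "e_gs_np1",
)

_MANDATORY = ("id", "eps_homo", "eps_lumo")


@dataclass(frozen=True)
class MoleculeEnergyRecord:
    """Orbital and ground-state energies of one molecule, in eV.

    Parameters
    ----------
    id : str
        Short token identifying the molecule.
    eps_homo, eps_lumo : float
        HOMO and LUMO energies of the neutral N-electron system (eV);
        ``eps_homo < eps_lumo`` strictly.
    eps_somo_anion : float, optional
        SOMO energy of the N+1 radical anion (its HOMO), eV.
    e_gs_nm1, e_gs_n, e_gs_np1 : float, optional
        Ground-state total energies of the N−1, N, N+1 electron systems (eV).
        KID computation requires all three.
    label : str
        Free-text name.
    source : str
        Provenance note.
    """

    id: str
    eps_homo: float
    eps_lumo: float
    eps_somo_anion: Optional[float] = None
    e_gs_nm1: Optional[float] = None
    e_gs_n: Optional[float] = None
    e_gs_np1: Optional[float] = None
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.eps_homo is None or self.eps_lumo is None:
            raise ValidationError(
                f"record {self.id!r}: eps_homo and eps_lumo are mandatory"
            )
        for name in ENERGY_COLUMNS:
            value = getattr(self, name)
            if value is not None and not math.isfinite(value):
                raise ValidationError(
                    f"record {self.id!r}: field {name} is not finite ({value!r})"
                )
        if not self.eps_homo < self.eps_lumo:
            raise ValidationError(
                f"record {self.id!r}: eps_homo ({self.eps_homo}) must be "
                f"strictly below eps_lumo ({self.eps_lumo})"
            )

    @property
    def has_kid_energies(self) -> bool:
        """True when all three ground-state total energies are present."""
        return None not in (self.e_gs_nm1, self.e_gs_n, self.e_gs_np1)

    @property
    def gap(self) -> float:
        """HOMO–LUMO gap, eV (strictly positive by construction)."""
        return self.eps_lumo - self.eps_homo

    def replace(self, **changes) -> "MoleculeEnergyRecord":
        return replace(self, **changes)


def _detect_sep(path_or_buf: Union[str, Path, IO[str]]) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab; python engine required
    return pd.read_csv(path_or_buf, sep=None, engine="python", dtype=str,
                       skipinitialspace=True)


def read_energy_records(
    source: Union[str, Path, IO[str]],
) -> list[MoleculeEnergyRecord]:
    """Read molecule energy records from a delimited file (CSV or TSV).

    Energies are converted to eV according to each row's ``unit`` cell
    (``eV`` assumed when the column is absent or blank).  Blank energy cells
    yield absent fields.  A header-only file yields an empty list.

    Raises
    ------
    SchemaError
        If a mandatory column (id, eps_homo, eps_lumo) is missing.
    ValidationError
        If a row violates a record invariant (named by record id).
    """
    frame = _detect_sep(source)
    frame.columns = [str(c).strip() for c in frame.columns]
    for column in _MANDATORY:
        if column not in frame.columns:
            raise SchemaError(f"missing mandatory column {column!r}")

    records: list[MoleculeEnergyRecord] = []
    for _, row in frame.iterrows():
        unit = "eV"
        if "unit" in frame.columns and isinstance(row.get("unit"), str):
            unit = row["unit"].strip() or "eV"
        if unit.lower() not in ("ev", "hartree"):
            raise SchemaError(f"unknown unit {unit!r} (expected eV or hartree)")
        convert = hartree_to_ev if unit.lower() == "hartree" else (lambda x: x)

        def cell(name: str) -> Optional[float]:
            if name not in frame.columns:
                return None
            raw = row[name]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                return None
            raw = str(raw).strip().replace("−", "-")  # unicode minus
            if not raw:
                return None
            try:
                return convert(float(raw))
            except ValueError as exc:
                raise SchemaError(
                    f"non-numeric value {raw!r} in column {name!r}"
                ) from exc

        rid = str(row["id"]).strip()
        records.append(
            MoleculeEnergyRecord(
                id=rid,
                label=str(row["label"]).strip()
                if "label" in frame.columns and isinstance(row.get("label"), str)
                else "",
                eps_homo=cell("eps_homo"),
                eps_lumo=cell("eps_lumo"),
                eps_somo_anion=cell("eps_somo_anion"),
                e_gs_nm1=cell("e_gs_nm1"),
                e_gs_n=cell("e_gs_n"),
                e_gs_np1=cell("e_gs_np1"),
                source=str(row["source"]).strip()
                if "source" in frame.columns and isinstance(row.get("source"), str)
                else "",
            )
        )
    return records


def records_to_frame(records: Iterable[MoleculeEnergyRecord]) -> pd.DataFrame:
    """Canonical DataFrame rendering of records (energies in eV)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "label": r.label,
                **{name: getattr(r, name) for name in ENERGY_COLUMNS},
                "unit": "eV",
                "source": r.source,
            }
        )
    columns = ["id", "label", *ENERGY_COLUMNS, "unit", "source"]
    return pd.DataFrame(rows, columns=columns)


def write_energy_records(
    records: Iterable[MoleculeEnergyRecord],
    sink: Union[str, Path, IO[str]],
) -> None:
    """Write records to a CSV file in the documented schema (eV)."""
    records_to_frame(records).to_csv(sink, index=False)
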