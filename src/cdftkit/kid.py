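"""KID ("Koopmans in DFT") compliance diagnostics.

A density functional whose orbital energies obey the ionization-energy and
Janak theorems satisfies −I ≈ ϵH and −A ≈ ϵL, where I and A are the vertical
ionization energy and electron affinity from ΔSCF total energies at fixed
geometry.  The KID residuals quantify the deviation:

    J_I  = ϵH + E(N−1) − E(N)
    J_A  = ϵL + E(N) − E(N+1)
    J_HL = sqrt(J_I² + J_A²)
    ΔSL  = ϵ_SOMO(anion) − ϵL(neutral)

all in eV.  Small residuals justify computing frontier-orbital reactivity
descriptors with that functional.  No universal pass threshold exists in the
literature; the default here is 0.15 eV applied independently to J_HL and
|ΔSL|, generous enough to accept residuals of the order reported for range-
separated functionals in water while rejecting the ~1 eV failures of
conventional GGAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .exceptions import ValidationError
from .records import MoleculeEnergyRecord

__all__ = [
    "DEFAULT_KID_TOLERANCE",
    "KidDiagnostics",
    "compute_ji",
    "compute_ja",
    "compute_jhl",
    "compute_delta_sl",
    "kid_assess",
]

DEFAULT_KID_TOLERANCE = 0.15
"""Default compliance threshold for J_HL and |ΔSL|, eV."""


@dataclass(frozen=True)
class KidDiagnostics:
    """KID residuals of one molecule and the pass/fail verdict."""

    ji: float
    ja: float
    jhl: float
    delta_sl: Optional[float]
    tolerance: float
    passed: bool


def _require(record: MoleculeEnergyRecord, *fields: str) -> None:
    missing = [f for f in fields if getattr(record, f) is None]
    if missing:
        raise ValidationError(
            f"record {record.id!r}: KID computation requires {', '.join(missing)}"
        )


def compute_ji(record: MoleculeEnergyRecord) -> float:
    """Ionization-side residual J_I = ϵH + E(N−1) − E(N), eV."""
    _require(record, "e_gs_nm1", "e_gs_n")
    return record.eps_homo + record.e_gs_nm1 - record.e_gs_n


def compute_ja(record: MoleculeEnergyRecord) -> float:
    """Affinity-side residual J_A = ϵL + E(N) − E(N+1), eV."""
    _require(record, "e_gs_n", "e_gs_np1")
    return record.eps_lumo + record.e_gs_n - record.e_gs_np1


def compute_jhl(ji: float, ja: float) -> float:
    """Combined residual, the root-sum-of-squares of J_I and J_A."""
    return math.hypot(ji, ja)


def compute_delta_sl(record: MoleculeEnergyRecord) -> float:
    """ΔSL = anion SOMO energy minus neutral LUMO energy, eV."""
    _require(record, "eps_somo_anion")
    return record.eps_somo_anion - record.eps_lumo


def kid_assess(
    record: MoleculeEnergyRecord,
    tolerance: float = DEFAULT_KID_TOLERANCE,
) -> KidDiagnostics:
    """Compute all KID residuals for a record and apply the pass rule.

    The verdict is ``passed`` iff J_HL <= tolerance and, when the anion SOMO
    is available, also |ΔSL| <= tolerance.  Requires the three ground-state
    total energies; the ΔSL term is skipped (not failed) when the SOMO is
    absent.
    """
    ji = compute_ji(record)
    ja = compute_ja(record)
    jhl = compute_jhl(ji, ja)
    delta_sl = (
        compute_delta_sl(record) if record.eps_somo_anion is not None else None
    )
    passed = jhl <= tolerance and (
        delta_sl is None or abs(delta_sl) <= tolerance
    )
    return KidDiagnostics(
        ji=ji, ja=ja, jhl=jhl, delta_sl=delta_sl,
        tolerance=tolerance, passed=passed,
    )
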