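"""Local reactivity fields: Fukui functions and the dual descriptor.

The Fukui function f(r) = (∂ρ(r)/∂N)_v is realised by finite differences of
ground-state densities at fixed geometry and fixed external potential:

    f⁺(r) = ρ_{N+1}(r) − ρ_N(r)     (susceptibility to nucleophilic attack)
    f⁻(r) = ρ_N(r) − ρ_{N−1}(r)     (susceptibility to electrophilic attack)
    DD(r) = f⁺(r) − f⁻(r) = ρ_{N+1}(r) − 2ρ_N(r) + ρ_{N−1}(r)

DD > 0 marks electrophilic-attack (electron-accepting) sites, DD < 0
nucleophilic ones.  Densities that integrate to N−1, N, N+1 electrons give
∫f⁺ = ∫f⁻ = 1 and ∫DD = 0 up to the quadrature of the grid.

The condensed (per-atom) variants act on per-atom electron populations from
any charge-partitioning scheme; no partitioning is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import ScalarField
from .exceptions import ValidationError

__all__ = [
    "DensityTriplet",
    "CondensedChargeSet",
    "fukui_plus",
    "fukui_minus",
    "dual_descriptor",
    "condensed_dual",
    "sign_partition",
    "field_integral",
]


def _check_same_geometry(a: ScalarField, b: ScalarField, what: str) -> None:
    if a.counts != b.counts:
        raise ValidationError(f"{what}: voxel counts differ ({a.counts} vs {b.counts})")
    if not np.array_equal(a.origin, b.origin):
        raise ValidationError(f"{what}: origins differ")
    if not np.array_equal(a.axes, b.axes):
        raise ValidationError(f"{what}: axes differ")
    if a.atoms != b.atoms:
        raise ValidationError(f"{what}: atom lists differ")


@dataclass(frozen=True)
class DensityTriplet:
    """Electron densities of the N−1, N and N+1 systems on one shared grid."""

    rho_nm1: ScalarField
    rho_n: ScalarField
    rho_np1: ScalarField

    def __post_init__(self) -> None:
        _check_same_geometry(self.rho_n, self.rho_nm1, "rho_nm1")
        _check_same_geometry(self.rho_n, self.rho_np1, "rho_np1")
        for name in ("rho_nm1", "rho_n", "rho_np1"):
            if np.any(getattr(self, name).values < 0):
                raise ValidationError(f"{name}: densities must be non-negative")


@dataclass(frozen=True)
class CondensedChargeSet:
    """Per-atom electron populations of the N−1, N and N+1 states."""

    p_nm1: np.ndarray
    p_n: np.ndarray
    p_np1: np.ndarray
    scheme: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_nm1", np.asarray(self.p_nm1, dtype=float))
        object.__setattr__(self, "p_n", np.asarray(self.p_n, dtype=float))
        object.__setattr__(self, "p_np1", np.asarray(self.p_np1, dtype=float))
        shapes = {self.p_nm1.shape, self.p_n.shape, self.p_np1.shape}
        if len(shapes) != 1 or self.p_n.ndim != 1:
            raise ValidationError(
                "population vectors must be 1-D with equal atom counts"
            )
        for arr in (self.p_nm1, self.p_n, self.p_np1):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("populations must be finite")


def fukui_plus(triplet: DensityTriplet) -> ScalarField:
    """f⁺ = ρ_{N+1} − ρ_N, voxelwise, on the shared grid."""
    return triplet.rho_n.with_values(
        triplet.rho_np1.values - triplet.rho_n.values
    )


def fukui_minus(triplet: DensityTriplet) -> ScalarField:
    """f⁻ = ρ_N − ρ_{N−1}, voxelwise, on the shared grid."""
    return triplet.rho_n.with_values(
        triplet.rho_n.values - triplet.rho_nm1.values
    )


def dual_descriptor(triplet: DensityTriplet) -> ScalarField:
    """DD = ρ_{N+1} − 2ρ_N + ρ_{N−1}, voxelwise, on the shared grid."""
    return triplet.rho_n.with_values(
        triplet.rho_np1.values
        - 2.0 * triplet.rho_n.values
        + triplet.rho_nm1.values
    )


def condensed_dual(charges: CondensedChargeSet) -> np.ndarray:
    """Per-atom dual descriptor: p_k(N+1) − 2 p_k(N) + p_k(N−1)."""
    return charges.p_np1 - 2.0 * charges.p_n + charges.p_nm1


def sign_partition(
    fieldobj: ScalarField, isovalue: float = 0.0
) -> tuple[ScalarField, ScalarField]:
    """Split a field into its > +isovalue and < −isovalue parts.

    Returns (positive, negative): the first keeps values strictly above
    +isovalue (0 elsewhere), the second keeps values strictly below
    −isovalue.  Both share the input grid.  With isovalue 0, positive +
    negative reconstructs every nonzero voxel of the input exactly.
    """
    if isovalue < 0:
        raise ValidationError(f"isovalue must be >= 0, got {isovalue}")
    v = fieldobj.values
    positive = np.where(v > isovalue, v, 0.0)
    negative = np.where(v < -isovalue, v, 0.0)
    return fieldobj.with_values(positive), fieldobj.with_values(negative)


def field_integral(fieldobj: ScalarField) -> float:
    """Riemann-sum integral: sum of voxel values times the voxel volume."""
    return float(fieldobj.values.sum()) * fieldobj.voxel_volume
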