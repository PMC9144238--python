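"""Synthetic inputs with known ground truth, plus the apratoxin fixture.

Every upstream quantity this toolkit consumes is normally produced by
electronic-structure software.  To make each pipeline stage testable without
one, this module generates:

* energy records with *injected* Koopmans residuals — the N±1 total energies
  are constructed as E(N−1) = E(N) − ϵH + r_I and E(N+1) = E(N) + ϵL − r_A,
  so the KID residuals J_I, J_A equal the drawn r values exactly and the
  residuals are returned as a ground-truth table;
* density triplets — sums of isotropic Gaussian bumps on a cubic grid,
  numerically renormalised so their grid integrals are exactly N−1, N, N+1
  electrons on the quadrature used by
  :func:`cdftkit.fields.field_integral`;
* condensed per-atom populations summing exactly to each state's electron
  count;
* minimal log texts that :func:`cdftkit.logparse.parse_simple_log` inverts.

It also packages the seven-row apratoxin A–G reference tables (frontier
orbital and KID data; printed global descriptors; printed pKa column) used
for calibration and regression checks.  Known quirks of the printed
reference data are noted on each constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import Atom, ScalarField
from .exceptions import GenerationError, ValidationError
from .fields import CondensedChargeSet, DensityTriplet
from .records import MoleculeEnergyRecord
from .units import ev_to_hartree

__all__ = [
    "SyntheticSpec",
    "generate_energy_records",
    "generate_density_triplet",
    "generate_condensed_charges",
    "generate_log_text",
    "apratoxin_fixture",
    "APRATOXIN_KID_TABLE",
    "APRATOXIN_GLOBAL_TABLE",
    "APRATOXIN_PKA_TABLE",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators (all energies eV, lengths bohr).

    Defaults emulate the apratoxin study conditions: seven drug-like
    molecules with HOMO near −6 eV, LUMO near −1.5 eV, Koopmans residuals of
    a few hundredths of an eV (the order reported for a KID-compliant
    range-separated functional in water), and SOMO–LUMO offsets of the same
    order.
    """

    seed: int = 0
    n_molecules: int = 7
    homo_range: tuple[float, float] = (-6.5, -5.8)
    lumo_range: tuple[float, float] = (-1.9, -1.1)
    koopmans_residual_sd: float = 0.05
    somo_offset_sd: float = 0.03
    grid_counts: tuple[int, int, int] = (24, 24, 24)
    box_length: float = 10.0
    n_atoms: int = 3
    electron_count: int = 10

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        for name in ("homo_range", "lumo_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be a non-degenerate interval")
        if self.homo_range[1] >= self.lumo_range[0]:
            raise ValidationError(
                "homo_range must lie strictly below lumo_range"
            )
        if self.koopmans_residual_sd < 0 or self.somo_offset_sd < 0:
            raise ValidationError("residual scales must be >= 0")
        if any(c < 1 for c in self.grid_counts) or len(self.grid_counts) != 3:
            raise ValidationError("grid_counts must be 3 positive ints")
        if self.n_atoms < 1 or self.electron_count < 2:
            raise ValidationError("need n_atoms >= 1 and electron_count >= 2")


def generate_energy_records(
    spec: SyntheticSpec,
) -> tuple[list[MoleculeEnergyRecord], pd.DataFrame]:
    """Draw energy records with retained KID ground truth.

    Returns (records, truth) where ``truth`` has one row per record with the
    injected residuals: columns id, ji, ja, delta_sl.  With
    ``koopmans_residual_sd = 0`` every record is exactly Koopmans-compliant.
    Identical specs produce identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeEnergyRecord] = []
    truth_rows = []
    for i in range(spec.n_molecules):
        h = float(rng.uniform(*spec.homo_range))
        l = float(rng.uniform(*spec.lumo_range))
        e_gs_n = float(rng.uniform(-2000.0, -1000.0))
        r_i = float(rng.normal(0.0, spec.koopmans_residual_sd)) \
            if spec.koopmans_residual_sd > 0 else 0.0
        r_a = float(rng.normal(0.0, spec.koopmans_residual_sd)) \
            if spec.koopmans_residual_sd > 0 else 0.0
        offset = float(rng.normal(0.0, spec.somo_offset_sd)) \
            if spec.somo_offset_sd > 0 else 0.0
        records.append(
            MoleculeEnergyRecord(
                id=f"M{i:03d}",
                label=f"synthetic molecule {i}",
                eps_homo=h,
                eps_lumo=l,
                eps_somo_anion=l + offset,
                e_gs_nm1=e_gs_n - h + r_i,
                e_gs_n=e_gs_n,
                e_gs_np1=e_gs_n + l - r_a,
                source=f"synthetic(seed={spec.seed})",
            )
        )
        truth_rows.append({"id": f"M{i:03d}", "ji": r_i, "ja": r_a,
                           "delta_sl": offset})
    return records, pd.DataFrame(truth_rows, columns=["id", "ji", "ja", "delta_sl"])


def _gaussian_mixture(
    grid: np.ndarray,
    centers: np.ndarray,
    widths: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    # grid: (nx,ny,nz,3); centers: (k,3)
    rho = np.zeros(grid.shape[:3])
    for c, w, a in zip(centers, widths, amplitudes):
        d2 = ((grid - c) ** 2).sum(axis=-1)
        rho += a * np.exp(-d2 / (2.0 * w * w))
    return rho


def generate_density_triplet(spec: SyntheticSpec) -> DensityTriplet:
    """Generate N−1/N/N+1 electron densities on a shared cubic grid.

    Each state is a sum of isotropic Gaussian bumps at shared atomic
    centers with per-state random amplitudes (so the finite-difference Fukui
    fields are spatially structured), then rescaled so the grid integrals
    equal N−1, N and N+1 exactly on the Riemann quadrature.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.electron_count
    counts = spec.grid_counts
    steps = np.diag([spec.box_length / c for c in counts])
    origin = np.zeros(3)

    # centers kept in the inner 50% of the box, at cube-header print precision
    centers = np.round(
        rng.uniform(0.25 * spec.box_length, 0.75 * spec.box_length,
                    size=(spec.n_atoms, 3)), 6)
    widths = rng.uniform(0.8, 1.6, size=spec.n_atoms)
    atoms = tuple(
        Atom(6, 6.0, tuple(pos)) for pos in centers
    )
    coords = [np.arange(c) * steps[i, i] + origin[i] for i, c in enumerate(counts)]
    grid = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)

    voxvol = float(np.linalg.det(steps))
    fields = []
    for target in (n - 1, n, n + 1):
        amplitudes = rng.uniform(0.5, 1.5, size=spec.n_atoms)
        rho = _gaussian_mixture(grid, centers, widths, amplitudes)
        raw = rho.sum() * voxvol
        if raw < 1e-8:
            raise GenerationError(
                "grid too coarse to normalise the synthetic density"
            )
        rho *= target / raw
        fields.append(
            ScalarField(origin=origin, axes=steps, counts=counts,
                        atoms=atoms, values=rho)
        )
    return DensityTriplet(rho_nm1=fields[0], rho_n=fields[1], rho_np1=fields[2])


def generate_condensed_charges(spec: SyntheticSpec) -> CondensedChargeSet:
    """Random per-atom populations summing exactly to N−1, N, N+1 electrons."""
    rng = np.random.default_rng(spec.seed)
    n = spec.electron_count
    states = []
    for target in (n - 1, n, n + 1):
        w = rng.uniform(0.5, 1.5, size=spec.n_atoms)
        states.append(w * (target / w.sum()))
    return CondensedChargeSet(p_nm1=states[0], p_n=states[1], p_np1=states[2],
                              scheme="synthetic")


def generate_log_text(record: MoleculeEnergyRecord) -> str:
    """Emit the minimal log dialect (hartree) for a record.

    :func:`cdftkit.logparse.parse_simple_log` inverts this on all populated
    fields.  Filler eigenvalues below the HOMO and above the LUMO pad the
    blocks so the parser's max/min selection is exercised.
    """
    h = ev_to_hartree(record.eps_homo)
    l = ev_to_hartree(record.eps_lumo)
    lines = [
        "# cdftkit minimal quantum-chemistry log",
        f"ID = {record.id}",
    ]
    if record.label:
        lines.append(f"LABEL = {record.label}")
    if record.e_gs_n is not None:
        lines.append(f"TOTAL ENERGY (HARTREE) = {ev_to_hartree(record.e_gs_n)!r}")
    if record.e_gs_nm1 is not None:
        lines.append(
            f"CATION TOTAL ENERGY (HARTREE) = {ev_to_hartree(record.e_gs_nm1)!r}"
        )
    if record.e_gs_np1 is not None:
        lines.append(
            f"ANION TOTAL ENERGY (HARTREE) = {ev_to_hartree(record.e_gs_np1)!r}"
        )
    lines.append("OCC EIGENVALUES (HARTREE):")
    lines.append(f"  {h - 0.25!r} {h - 0.11!r} {h!r}")
    lines.append("VIRT EIGENVALUES (HARTREE):")
    lines.append(f"  {l!r} {l + 0.09!r} {l + 0.21!r}")
    if record.eps_somo_anion is not None:
        lines.append(
            f"ANION SOMO (HARTREE) = {ev_to_hartree(record.eps_somo_anion)!r}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Apratoxin A-G printed reference tables
# ---------------------------------------------------------------------------

#: Frontier-orbital energies and KID residuals of apratoxins A-G (eV),
#: as printed at 2-3 decimals.  Quirks of the printed data, preserved here
#: verbatim: row B's gap (4.47) differs from LUMO−HOMO of the same row
#: (4.46) by one unit in the last digit, and row A's jhl (0.032) is not the
#: root-sum-of-squares of its printed ji/ja (0.0314) — both are artifacts of
#: rounding energies before vs after combining them.
APRATOXIN_KID_TABLE: dict[str, dict[str, float]] = {
    "A": {"homo": -6.24, "lumo": -1.22, "somo": -1.18, "gap": 5.02,
          "ji": 0.025, "ja": 0.019, "jhl": 0.032, "delta_sl": 0.038},
    "B": {"homo": -6.20, "lumo": -1.74, "somo": -1.70, "gap": 4.47,
          "ji": 0.023, "ja": 0.017, "jhl": 0.028, "delta_sl": 0.037},
    "C": {"homo": -6.04, "lumo": -1.76, "somo": -1.73, "gap": 4.28,
          "ji": 0.091, "ja": 0.016, "jhl": 0.092, "delta_sl": 0.029},
    "D": {"homo": -6.22, "lumo": -1.38, "somo": -1.38, "gap": 4.84,
          "ji": 0.013, "ja": 0.005, "jhl": 0.014, "delta_sl": 0.005},
    "E": {"homo": -6.08, "lumo": -1.69, "somo": -1.67, "gap": 4.39,
          "ji": 0.117, "ja": 0.007, "jhl": 0.117, "delta_sl": 0.015},
    "F": {"homo": -6.19, "lumo": -1.40, "somo": -1.37, "gap": 4.79,
          "ji": 0.015, "ja": 0.019, "jhl": 0.024, "delta_sl": 0.037},
    "G": {"homo": -6.12, "lumo": -1.79, "somo": -1.77, "gap": 4.33,
          "ji": 0.100, "ja": 0.010, "jhl": 0.100, "delta_sl": 0.022},
}

#: Printed global reactivity descriptors of apratoxins A-G (eV; softness
#: eV⁻¹), at 2 decimals.  Computed by the original study from unrounded
#: energies; recomputing from the 2-decimal orbital energies above
#: reproduces these to ~±0.015 (row B inherits the gap quirk noted on
#: APRATOXIN_KID_TABLE).  The net column is exactly the sum of the printed
#: (rounded) omega_minus and omega_plus columns.
APRATOXIN_GLOBAL_TABLE: dict[str, dict[str, float]] = {
    "A": {"chi": 3.73, "eta": 5.02, "omega": 1.39, "softness": 0.20,
          "nucleophilicity": 2.56, "omega_minus": 4.95, "omega_plus": 1.22,
          "net_electrophilicity": 6.17},
    "B": {"chi": 3.97, "eta": 4.47, "omega": 1.76, "softness": 0.22,
          "nucleophilicity": 2.59, "omega_minus": 5.79, "omega_plus": 1.82,
          "net_electrophilicity": 7.61},
    "C": {"chi": 3.90, "eta": 4.28, "omega": 1.78, "softness": 0.23,
          "nucleophilicity": 2.75, "omega_minus": 5.78, "omega_plus": 1.87,
          "net_electrophilicity": 7.65},
    "D": {"chi": 3.80, "eta": 4.84, "omega": 1.50, "softness": 0.21,
          "nucleophilicity": 2.57, "omega_minus": 5.19, "omega_plus": 1.39,
          "net_electrophilicity": 6.58},
    "E": {"chi": 3.88, "eta": 4.39, "omega": 1.72, "softness": 0.23,
          "nucleophilicity": 2.72, "omega_minus": 5.65, "omega_plus": 1.76,
          "net_electrophilicity": 7.41},
    "F": {"chi": 3.80, "eta": 4.79, "omega": 1.51, "softness": 0.21,
          "nucleophilicity": 2.60, "omega_minus": 5.21, "omega_plus": 1.41,
          "net_electrophilicity": 6.62},
    "G": {"chi": 3.96, "eta": 4.33, "omega": 1.81, "softness": 0.23,
          "nucleophilicity": 2.67, "omega_minus": 5.86, "omega_plus": 1.91,
          "net_electrophilicity": 7.77},
}

#: Externally predicted pKa column of the apratoxin reference data.  These
#: values do NOT follow the hardness QSAR of :mod:`cdftkit.pka` applied to
#: the hardness values above (e.g. row A: QSAR gives 12.16, the table
#: prints 12.90); they evidently come from a different, structure-based
#: predictor and are kept only for comparison, never reproduced.
APRATOXIN_PKA_TABLE: dict[str, float] = {
    "A": 12.90, "B": 12.97, "C": 12.90, "D": 12.90,
    "E": 12.47, "F": 12.73, "G": 12.76,
}


def apratoxin_fixture() -> list[MoleculeEnergyRecord]:
    """The seven apratoxin A-G energy records (printed values, eV).

    Ground-state total energies are absent (not printed in the reference
    data), so KID residual computation is not possible from the fixture;
    the printed residuals live in :data:`APRATOXIN_KID_TABLE`.
    """
    return [
        MoleculeEnergyRecord(
            id=key,
            label=f"Apratoxin {key}",
            eps_homo=row["homo"],
            eps_lumo=row["lumo"],
            eps_somo_anion=row["somo"],
            source="packaged apratoxin reference table",
        )
        for key, row in APRATOXIN_KID_TABLE.items()
    ]
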