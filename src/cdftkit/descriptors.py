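"""Global Conceptual-DFT reactivity descriptors and reactivity classes.

Within the frozen-orbital (Koopmans-like) approximation, with ϵH and ϵL the
HOMO/LUMO energies of the neutral molecule in eV, the global descriptors
are:

    electronegativity        χ  = −(ϵH + ϵL)/2        (χ = −μ)
    chemical potential       μ  =  (ϵH + ϵL)/2
    global hardness          η  =  ϵL − ϵH
    global softness          S  =  1/η
    electrophilicity index   ω  =  χ²/(2η) = μ²/(2η)
    electrodonating power    ω⁻ =  (3ϵH + ϵL)²/(16η)
    electroaccepting power   ω⁺ =  (ϵH + 3ϵL)²/(16η)
    net electrophilicity     Δω± = ω⁻ + ω⁺
    nucleophilicity index    N  =  ϵH − ϵH(reference electrophile)

N is referenced to tetracyanoethylene (TCE), the customary zero of the
nucleophilicity scale; its ϵH depends on the model chemistry, so the
reference is a parameter here (see
:func:`calibrate_nucleophilicity_reference`).

Classification scales from the polar organic reactivity literature:
electrophiles are strong for ω > 1.5 eV, moderate for 0.8 < ω < 1.5 eV,
marginal for ω < 0.8 eV (both boundary points, left open by the strict
inequalities, are assigned downward here: 1.5 → moderate, 0.8 → marginal);
nucleophiles are strong for N > 3 eV, moderate for 2 ≤ N ≤ 3 eV, marginal
for N < 2 eV.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

from .exceptions import ValidationError
from .records import MoleculeEnergyRecord

__all__ = [
    "GlobalDescriptors",
    "NucleophilicityReference",
    "DEFAULT_NUCLEOPHILICITY_REFERENCE",
    "electronegativity",
    "hardness",
    "softness",
    "electrophilicity",
    "electrodonating_power",
    "electroaccepting_power",
    "net_electrophilicity",
    "nucleophilicity",
    "calibrate_nucleophilicity_reference",
    "classify_electrophile",
    "classify_nucleophile",
    "compute_all",
]


@dataclass(frozen=True)
class NucleophilicityReference:
    """HOMO energy (eV) of the reference electrophile (TCE) and its provenance."""

    eps_homo_ref: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.eps_homo_ref):
            raise ValidationError("reference HOMO energy must be finite")


#: TCE HOMO energy consistent with the packaged apratoxin reference tables
#: (mean over the seven printed (ϵH, N) pairs; residual sd ≈ 0.005 eV).
#: Override for other model chemistries.
DEFAULT_NUCLEOPHILICITY_REFERENCE = NucleophilicityReference(
    eps_homo_ref=-8.79,
    provenance="calibrated from packaged apratoxin reference tables",
)


@dataclass(frozen=True)
class GlobalDescriptors:
    """The full global-descriptor set of one molecule (eV; softness eV⁻¹)."""

    chi: float
    mu: float
    eta: float
    softness: float
    omega: float
    nucleophilicity: float
    omega_minus: float
    omega_plus: float
    net_electrophilicity: float
    electrophile_class: str
    nucleophile_class: str


def _check_gap(eps_homo: float, eps_lumo: float) -> None:
    if not eps_homo < eps_lumo:
        raise ValidationError(
            f"eps_homo ({eps_homo}) must lie strictly below eps_lumo ({eps_lumo})"
        )


def electronegativity(eps_homo: float, eps_lumo: float) -> float:
    """Mulliken-style electronegativity χ = −(ϵH + ϵL)/2, eV."""
    _check_gap(eps_homo, eps_lumo)
    return -(eps_homo + eps_lumo) / 2.0


def hardness(eps_homo: float, eps_lumo: float) -> float:
    """Global hardness η = ϵL − ϵH (the HOMO–LUMO gap), eV."""
    _check_gap(eps_homo, eps_lumo)
    return eps_lumo - eps_homo


def softness(eta: float) -> float:
    """Global softness S = 1/η, eV⁻¹."""
    if eta <= 0:
        raise ValidationError(f"hardness must be positive, got {eta}")
    return 1.0 / eta


def electrophilicity(eps_homo: float, eps_lumo: float) -> float:
    """Electrophilicity index ω = χ²/(2η) = (ϵH + ϵL)²/(8(ϵL − ϵH)), eV."""
    chi = electronegativity(eps_homo, eps_lumo)
    return chi * chi / (2.0 * hardness(eps_homo, eps_lumo))


def electrodonating_power(eps_homo: float, eps_lumo: float) -> float:
    """Electrodonating power ω⁻ = (3ϵH + ϵL)²/(16η), eV."""
    _check_gap(eps_homo, eps_lumo)
    num = 3.0 * eps_homo + eps_lumo
    return num * num / (16.0 * (eps_lumo - eps_homo))


def electroaccepting_power(eps_homo: float, eps_lumo: float) -> float:
    """Electroaccepting power ω⁺ = (ϵH + 3ϵL)²/(16η), eV."""
    _check_gap(eps_homo, eps_lumo)
    num = eps_homo + 3.0 * eps_lumo
    return num * num / (16.0 * (eps_lumo - eps_homo))


def net_electrophilicity(omega_minus: float, omega_plus: float) -> float:
    """Net electrophilicity Δω± = ω⁻ + ω⁺, eV."""
    if omega_minus < 0 or omega_plus < 0:
        raise ValidationError("electrodonating/accepting powers must be >= 0")
    return omega_minus + omega_plus


def nucleophilicity(
    eps_homo: float,
    ref: NucleophilicityReference = DEFAULT_NUCLEOPHILICITY_REFERENCE,
) -> float:
    """Nucleophilicity index N = ϵH − ϵH(TCE reference), eV."""
    return eps_homo - ref.eps_homo_ref


def calibrate_nucleophilicity_reference(
    pairs: Sequence[tuple[float, float]],
) -> NucleophilicityReference:
    """Recover the reference HOMO energy from (ϵH, N) pairs.

    Since N = ϵH − ϵH(ref), the least-squares estimate of the single offset
    parameter is the mean of ϵH − N over the pairs; the residual standard
    deviation is recorded in the provenance string.
    """
    if len(pairs) == 0:
        raise ValidationError("calibration requires at least one (eps_homo, N) pair")
    offsets = [eps_homo - n for eps_homo, n in pairs]
    ref = statistics.fmean(offsets)
    sd = statistics.pstdev(offsets) if len(offsets) > 1 else 0.0
    return NucleophilicityReference(
        eps_homo_ref=ref,
        provenance=f"calibrated from {len(pairs)} pairs, residual sd {sd:.4f} eV",
    )


def classify_electrophile(omega: float) -> str:
    """Strong (ω > 1.5 eV), moderate (0.8 < ω <= 1.5), marginal (ω <= 0.8)."""
    if omega < 0:
        raise ValidationError(f"electrophilicity must be >= 0, got {omega}")
    if omega > 1.5:
        return "strong"
    if omega > 0.8:
        return "moderate"
    return "marginal"


def classify_nucleophile(n: float) -> str:
    """Strong (N > 3 eV), moderate (2 <= N <= 3), marginal (N < 2)."""
    if not math.isfinite(n):
        raise ValidationError("nucleophilicity index must be finite")
    if n > 3.0:
        return "strong"
    if n >= 2.0:
        return "moderate"
    return "marginal"


def compute_all(
    record: MoleculeEnergyRecord,
    ref: NucleophilicityReference = DEFAULT_NUCLEOPHILICITY_REFERENCE,
) -> GlobalDescriptors:
    """Compute the full global-descriptor set for one molecule."""
    h, l = record.eps_homo, record.eps_lumo
    chi = electronegativity(h, l)
    eta = hardness(h, l)
    omega = electrophilicity(h, l)
    wminus = electrodonating_power(h, l)
    wplus = electroaccepting_power(h, l)
    n = nucleophilicity(h, ref)
    return GlobalDescriptors(
        chi=chi,
        mu=-chi,
        eta=eta,
        softness=softness(eta),
        omega=omega,
        nucleophilicity=n,
        omega_minus=wminus,
        omega_plus=wplus,
        net_electrophilicity=net_electrophilicity(wminus, wplus),
        electrophile_class=classify_electrophile(omega),
        nucleophile_class=classify_nucleophile(n),
    )
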