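"""Hardness-based pKa QSAR.

A one-descriptor linear model relating pKa to global hardness η (eV),

    pKa = 16.3088 − 0.8268 η,

originally regressed on amino acids and short peptides.  The coefficients
are data, not constants of nature: both are overridable, and the model is
strictly a screening-level estimate.  Any externally predicted pKa supplied
alongside is reported as-is, never reconciled with the QSAR value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .exceptions import ValidationError

__all__ = ["PkaModel", "DEFAULT_PKA_MODEL", "pka_from_hardness"]


@dataclass(frozen=True)
class PkaModel:
    """Affine pKa model: pKa = intercept − slope·η (η in eV)."""

    intercept: float = 16.3088
    slope: float = 0.8268


DEFAULT_PKA_MODEL = PkaModel()


def pka_from_hardness(eta: float, model: Optional[PkaModel] = None) -> float:
    """Predict pKa from global hardness η (eV) via the affine QSAR."""
    if eta <= 0:
        raise ValidationError(f"hardness must be positive, got {eta}")
    m = model or DEFAULT_PKA_MODEL
    return m.intercept - m.slope * eta
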