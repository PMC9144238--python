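"""Energy unit conversion.

All toolkit internals work in electron-volts; hartree is accepted on input
only.  The conversion factor is the 2018 CODATA value.
"""

HARTREE_TO_EV: float = 27.211386245988
"""eV per hartree (2018 CODATA)."""


def hartree_to_ev(x: float) -> float:
    """Convert an energy from hartree to eV."""
    return x * HARTREE_TO_EV


def ev_to_hartree(x: float) -> float:
    """Convert an energy from eV to hartree."""
    return x / HARTREE_TO_EV
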