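"""Parser for the toolkit's minimal quantum-chemistry log dialect.

Full electronic-structure logs vary wildly between codes and versions;
parsing them in generality is out of scope here.  Instead the toolkit
defines a small, stable dialect (emitted by
:func:`cdftkit.synthetic.generate_log_text`) into which real outputs can be
pre-converted.  All quantities in the dialect are in hartree; parsed records
are in eV.

Dialect (one item per line; order of blocks is free)::

    ID = <token>
    LABEL = <free text>
    TOTAL ENERGY (HARTREE) = <float>          # neutral system; last one wins
    CATION TOTAL ENERGY (HARTREE) = <float>   # N-1 electrons, optional
    ANION TOTAL ENERGY (HARTREE) = <float>    # N+1 electrons, optional
    ANION SOMO (HARTREE) = <float>            # optional
    OCC EIGENVALUES (HARTREE):
      <floats, whitespace separated, one or more lines>
    VIRT EIGENVALUES (HARTREE):
      <floats, one or more lines>

The HOMO is the highest occupied eigenvalue, the LUMO the lowest virtual
one.
"""

from __future__ import annotations

from typing import Optional

from .exceptions import ParseError
from .records import MoleculeEnergyRecord
from .units import hartree_to_ev

__all__ = ["parse_simple_log"]

_SCALARS = {
    "TOTAL ENERGY (HARTREE)": "e_gs_n",
    "CATION TOTAL ENERGY (HARTREE)": "e_gs_nm1",
    "ANION TOTAL ENERGY (HARTREE)": "e_gs_np1",
    "ANION SOMO (HARTREE)": "eps_somo_anion",
}
_BLOCKS = ("OCC EIGENVALUES (HARTREE):", "VIRT EIGENVALUES (HARTREE):")


def parse_simple_log(text: str) -> MoleculeEnergyRecord:
    """Parse the minimal log dialect into a :class:`MoleculeEnergyRecord`.

    When a scalar line repeats, the later occurrence wins.  Raises
    :class:`~cdftkit.exceptions.ParseError` when an eigenvalue block is
    missing or empty, or when a numeric token is malformed.
    """
    rid = "unknown"
    label = ""
    scalars: dict[str, Optional[float]] = {v: None for v in _SCALARS.values()}
    blocks: dict[str, list[float]] = {b: [] for b in _BLOCKS}
    seen: dict[str, bool] = {b: False for b in _BLOCKS}
    current: Optional[str] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in _BLOCKS:
            current = line
            seen[line] = True
            continue
        if line.startswith("ID ="):
            rid = line.partition("=")[2].strip()
            current = None
            continue
        if line.startswith("LABEL ="):
            label = line.partition("=")[2].strip()
            current = None
            continue
        matched = False
        for key, field_name in _SCALARS.items():
            if line.startswith(key):
                value = line.partition("=")[2].strip()
                try:
                    scalars[field_name] = float(value)
                except ValueError as exc:
                    raise ParseError(
                        f"line {lineno}: non-numeric value {value!r}"
                    ) from exc
                current = None
                matched = True
                break
        if matched:
            continue
        if current is not None:
            try:
                blocks[current].extend(float(tok) for tok in line.split())
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: non-numeric eigenvalue in {current!r}"
                ) from exc
            continue
        raise ParseError(f"line {lineno}: unrecognised line {line!r}")

    for block in _BLOCKS:
        if not seen[block]:
            raise ParseError(f"missing block {block!r}")
        if not blocks[block]:
            raise ParseError(f"empty block {block!r}")

    def to_ev(value: Optional[float]) -> Optional[float]:
        return None if value is None else hartree_to_ev(value)

    return MoleculeEnergyRecord(
        id=rid,
        label=label,
        eps_homo=hartree_to_ev(max(blocks[_BLOCKS[0]])),
        eps_lumo=hartree_to_ev(min(blocks[_BLOCKS[1]])),
        eps_somo_anion=to_ev(scalars["eps_somo_anion"]),
        e_gs_nm1=to_ev(scalars["e_gs_nm1"]),
        e_gs_n=to_ev(scalars["e_gs_n"]),
        e_gs_np1=to_ev(scalars["e_gs_np1"]),
        source="parsed minimal log",
    )
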