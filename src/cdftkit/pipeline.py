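"""End-to-end reactivity-prospection pipeline and report tables.

Orchestrates the toolkit over a batch of molecules: KID compliance
assessment, global reactivity descriptors with electrophile/nucleophile
classification, and the hardness pKa QSAR, emitting three report tables
(KID, descriptors, pKa) plus a classification summary.

Molecules lacking the N±1 ground-state energies get their KID residual
columns marked absent rather than aborting the run — the descriptor tables
only need the frontier-orbital energies.  Display tables are rounded (3
decimals for KID, 2 for descriptors and pKa); the structured JSON mirror
carries full precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .descriptors import (
    GlobalDescriptors,
    NucleophilicityReference,
    calibrate_nucleophilicity_reference,
    compute_all,
)
from .exceptions import ValidationError
from .kid import DEFAULT_KID_TOLERANCE, compute_delta_sl, kid_assess
from .pka import DEFAULT_PKA_MODEL, PkaModel, pka_from_hardness
from .records import MoleculeEnergyRecord, read_energy_records
from .synthetic import (
    APRATOXIN_GLOBAL_TABLE,
    APRATOXIN_KID_TABLE,
    apratoxin_fixture,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "summarize_classes"]

logger = logging.getLogger("cdftkit")

_FORMATS = ("delimited", "structured", "markdown")

KID_COLUMNS = ["id", "eps_homo", "eps_lumo", "eps_somo_anion", "gap",
               "ji", "ja", "jhl", "delta_sl", "kid_passed"]
DESCRIPTOR_COLUMNS = ["id", "chi", "eta", "omega", "softness",
                      "nucleophilicity", "omega_minus", "omega_plus",
                      "net_electrophilicity", "mu",
                      "electrophile_class", "nucleophile_class"]
PKA_COLUMNS = ["id", "eta", "pka_qsar"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    ``records_path`` may be None, in which case the packaged apratoxin
    fixture is analysed.  ``nucleophilicity_reference`` is either the TCE
    reference HOMO energy in eV or the string ``"calibrate"`` to recover it
    from the packaged reference tables.
    """

    records_path: Optional[Union[str, Path]] = None
    kid_tolerance: float = DEFAULT_KID_TOLERANCE
    nucleophilicity_reference: Union[float, str] = -8.79
    pka_model: PkaModel = DEFAULT_PKA_MODEL
    kid_decimals: int = 3
    descriptor_decimals: int = 2
    output_dir: Optional[Union[str, Path]] = None
    formats: tuple[str, ...] = _FORMATS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kid_decimals < 0 or self.descriptor_decimals < 0:
            raise ValidationError("rounding decimals must be >= 0")
        unknown = set(self.formats) - set(_FORMATS)
        if unknown:
            raise ValidationError(f"unknown output formats: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Load a config from a YAML or JSON mapping."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must be a mapping")
        if "pka_model" in raw and isinstance(raw["pka_model"], dict):
            raw["pka_model"] = PkaModel(**raw["pka_model"])
        if "formats" in raw:
            raw["formats"] = tuple(raw["formats"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """The pipeline's output tables (full precision) and run metadata."""

    kid_table: pd.DataFrame
    descriptor_table: pd.DataFrame
    pka_table: pd.DataFrame
    class_summary: dict
    metadata: dict

    def write(self, output_dir: Union[str, Path], formats: Sequence[str] = _FORMATS,
              kid_decimals: int = 3, descriptor_decimals: int = 2) -> None:
        """Write the bundle to ``output_dir`` in the requested formats."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "kid": (self.kid_table, kid_decimals),
            "descriptors": (self.descriptor_table, descriptor_decimals),
            "pka": (self.pka_table, descriptor_decimals),
        }
        for name, (table, decimals) in tables.items():
            display = table.round(decimals)
            if "delimited" in formats:
                display.to_csv(out / f"{name}.csv", index=False)
            if "markdown" in formats:
                (out / f"{name}.md").write_text(_to_markdown(display))
        if "structured" in formats:
            payload = {
                "kid": _frame_records(self.kid_table),
                "descriptors": _frame_records(self.descriptor_table),
                "pka": _frame_records(self.pka_table),
                "classification": self.class_summary,
            }
            (out / "report.json").write_text(json.dumps(payload, indent=2))
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=2))


def _frame_records(frame: pd.DataFrame) -> list[dict]:
    out = []
    for row in frame.to_dict(orient="records"):
        out.append({k: (None if pd.isna(v) else v) if not isinstance(v, str)
                    else v for k, v in row.items()})
    return out


def _to_markdown(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for row in frame.itertuples(index=False):
        cells = ["" if (not isinstance(v, str) and pd.isna(v)) else str(v)
                 for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def resolve_reference(
    reference: Union[float, str, NucleophilicityReference],
) -> NucleophilicityReference:
    """Turn a config reference value into a :class:`NucleophilicityReference`."""
    if isinstance(reference, NucleophilicityReference):
        return reference
    if reference == "calibrate":
        pairs = [
            (APRATOXIN_KID_TABLE[k]["homo"],
             APRATOXIN_GLOBAL_TABLE[k]["nucleophilicity"])
            for k in APRATOXIN_KID_TABLE
        ]
        return calibrate_nucleophilicity_reference(pairs)
    return NucleophilicityReference(eps_homo_ref=float(reference),
                                    provenance="user-supplied")


def summarize_classes(
    descriptors: Sequence[GlobalDescriptors],
    ids: Optional[Sequence[str]] = None,
) -> dict:
    """Count electrophile/nucleophile classes and list per-molecule labels."""
    classes = ("strong", "moderate", "marginal")
    e_counts = Counter(d.electrophile_class for d in descriptors)
    n_counts = Counter(d.nucleophile_class for d in descriptors)
    labels = {}
    for i, d in enumerate(descriptors):
        key = ids[i] if ids is not None else str(i)
        labels[key] = {"electrophile": d.electrophile_class,
                       "nucleophile": d.nucleophile_class}
    return {
        "electrophile": {c: e_counts.get(c, 0) for c in classes},
        "nucleophile": {c: n_counts.get(c, 0) for c in classes},
        "labels": labels,
    }


def run_pipeline(
    config: PipelineConfig,
    records: Optional[Sequence[MoleculeEnergyRecord]] = None,
) -> ReportBundle:
    """Run the full analysis and, if configured, write the report bundle.

    ``records`` overrides ``config.records_path``; with neither given the
    packaged apratoxin fixture is used.  Molecules failing the KID check are
    flagged in the KID table, never dropped.
    """
    if records is None:
        if config.records_path is not None:
            records = read_energy_records(config.records_path)
        else:
            records = apratoxin_fixture()
            logger.info("no input records configured; using apratoxin fixture")
    records = list(records)
    if not records:
        logger.warning("empty record list: emitting empty tables")

    ref = resolve_reference(config.nucleophilicity_reference)

    kid_rows = []
    desc_rows = []
    pka_rows = []
    descriptors: list[GlobalDescriptors] = []
    for record in records:
        kid_row = {
            "id": record.id,
            "eps_homo": record.eps_homo,
            "eps_lumo": record.eps_lumo,
            "eps_somo_anion": record.eps_somo_anion,
            "gap": record.gap,
            "ji": None, "ja": None, "jhl": None,
            "delta_sl": (compute_delta_sl(record)
                         if record.eps_somo_anion is not None else None),
            "kid_passed": None,
        }
        if record.has_kid_energies:
            diag = kid_assess(record, tolerance=config.kid_tolerance)
            kid_row.update(ji=diag.ji, ja=diag.ja, jhl=diag.jhl,
                           delta_sl=diag.delta_sl, kid_passed=diag.passed)
            if not diag.passed:
                logger.warning("record %s fails the KID check (jhl=%.3f eV)",
                               record.id, diag.jhl)
        kid_rows.append(kid_row)

        d = compute_all(record, ref)
        descriptors.append(d)
        desc_rows.append({"id": record.id, **dataclasses.asdict(d)})
        pka_rows.append({"id": record.id, "eta": d.eta,
                         "pka_qsar": pka_from_hardness(d.eta, config.pka_model)})

    bundle = ReportBundle(
        kid_table=pd.DataFrame(kid_rows, columns=KID_COLUMNS),
        descriptor_table=pd.DataFrame(desc_rows, columns=DESCRIPTOR_COLUMNS),
        pka_table=pd.DataFrame(pka_rows, columns=PKA_COLUMNS),
        class_summary=summarize_classes(descriptors, [r.id for r in records]),
        metadata={
            "version": __version__,
            "n_molecules": len(records),
            "kid_tolerance": config.kid_tolerance,
            "nucleophilicity_reference": ref.eps_homo_ref,
            "reference_provenance": ref.provenance,
            "pka_model": dataclasses.asdict(config.pka_model),
            "seed": config.seed,
            "generated_at": datetime.now(timezone.utc).isoformat(),
        },
    )
    if config.output_dir is not None:
        bundle.write(config.output_dir, config.formats,
                     config.kid_decimals, config.descriptor_decimals)
    return bundle
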