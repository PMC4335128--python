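"""Curation of compound-target IC50 tables into a deduplicated pIC50 matrix.

Public bioactivity databases report half-maximal inhibitory concentrations
(IC50) per compound-target pair, often with several independent measurements
per pair and heterogeneous units and assay quality. This module turns such an
export into the sparse response matrix a proteochemometric model is trained
on: records are quality-filtered (exact-equality relationship, assay score
confidence >= 8, nanomolar units), converted to pIC50 = -log10(IC50 in molar),
and replicate measurements on the same (compound, target) pair are averaged.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BioactivityRecord",
    "BioactivityTable",
    "DatasetSummary",
    "FilterReport",
    "parse_bioactivity_table",
    "apply_quality_filters",
    "to_pic50",
    "deduplicate",
    "summarize",
]

#: Default mapping from record fields to column names of a raw export.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "value": "value",
    "relationship": "relationship",
    "unit": "unit",
    "assay_confidence": "assay_confidence",
}


@dataclass(frozen=True)
class BioactivityRecord:
    """One raw IC50 measurement for a compound on a target (value in nM)."""

    compound_id: str
    smiles: str
    target_id: str
    value: float
    relationship: str
    unit: str
    assay_confidence: int

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(
                f"IC50 must be positive, got {self.value!r} for "
                f"({self.compound_id}, {self.target_id})"
            )


@dataclass
class BioactivityTable:
    """Deduplicated (compound, target) -> pIC50 map with provenance counts."""

    entries: dict[tuple[str, str], float]
    n_source_records: dict[tuple[str, str], int]
    pic50_sd: dict[tuple[str, str], float] = field(default_factory=dict)
    smiles: dict[str, str] = field(default_factory=dict)

    @property
    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, _ in self.entries:
            seen.setdefault(cid, None)
        return list(seen)

    @property
    def targets(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, tid in self.entries:
            seen.setdefault(tid, None)
        return list(seen)

    @property
    def completeness(self) -> float:
        return len(self.entries) / (len(self.compounds) * len(self.targets))

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": cid,
                "target_id": tid,
                "pIC50": v,
                "n_source_records": self.n_source_records[(cid, tid)],
            }
            for (cid, tid), v in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["compound_id", "target_id", "pIC50", "n_source_records"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BioactivityTable":
        entries = {}
        n_src = {}
        for row in frame.itertuples(index=False):
            key = (str(row.compound_id), str(row.target_id))
            entries[key] = float(row.pIC50)
            n_src[key] = int(getattr(row, "n_source_records", 1))
        return cls(entries=entries, n_source_records=n_src)


@dataclass(frozen=True)
class DatasetSummary:
    """Headline counts of a bioactivity table."""

    n_compounds: int
    n_targets: int
    n_datapoints: int
    completeness_pct: float
    per_target_counts: dict[str, int]
    per_target_annotated_pct: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass(frozen=True)
class FilterReport:
    """Per-rule rejection counts from :func:`apply_quality_filters`."""

    n_input: int
    n_kept: int
    n_rejected_relationship: int
    n_rejected_confidence: int
    n_rejected_unit: int


def parse_bioactivity_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[BioactivityRecord]:
    """Read a delimited bioactivity export into records.

    The delimiter (comma or tab) is sniffed from the header line. Rows whose
    IC50 value does not parse as a positive number are skipped with a logged
    warning rather than aborting the import.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        header_line = handle.readline()
        delimiter = "\t" if header_line.count("\t") >= header_line.count(",") else ","
        handle.seek(0)
        reader = csv.DictReader(handle, delimiter=delimiter)
        fieldnames = reader.fieldnames or []
        missing = [col for col in colmap.values() if col not in fieldnames]
        if missing:
            raise KeyError(f"mapped column(s) {missing} not found in {path.name} header {fieldnames}")

        records: list[BioactivityRecord] = []
        for i, row in enumerate(reader, start=2):
            try:
                value = float(row[colmap["value"]])
                confidence = int(float(row[colmap["assay_confidence"]]))
                record = BioactivityRecord(
                    compound_id=row[colmap["compound_id"]].strip(),
                    smiles=row[colmap["smiles"]].strip(),
                    target_id=row[colmap["target_id"]].strip(),
                    value=value,
                    relationship=row[colmap["relationship"]],
                    unit=row[colmap["unit"]],
                    assay_confidence=confidence,
                )
            except (TypeError, ValueError) as exc:
                logger.warning("skipping row %d of %s: %s", i, path.name, exc)
                continue
            records.append(record)
    return records


def apply_quality_filters(
    records: Iterable[BioactivityRecord],
    min_confidence: int = 8,
    unit: str = "nM",
) -> tuple[list[BioactivityRecord], FilterReport]:
    """Keep records with exact-equality relationship, confident assays, nM units.

    A record survives iff its relationship symbol is ``=`` (surrounding
    whitespace tolerated), its assay score confidence is at least
    ``min_confidence`` and its unit equals ``unit`` case-insensitively.
    """
    kept: list[BioactivityRecord] = []
    n_rel = n_conf = n_unit = 0
    n_input = 0
    for rec in records:
        n_input += 1
        if rec.relationship.strip() != "=":
            n_rel += 1
            continue
        if rec.assay_confidence < min_confidence:
            n_conf += 1
            continue
        if rec.unit.strip().lower() != unit.lower():
            n_unit += 1
            continue
        kept.append(rec)
    report = FilterReport(
        n_input=n_input,
        n_kept=len(kept),
        n_rejected_relationship=n_rel,
        n_rejected_confidence=n_conf,
        n_rejected_unit=n_unit,
    )
    return kept, report


def to_pic50(ic50_nM: float) -> float:
    """Convert an IC50 in nanomolar to pIC50 = -log10(IC50 in molar).

    With the nanomolar input this is ``9 - log10(ic50_nM)``: 1 nM -> 9.0,
    1 uM -> 6.0.
    """
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM!r}")
    return 9.0 - math.log10(ic50_nM)


def deduplicate(records: Sequence[BioactivityRecord]) -> BioactivityTable:
    """Collapse replicate measurements to one mean pIC50 per (compound, target).

    The arithmetic mean is used (replicate public IC50 values rarely contain
    outliers that would favor the median); the per-pair standard deviation is
    retained as a replicate-consistency diagnostic.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    smiles: dict[str, str] = {}
    for rec in records:
        key = (rec.compound_id, rec.target_id)
        groups.setdefault(key, []).append(to_pic50(rec.value))
        smiles.setdefault(rec.compound_id, rec.smiles)

    entries = {}
    n_src = {}
    sds = {}
    for key, values in groups.items():
        arr = np.asarray(values, dtype=float)
        entries[key] = float(arr.mean())
        n_src[key] = len(values)
        sds[key] = float(arr.std(ddof=1)) if len(values) > 1 else 0.0
    return BioactivityTable(entries=entries, n_source_records=n_src, pic50_sd=sds, smiles=smiles)


def summarize(table: BioactivityTable) -> DatasetSummary:
    """Count compounds, targets and datapoints and derive completeness.

    completeness_pct = 100 * n_datapoints / (n_compounds * n_targets); the
    per-target annotated percentage is the share of all distinct compounds
    measured on that target.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty bioactivity table")
    compounds = table.compounds
    targets = table.targets
    per_target_counts: dict[str, int] = {t: 0 for t in targets}
    per_target_compounds: dict[str, set[str]] = {t: set() for t in targets}
    for cid, tid in table.entries:
        per_target_counts[tid] += 1
        per_target_compounds[tid].add(cid)
    n_compounds = len(compounds)
    return DatasetSummary(
        n_compounds=n_compounds,
        n_targets=len(targets),
        n_datapoints=len(table),
        completeness_pct=100.0 * len(table) / (n_compounds * len(targets)),
        per_target_counts=per_target_counts,
        per_target_annotated_pct={
            t: 100.0 * len(c) / n_compounds for t, c in per_target_compounds.items()
        },
    )


def summarize_counts(n_datapoints: int, n_compounds: int, n_targets: int) -> float:
    """Completeness percentage from raw counts (100*n/(rows*cols))."""
    return 100.0 * n_datapoints / (n_compounds * n_targets)
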