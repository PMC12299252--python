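"""Reading and writing activity tables, docking-score tables and
interaction tables.

Supported dialects are comma- and tab-delimited text with a header row;
the delimiter is auto-detected from the header line. Numeric cells accept
both the ASCII hyphen and the Unicode minus sign, and empty cells or
``NA`` mean *missing* — never zero.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

from .postdock import DockScoreRow, InteractionRecord
from .records import ActivityRecord, CuratedDataset

__all__ = [
    "ColumnMap",
    "ColumnMapError",
    "CHEMBL_COLMAP",
    "DEFAULT_COLMAP",
    "read_activity_table",
    "write_activity_table",
    "read_dock_scores",
    "read_interaction_table",
]

#: Semantic fields every activity table must provide.
REQUIRED_FIELDS = ("molecule_id", "smiles", "type", "value", "units", "relation", "assay_id")

#: Optional semantic fields picked up when mapped and present.
OPTIONAL_FIELDS = ("assay_description", "source_id", "smiles_std", "pic50")

MISSING_TOKENS = frozenset({"", "na", "nan", "none", "null"})


class ColumnMapError(KeyError):
    """A required semantic field is unmapped or its column is absent."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from semantic field names to source column names."""

    mapping: dict[str, str] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.mapping]
        if missing:
            raise ColumnMapError(f"column map {self.name!r} lacks required fields: {missing}")

    def validate_header(self, header: list[str]) -> None:
        for semantic in REQUIRED_FIELDS:
            column = self.mapping[semantic]
            if column not in header:
                raise ColumnMapError(
                    f"mapped column {column!r} (for field {semantic!r}) not found in header {header}"
                )

    def get(self, row: dict[str, str], semantic: str) -> str | None:
        column = self.mapping.get(semantic)
        if column is None:
            return None
        return row.get(column)


#: Column names as they appear in a ChEMBL web-export CSV.
CHEMBL_COLMAP = ColumnMap(
    mapping={
        "molecule_id": "Molecule ChEMBL ID",
        "smiles": "Smiles",
        "type": "Standard Type",
        "value": "Standard Value",
        "units": "Standard Units",
        "relation": "Standard Relation",
        "assay_id": "Assay ChEMBL ID",
        "assay_description": "Assay Description",
        "source_id": "Source ID",
    },
    name="chembl",
)

#: Canonical column names used by :func:`write_activity_table`.
DEFAULT_COLMAP = ColumnMap(
    mapping={
        "molecule_id": "molecule_id",
        "smiles": "smiles",
        "type": "standard_type",
        "value": "value",
        "units": "units",
        "relation": "relation",
        "assay_id": "assay_id",
        "assay_description": "assay_description",
        "source_id": "source_id",
        "smiles_std": "smiles_std",
        "pic50": "pic50",
    },
    name="default",
)

PRESETS = {"chembl": CHEMBL_COLMAP, "default": DEFAULT_COLMAP}


def parse_number(text: str | None) -> float | None:
    """Parse a numeric cell; Unicode minus accepted; missing -> None."""
    if text is None:
        return None
    cleaned = text.strip().replace("−", "-")
    if cleaned.lower() in MISSING_TOKENS:
        return None
    try:
        return float(cleaned)
    except ValueError:
        return None


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") and "\t" in header_line else ","


def _clean_text(text: str | None) -> str:
    return "" if text is None else text.strip()


def read_activity_table(path: str | Path, colmap: ColumnMap = DEFAULT_COLMAP) -> CuratedDataset:
    """Read a delimited activity table into a raw :class:`CuratedDataset`.

    One record per data row, row order preserved. Unparseable numeric
    values are retained with ``value=None`` (standard cleaning drops
    them later); a missing mapped column raises :class:`ColumnMapError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty file, no header row")
        delimiter = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        colmap.validate_header(list(header))
        records: list[ActivityRecord] = []
        for row in reader:
            relation = _clean_text(colmap.get(row, "relation")).replace("'", "") or None
            units = _clean_text(colmap.get(row, "units")) or None
            pic50_cell = colmap.get(row, "pic50")
            pic50 = parse_number(pic50_cell) if pic50_cell is not None else None
            smiles_std = _clean_text(colmap.get(row, "smiles_std")) or None
            records.append(
                ActivityRecord(
                    molecule_id=_clean_text(colmap.get(row, "molecule_id")),
                    smiles_raw=_clean_text(colmap.get(row, "smiles")),
                    standard_type=_clean_text(colmap.get(row, "type")),
                    value=parse_number(colmap.get(row, "value")),
                    units=units,
                    relation=relation,
                    assay_id=_clean_text(colmap.get(row, "assay_id")),
                    assay_description=colmap.get(row, "assay_description") or "",
                    source_id=_clean_text(colmap.get(row, "source_id")) or "",
                    smiles_std=smiles_std,
                    pic50=pic50,
                )
            )
    dataset = CuratedDataset(records=records, stage="raw")
    return dataset.advance(
        records,
        stage="raw",
        step="read_activity_table",
        params={"path": str(path), "colmap": colmap.name},
    )


def write_activity_table(dataset: CuratedDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a dataset using the canonical column names.

    ``read_activity_table(write_activity_table(d))`` with the default
    column map reproduces the records field-for-field.
    """
    if not dataset.records:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    columns = [
        "molecule_id",
        "smiles",
        "standard_type",
        "value",
        "units",
        "relation",
        "assay_id",
        "assay_description",
        "source_id",
        "smiles_std",
        "pic50",
    ]

    def fmt(x: object) -> str:
        if x is None:
            return ""
        if isinstance(x, float):  # incl. numpy scalars; repr(float) round-trips
            return "" if math.isnan(x) else repr(float(x))
        return str(x)

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(columns)
        for rec in dataset.records:
            writer.writerow(
                [
                    fmt(rec.molecule_id),
                    fmt(rec.smiles_raw),
                    fmt(rec.standard_type),
                    fmt(rec.value),
                    fmt(rec.units),
                    fmt(rec.relation),
                    fmt(rec.assay_id),
                    fmt(rec.assay_description),
                    fmt(rec.source_id),
                    fmt(rec.smiles_std),
                    fmt(rec.pic50),
                ]
            )


def read_dock_scores(path: str | Path, ligand_column: str | None = None) -> list[DockScoreRow]:
    """Read a docking-score CSV into one :class:`DockScoreRow` per ligand.

    All columns except the ligand-id column are treated as numeric score
    columns; blank cells are recorded as absent, never as zero. Duplicate
    ligand ids are an error.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            return []
        delimiter = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = list(reader.fieldnames or [])
        if not header:
            return []
        lig_col = ligand_column or header[0]
        if lig_col not in header:
            raise ColumnMapError(f"ligand column {lig_col!r} not in header {header}")
        score_cols = [c for c in header if c != lig_col]
        rows: list[DockScoreRow] = []
        seen: dict[str, int] = {}
        for row in reader:
            ligand = _clean_text(row.get(lig_col))
            seen[ligand] = seen.get(ligand, 0) + 1
            scores = {c: parse_number(row.get(c)) for c in score_cols}
            rows.append(DockScoreRow(ligand_id=ligand, scores=scores))
    duplicates = sorted(lig for lig, n in seen.items() if n > 1)
    if duplicates:
        raise ValueError(f"duplicate ligand ids in {path}: {duplicates}")
    return rows


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a per-interaction energy CSV (residue, ligand, type, energy).

    Energy signs are preserved and residue labels kept verbatim; a
    non-numeric energy cell is an error naming the offending row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            return []
        delimiter = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = list(reader.fieldnames or [])
        required = ("residue", "ligand", "interaction", "energy")
        lowered = {c.lower().strip(): c for c in header}
        missing = [c for c in required if c not in lowered]
        if missing:
            raise ColumnMapError(f"interaction table missing columns {missing}; header {header}")
        records: list[InteractionRecord] = []
        for i, row in enumerate(reader, start=2):
            raw_energy = row.get(lowered["energy"])
            energy = parse_number(raw_energy)
            if energy is None or not math.isfinite(energy):
                raise ValueError(f"{path}:{i}: non-numeric energy cell {raw_energy!r}")
            records.append(
                InteractionRecord(
                    residue=_clean_text(row.get(lowered["residue"])),
                    ligand_id=_clean_text(row.get(lowered["ligand"])),
                    interaction_type=_clean_text(row.get(lowered["interaction"])),
                    energy=energy,
                )
            )
    return records
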