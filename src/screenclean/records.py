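"""Core record types shared across the pipeline.

An :class:`ActivityRecord` is a single bioactivity measurement; a
:class:`CuratedDataset` is an ordered collection of records that moves
through the pipeline stages ``raw -> standard_cleaned -> filtered ->
sc_cleaned``, carrying a provenance log of every step applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterator

#: Pipeline stages in forward order.
STAGES = ("raw", "standard_cleaned", "filtered", "sc_cleaned")

#: Relation labels recognised on activity rows. ``None`` means missing.
RELATIONS = ("=", ">", "<", ">=", "<=")

CENSORED_RELATIONS = frozenset({">", "<", ">=", "<="})


class StageError(ValueError):
    """Raised when an operation is applied at the wrong pipeline stage."""


@dataclass
class ActivityRecord:
    """One bioactivity measurement for one molecule in one assay."""

    molecule_id: str
    smiles_raw: str
    standard_type: str = "IC50"
    value: float | None = None
    units: str | None = None
    relation: str | None = "="
    assay_id: str = ""
    assay_description: str = ""
    source_id: str = ""
    smiles_std: str | None = None
    pic50: float | None = None

    def __post_init__(self) -> None:
        if self.value is not None and not math.isnan(self.value) and self.value < 0:
            raise ValueError(f"negative activity value {self.value!r} for {self.molecule_id!r}")
        if self.pic50 is not None and not math.isfinite(self.pic50):
            raise ValueError(f"non-finite pic50 for {self.molecule_id!r}")

    def copy(self, **changes: Any) -> "ActivityRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class ProvenanceStep:
    """Descriptor of one pipeline step applied to a dataset."""

    step: str
    params: dict[str, Any] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0
    notes: str = ""


@dataclass
class CuratedDataset:
    """Ordered collection of activity records with a pipeline-stage tag.

    Stage transitions only move forward; each applied step appends one
    :class:`ProvenanceStep` whose record counts chain together
    (records-out of step k equals records-in of step k+1).
    """

    records: list[ActivityRecord] = field(default_factory=list)
    stage: str = "raw"
    provenance: list[ProvenanceStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ActivityRecord]:
        return iter(self.records)

    def advance(
        self,
        records: list[ActivityRecord],
        stage: str,
        step: str,
        params: dict[str, Any] | None = None,
        notes: str = "",
    ) -> "CuratedDataset":
        """Return a new dataset at ``stage`` with a provenance entry appended."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move backwards from {self.stage!r} to {stage!r}")
        entry = ProvenanceStep(
            step=step,
            params=dict(params or {}),
            n_in=len(self.records),
            n_out=len(records),
            notes=notes,
        )
        return CuratedDataset(
            records=records,
            stage=stage,
            provenance=[*self.provenance, entry],
        )

    def molecule_keys(self) -> list[str]:
        """Distinct molecule keys (standardized SMILES) in input order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            key = rec.smiles_std if rec.smiles_std is not None else rec.smiles_raw
            seen.setdefault(key, None)
        return list(seen)


def molecule_key(record: ActivityRecord) -> str:
    """Molecule identity used for grouping: standardized SMILES when set."""
    return record.smiles_std if record.smiles_std is not None else record.smiles_raw
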