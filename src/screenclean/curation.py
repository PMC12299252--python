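"""Standard cleaning and molecular-weight filtering.

Standard cleaning standardizes structures (largest organic fragment,
neutralized, canonical SMILES), converts measured concentrations to
pIC50, drops records that cannot be converted, and collapses *exact*
duplicates (same standardized SMILES, assay and pIC50). Conflicting
values for one molecule across assays are deliberately retained — which
value represents a molecule is decided downstream by selective cleaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import CENSORED_RELATIONS, ActivityRecord, CuratedDataset, StageError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "InvalidSmilesError",
    "standardize_smiles",
    "to_pic50",
    "standard_clean",
    "filter_mw",
    "molecular_weight",
]

#: Concentration units accepted by pIC50 conversion, as mol/L factors.
UNIT_FACTORS = {
    "pm": 1e-12,
    "nm": 1e-9,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "mm": 1e-3,
    "m": 1.0,
}


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


@dataclass(frozen=True)
class CleaningConfig:
    """Knobs for standard cleaning and molecular-weight filtering."""

    mw_low: float = 100.0  # Da, exclusive
    mw_high: float = 750.0  # Da, exclusive
    allowed_types: frozenset[str] = frozenset({"IC50"})
    drop_censored: bool = True
    stereo_mode: str = "as_given"  # or "collapse"

    def __post_init__(self) -> None:
        if not 0 < self.mw_low < self.mw_high:
            raise ValueError(f"need 0 < mw_low < mw_high, got ({self.mw_low}, {self.mw_high})")
        if self.stereo_mode not in ("as_given", "collapse"):
            raise ValueError(f"unknown stereo_mode {self.stereo_mode!r}")


@dataclass
class CleaningReport:
    """Removal accounting for one cleaning step; the books must balance."""

    records_in: int = 0
    records_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    REASONS = (
        "null_value",
        "invalid_smiles",
        "disallowed_type",
        "censored_relation",
        "unit_failure",
        "out_of_range_mw",
        "exact_duplicate",
    )

    def tally(self, reason: str) -> None:
        if reason not in self.REASONS:
            raise ValueError(f"unknown removal reason {reason!r}")
        self.removed[reason] = self.removed.get(reason, 0) + 1

    @property
    def balanced(self) -> bool:
        return self.records_in - self.records_out == sum(self.removed.values())

    def as_dict(self) -> dict:
        return {
            "records_in": self.records_in,
            "records_out": self.records_out,
            "removed": dict(self.removed),
        }


@lru_cache(maxsize=200_000)
def _standardize_cached(raw: str, collapse_stereo: bool) -> str:
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {raw!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)  # largest organic fragment, desalted
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    if collapse_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def standardize_smiles(raw: str, stereo_mode: str = "as_given") -> str:
    """Return the canonical parent SMILES of ``raw``.

    Keeps the largest organic fragment, neutralizes charges where
    possible, and canonicalizes. With ``stereo_mode='collapse'`` all
    stereo descriptors are removed so stereoisomers share one key.
    Deterministic and idempotent; raises :class:`InvalidSmilesError`
    on unparsable input.
    """
    if not raw or not raw.strip():
        raise InvalidSmilesError("empty SMILES")
    return _standardize_cached(raw.strip(), stereo_mode == "collapse")


def to_pic50(
    value: float,
    units: str | None,
    relation: str | None,
    config: CleaningConfig = CleaningConfig(),
) -> float | None:
    """Convert a measured concentration to pIC50, or None on rejection.

    pIC50 = -log10(value in mol/L). Rejected when the value is missing,
    non-positive or non-finite, the units are unsupported, or the
    relation is censored while ``drop_censored`` is set.
    """
    if value is None or not math.isfinite(value) or value <= 0:
        return None
    if config.drop_censored and relation in CENSORED_RELATIONS:
        return None
    factor = UNIT_FACTORS.get((units or "").strip().lower())
    if factor is None:
        return None
    return -math.log10(value * factor)


@lru_cache(maxsize=200_000)
def molecular_weight(smiles: str) -> float:
    """Average molecular weight (Da) of a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {smiles!r}")
    return Descriptors.MolWt(mol)


def standard_clean(
    dataset: CuratedDataset, config: CleaningConfig = CleaningConfig()
) -> tuple[CuratedDataset, CleaningReport]:
    """Apply standard cleaning; see the module docstring for semantics.

    Every surviving record carries ``smiles_std`` and ``pic50``. Exact
    duplicates (identical smiles_std, assay_id and pIC50) collapse to
    their first occurrence; cross-assay or cross-value duplicates stay.
    Idempotent on its own output.
    """
    if dataset.stage not in ("raw", "standard_cleaned"):
        raise StageError(f"standard_clean expects a raw dataset, got stage {dataset.stage!r}")
    report = CleaningReport(records_in=len(dataset.records))
    kept: list[ActivityRecord] = []
    seen: set[tuple[str, str, float]] = set()
    for rec in dataset.records:
        if rec.value is None or not math.isfinite(rec.value):
            report.tally("null_value")
            continue
        if rec.standard_type not in config.allowed_types:
            report.tally("disallowed_type")
            continue
        if config.drop_censored and rec.relation in CENSORED_RELATIONS:
            report.tally("censored_relation")
            continue
        try:
            smiles_std = standardize_smiles(rec.smiles_raw, config.stereo_mode)
        except InvalidSmilesError:
            report.tally("invalid_smiles")
            continue
        pic50 = to_pic50(rec.value, rec.units, rec.relation, config)
        if pic50 is None:
            report.tally("unit_failure")
            continue
        key = (smiles_std, rec.assay_id, pic50)
        if key in seen:
            report.tally("exact_duplicate")
            continue
        seen.add(key)
        kept.append(rec.copy(smiles_std=smiles_std, pic50=pic50))
    report.records_out = len(kept)
    notes = "" if kept else "warning: no records survived standard cleaning"
    out = dataset.advance(
        kept,
        stage="standard_cleaned",
        step="standard_clean",
        params={
            "allowed_types": sorted(config.allowed_types),
            "drop_censored": config.drop_censored,
            "stereo_mode": config.stereo_mode,
        },
        notes=notes,
    )
    return out, report


def filter_mw(
    dataset: CuratedDataset, config: CleaningConfig = CleaningConfig()
) -> tuple[CuratedDataset, CleaningReport]:
    """Keep records with mw_low < MW < mw_high (strict bounds).

    MW is computed on the standardized parent structure. Idempotent.
    """
    if dataset.stage not in ("standard_cleaned", "filtered"):
        raise StageError(f"filter_mw expects a standard-cleaned dataset, got {dataset.stage!r}")
    report = CleaningReport(records_in=len(dataset.records))
    kept: list[ActivityRecord] = []
    for rec in dataset.records:
        if rec.smiles_std is None:
            raise ValueError(f"record {rec.molecule_id!r} lacks smiles_std; run standard_clean first")
        mw = molecular_weight(rec.smiles_std)
        if config.mw_low < mw < config.mw_high:
            kept.append(rec)
        else:
            report.tally("out_of_range_mw")
    report.records_out = len(kept)
    out = dataset.advance(
        kept,
        stage="filtered",
        step="filter_mw",
        params={"mw_low": config.mw_low, "mw_high": config.mw_high},
    )
    return out, report
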