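"""Post-docking analysis: site-selectivity deltas, rank-based consensus
scoring across docking engines, and interaction-strength classification.

Interaction energies are graded into four classes::

    '-'    E > -0.1        insignificant
    '+'    -1.0 < E <= -0.1   weak
    '++'   -3.0 < E <= -1.0   moderate
    '+++'  E <= -3.0          strong

Classification is total and monotone: a more negative energy never maps
to a weaker class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "DockScoreRow",
    "InteractionRecord",
    "EngineSpec",
    "DEFAULT_ENGINES",
    "CLASS_SYMBOLS",
    "selectivity_delta",
    "consensus_rank",
    "classify_interaction",
    "build_profile",
    "profile_similarity",
]

#: Interaction-class boundaries (kcal/mol), strongest last.
THRESHOLD_INSIGNIFICANT = -0.1
THRESHOLD_WEAK = -1.0
THRESHOLD_STRONG = -3.0

CLASS_SYMBOLS = ("-", "+", "++", "+++")


@dataclass
class DockScoreRow:
    """Per-ligand docking scores keyed by score-column name.

    Missing scores are ``None`` (absent), never zero. The selectivity
    delta is derived only when both MDM2 pocket scores are present.
    """

    ligand_id: str
    scores: dict[str, float | None] = field(default_factory=dict)

    def score(self, column: str) -> float | None:
        return self.scores.get(column)

    @property
    def selectivity(self) -> float | None:
        p1 = self.scores.get("MDM2_p1")
        p2 = self.scores.get("MDM2_p2")
        if p1 is None or p2 is None:
            return None
        return selectivity_delta(p1, p2)


@dataclass(frozen=True)
class InteractionRecord:
    """One non-covalent contact between a residue and a ligand."""

    residue: str
    ligand_id: str
    interaction_type: str
    energy: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"non-finite interaction energy for {self.residue}/{self.ligand_id}")


@dataclass(frozen=True)
class EngineSpec:
    """One engine's score column and polarity for consensus ranking."""

    column: str
    higher_is_better: bool = False


#: MDM2-directed score columns of the redocking table: two energy scores
#: (lower is better) and one fitness score (higher is better).
DEFAULT_ENGINES = (
    EngineSpec("MDM2_p1", higher_is_better=False),
    EngineSpec("Vina_MDM2", higher_is_better=False),
    EngineSpec("GOLD_MDM2", higher_is_better=True),
)


def selectivity_delta(score_p1: float, score_p2: float) -> float:
    """Pocket-selectivity difference, positive when p1 binds stronger.

    Docking scores are negative energies, so preference for p1 (a more
    negative p1 score) shows up as ``score_p2 - score_p1 > 0``.
    """
    if not (math.isfinite(score_p1) and math.isfinite(score_p2)):
        raise ValueError("pocket scores must be finite")
    return score_p2 - score_p1


def consensus_rank(
    rows: list[DockScoreRow],
    engines: tuple[EngineSpec, ...] = DEFAULT_ENGINES,
) -> list[dict]:
    """Rank ligands by mean per-engine rank.

    Each engine ranks ligands with its own polarity (rank 1 = best);
    ties get average ranks. A ligand missing an engine's score is simply
    excluded from that engine's ranking and from its own mean. Ligands
    with no scores at all are excluded entirely. The result is sorted by
    consensus rank, ties broken by ligand id.
    """
    rows = list(rows)
    per_engine: dict[str, dict[str, float]] = {}
    for spec in engines:
        scored = [(r.ligand_id, r.score(spec.column)) for r in rows]
        scored = [(lig, s) for lig, s in scored if s is not None]
        if not scored:
            continue
        values = np.array([s for _, s in scored], dtype=float)
        if spec.higher_is_better:
            values = -values
        ranks = rankdata(values, method="average")
        per_engine[spec.column] = {lig: float(rk) for (lig, _), rk in zip(scored, ranks)}

    report = []
    for row in rows:
        engine_ranks = {
            col: ranks[row.ligand_id] for col, ranks in per_engine.items() if row.ligand_id in ranks
        }
        if not engine_ranks:
            continue
        report.append(
            {
                "ligand_id": row.ligand_id,
                "engine_ranks": engine_ranks,
                "consensus": float(np.mean(list(engine_ranks.values()))),
                "selectivity_delta": row.selectivity,
            }
        )
    report.sort(key=lambda item: (item["consensus"], item["ligand_id"]))
    return report


def classify_interaction(energy: float) -> str:
    """Grade one interaction energy (kcal/mol) into '-', '+', '++' or '+++'."""
    if not math.isfinite(energy):
        raise ValueError("interaction energy must be finite")
    if energy > THRESHOLD_INSIGNIFICANT:
        return "-"
    if energy > THRESHOLD_WEAK:
        return "+"
    if energy > THRESHOLD_STRONG:
        return "++"
    return "+++"


def build_profile(records: list[InteractionRecord]) -> dict[str, dict[str, str]]:
    """Aggregate interactions into a residue x ligand symbol matrix.

    Multiple contacts between one residue and one ligand are summed in
    energy before classification; (residue, ligand) pairs with no record
    are marked '-'. Residues and ligands keep first-seen order.
    """
    residues: dict[str, None] = {}
    ligands: dict[str, None] = {}
    sums: dict[tuple[str, str], float] = {}
    for rec in records:
        residues.setdefault(rec.residue, None)
        ligands.setdefault(rec.ligand_id, None)
        key = (rec.residue, rec.ligand_id)
        sums[key] = sums.get(key, 0.0) + rec.energy
    return {
        residue: {
            ligand: classify_interaction(sums[(residue, ligand)]) if (residue, ligand) in sums else "-"
            for ligand in ligands
        }
        for residue in residues
    }


def profile_similarity(a: dict[str, str], b: dict[str, str]) -> float:
    """Fraction of residues on which two profile columns agree exactly."""
    if set(a) != set(b) or not a:
        raise ValueError("profile columns must cover the same non-empty residue set")
    matches = sum(1 for residue in a if a[residue] == b[residue])
    return matches / len(a)
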