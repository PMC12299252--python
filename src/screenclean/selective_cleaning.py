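"""Assay-aware duplicate resolution.

When a molecule carries several measurements, the two-layer rule keeps
the record that (1) comes from the molecule's most *globally prevalent*
assay — the assay with the most records in the whole dataset, ties
broken by assay id — and (2) has the highest pIC50 within that assay,
ties keeping the earliest input row. This guards against representative
values drawn from rarely-used assay procedures, the failure mode of the
plain take-the-maximum convention.

:func:`sc_oracle` is a deliberately naive re-statement of the same rule
by exhaustive enumeration; it exists so the production path can be
checked against an independent implementation.
"""

from __future__ import annotations

import random as _random
import statistics
from dataclasses import dataclass, field

from .records import ActivityRecord, CuratedDataset, StageError, molecule_key

__all__ = [
    "AssayStats",
    "SCReport",
    "NAIVE_STRATEGIES",
    "compute_assay_prevalence",
    "selective_clean",
    "sc_oracle",
    "naive_clean",
]

NAIVE_STRATEGIES = ("random", "average", "global_max", "most_recent")

_ALLOWED_STAGES = ("standard_cleaned", "filtered")


@dataclass(frozen=True)
class AssayStats:
    """Global record count and prevalence rank of one assay."""

    assay_id: str
    count: int
    rank: int  # 1-based, 1 = most prevalent


@dataclass
class MoleculeChoice:
    """Per-molecule outcome of selective cleaning."""

    molecule: str
    chosen: ActivityRecord
    chosen_assay: str
    chosen_rank: int
    n_candidates: int
    discarded: list[tuple[ActivityRecord, str]] = field(default_factory=list)


@dataclass
class SCReport:
    """Choice log per molecule key; chosen + discarded = candidates."""

    choices: dict[str, MoleculeChoice] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            key: {
                "chosen_molecule_id": choice.chosen.molecule_id,
                "chosen_assay": choice.chosen_assay,
                "chosen_rank": choice.chosen_rank,
                "chosen_pic50": choice.chosen.pic50,
                "n_candidates": choice.n_candidates,
                "discarded": [
                    {"molecule_id": rec.molecule_id, "assay_id": rec.assay_id,
                     "pic50": rec.pic50, "reason": reason}
                    for rec, reason in choice.discarded
                ],
            }
            for key, choice in self.choices.items()
        }


def _check_stage(dataset: CuratedDataset, op: str) -> None:
    if dataset.stage not in _ALLOWED_STAGES:
        raise StageError(f"{op} expects stage in {_ALLOWED_STAGES}, got {dataset.stage!r}")


def compute_assay_prevalence(dataset: CuratedDataset) -> list[AssayStats]:
    """Tally records per assay, sorted by count desc then assay id asc."""
    _check_stage(dataset, "compute_assay_prevalence")
    counts: dict[str, int] = {}
    for rec in dataset.records:
        counts[rec.assay_id] = counts.get(rec.assay_id, 0) + 1
    ordered = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return [AssayStats(assay_id=a, count=c, rank=i) for i, (a, c) in enumerate(ordered, start=1)]


def selective_clean(dataset: CuratedDataset) -> tuple[CuratedDataset, SCReport]:
    """Resolve duplicates with the two-layer rule; one record per molecule.

    Equivalent to stable-sorting all records by (global assay rank asc,
    pIC50 desc) and keeping the first occurrence of each molecule key.
    Output order follows first appearance of each molecule in the input.
    """
    _check_stage(dataset, "selective_clean")
    for rec in dataset.records:
        if rec.pic50 is None:
            raise ValueError(f"record {rec.molecule_id!r} has no pic50; run standard_clean first")
    rank_of = {s.assay_id: s.rank for s in compute_assay_prevalence(dataset)}

    # Stable sort: input order breaks pIC50 ties inside the chosen assay.
    order = sorted(
        range(len(dataset.records)),
        key=lambda i: (rank_of[dataset.records[i].assay_id], -dataset.records[i].pic50),
    )
    chosen_index: dict[str, int] = {}
    for i in order:
        key = molecule_key(dataset.records[i])
        chosen_index.setdefault(key, i)

    report = SCReport()
    kept: list[ActivityRecord] = []
    seen_keys: list[str] = []
    candidates: dict[str, list[ActivityRecord]] = {}
    for rec in dataset.records:
        key = molecule_key(rec)
        if key not in candidates:
            candidates[key] = []
            seen_keys.append(key)
        candidates[key].append(rec)
    for key in seen_keys:
        winner = dataset.records[chosen_index[key]]
        kept.append(winner)
        discarded = []
        for rec in candidates[key]:
            if rec is winner:
                continue
            if rec.assay_id == winner.assay_id:
                discarded.append((rec, "lower value in chosen assay"))
            else:
                discarded.append((rec, "less prevalent assay"))
        report.choices[key] = MoleculeChoice(
            molecule=key,
            chosen=winner,
            chosen_assay=winner.assay_id,
            chosen_rank=rank_of[winner.assay_id],
            n_candidates=len(candidates[key]),
            discarded=discarded,
        )
    out = dataset.advance(kept, stage="sc_cleaned", step="selective_clean")
    return out, report


def sc_oracle(records: list[ActivityRecord], stats: list[AssayStats]) -> ActivityRecord:
    """Reference two-layer choice by exhaustive enumeration (test aid).

    All ``records`` must share one molecule key. Layer 1: restrict to the
    assay with the best (lowest) global rank among the molecule's assays.
    Layer 2: among those, take the maximum pIC50, earliest row on ties.
    """
    if not records:
        raise ValueError("sc_oracle needs at least one record")
    keys = {molecule_key(r) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple molecule keys: {sorted(keys)}")
    rank_of = {s.assay_id: s.rank for s in stats}
    best_rank = min(rank_of[r.assay_id] for r in records)
    in_best_assay = [r for r in records if rank_of[r.assay_id] == best_rank]
    best = in_best_assay[0]
    for rec in in_best_assay[1:]:
        if rec.pic50 > best.pic50:  # strict: earliest row wins ties
            best = rec
    return best


def naive_clean(
    dataset: CuratedDataset, strategy: str, seed: int = 0
) -> CuratedDataset:
    """One record per molecule chosen by a conventional strategy.

    random: seeded uniform choice. average: synthesizes a record with
    the mean pIC50 and an 'aggregate' assay label. global_max: maximum
    pIC50 over all assays. most_recent: last input row (input order is
    the recency proxy).
    """
    _check_stage(dataset, "naive_clean")
    if strategy not in NAIVE_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {NAIVE_STRATEGIES}")
    groups: dict[str, list[ActivityRecord]] = {}
    order: list[str] = []
    for rec in dataset.records:
        key = molecule_key(rec)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    rng = _random.Random(seed)
    kept: list[ActivityRecord] = []
    for key in order:
        recs = groups[key]
        if strategy == "random":
            kept.append(rng.choice(recs))
        elif strategy == "global_max":
            best = recs[0]
            for rec in recs[1:]:
                if rec.pic50 > best.pic50:
                    best = rec
            kept.append(best)
        elif strategy == "most_recent":
            kept.append(recs[-1])
        else:  # average
            mean = statistics.fmean(r.pic50 for r in recs)
            kept.append(
                recs[0].copy(
                    pic50=mean,
                    assay_id="aggregate",
                    assay_description="synthetic aggregate of duplicate records",
                )
            )
    out = dataset.advance(
        kept, stage="sc_cleaned", step="naive_clean", params={"strategy": strategy, "seed": seed}
    )
    return out
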