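"""Hit triage after ML-based screening.

Two stages: a 2-D region gate on (predicted pIC50, docking affinity)
selecting the favorable box, and structural admissibility rules that
demand a sigma-hole donor (halogen), a modest aromatic ring count, a
bounded flexibility, and the absence of peptide-, nucleotide- and
fatty-acid-like features or long aliphatic chains. All thresholds are
configurable; the numeric stand-ins for the qualitative exclusion rules
are documented on :class:`TriageCriteria`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski

__all__ = [
    "TriageCriteria",
    "HitCandidate",
    "region_gate",
    "structural_filter",
    "triage",
    "write_hits_sdf",
]

HALOGENS = frozenset({9, 17, 35, 53})  # F, Cl, Br, I

_AMIDE = Chem.MolFromSmarts("[CX3](=O)[NX3]")
_PHOSPHATE = Chem.MolFromSmarts("[PX4](=O)([OX2,OX1-])[OX2,OX1-]")
_GLYCOSIDIC = Chem.MolFromSmarts("[CX4;R][OX2][CX4;R]")
_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1,OX1-]")


@dataclass(frozen=True)
class TriageCriteria:
    """Region-gate bounds and structural admissibility thresholds.

    Exclusion-rule operationalizations (numeric stand-ins for the
    qualitative criteria; all overridable):

    * peptide_like — at least ``peptide_amide_count`` backbone amides;
    * nucleotide_like — a phosphate group plus a glycosidic
      ring-C-O-ring-C pattern;
    * fatty_acid_like — a carboxylic acid plus an unbranched acyclic
      sp3 carbon chain of ``long_chain_length`` or more;
    * long_aliphatic — any such chain regardless of other groups;
    * the rotatable-bond cap is a stand-in for "constrained spatial
      arrangement", which has no printed numeric definition.
    """

    pic50_low: float = 6.0
    pic50_high: float = 10.0
    affinity_low: float = -9.0  # kcal/mol
    affinity_high: float = -6.0  # kcal/mol
    min_aromatic_rings: int = 2
    max_aromatic_rings: int = 4
    require_sigma_hole: bool = True
    max_rotatable_bonds: int = 10
    peptide_amide_count: int = 3
    long_chain_length: int = 8

    def __post_init__(self) -> None:
        if not self.pic50_low < self.pic50_high:
            raise ValueError("pic50 bounds out of order")
        if not self.affinity_low < self.affinity_high:
            raise ValueError("affinity bounds out of order")
        if not 0 <= self.min_aromatic_rings <= self.max_aromatic_rings:
            raise ValueError("aromatic ring bounds out of order")


@dataclass
class HitCandidate:
    """One screened molecule with gate/filter verdicts and rank."""

    molecule_id: str
    smiles_std: str | None
    pic50: float
    affinity: float
    region: str = "outside"  # 'favorable' or 'outside'
    region_failures: list[str] = field(default_factory=list)
    structural_pass: bool = True
    structural_reasons: list[str] = field(default_factory=list)
    rank: int | None = None


def region_gate(pic50: float, affinity: float, criteria: TriageCriteria = TriageCriteria()) -> tuple[str, list[str]]:
    """Classify a (pIC50, affinity) pair; boundaries inclusive.

    Returns ('favorable', []) inside the box, else ('outside', failures)
    naming each violated condition.
    """
    if not (math.isfinite(pic50) and math.isfinite(affinity)):
        raise ValueError("pic50 and affinity must be finite")
    failures = []
    if not criteria.pic50_low <= pic50 <= criteria.pic50_high:
        failures.append("pic50_out_of_range")
    if not criteria.affinity_low <= affinity <= criteria.affinity_high:
        failures.append("affinity_out_of_range")
    return ("favorable" if not failures else "outside", failures)


def _longest_unbranched_sp3_chain(mol: Chem.Mol) -> int:
    """Length of the longest unbranched chain of acyclic sp3 carbons.

    Branch points (three or more neighbors within the chain-atom set)
    terminate a run, so only straight runs count.
    """
    chain_atoms = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6
        and not a.GetIsAromatic()
        and not a.IsInRing()
        and a.GetHybridization() == Chem.HybridizationType.SP3
    }
    adj = {
        i: [n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors() if n.GetIdx() in chain_atoms]
        for i in chain_atoms
    }
    # Remove branch points; the rest decomposes into simple paths.
    path_atoms = {i for i in chain_atoms if len(adj[i]) <= 2}
    best = 0
    seen: set[int] = set()
    for start in path_atoms:
        if start in seen:
            continue
        component = []
        stack = [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            component.append(i)
            stack.extend(n for n in adj[i] if n in path_atoms and n not in seen)
        # A component with no cycles and max degree 2 is a path.
        best = max(best, len(component))
    return best


def structural_filter(
    smiles: str, criteria: TriageCriteria = TriageCriteria()
) -> tuple[bool, list[str]]:
    """Apply the structural admissibility rules to one molecule.

    Returns (passes, reasons); every violated rule is named.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    reasons: list[str] = []

    if criteria.require_sigma_hole and not any(
        a.GetAtomicNum() in HALOGENS for a in mol.GetAtoms()
    ):
        reasons.append("no_sigma_hole_donor")

    n_aromatic = Lipinski.NumAromaticRings(mol)
    if not criteria.min_aromatic_rings <= n_aromatic <= criteria.max_aromatic_rings:
        reasons.append("aromatic_ring_count")

    if Descriptors.NumRotatableBonds(mol) > criteria.max_rotatable_bonds:
        reasons.append("too_flexible")

    n_amides = len(mol.GetSubstructMatches(_AMIDE))
    if n_amides >= criteria.peptide_amide_count:
        reasons.append("peptide_like")

    if mol.HasSubstructMatch(_PHOSPHATE) and mol.HasSubstructMatch(_GLYCOSIDIC):
        reasons.append("nucleotide_like")

    chain = _longest_unbranched_sp3_chain(mol)
    if chain >= criteria.long_chain_length:
        reasons.append("long_aliphatic")
        if mol.HasSubstructMatch(_CARBOXYLIC_ACID):
            reasons.append("fatty_acid_like")

    return (not reasons, reasons)


def triage(
    candidates: list[tuple[str, str | None, float, float]],
    criteria: TriageCriteria = TriageCriteria(),
) -> list[HitCandidate]:
    """Gate, filter and rank screened candidates.

    ``candidates`` rows are (id, smiles, predicted pIC50, affinity);
    smiles may be None, in which case structural rules are skipped.
    All inputs are returned with their verdicts; only favorable+passing
    candidates get ranks — descending pIC50, ties by more negative
    affinity, then id.
    """
    out: list[HitCandidate] = []
    for mol_id, smiles, pic50, affinity in candidates:
        region, failures = region_gate(pic50, affinity, criteria)
        if smiles is not None:
            ok, reasons = structural_filter(smiles, criteria)
        else:
            ok, reasons = True, []
        out.append(
            HitCandidate(
                molecule_id=mol_id,
                smiles_std=smiles,
                pic50=pic50,
                affinity=affinity,
                region=region,
                region_failures=failures,
                structural_pass=ok,
                structural_reasons=reasons,
            )
        )
    winners = [c for c in out if c.region == "favorable" and c.structural_pass]
    winners.sort(key=lambda c: (-c.pic50, c.affinity, c.molecule_id))
    for i, cand in enumerate(winners, start=1):
        cand.rank = i
    return out


def write_hits_sdf(hits: list[HitCandidate], path: str) -> int:
    """Export ranked hits to SDF with pIC50/affinity properties; returns
    the number of molecules written."""
    writer = Chem.SDWriter(str(path))
    n = 0
    for hit in sorted((h for h in hits if h.rank is not None), key=lambda h: h.rank):
        if hit.smiles_std is None:
            continue
        mol = Chem.MolFromSmiles(hit.smiles_std)
        if mol is None:
            continue
        mol.SetProp("_Name", hit.molecule_id)
        mol.SetProp("predicted_pIC50", f"{hit.pic50:.4f}")
        mol.SetProp("docking_score_kcal_mol", f"{hit.affinity:.4f}")
        mol.SetProp("rank", str(hit.rank))
        writer.write(mol)
        n += 1
    writer.close()
    return n
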