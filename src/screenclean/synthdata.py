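"""Synthetic multi-assay bioactivity tables with known ground truth.

Generates molecule libraries from a small fragment grammar, then emits
activity records in which each observation is

    observed pIC50 = latent pIC50 + assay bias + measurement noise,

reported as an IC50 in nM so the whole cleaning path (unit conversion
included) is exercised. Assays are sampled from a Zipf prevalence law;
optionally the *least* prevalent assay carries an extra positive bias —
exactly the failure mode that makes take-the-maximum curation unsafe —
and a fraction of molecules is re-emitted with flipped stereo
descriptors to mimic stereo-ambiguous duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curation import CleaningConfig, filter_mw, molecular_weight, standard_clean, standardize_smiles
from .records import ActivityRecord, CuratedDataset, molecule_key
from .selective_cleaning import NAIVE_STRATEGIES, naive_clean, selective_clean

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_molecules",
    "generate_activity_table",
    "evaluate_curation_recovery",
]

# --- fragment grammar -------------------------------------------------------

# Cores with one substitution slot; terminal cores use ring digits 2-3 so
# they can be nested inside a slot without ring-closure clashes.
_SLOT_CORES = (
    "c1ccc({})cc1",
    "c1ccc2cc({})ccc2c1",
    "c1ccnc({})c1",
    "c1csc({})c1",
    "c1occ({})c1",
)
_TERMINAL_CORES = (
    "c2ccccc2",
    "c2ccncc2",
    "c2ccc3ccccc3c2",
    "c2ccco2",
    "C2CCCCC2",
    "C2CCNCC2",
)
_LINKERS = ("C", "CC", "CCC", "CO", "CCO", "C(=O)N", "CC(=O)N", "CCN", "C[C@@H](O)", "C[C@@H](N)C")
_HALO_PREFIXES = ("", "", "F", "Cl", "Br")
_SMALL = ("CC", "CCO", "CCC", "CCN", "CC(C)O", "C1CCCC1", "CCOC", "CC#N", "CCS")


def _random_medium(rng: np.random.Generator) -> str:
    core = _SLOT_CORES[rng.integers(len(_SLOT_CORES))]
    linker = _LINKERS[rng.integers(len(_LINKERS))]
    tcore = _TERMINAL_CORES[rng.integers(len(_TERMINAL_CORES))]
    halo = _HALO_PREFIXES[rng.integers(len(_HALO_PREFIXES))]
    alkyl = "C" * int(rng.integers(0, 5))
    return halo + core.format(alkyl + linker + tcore)


def _random_large(rng: np.random.Generator) -> str:
    core = _SLOT_CORES[rng.integers(len(_SLOT_CORES))]
    tcore = "c2ccc(CCCCCCCCCCCC(=O)Nc3ccc4ccccc4c3)cc2"
    chain = "C" * int(rng.integers(14, 24))
    return "Cl" + core.format(chain + "C(=O)N" + tcore)


def generate_molecules(n: int, seed: int = 0) -> list[str]:
    """Generate ``n`` distinct, standardizable SMILES.

    The grammar spans MW roughly 30-1000 Da so molecular-weight
    filtering is exercised: ~8% of draws are deliberately tiny, ~8%
    deliberately oversized. Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("fragment grammar exhausted; could not generate distinct molecules")
        u = rng.random()
        if u < 0.08:
            smiles = _SMALL[rng.integers(len(_SMALL))]
        elif u < 0.16:
            smiles = _random_large(rng)
        else:
            smiles = _random_medium(rng)
        try:
            canonical = standardize_smiles(smiles)
        except Exception:  # pragma: no cover - grammar should always be valid
            continue
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(smiles)
    return out


# --- activity table generation ---------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic multi-assay generator."""

    n_molecules: int = 100
    n_assays: int = 5
    zipf_exponent: float = 1.5
    duplication_lambda: float = 1.0  # extra records per molecule ~ Poisson
    sigma_assay: float = 0.0  # assay-bias scale, pIC50 units
    sigma_noise: float = 0.2  # measurement-noise scale, pIC50 units
    latent_mu: float = 6.5
    latent_sigma: float = 1.0
    rare_assay_bias: float = 0.0  # extra bias on the least prevalent assay
    stereo_dup_rate: float = 0.0
    stereo_offset: float = 0.0  # latent shift of the stereo duplicate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assays < 1:
            raise ValueError("need at least one assay")
        if min(self.sigma_assay, self.sigma_noise, self.latent_sigma, self.duplication_lambda) < 0:
            raise ValueError("scales must be non-negative")
        if not 0 <= self.stereo_dup_rate <= 1:
            raise ValueError("stereo_dup_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """Latent potency per molecule key and bias per assay."""

    latent: dict[str, float] = field(default_factory=dict)
    assay_bias: dict[str, float] = field(default_factory=dict)


def _flip_stereo(smiles: str) -> str | None:
    if "@@" in smiles:
        return smiles.replace("@@", "@")
    if "@" in smiles:
        return smiles.replace("@", "@@")
    return None


def generate_activity_table(config: SyntheticConfig) -> tuple[CuratedDataset, GroundTruth]:
    """Emit a raw activity table plus its generating ground truth.

    Each molecule gets ``1 + Poisson(lambda)`` records; each record's
    assay is a Zipf draw; values are IC50s in nM with relation '='.
    """
    rng = np.random.default_rng(config.seed)
    molecules = generate_molecules(config.n_molecules, seed=config.seed)

    weights = np.array([1.0 / (k + 1) ** config.zipf_exponent for k in range(config.n_assays)])
    probs = weights / weights.sum()
    assay_ids = [f"ASSAY_{k + 1:03d}" for k in range(config.n_assays)]
    biases = rng.normal(0.0, config.sigma_assay, size=config.n_assays)
    biases[-1] += config.rare_assay_bias  # least prevalent assay by construction

    truth = GroundTruth(assay_bias=dict(zip(assay_ids, biases.tolist())))
    records: list[ActivityRecord] = []

    def emit(mol_index: int, raw: str, latent: float) -> None:
        n_records = 1 + rng.poisson(config.duplication_lambda)
        for _ in range(n_records):
            k = int(rng.choice(config.n_assays, p=probs))
            observed = float(latent + biases[k] + rng.normal(0.0, config.sigma_noise))
            ic50_nm = 10.0 ** (9.0 - observed)
            records.append(
                ActivityRecord(
                    molecule_id=f"MOL_{mol_index + 1:05d}",
                    smiles_raw=raw,
                    standard_type="IC50",
                    value=ic50_nm,
                    units="nM",
                    relation="=",
                    assay_id=assay_ids[k],
                    source_id="synthetic",
                )
            )

    for i, raw in enumerate(molecules):
        latent = float(rng.normal(config.latent_mu, config.latent_sigma))
        key = standardize_smiles(raw)
        truth.latent[key] = latent
        emit(i, raw, latent)
        if config.stereo_dup_rate > 0 and rng.random() < config.stereo_dup_rate:
            flipped = _flip_stereo(raw)
            if flipped is not None:
                fkey = standardize_smiles(flipped)
                if fkey not in truth.latent:
                    truth.latent[fkey] = latent + config.stereo_offset
                    emit(i, flipped, latent + config.stereo_offset)

    dataset = CuratedDataset(records=records, stage="raw")
    dataset = dataset.advance(
        records,
        stage="raw",
        step="generate_activity_table",
        params={"n_molecules": config.n_molecules, "seed": config.seed},
    )
    return dataset, truth


# --- curation-strategy recovery experiment ----------------------------------


def _strategy_mae(dataset: CuratedDataset, truth: GroundTruth) -> float:
    deviations = [abs(rec.pic50 - truth.latent[molecule_key(rec)]) for rec in dataset.records]
    return float(np.mean(deviations)) if deviations else float("nan")


def evaluate_curation_recovery(
    config: SyntheticConfig,
    strategies: list[str],
    n_reps: int = 20,
    seed: int = 0,
    cleaning: CleaningConfig = CleaningConfig(),
) -> dict:
    """Measure how well each duplicate-resolution strategy recovers the
    latent potency, over ``n_reps`` independent replicates.

    For each replicate: generate, standard-clean, MW-filter, apply each
    strategy, and take the mean absolute deviation of curated labels
    from the latent truth. Reports per-strategy MAE distributions and
    pairwise win rates (fraction of replicates with strictly lower MAE).
    """
    for s in strategies:
        if s != "sc" and s not in NAIVE_STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    maes: dict[str, list[float]] = {s: [] for s in strategies}
    for rep in range(n_reps):
        rep_config = replace(config, seed=seed + 7919 * rep)
        raw, truth = generate_activity_table(rep_config)
        cleaned, _ = standard_clean(raw, cleaning)
        filtered, _ = filter_mw(cleaned, cleaning)
        if not filtered.records:
            continue
        for s in strategies:
            if s == "sc":
                curated, _ = selective_clean(filtered)
            else:
                curated = naive_clean(filtered, s, seed=seed + rep)
            maes[s].append(_strategy_mae(curated, truth))

    summary = {
        s: {
            "mean_mae": float(np.mean(vals)) if vals else float("nan"),
            "mae_per_rep": vals,
        }
        for s, vals in maes.items()
    }
    win_rates: dict[str, float] = {}
    for a in strategies:
        for b in strategies:
            if a >= b:
                continue
            wins_a = sum(1 for x, y in zip(maes[a], maes[b]) if x < y)
            wins_b = sum(1 for x, y in zip(maes[a], maes[b]) if y < x)
            n = len(maes[a])
            win_rates[f"{a}>{b}"] = wins_a / n if n else float("nan")
            win_rates[f"{b}>{a}"] = wins_b / n if n else float("nan")
    return {
        "n_reps": n_reps,
        "strategies": summary,
        "win_rates": win_rates,
        "config": {
            "n_molecules": config.n_molecules,
            "n_assays": config.n_assays,
            "sigma_assay": config.sigma_assay,
            "sigma_noise": config.sigma_noise,
            "rare_assay_bias": config.rare_assay_bias,
        },
    }
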