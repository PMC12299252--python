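"""Descriptor featurization, cross-validated regression, and
curation-strategy comparison.

The harness measures how a *fixed* learner responds to different
curation strategies; the learner itself is pluggable through a registry
of classical scikit-learn regressors (an adapter seam for external
models). Deep/graph models are intentionally not bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from .records import CuratedDataset

__all__ = [
    "ModelSpec",
    "BenchResult",
    "CurationComparison",
    "LEARNERS",
    "DESCRIPTOR_SETS",
    "featurize",
    "metrics",
    "cross_validate",
    "compare_strategies",
    "parity_summary",
    "pct_improvement",
]

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# descriptor sets

def _rdkit2d_names() -> tuple[str, ...]:
    return tuple(name for name, _ in Descriptors._descList)


#: Named, frozen descriptor sets: name -> ordered descriptor-name tuple.
DESCRIPTOR_SETS: dict[str, tuple[str, ...]] = {
    "rdkit2d": _rdkit2d_names(),
    # Small, fast subset for smoke tests and simulations.
    "basic": ("MolWt", "MolLogP", "TPSA", "NumHAcceptors", "NumHDonors",
              "NumRotatableBonds", "RingCount", "NumAromaticRings",
              "FractionCSP3", "HeavyAtomCount"),
}

_DESC_FN = dict(Descriptors._descList)


def featurize(smiles: str, descriptor_set: str = "rdkit2d") -> np.ndarray:
    """Compute the named 2D-descriptor vector for one molecule.

    Fixed length and ordering per descriptor set; non-finite descriptor
    values are imputed to 0 and logged. Raises ValueError on invalid
    SMILES or unknown set name.
    """
    names = DESCRIPTOR_SETS.get(descriptor_set)
    if names is None:
        raise ValueError(f"unknown descriptor set {descriptor_set!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    values = np.empty(len(names), dtype=float)
    for i, name in enumerate(names):
        try:
            v = float(_DESC_FN[name](mol))
        except Exception:
            v = float("nan")
        if not np.isfinite(v):
            log.debug("descriptor %s non-finite for %s; imputed to 0", name, smiles)
            v = 0.0
        values[i] = v
    return values


# ---------------------------------------------------------------------------
# learners

LEARNERS: dict[str, Callable[[dict, int], object]] = {
    "linear": lambda hp, seed: LinearRegression(**hp),
    "ridge": lambda hp, seed: Ridge(**{"alpha": 1.0, **hp}),
    "knn": lambda hp, seed: KNeighborsRegressor(**{"n_neighbors": 5, **hp}),
    "rf": lambda hp, seed: RandomForestRegressor(
        **{"n_estimators": 100, **hp}, random_state=seed
    ),
    "gbr": lambda hp, seed: GradientBoostingRegressor(**hp, random_state=seed),
}


@dataclass(frozen=True)
class ModelSpec:
    """A registered learner plus explicit hyperparameters and seed."""

    learner: str = "ridge"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    descriptor_set: str = "rdkit2d"

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unregistered learner {self.learner!r}; known: {sorted(LEARNERS)}")

    def build(self):
        return LEARNERS[self.learner](dict(self.hyperparameters), self.seed)


@dataclass
class BenchResult:
    """Per-fold and aggregate metrics of one cross-validated run."""

    fold_metrics: list[dict[str, float]]
    k: int
    split: str = "kfold"
    parity: list[tuple[float, float]] = field(default_factory=list)

    @property
    def aggregate(self) -> dict[str, float]:
        keys = self.fold_metrics[0].keys()
        return {m: float(np.mean([f[m] for f in self.fold_metrics])) for m in keys}


@dataclass
class CurationComparison:
    """RMSE/R2 per labelled curation strategy plus percent improvement."""

    strategies: dict[str, dict[str, float]]
    baseline: str
    final: str

    @property
    def pct_improvement(self) -> float:
        return pct_improvement(
            self.strategies[self.baseline]["rmse"], self.strategies[self.final]["rmse"]
        )


def metrics(y: Sequence[float], yhat: Sequence[float]) -> dict[str, float]:
    """RMSE, MAE and R2 of predictions against observations."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y and yhat must be equal-length 1-D vectors of size >= 2")
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined: y has zero variance")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"rmse": rmse, "mae": mae, "r2": r2}


def _design_matrix(dataset: CuratedDataset, descriptor_set: str) -> tuple[np.ndarray, np.ndarray]:
    keys = [rec.smiles_std or rec.smiles_raw for rec in dataset.records]
    if len(set(keys)) != len(keys):
        raise ValueError("cross-validation requires one record per molecule")
    X = np.vstack([featurize(s, descriptor_set) for s in keys])
    y = np.array([rec.pic50 for rec in dataset.records], dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("all records need pic50 set")
    return X, y


def cross_validate(
    dataset: CuratedDataset, spec: ModelSpec, k: int = 5, seed: int = 0
) -> BenchResult:
    """Seeded molecule-level k-fold cross-validation of one learner."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset.records) < k:
        raise ValueError(f"dataset of {len(dataset.records)} records is smaller than k={k}")
    X, y = _design_matrix(dataset, spec.descriptor_set)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[dict[str, float]] = []
    parity: list[tuple[float, float]] = []
    for train_idx, test_idx in folds.split(X):
        model = spec.build()
        model.fit(X[train_idx], y[train_idx])
        yhat = np.asarray(model.predict(X[test_idx]), dtype=float)
        fold_metrics.append(metrics(y[test_idx], yhat))
        parity.extend(zip(y[test_idx].tolist(), yhat.tolist()))
    return BenchResult(fold_metrics=fold_metrics, k=k, parity=parity)


def pct_improvement(rmse_baseline: float, rmse_final: float) -> float:
    """Percent RMSE reduction: 100 * (baseline - final) / baseline."""
    if rmse_baseline == 0:
        raise ZeroDivisionError("baseline RMSE is 0; improvement undefined")
    return 100.0 * (rmse_baseline - rmse_final) / rmse_baseline


def compare_strategies(
    datasets: dict[str, CuratedDataset],
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    baseline: str | None = None,
    final: str | None = None,
) -> CurationComparison:
    """Cross-validate each labelled dataset and report the improvement
    of ``final`` over ``baseline`` (defaults: first and last label)."""
    if len(datasets) < 2:
        raise ValueError("need at least two labelled datasets to compare")
    labels = list(datasets)
    baseline = baseline or labels[0]
    final = final or labels[-1]
    results: dict[str, dict[str, float]] = {}
    for label, ds in datasets.items():
        bench = cross_validate(ds, spec, k=k, seed=seed)
        agg = bench.aggregate
        results[label] = {"n_records": len(ds.records), "rmse": agg["rmse"], "r2": agg["r2"]}
    return CurationComparison(strategies=results, baseline=baseline, final=final)


def parity_summary(
    y: Sequence[float], yhat: Sequence[float], band: float = 0.5
) -> dict:
    """Fraction of predictions within +-band of the observation."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    pairs = list(zip(y.tolist(), yhat.tolist()))
    if not pairs:
        return {"fraction_within_band": float("nan"), "pairs": []}
    within = float(np.mean(np.abs(y - yhat) <= band))
    return {"fraction_within_band": within, "pairs": pairs}
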