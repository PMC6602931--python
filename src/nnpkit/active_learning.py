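"""Query-by-committee active learning.

An ensemble pretrained on cheap labels scores a pool of unlabeled
conformations by member disagreement; the most contentious points are sent
to the expensive oracle, added to the curated set, and the ensemble is
retrained by transfer learning.  Three selection iterations follow an
initial random subsample, and disagreement is recomputed with the retrained
ensemble each iteration (a static-ranking ablation mode is provided).
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conformation import Conformation
from .model import Ensemble, member_energies_from_aev
from .training import Dataset, FreezeSpec, TrainConfig, transfer_learn

logger = logging.getLogger(__name__)


@dataclass
class ALConfig:
    initial_random_size: int = 24
    iterations: int = 3
    per_iteration_budget: int = 24
    normalize_disagreement: bool = True
    oracle_subsample_fraction: float = 1.0  # 0.1 mirrors random 10% relabeling
    static_ranking: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("initial_random_size", "iterations", "per_iteration_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.oracle_subsample_fraction <= 1.0):
            raise ValueError("oracle_subsample_fraction must be in (0, 1]")

    def iteration_seeds(self) -> List[int]:
        """Master seed → per-round seeds by a fixed splitting rule."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s) % 2**31 for s in ss.generate_state(self.iterations + 1)]


@dataclass
class ALTrace:
    """Audit trail: per round, what was selected at which disagreement and
    how large the curated set became."""

    rounds: List[dict] = field(default_factory=list)

    def record(self, **kw) -> None:
        self.rounds.append(kw)

    def dataset_sizes(self) -> List[int]:
        return [r["dataset_size"] for r in self.rounds]

    def to_json(self) -> str:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return json.dumps(
            [{k: clean(v) for k, v in r.items()} for r in self.rounds], sort_keys=True
        )

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["round", "kind", "n_selected", "dataset_size", "mean_disagreement"]
            )
            for i, r in enumerate(self.rounds):
                sel = r.get("selected", [])
                scores = np.asarray(r.get("scores", []), dtype=float)
                w.writerow(
                    [
                        i,
                        r.get("kind", ""),
                        len(sel),
                        r.get("dataset_size", ""),
                        float(scores.mean()) if scores.size else "",
                    ]
                )


def pool_disagreements(
    ensemble: Ensemble, pool: Dataset, normalize: bool = True
) -> np.ndarray:
    """Committee disagreement (population std of member energies, optionally
    per-√N_atoms) for every pool conformation."""
    aevs = pool.get_aevs(ensemble.spec)
    out = np.empty(len(pool))
    for i, c in enumerate(pool.conformations):
        e = member_energies_from_aev(ensemble, c.species, aevs[i])
        d = float(e.std())
        if normalize:
            d /= np.sqrt(c.n_atoms)
        out[i] = d
    return out


def rank_by_disagreement(
    ensemble: Ensemble,
    pool: Dataset,
    budget: int,
    normalize: bool = True,
    scores: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Indices of the `budget` pool members with largest disagreement,
    in decreasing-score order; ties break by stable input order."""
    if ensemble.size < 2:
        raise ValueError("query by committee needs at least two members")
    if budget > len(pool):
        raise ValueError(f"budget {budget} exceeds pool size {len(pool)}")
    if scores is None:
        scores = pool_disagreements(ensemble, pool, normalize)
    order = np.argsort(-scores, kind="stable")
    return order[:budget]


def active_learning_loop(
    low_ensemble: Ensemble,
    pool: Dataset,
    high_oracle: Callable[[Conformation], object],
    config: ALConfig,
    train_config: Optional[TrainConfig] = None,
    freeze: Optional[FreezeSpec] = None,
) -> Tuple[Dataset, Ensemble, ALTrace]:
    """Curate a high-fidelity dataset by committee disagreement.

    Round 0 draws `initial_random_size` pool points uniformly (seeded) and
    labels them; each of the `iterations` subsequent rounds labels the
    top-budget disagreement points among the remaining pool, grows the
    curated set, and retrains by transfer learning from the original
    low-fidelity ensemble.  Oracle failures are logged and skipped, never
    silently dropped.
    """
    train_config = train_config or TrainConfig()
    total_wanted = config.initial_random_size + config.iterations * config.per_iteration_budget
    if total_wanted > len(pool):
        raise ValueError(
            f"budget {total_wanted} exceeds pool size {len(pool)}"
        )
    seeds = config.iteration_seeds()
    rng = np.random.default_rng(seeds[0])
    trace = ALTrace()
    remaining = list(range(len(pool)))

    n0 = min(config.initial_random_size, len(pool))
    picked = sorted(rng.choice(len(pool), size=n0, replace=False).tolist())
    labeled = _label(pool, picked, high_oracle, trace_kind="random", trace=trace)
    for i in picked:
        remaining.remove(i)

    curated = Dataset(labeled, fidelity="high")
    ensemble = transfer_learn(low_ensemble, curated, freeze, train_config)
    static_scores = (
        pool_disagreements(ensemble, pool, config.normalize_disagreement)
        if config.static_ranking
        else None
    )

    for it in range(config.iterations):
        if not remaining:
            trace.record(
                kind="selection", selected=[], scores=[], dataset_size=len(curated)
            )
            continue
        sub = pool.subset(remaining)
        if static_scores is not None:
            scores = static_scores[remaining]
        else:
            scores = pool_disagreements(
                ensemble, sub, config.normalize_disagreement
            )
        budget = min(config.per_iteration_budget, len(remaining))
        top = rank_by_disagreement(ensemble, sub, budget, scores=scores)
        chosen = [remaining[i] for i in top]
        if config.oracle_subsample_fraction < 1.0:
            srng = np.random.default_rng(seeds[it + 1])
            keep = max(1, int(round(config.oracle_subsample_fraction * len(chosen))))
            chosen = sorted(
                srng.choice(chosen, size=keep, replace=False).tolist()
            )
        new_labeled = _label(
            pool, chosen, high_oracle, trace_kind="selection", trace=trace,
            scores=scores[top],
        )
        for i in chosen:
            remaining.remove(i)
        curated = Dataset(curated.conformations + new_labeled, fidelity="high")
        trace.rounds[-1]["dataset_size"] = len(curated)
        ensemble = transfer_learn(
            low_ensemble, curated, freeze,
            train_config.replace(seed=train_config.seed + it + 1),
        )
    return curated, ensemble, trace


def _label(pool, indices, oracle, trace_kind, trace, scores=None):
    labeled = []
    failed = []
    for i in indices:
        c = pool.conformations[i]
        try:
            result = oracle(c)
        except Exception as exc:  # noqa: BLE001 - oracle failures are data, not bugs
            logger.warning("oracle failed on pool index %d (%s): %s", i, c.molecule_id, exc)
            failed.append(i)
            continue
        if isinstance(result, Conformation):
            labeled.append(result)
        elif isinstance(result, tuple):
            e, f = result
            labeled.append(c.with_(energy_high=float(e), forces=np.asarray(f)))
        else:
            labeled.append(c.with_(energy_high=float(result)))
    trace.record(
        kind=trace_kind,
        selected=[i for i in indices if i not in failed],
        failed=failed,
        scores=[] if scores is None else np.asarray(scores),
        dataset_size=len(labeled),
    )
    return labeled
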