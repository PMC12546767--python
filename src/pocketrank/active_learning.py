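"""Active-learning campaign for lead optimization.

The loop mirrors the way expensive free-energy labels are spent in
practice: seed with a random batch, retrain a surrogate on everything
labeled so far, score the unlabeled pool, acquire the next batch (greedy
on predicted potency, or epsilon-greedy exploration-exploitation with the
exploration picks spread over unsampled scaffold clusters), query the
oracle, repeat.  Recall of the true top-k% and r^2 on the pool are
recorded every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .metrics import correlation_suite, topk_recall

logger = logging.getLogger(__name__)


@dataclass
class ALState:
    """Labeled/unlabeled pool partition and per-iteration history."""

    labeled: dict = field(default_factory=dict)  # ligand_id -> oracle potency
    unlabeled: list = field(default_factory=list)
    iteration: int = 0
    selections: list = field(default_factory=list)  # list of id lists
    history: list = field(default_factory=list)  # list of metric dicts

    @property
    def labeled_fraction(self) -> float:
        n = len(self.labeled) + len(self.unlabeled)
        return len(self.labeled) / n if n else 0.0


def _truth_topk(pool_ids, oracle, k_fraction):
    pot = {l: oracle(l) for l in pool_ids}
    k = max(1, int(round(k_fraction * len(pool_ids))))
    return set(sorted(pool_ids, key=lambda l: (-pot[l], l))[:k]), pot


def greedy_select(scores: dict, unlabeled: list, batch: int, rng) -> list:
    return sorted(unlabeled, key=lambda l: (-scores[l], l))[:batch]


def explore_exploit_select(
    scores: dict,
    unlabeled: list,
    batch: int,
    rng,
    epsilon: float,
    scaffold_of: dict | None,
    sampled_clusters: set,
) -> list:
    """epsilon-fraction exploration (uniform over scaffold clusters not yet
    sampled, then uniform) + greedy remainder."""
    n_explore = int(round(epsilon * batch))
    explore = []
    pool = list(unlabeled)
    if scaffold_of:
        fresh = [l for l in pool if scaffold_of.get(l) not in sampled_clusters]
        by_cluster: dict = {}
        for l in fresh:
            by_cluster.setdefault(scaffold_of[l], []).append(l)
        clusters = sorted(by_cluster)
        rng.shuffle(clusters)
        for c in clusters[:n_explore]:
            members = sorted(by_cluster[c])
            explore.append(members[int(rng.integers(len(members)))])
    while len(explore) < n_explore and pool:
        cand = pool[int(rng.integers(len(pool)))]
        if cand not in explore:
            explore.append(cand)
    rest = [l for l in unlabeled if l not in set(explore)]
    return explore + greedy_select(scores, rest, batch - len(explore), rng)


def active_learning_run(
    pool_ids: list,
    oracle,
    model_factory,
    strategy: str = "greedy",
    batch_fraction: float = 0.01,
    iterations: int = 5,
    seed: int = 0,
    k_fraction: float = 0.02,
    scaffold_of: dict | None = None,
    epsilon_schedule=(0.5, 0.1),
) -> ALState:
    """Run one seeded campaign.

    `model_factory(labeled: dict, seed: int) -> scores: dict over pool_ids`
    retrains the surrogate from scratch each iteration and scores the whole
    pool.  `strategy` is 'greedy' or 'explore-exploit'.
    """
    if len(pool_ids) < 100:
        raise ValueError("pool must hold at least 100 ligands")
    rng = np.random.default_rng(seed)
    pool_ids = sorted(pool_ids)
    truth, true_pot = _truth_topk(pool_ids, oracle, k_fraction)
    batch = max(1, int(round(batch_fraction * len(pool_ids))))

    state = ALState(unlabeled=list(pool_ids))
    # iteration 0: random seed batch
    seed_idx = rng.choice(len(pool_ids), size=batch, replace=False)
    seed_batch = [pool_ids[i] for i in sorted(seed_idx)]
    for l in seed_batch:
        state.labeled[l] = oracle(l)
    state.unlabeled = [l for l in pool_ids if l not in state.labeled]
    state.selections.append(seed_batch)

    sampled_clusters = (
        {scaffold_of[l] for l in seed_batch if l in scaffold_of} if scaffold_of else set()
    )
    for it in range(1, iterations + 1):
        scores = model_factory(dict(state.labeled), seed + 1000 * it)
        take = min(batch, len(state.unlabeled))
        if take < batch:
            logger.warning("final-iteration truncation: only %d ligands left", take)
        if take == 0:
            break
        if strategy == "greedy":
            chosen = greedy_select(scores, state.unlabeled, take, rng)
        elif strategy == "explore-exploit":
            eps0, eps1 = epsilon_schedule
            eps = eps0 + (eps1 - eps0) * (it - 1) / max(1, iterations - 1)
            chosen = explore_exploit_select(
                scores, state.unlabeled, take, rng, eps, scaffold_of, sampled_clusters
            )
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        for l in chosen:
            state.labeled[l] = oracle(l)
            if scaffold_of and l in scaffold_of:
                sampled_clusters.add(scaffold_of[l])
        state.unlabeled = [l for l in state.unlabeled if l not in set(chosen)]
        state.selections.append(chosen)
        state.iteration = it

        suite = correlation_suite(
            [scores[l] for l in pool_ids], [true_pot[l] for l in pool_ids]
        )
        state.history.append(
            {
                "iteration": it,
                "labeled": len(state.labeled),
                "labeled_fraction": state.labeled_fraction,
                "topk_recall": topk_recall(state.labeled, truth),
                "r2": suite["r2"],
                "spearman": suite["spearman"],
            }
        )
    return state


# ---------------------------------------------------------------------------
# surrogate factories
# ---------------------------------------------------------------------------

def sklearn_factory(features: dict, estimator="rf"):
    """Baseline surrogates over ligand features (the classic fingerprint
    regressors used as comparison points): 'linear', 'rf' or 'gbm'."""

    def factory(labeled: dict, seed: int) -> dict:
        ids = sorted(labeled)
        X = np.stack([features[l] for l in ids])
        y = np.array([labeled[l] for l in ids])
        if estimator == "linear":
            est = LinearRegression()
        elif estimator == "rf":
            est = RandomForestRegressor(n_estimators=100, random_state=seed % 2**31)
        elif estimator == "gbm":
            est = GradientBoostingRegressor(random_state=seed % 2**31)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        est.fit(X, y)
        all_ids = sorted(features)
        preds = est.predict(np.stack([features[l] for l in all_ids]))
        return dict(zip(all_ids, preds))

    return factory


def finetune_factory(results, assay_template, ligand_records, steps: int = 120, lr: float = 0.02):
    """Surrogate built on the pre-trained embedding model: each iteration
    re-runs few-shot fine-tuning (from the pre-trained parameters, not
    warm-started) on the labeled set, then scores the pool by cosine."""
    from .data_model import AffinityMeasurement, Assay, Unit

    pocket_record = results.model.collection.pockets.get(
        assay_template.pocket_ids[0], {"pocket_id": assay_template.pocket_ids[0]}
    )

    def factory(labeled: dict, seed: int) -> dict:
        assay = Assay(
            assay_id="al-support",
            target_group_id=assay_template.target_group_id,
            pocket_ids=assay_template.pocket_ids,
            measurements=tuple(
                AffinityMeasurement(ligand_id=l, value=10.0 ** (9.0 - p), unit=Unit.NM)
                for l, p in labeled.items()
            ),
            unit=Unit.NM,
        )
        tuned = results.finetune(
            assay, ligand_records, sorted(labeled), steps=steps, lr=lr, seed=seed,
            pocket_record=pocket_record,
        )
        return tuned.predict_scores(pocket_record, ligand_records)

    return factory


def random_factory(pool_ids: list):
    """Uninformed surrogate: fresh random scores each call (the analytic
    null for recall comparisons)."""

    def factory(labeled: dict, seed: int) -> dict:
        rng = np.random.default_rng(seed % 2**31)
        return dict(zip(sorted(pool_ids), rng.normal(size=len(pool_ids))))

    return factory
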