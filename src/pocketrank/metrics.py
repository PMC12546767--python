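"""Screening and ranking evaluation metrics.

Enrichment factor, BEDROC (Truchon-Bayly closed form), the correlation
suite (Spearman rho, Pearson r, r^2) and top-k% recall.  Score ties are
broken stably by ligand id before any rank-based metric, because EF at
small fractions is tie-sensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_BEDROC_ALPHA = 80.5


class DomainError(ValueError):
    pass


@dataclass
class ScreenRanking:
    """A scored, labeled screening ranking (best score first)."""

    ligand_ids: list
    scores: np.ndarray
    labels: np.ndarray  # bool, True = active

    def __post_init__(self):
        order = sorted(
            range(len(self.ligand_ids)),
            key=lambda i: (-float(self.scores[i]), str(self.ligand_ids[i])),
        )
        self.ligand_ids = [self.ligand_ids[i] for i in order]
        self.scores = np.asarray(self.scores, dtype=float)[order]
        self.labels = np.asarray(self.labels, dtype=bool)[order]

    @property
    def n_total(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def active_ranks(self) -> np.ndarray:
        """1-based ranks of the actives."""
        return np.flatnonzero(self.labels) + 1


def enrichment_factor(r: ScreenRanking, fraction: float = 0.01) -> float:
    """(active rate in the top ceil(fraction*N)) / (overall active rate)."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError("fraction must lie in (0, 1]")
    if r.n_actives == 0:
        raise DomainError("enrichment undefined with no actives")
    top = math.ceil(fraction * r.n_total)
    hits = int(r.labels[:top].sum())
    return (hits / top) / (r.n_actives / r.n_total)


def bedroc(r: ScreenRanking, alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of ROC, in [0, 1].

    Closed form: RIE (the mean of exp(-alpha * rank/N) over actives,
    normalised by its uniform expectation) min-max rescaled between the
    analytic worst and best cases.
    """
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    n, N = r.n_actives, r.n_total
    if n == 0 or n >= N:
        raise DomainError("BEDROC needs 0 < n_actives < n_total")
    ra = n / N
    ranks = r.active_ranks
    s = np.exp(-alpha * ranks / N).sum()
    rand_sum = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    rie = s / rand_sum
    factor = (
        ra * math.sinh(alpha / 2)
        / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
    )
    cte = 1.0 / (1 - math.exp(alpha * (1 - ra)))
    return float(rie * factor + cte)


def bedroc_random_expectation(alpha: float = DEFAULT_BEDROC_ALPHA, ra: float = 0.01) -> float:
    """Analytic expectation of BEDROC under a uniformly random ranking
    (RIE expectation is 1 by construction)."""
    factor = (
        ra * math.sinh(alpha / 2)
        / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
    )
    cte = 1.0 / (1 - math.exp(alpha * (1 - ra)))
    return float(factor + cte)


def correlation_suite(predicted, observed, r2_mode: str = "pearson") -> dict:
    """Spearman rho (average ranks on ties), Pearson r and r^2.

    r^2 defaults to the squared Pearson correlation, the convention of the
    relative binding free energy benchmark literature; pass
    ``r2_mode='determination'`` for the coefficient-of-determination
    variant 1 - SS_res/SS_tot.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    if r2_mode == "pearson":
        r2 = r * r
    elif r2_mode == "determination":
        ss_res = float(((y - x) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
    else:
        raise DomainError(f"unknown r2_mode {r2_mode!r}")
    return {"spearman": rho, "pearson": r, "r2": r2}


def topk_recall(selected, truth) -> float:
    """|selected ∩ truth| / |truth| for a world-truth top-k% set."""
    truth = set(truth)
    if not truth:
        raise DomainError("empty truth set")
    return len(set(selected) & truth) / len(truth)


@dataclass
class MetricReport:
    """Named scalar metrics with their parameters."""

    values: dict = field(default_factory=dict)

    @classmethod
    def from_ranking(
        cls,
        r: ScreenRanking,
        ef_fractions=(0.01,),
        alpha: float = DEFAULT_BEDROC_ALPHA,
    ) -> "MetricReport":
        vals = {f"ef_{f:g}": enrichment_factor(r, f) for f in ef_fractions}
        vals[f"bedroc_alpha_{alpha:g}"] = bedroc(r, alpha)
        return cls(values=vals)

    def to_json(self) -> str:
        import json

        return json.dumps(self.values, indent=1, sort_keys=True)


def wilcoxon_one_sided(x, y) -> float:
    """One-sided Wilcoxon signed-rank p-value for median(x - y) > 0,
    the paired comparison helper used in reports."""
    res = stats.wilcoxon(x, y, alternative="greater")
    return float(res.pvalue)
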