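"""Training objectives: listwise pharmacophore ranking, in-batch
contrastive scaffold discrimination, their combination, and the regression
baseline used in ablations.

The ranking term treats the within-assay affinity order as a Plackett-Luce
sequential selection process: at step k the k-th ranked ligand is chosen by
a temperature softmax over the ligands not yet selected (those with
affinity no stronger than its own), and the loss is the weighted negative
log-likelihood of the observed order with per-step decay
``mu_k = 1 / (|L_i| * ln(k+1))``.  The contrastive term is a two-direction
in-batch softmax over active pocket-ligand pairs, with cross-assay pairs
sharing a protein target group excluded from the negatives (potential false
negatives), normalised per assay by the active count and weighted by
``gamma_i = 1 / |L_i|``.  Natural logarithms throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autodiff import Var, as_var, logsumexp
from .encoders import normalize_rows_var

logger = logging.getLogger(__name__)

NEG_INF = -1e30  # additive mask for excluded softmax entries


class ConfigError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass
class AssayBatchItem:
    """One assay's contribution to a batch step.

    Ligand rows must already be sorted best-first (strongest binder first,
    ties stable by ligand_id); ``potency`` holds the within-assay ordering
    keys in the same order.  ``pocket_emb`` is the embedding of the single
    pocket structure sampled for this step (None for ligand-only context
    items that only enlarge the negative pool).
    """

    assay_id: str
    target_group_id: str
    pocket_emb: object  # Var (1, d) or None
    ligand_embs: object  # Var (m, d)
    potency: np.ndarray  # (m,), larger = stronger
    active: np.ndarray  # (m,) bool
    ligand_ids: tuple = ()
    n_ligands_total: int | None = None  # |L_i| context; defaults to m

    @property
    def m(self) -> int:
        return self.ligand_embs.shape[0]

    @property
    def size_context(self) -> int:
        return self.n_ligands_total if self.n_ligands_total else self.m


@dataclass
class RankedAssayBatch:
    items: list
    tau_rank: float = 0.07
    tau_contrast: float = 0.07

    def __post_init__(self):
        if self.tau_rank <= 0 or self.tau_contrast <= 0:
            raise ConfigError("temperatures must be positive")


@dataclass
class NegativeMask:
    """usable[i, j]: may ligand column j serve as a negative for pocket i?
    Measured positives and cross-assay pairs sharing a target group are
    excluded; a positive is re-admitted for its own softmax by the loss."""

    usable: np.ndarray  # (n_items, M) bool
    item_of_col: np.ndarray  # (M,) item index of each ligand column


def step_selection_prob(scores, chosen: int, tau: float) -> float:
    """Plackett-Luce single-step selection probability: temperature softmax
    over the candidate set, evaluated at the chosen index."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ContractError("empty candidate set")
    if tau <= 0:
        raise ConfigError("tau must be positive")
    z = scores / tau
    z -= z.max()
    w = np.exp(z)
    return float(w[chosen] / w.sum())


def _cosine_scores(item: AssayBatchItem) -> Var:
    """(m,)-shaped Var of cosine similarities pocket vs item ligands."""
    p = normalize_rows_var(item.pocket_emb)
    l = normalize_rows_var(item.ligand_embs)
    return (p @ l.T).reshape(item.m)


def ranking_loss(batch: RankedAssayBatch) -> Var:
    """Weighted Plackett-Luce negative log-likelihood, averaged over assays.

    Per assay: ``sum_k mu_k * (-log pi(l_k | L^{<=k}, p))`` where the step-k
    candidate set holds every ligand whose affinity is no stronger than the
    k-th ranked one (ties included on both sides), and
    ``mu_k = 1 / (|L_i| * ln(k+1))``.
    """
    terms = []
    for item in batch.items:
        if item.pocket_emb is None:
            continue
        m = item.m
        if m == 0:
            raise ContractError(f"assay {item.assay_id}: no ligands in batch")
        s = _cosine_scores(item) * (1.0 / batch.tau_rank)  # (m,)
        pot = np.asarray(item.potency, dtype=float)
        # candidate mask: row k admits ligands no stronger than ligand k
        cand = pot[None, :] <= pot[:, None] + 1e-12
        mask = np.where(cand, 0.0, NEG_INF)
        S = Var(np.ones((m, 1))) @ s.reshape(1, m) + Var(mask)  # (m, m)
        lse = logsumexp(S, axis=1)  # (m,)
        sel = (S * Var(np.eye(m))).sum(axis=1)  # chosen-score diagonal
        mu = 1.0 / (item.size_context * np.log(np.arange(1, m + 1) + 1.0))
        terms.append(((lse - sel) * Var(mu)).sum())
    if not terms:
        raise ContractError("batch has no assay with a pocket embedding")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def build_negative_mask(batch: RankedAssayBatch, labels: dict | None = None) -> NegativeMask:
    """Apply the false-negative exclusion rule: a cross-assay (pocket,
    ligand) pair is unusable as a negative when the two assays share a
    protein target group; measured-active pairs are likewise excluded."""
    items = batch.items
    groups = [it.target_group_id for it in items]
    item_of_col = np.concatenate(
        [np.full(it.m, i, dtype=int) for i, it in enumerate(items)]
    )
    col_group = np.array([groups[i] for i in item_of_col], dtype=object)
    usable = np.array([[g != cg for cg in col_group] for g in groups], dtype=bool)
    if labels is not None:
        from .data_model import Activity

        col_ids = [lid for it in items for lid in it.ligand_ids]
        for i, g in enumerate(groups):
            for j, lid in enumerate(col_ids):
                if labels.get((g, lid)) is Activity.ACTIVE:
                    usable[i, j] = False
    return NegativeMask(usable=usable, item_of_col=item_of_col)


def contrastive_loss(batch: RankedAssayBatch, mask: NegativeMask) -> Var:
    """Two-direction in-batch softmax over active pairs (Eqs. of the
    scaffold-discrimination objective), per-assay normalised by the active
    count, weighted by ``gamma_i = 1/|L_i|`` and averaged over assays."""
    items = batch.items
    pocket_items = [i for i, it in enumerate(items) if it.pocket_emb is not None]
    if not pocket_items:
        raise ContractError("batch has no pocket embeddings")

    P = normalize_rows_var(
        _concat_rows([items[i].pocket_emb for i in pocket_items])
    )  # (B, d)
    L = normalize_rows_var(_concat_rows([it.ligand_embs for it in items]))  # (M, d)
    S = (P @ L.T) * (1.0 / batch.tau_contrast)  # (B, M)
    M_total = S.shape[1]
    col_offset = np.cumsum([0] + [it.m for it in items])

    group_of_row = [items[i].target_group_id for i in pocket_items]
    per_assay = []
    for row, item_idx in enumerate(pocket_items):
        it = items[item_idx]
        act_local = np.flatnonzero(np.asarray(it.active, dtype=bool))
        if act_local.size == 0:
            logger.debug("assay %s: no active ligand in batch", it.assay_id)
            per_assay.append(Var(0.0))
            continue
        act_cols = act_local + col_offset[item_idx]
        allowed = mask.usable[item_idx]  # (M,)

        # pocket -> ligand: softmax over {positive} + allowed negatives
        rowsel = np.zeros((act_cols.size, len(pocket_items)))
        rowsel[np.arange(act_cols.size), row] = 1.0
        R = Var(rowsel) @ S  # (n_act, M)
        msk = np.where(allowed[None, :], 0.0, NEG_INF).repeat(act_cols.size, axis=0)
        msk[np.arange(act_cols.size), act_cols] = 0.0
        lse_pl = logsumexp(R + Var(msk), axis=1)
        selmat = np.zeros((act_cols.size, M_total))
        selmat[np.arange(act_cols.size), act_cols] = 1.0
        sel_pl = (R * Var(selmat)).sum(axis=1)

        # ligand -> pocket: softmax over {own pocket} + different-group pockets
        colsel = np.zeros((act_cols.size, M_total))
        colsel[np.arange(act_cols.size), act_cols] = 1.0
        C = Var(colsel) @ S.T  # (n_act, B)
        pallow = np.array(
            [g != it.target_group_id for g in group_of_row], dtype=bool
        )
        pallow[row] = True
        pmsk = np.where(pallow[None, :], 0.0, NEG_INF).repeat(act_cols.size, axis=0)
        lse_lp = logsumexp(C + Var(pmsk), axis=1)
        psel = np.zeros((act_cols.size, len(pocket_items)))
        psel[np.arange(act_cols.size), row] = 1.0
        sel_lp = (C * Var(psel)).sum(axis=1)

        gamma = 1.0 / it.size_context
        inv_act = 1.0 / act_cols.size
        per_assay.append(
            ((lse_pl - sel_pl).sum() + (lse_lp - sel_lp).sum()) * (gamma * inv_act)
        )

    total = per_assay[0]
    for t in per_assay[1:]:
        total = total + t
    return total * (1.0 / len(per_assay))


def _concat_rows(vars_):
    from ._autodiff import concat

    return concat([as_var(v) for v in vars_], axis=0)


def combined_loss(batch: RankedAssayBatch, mask: NegativeMask) -> Var:
    """Pre-training objective: contrastive + ranking with unit weights."""
    return contrastive_loss(batch, mask) + ranking_loss(batch)


def regression_baseline_loss(scores, potencies, calibration=(0.0, 1.0), rank_only=False) -> Var:
    """Mean squared error between an affine-calibrated cosine score and
    absolute potency — the regression ablation of the ranking objective.
    Undefined for rank-only (percent-unit) assays."""
    if rank_only:
        raise ContractError("regression baseline undefined for rank-only units")
    a, b = (as_var(c) for c in calibration)
    s = as_var(scores)
    resid = a + b * s - Var(np.asarray(potencies, dtype=float))
    return (resid * resid).mean()
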