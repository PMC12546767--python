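"""Pocket-ligand knowledge graph and attention-based pocket refinement.

A directed heterogeneous graph connects active ligands to their pockets and
sequence-similar pockets to each other (edge B->A whenever the BLOSUM50
global alignment score of A and B exceeds half of A's self-alignment
score).  A query pocket embedding is refined by two attention aggregators —
one over its in-neighbour pockets, one over their active ligands reached in
two hops, each ligand transformed by a 2-layer MLP together with a relation
embedding derived from the connecting alignment score — and combined with
the original embedding through a convex combination
``p* = g1*p_lig + g2*p_poc + (1-g1-g2)*p`` whose coefficients live on the
simplex by a 3-way softmax parameterisation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from ._autodiff import Adam, Var, concat, logsumexp
from .data_model import Activity

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
GAP_OPEN = 11.0
GAP_EXTEND = 1.0
N_RELATION_BINS = 8
NEIGHBOR_CAP = 64


class DomainError(ValueError):
    pass


class ContractError(ValueError):
    pass


def pocket_alignment_score(
    seq_a: str, seq_b: str, gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND
) -> float:
    """Global pairwise protein alignment score under BLOSUM50 (symmetric).

    Unknown residue letters are mapped to X with a warning.
    """
    from skbio.alignment import pair_align_prot

    cleaned = []
    for seq in (seq_a, seq_b):
        if not seq:
            raise DomainError("empty sequence")
        s = seq.upper()
        if not set(s) <= AA_ALPHABET:
            bad = sorted(set(s) - AA_ALPHABET)
            logger.warning("mapping unknown residue letter(s) %s to X", bad)
            s = "".join(c if c in AA_ALPHABET else "X" for c in s)
        cleaned.append(s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pair_align_prot(
            cleaned[0],
            cleaned[1],
            mode="global",
            sub_score="BLOSUM50",
            gap_cost=(gap_open, gap_extend),
            free_ends=False,
        )
    return float(res.score)


def build_graph(collection, labels: dict, score_fn=pocket_alignment_score) -> nx.DiGraph:
    """Assemble the knowledge graph from a validated collection and labels.

    Ligand->pocket edges connect each active (target group, ligand) pair to
    every pocket of that group.  Pocket->pocket edges follow the asymmetric
    alignment criterion score(A, B) > 0.5 * score(A, A), carrying the raw
    score and the score normalised by the target's self-alignment.
    """
    g = nx.DiGraph()
    group_of_pocket = {}
    for a in collection.assays.values():
        for p in a.pocket_ids:
            group_of_pocket.setdefault(p, a.target_group_id)

    pockets = []
    for pid, rec in collection.pockets.items():
        seq = rec.get("sequence")
        if not seq:
            logger.warning("pocket %s has no sequence; excluded from graph", pid)
            continue
        g.add_node(pid, kind="pocket", sequence=seq)
        pockets.append(pid)

    for (group, lig), lab in labels.items():
        if lab is not Activity.ACTIVE:
            continue
        g.add_node(lig, kind="ligand")
        for pid in pockets:
            if group_of_pocket.get(pid) == group:
                g.add_edge(lig, pid, kind="lp")

    cache = {}

    def score(x, y):
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = score_fn(
                g.nodes[key[0]]["sequence"], g.nodes[key[1]]["sequence"]
            )
        return cache[key]

    self_score = {p: score(p, p) for p in pockets}
    for a_id in pockets:
        for b_id in pockets:
            if a_id == b_id:
                continue
            s = score(a_id, b_id)
            if s > 0.5 * self_score[a_id]:
                g.add_edge(
                    b_id, a_id, kind="pp", score=s, norm_score=s / self_score[a_id]
                )
    return g


def two_hop_ligand_neighbors(graph: nx.DiGraph, pocket_k: str, cap: int = NEIGHBOR_CAP):
    """{ligand j : exists i with (j->i) in E_lp and (i->k) in E_pp}.

    Each ligand carries the normalised alignment score of its best-scoring
    connecting pocket edge (multi-path ligands deduplicated on the max);
    capped at `cap` ligands, score-ranked, ties stable by ligand id.
    """
    if pocket_k not in graph:
        raise ContractError(f"pocket {pocket_k!r} not in graph")
    best = {}
    for i, _, data in graph.in_edges(pocket_k, data=True):
        if data.get("kind") != "pp":
            continue
        rel = data["norm_score"]
        for j, _, d2 in graph.in_edges(i, data=True):
            if d2.get("kind") != "lp":
                continue
            if j not in best or rel > best[j]:
                best[j] = rel
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:cap]
    return dict(ranked)


def add_query_pocket(
    graph: nx.DiGraph, pocket_id: str, sequence: str, score_fn=pocket_alignment_score
) -> int:
    """Connect a cold-start query pocket into an existing graph.

    Only incoming pocket edges are added (B -> query where the alignment
    score with B exceeds half the query's self-alignment) — outgoing edges
    do not influence the query's own refinement.  Returns the number of
    edges added.
    """
    if not sequence:
        raise DomainError("query pocket has no sequence")
    graph.add_node(pocket_id, kind="pocket", sequence=sequence)
    self_score = score_fn(sequence, sequence)
    added = 0
    for other, data in graph.nodes(data=True):
        if other == pocket_id or data.get("kind") != "pocket":
            continue
        s = score_fn(sequence, data["sequence"])
        if s > 0.5 * self_score:
            graph.add_edge(
                other, pocket_id, kind="pp", score=s, norm_score=s / self_score
            )
            added += 1
    return added


# ---------------------------------------------------------------------------
# attention parameters and aggregation
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Two independent attention heads (pocket-pocket, pocket-ligand), the
    ligand-relation MLP Phi, the relation embedding table and the simplex
    logits for the final convex combination."""

    d: int
    d_h: int
    params: dict = field(default_factory=dict)

    def trainable(self) -> dict:
        return self.params


def init_attention_params(d: int, d_h: int | None = None, seed: int = 0) -> AttentionParams:
    d_h = d_h or 2 * d
    rng = np.random.default_rng(seed)
    p = {}
    for head in ("pp", "pl"):
        p[f"{head}.W1"] = Var(rng.normal(0, np.sqrt(1.0 / d), size=(2 * d, d_h)))
        p[f"{head}.b1"] = Var(np.zeros((1, d_h)))
        p[f"{head}.W2"] = Var(rng.normal(0, np.sqrt(1.0 / d_h), size=(d_h, 1)))
    # Phi: 2-layer MLP, input [ligand | relation] (2d), hidden 2d, output d.
    # Initialised as an exact pass-through of the ligand part (relu pairs),
    # so an untrained refinement stays in the ligand embedding space.
    W0 = np.zeros((2 * d, 2 * d))
    W0[:d, :d] = np.eye(d)
    W0[:d, d:] = -np.eye(d)
    W1 = np.vstack([np.eye(d), -np.eye(d)])
    p["phi.W0"] = Var(W0 + 0.01 * rng.normal(size=W0.shape))
    p["phi.b0"] = Var(np.zeros((1, 2 * d)))
    p["phi.W1"] = Var(W1 + 0.01 * rng.normal(size=W1.shape))
    p["phi.b1"] = Var(np.zeros((1, d)))
    p["relation.table"] = Var(0.1 * rng.normal(size=(N_RELATION_BINS, d)))
    p["gamma.logits"] = Var(np.array([0.0, 0.0, 1.0]))
    return AttentionParams(d=d, d_h=d_h, params=p)


def relation_bin(norm_score: float) -> int:
    """Bucketize a self-normalised alignment score (~(0.5, 1]) into one of
    N_RELATION_BINS learned relation embeddings."""
    b = int(np.clip((norm_score - 0.5) * 2.0, 0.0, 0.999999) * N_RELATION_BINS)
    return b


def _attention(query: Var, values: Var, params: AttentionParams, head: str) -> Var:
    """softmax(W2^T relu(W1 [value_i | query] + b1)) weighted value sum."""
    n = values.shape[0]
    q_rep = Var(np.ones((n, 1))) @ query.reshape(1, -1)
    X = concat([values, q_rep], axis=1)  # (n, 2d)
    h = (X @ params.params[f"{head}.W1"] + params.params[f"{head}.b1"]).relu()
    logits = (h @ params.params[f"{head}.W2"]).reshape(n)
    lse = logsumexp(logits.reshape(1, n), axis=1)
    alpha = (logits - Var(np.ones(n)) * lse).exp()  # (n,)
    return alpha.reshape(1, n) @ values


def attention_aggregate(query, neighbors, params: AttentionParams, head: str = "pp"):
    """Aggregate neighbour values for one query embedding.

    `neighbors` is a list of (vector, relation_norm_score_or_None); for the
    pocket-ligand head each value is Phi([ligand | relation embedding]).
    An empty neighbour list falls back to the query itself so downstream
    refinement degrades to the identity.
    """
    q = np.asarray(query, dtype=float).ravel()
    if len(neighbors) == 0:
        return q.copy()
    vals = []
    for vec, rel in neighbors:
        v = Var(np.asarray(vec, dtype=float).reshape(1, -1))
        if head == "pl":
            r = relation_bin(rel if rel is not None else 0.5)
            onehot = np.zeros((1, N_RELATION_BINS))
            onehot[0, r] = 1.0
            rel_emb = Var(onehot) @ params.params["relation.table"]
            x = concat([v, rel_emb], axis=1)
            h = (x @ params.params["phi.W0"] + params.params["phi.b0"]).relu()
            v = h @ params.params["phi.W1"] + params.params["phi.b1"]
        vals.append(v)
    V = concat(vals, axis=0)
    out = _attention(Var(q), V, params, head)
    return out.value.ravel()


def attention_weights(query, values: np.ndarray, params: AttentionParams, head: str = "pp"):
    """Normalized attention weights only (diagnostic surface)."""
    q = Var(np.asarray(query, dtype=float).ravel())
    V = Var(np.atleast_2d(np.asarray(values, dtype=float)))
    n = V.shape[0]
    q_rep = Var(np.ones((n, 1))) @ q.reshape(1, -1)
    X = concat([V, q_rep], axis=1)
    h = (X @ params.params[f"{head}.W1"] + params.params[f"{head}.b1"]).relu()
    logits = (h @ params.params[f"{head}.W2"]).value.ravel()
    w = np.exp(logits - logits.max())
    return w / w.sum()


@dataclass
class RefineParams:
    """Convex-combination coefficients recovered from the simplex logits."""

    gamma1: float
    gamma2: float

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "RefineParams":
        z = np.exp(logits - logits.max())
        z /= z.sum()
        return cls(gamma1=float(z[0]), gamma2=float(z[1]))


def _gamma_var(params: AttentionParams):
    logits = params.params["gamma.logits"].reshape(1, 3)
    lse = logsumexp(logits, axis=1)
    g = (logits - Var(np.ones((1, 3))) * lse).exp()
    return g  # (1,3) Var summing to 1


def refine_pocket_var(
    pocket_id: str,
    p_emb: Var,
    graph: nx.DiGraph,
    pocket_embs: dict,
    ligand_embs: dict,
    params: AttentionParams,
) -> Var:
    """Differentiable refinement p* = g1*p_l + g2*p_p + (1-g1-g2)*p."""
    d = params.d

    pp_neighbors = [
        i
        for i, _, dat in graph.in_edges(pocket_id, data=True)
        if dat.get("kind") == "pp" and i in pocket_embs
    ] if pocket_id in graph else []
    if pp_neighbors:
        V = Var(np.stack([np.asarray(pocket_embs[i], dtype=float) for i in pp_neighbors]))
        p_p = _attention(p_emb.reshape(d), V, params, "pp")
    else:
        p_p = p_emb.reshape(1, d)

    two_hop = (
        {
            j: r
            for j, r in two_hop_ligand_neighbors(graph, pocket_id).items()
            if j in ligand_embs
        }
        if pocket_id in graph
        else {}
    )
    if two_hop:
        vals = []
        for j, rel in sorted(two_hop.items()):
            v = Var(np.asarray(ligand_embs[j], dtype=float).reshape(1, -1))
            onehot = np.zeros((1, N_RELATION_BINS))
            onehot[0, relation_bin(rel)] = 1.0
            rel_emb = Var(onehot) @ params.params["relation.table"]
            x = concat([v, rel_emb], axis=1)
            h = (x @ params.params["phi.W0"] + params.params["phi.b0"]).relu()
            vals.append(h @ params.params["phi.W1"] + params.params["phi.b1"])
        p_l = _attention(p_emb.reshape(d), concat(vals, axis=0), params, "pl")
    else:
        p_l = p_emb.reshape(1, d)

    g = _gamma_var(params)
    g1 = (g * Var(np.array([[1.0, 0.0, 0.0]]))).sum()
    g2 = (g * Var(np.array([[0.0, 1.0, 0.0]]))).sum()
    one = Var(1.0)
    return (
        p_l * g1.reshape(1, 1)
        + p_p * g2.reshape(1, 1)
        + p_emb.reshape(1, d) * (one - g1 - g2).reshape(1, 1)
    )


def refine_pocket(
    pocket_id: str,
    p_emb: np.ndarray,
    graph: nx.DiGraph | None,
    pocket_embs: dict,
    ligand_embs: dict,
    params: AttentionParams,
) -> np.ndarray:
    """Numpy-facing refinement; graph=None or an empty graph is the identity."""
    if graph is None or graph.number_of_nodes() == 0:
        return np.asarray(p_emb, dtype=float).ravel().copy()
    out = refine_pocket_var(
        pocket_id, Var(np.asarray(p_emb, dtype=float).reshape(1, -1)),
        graph, pocket_embs, ligand_embs, params,
    )
    return out.value.ravel()


def train_hgnn(
    graph: nx.DiGraph,
    pocket_embs: dict,
    ligand_embs: dict,
    params: AttentionParams,
    steps: int = 200,
    lr: float = 0.02,
    tau: float = 0.07,
    seed: int = 0,
    n_negatives: int = 32,
    query_noise: float = 0.5,
) -> list:
    """Train the refinement parameters with encoders frozen.

    Each step treats one pocket as a cold-start query: its embedding —
    perturbed by Gaussian noise of `query_noise` times the mean embedding
    norm, emulating an unseen pocket variant — is refined through the graph
    and asked to retrieve its own active ligands (softmax cross-entropy
    against sampled negatives).  The query's own ligand edges never enter
    its refinement (they sit downstream of it), so the target is not
    leaked.  Returns the per-step loss trajectory.
    """
    rng = np.random.default_rng(seed)
    lig_ids = sorted(ligand_embs)
    candidates = []
    for pid in pocket_embs:
        if pid not in graph:
            continue
        has_pp = any(
            d.get("kind") == "pp" for _, _, d in graph.in_edges(pid, data=True)
        )
        actives = [
            j
            for j, _, d in graph.in_edges(pid, data=True)
            if d.get("kind") == "lp" and j in ligand_embs
        ]
        if has_pp and actives:
            candidates.append((pid, actives))
    if not candidates:
        logger.warning("no trainable pockets in graph; refinement left at init")
        return []

    opt = Adam(params.trainable(), lr=lr)
    log = []
    L_all = np.stack([np.asarray(ligand_embs[j], dtype=float) for j in lig_ids])
    L_all = L_all / np.linalg.norm(L_all, axis=1, keepdims=True)
    index_of = {j: i for i, j in enumerate(lig_ids)}
    mean_norm = float(
        np.mean([np.linalg.norm(v) for v in pocket_embs.values()])
    )
    for step in range(steps):
        pid, actives = candidates[int(rng.integers(len(candidates)))]
        target = actives[int(rng.integers(len(actives)))]
        neg = rng.choice(len(lig_ids), size=min(n_negatives, len(lig_ids)), replace=False)
        cols = np.unique(np.concatenate([[index_of[target]], neg]))
        tpos = int(np.where(cols == index_of[target])[0][0])

        q = np.asarray(pocket_embs[pid], dtype=float).reshape(1, -1).copy()
        if query_noise > 0:
            q = q + query_noise * mean_norm * rng.normal(size=q.shape) / np.sqrt(
                q.shape[1]
            )
        p_star = refine_pocket_var(
            pid, Var(q), graph, pocket_embs, ligand_embs, params,
        )
        norm = ((p_star * p_star).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        p_hat = p_star / norm
        scores = (p_hat @ Var(L_all[cols].T)) * (1.0 / tau)  # (1, k)
        loss = logsumexp(scores, axis=1).sum() - (
            scores * Var(np.eye(1, len(cols), tpos))
        ).sum()
        for v in params.trainable().values():
            v.grad = None
        loss.backward()
        opt.step()
        log.append(float(loss.value))
    return log


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_graph(graph: nx.DiGraph, path):
    """Edge-list TSVs (one per edge kind) + JSON header, deterministic order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "n_nodes": graph.number_of_nodes(),
        "pockets": sorted(n for n, d in graph.nodes(data=True) if d["kind"] == "pocket"),
        "ligands": sorted(n for n, d in graph.nodes(data=True) if d["kind"] == "ligand"),
    }
    (path / "graph.json").write_text(json.dumps(header, indent=1, sort_keys=True))
    with open(path / "edges_lp.tsv", "w") as fh:
        fh.write("ligand\tpocket\n")
        for u, v, d in sorted(graph.edges(data=True)):
            if d.get("kind") == "lp":
                fh.write(f"{u}\t{v}\n")
    with open(path / "edges_pp.tsv", "w") as fh:
        fh.write("source\ttarget\tscore\tnorm_score\n")
        for u, v, d in sorted(graph.edges(data=True)):
            if d.get("kind") == "pp":
                fh.write(f"{u}\t{v}\t{d['score']:.17g}\t{d['norm_score']:.17g}\n")


def load_graph(path) -> nx.DiGraph:
    path = Path(path)
    header = json.loads((path / "graph.json").read_text())
    g = nx.DiGraph()
    for p in header["pockets"]:
        g.add_node(p, kind="pocket")
    for l in header["ligands"]:
        g.add_node(l, kind="ligand")
    with open(path / "edges_lp.tsv") as fh:
        next(fh)
        for line in fh:
            u, v = line.rstrip("\n").split("\t")
            g.add_edge(u, v, kind="lp")
    with open(path / "edges_pp.tsv") as fh:
        next(fh)
        for line in fh:
            u, v, s, ns = line.rstrip("\n").split("\t")
            g.add_edge(u, v, kind="pp", score=float(s), norm_score=float(ns))
    return g
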