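"""Model/Results surface for the shared pocket-ligand embedding.

`PocketLigandModel` is built from an :class:`AssayCollection`; `fit()` runs
the pre-training loop (combined ranking + contrastive objective over
assay-sampled batches, one pocket variant per assay per step) and returns a
:class:`PocketLigandResults` carrying the trained encoder parameters, the
loss trajectory and diagnostics.  Screening, few-shot fine-tuning and
masking-based importance hang off the results object.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Adam, Var
from .data_model import (
    Activity,
    Assay,
    AssayCollection,
    assay_potencies,
    ingest_assays,
    label_activity,
    rank_ligands,
)
from .encoders import (
    EncoderParams,
    EmbeddingStore,
    encode_var,
    featurize,
    init_encoder_params,
    score_pair,
)
from .hgnn import AttentionParams, refine_pocket
from .metrics import ScreenRanking, correlation_suite
from .objectives import (
    AssayBatchItem,
    ContractError,
    RankedAssayBatch,
    build_negative_mask,
    combined_loss,
    ranking_loss,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Pre-training settings; every run is seeded."""

    seed: int
    steps: int = 300
    batch_assays: int = 8
    ligands_per_assay: int = 10
    lr: float = 0.05
    tau_rank: float = 0.07
    tau_contrast: float = 0.07
    loss_weights: tuple = (1.0, 1.0)  # (contrastive, ranking)
    eval_every: int = 50

    def __post_init__(self):
        if min(self.steps, self.batch_assays, self.ligands_per_assay) <= 0:
            raise ConfigError("steps, batch_assays, ligands_per_assay must be positive")
        if self.lr <= 0 or self.tau_rank <= 0 or self.tau_contrast <= 0:
            raise ConfigError("lr and temperatures must be positive")


class PocketLigandModel:
    """Shared-embedding affinity model over an assay collection."""

    def __init__(
        self,
        collection: AssayCollection,
        d: int = 16,
        hidden: int | None = None,
        labels: dict | None = None,
        init_seed: int = 0,
    ):
        self.collection = collection
        self.labels = labels if labels is not None else label_activity(collection)
        self._lig_features = {
            lid: featurize(rec, "ligand") for lid, rec in collection.ligands.items()
        }
        self._poc_features = {
            pid: featurize(rec, "pocket") for pid, rec in collection.pockets.items()
        }
        lig_dim = len(next(iter(self._lig_features.values())))
        poc_dim = len(next(iter(self._poc_features.values())))
        self.encoder_spec = dict(
            ligand_dim=lig_dim, pocket_dim=poc_dim, d=d, hidden=hidden
        )
        self.init_seed = init_seed
        self._rankable = [
            a for a in collection.assays.values() if len(a) >= 2
        ]
        if not self._rankable:
            raise ConfigError("collection has no assay with >= 2 ligands")

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "PocketLigandModel":
        return cls(ingest_assays(df), **kwargs)

    # ---- batch assembly --------------------------------------------------
    def _make_item(
        self,
        assay: Assay,
        ep: EncoderParams,
        rng: np.random.Generator,
        max_ligands: int | None = None,
        ligand_subset: list | None = None,
        pocket_id: str | None = None,
    ) -> AssayBatchItem:
        ranking = rank_ligands(assay)
        order = [l for l in ranking.order if ligand_subset is None or l in ligand_subset]
        if max_ligands is not None and len(order) > max_ligands:
            keep = set(
                np.array(order)[
                    rng.choice(len(order), size=max_ligands, replace=False)
                ]
            )
            order = [l for l in order if l in keep]
        pid = pocket_id or assay.pocket_ids[int(rng.integers(len(assay.pocket_ids)))]
        X_l = np.stack([self._lig_features[l] for l in order])
        X_p = self._poc_features[pid][None, :]
        pot = np.array([ranking.potency[l] for l in order])
        act = np.array(
            [
                self.labels.get((assay.target_group_id, l)) is Activity.ACTIVE
                for l in order
            ]
        )
        return AssayBatchItem(
            assay_id=assay.assay_id,
            target_group_id=assay.target_group_id,
            pocket_emb=encode_var(ep, X_p, "pocket"),
            ligand_embs=encode_var(ep, X_l, "ligand"),
            potency=pot,
            active=act,
            ligand_ids=tuple(order),
            n_ligands_total=len(assay),
        )

    # ---- fitting ---------------------------------------------------------
    def fit(self, config: TrainConfig | None = None, **kwargs) -> "PocketLigandResults":
        cfg = config or TrainConfig(**kwargs)
        rng = np.random.default_rng(cfg.seed)
        ep = init_encoder_params(
            seed=self.init_seed, **self.encoder_spec
        )
        opt = Adam(ep.params, lr=cfg.lr)
        w_c, w_r = cfg.loss_weights
        log = []
        t0 = time.time()
        for step in range(cfg.steps):
            idx = rng.choice(
                len(self._rankable),
                size=min(cfg.batch_assays, len(self._rankable)),
                replace=False,
            )
            items = [
                self._make_item(self._rankable[i], ep, rng, cfg.ligands_per_assay)
                for i in idx
            ]
            batch = RankedAssayBatch(
                items=items, tau_rank=cfg.tau_rank, tau_contrast=cfg.tau_contrast
            )
            mask = build_negative_mask(batch, self.labels)
            from .objectives import contrastive_loss

            lc = contrastive_loss(batch, mask)
            lr_ = ranking_loss(batch)
            loss = lc * w_c + lr_ * w_r
            for v in ep.params.values():
                v.grad = None
            loss.backward()
            opt.step()
            log.append(
                {
                    "step": step,
                    "loss": float(loss.value),
                    "contrastive": float(lc.value),
                    "ranking": float(lr_.value),
                }
            )
        return PocketLigandResults(
            model=self, params=ep, config=cfg, training_log=log,
            wall_time=time.time() - t0,
        )


@dataclass
class PocketLigandResults:
    """Fitted encoders plus diagnostics; all inference goes through here."""

    model: PocketLigandModel
    params: EncoderParams
    config: TrainConfig
    training_log: list
    wall_time: float = 0.0
    _store: EmbeddingStore | None = field(default=None, repr=False)

    # ---- embeddings ------------------------------------------------------
    def embed(self, record: dict, side: str) -> np.ndarray:
        fv = featurize(record, side)
        return encode_var(self.params, fv[None, :], side).value[0]

    def embedding_store(self) -> EmbeddingStore:
        if self._store is None or self._store.params_hash != self.params.params_hash():
            self._store = EmbeddingStore(self.params.params_hash(), self.params.d)
        return self._store

    def _cached_embed(self, record: dict, side: str) -> np.ndarray:
        store = self.embedding_store()
        key = record.get("ligand_id") or record.get("pocket_id")
        if key and key in store:
            return store.get(key)
        vec = self.embed(record, side)
        if key:
            store.put(key, vec)
        return vec

    # ---- screening -------------------------------------------------------
    def screen(
        self,
        pocket_record: dict,
        ligand_records: dict,
        labels: dict | None = None,
        graph=None,
        attention_params: AttentionParams | None = None,
        pocket_embs: dict | None = None,
        ligand_embs: dict | None = None,
    ) -> ScreenRanking:
        """Rank a library by cosine similarity to the (optionally
        graph-refined) query pocket embedding."""
        if not ligand_records:
            raise ContractError("empty screening library")
        p = self.embed(pocket_record, "pocket")
        if graph is not None:
            if attention_params is None:
                raise ContractError("graph refinement needs attention parameters")
            p = refine_pocket(
                pocket_record.get("pocket_id"), p, graph,
                pocket_embs or {}, ligand_embs or {}, attention_params,
            )
        ids = list(ligand_records)
        scores = np.array(
            [score_pair(p, self._cached_embed(ligand_records[l], "ligand")) for l in ids]
        )
        lab = np.array([bool(labels[l]) for l in ids]) if labels else np.zeros(len(ids), bool)
        return ScreenRanking(ligand_ids=ids, scores=scores, labels=lab)

    def predict_scores(self, pocket_record: dict, ligand_records: dict) -> dict:
        p = self.embed(pocket_record, "pocket")
        return {
            l: score_pair(p, self._cached_embed(r, "ligand"))
            for l, r in ligand_records.items()
        }

    # ---- few-shot fine-tuning --------------------------------------------
    def finetune(
        self,
        assay: Assay,
        ligand_records: dict,
        support_ids: list,
        steps: int = 150,
        lr: float = 0.005,
        seed: int = 0,
        pocket_record: dict | None = None,
        anchor: float = 2.0,
    ) -> "PocketLigandResults":
        """Continue optimising the ranking loss on a support subset of one
        assay.  Empty support returns the zero-shot parameters unchanged
        (bit-identical copy).

        `anchor` is the weight of an L2 penalty tying the parameters to
        their pre-trained values, scaled down as the support grows; it
        keeps tiny supports from erasing the pre-trained structure.
        """
        unknown = [l for l in support_ids if l not in set(assay.ligand_ids)]
        if unknown:
            raise ContractError(f"support ligand(s) not in assay: {unknown}")
        ep = self.params.copy()
        out = replace(self, params=ep, training_log=list(self.training_log), _store=None)
        if not support_ids:
            return out
        rng = np.random.default_rng(seed)
        pot = assay_potencies(assay)
        order = sorted(support_ids, key=lambda l: (-pot[l], l))
        X_l = np.stack([featurize(ligand_records[l], "ligand") for l in order])
        prec = pocket_record or {"pocket_id": assay.pocket_ids[0]}
        if "factor" not in prec and "sequence" not in prec:
            prec = self.model.collection.pockets.get(assay.pocket_ids[0], prec)
        X_p = featurize(prec, "pocket")[None, :]
        anchors = {k: v.value.copy() for k, v in ep.params.items()}
        lam = anchor / len(support_ids)
        opt = Adam(ep.params, lr=lr)
        for _ in range(steps):
            item = AssayBatchItem(
                assay_id=assay.assay_id,
                target_group_id=assay.target_group_id,
                pocket_emb=encode_var(ep, X_p, "pocket"),
                ligand_embs=encode_var(ep, X_l, "ligand"),
                potency=np.array([pot[l] for l in order]),
                active=np.zeros(len(order), bool),
                ligand_ids=tuple(order),
                n_ligands_total=len(order),
            )
            batch = RankedAssayBatch(
                items=[item],
                tau_rank=self.config.tau_rank,
                tau_contrast=self.config.tau_contrast,
            )
            loss = ranking_loss(batch)
            for k, v in ep.params.items():
                diff = v - Var(anchors[k])
                loss = loss + (diff * diff).sum() * lam
            for v in ep.params.values():
                v.grad = None
            loss.backward()
            opt.step()
            _ = rng  # seed reserved for stochastic variants
        return out

    # ---- masking-based importance ----------------------------------------
    def importance(self, pocket_record: dict, ligand_record: dict) -> "ImportanceReport":
        """Per-unit score drops from masking one maskable unit at a time.

        Units are ligand atoms (SMILES input) or ligand feature components
        (latent-factor input), and pocket residues (sequence input) or
        pocket feature components.  Masking zeroes the unit's feature
        contributions and re-encodes.
        """
        p_full = self.embed(pocket_record, "pocket")
        l_full = self.embed(ligand_record, "ligand")
        base = score_pair(p_full, l_full)

        lig_deltas = {}
        for name, fv in _masked_ligand_features(ligand_record):
            emb = encode_var(self.params, fv[None, :], "ligand").value[0]
            lig_deltas[name] = base - score_pair(p_full, emb)
        poc_deltas = {}
        for name, rec in _masked_pocket_records(pocket_record):
            emb = self.embed(rec, "pocket")
            poc_deltas[name] = base - score_pair(emb, l_full)
        return ImportanceReport(
            pair=(pocket_record.get("pocket_id", "?"), ligand_record.get("ligand_id", "?")),
            baseline_delta=base - score_pair(p_full, l_full),
            ligand_deltas=lig_deltas,
            pocket_deltas=poc_deltas,
        )

    # ---- diagnostics -----------------------------------------------------
    def heldout_spearman(
        self, assays, ligand_records: dict, pocket_records: dict | None = None
    ) -> float:
        """Mean within-assay Spearman between predicted scores and measured
        potency over held-out assays."""
        pockets = pocket_records or self.model.collection.pockets
        rhos = []
        for a in assays:
            pot = assay_potencies(a)
            prec = pockets.get(a.pocket_ids[0], {"pocket_id": a.pocket_ids[0]})
            scores = self.predict_scores(
                prec, {l: ligand_records[l] for l in a.ligand_ids}
            )
            ids = sorted(pot)
            suite = correlation_suite([scores[l] for l in ids], [pot[l] for l in ids])
            rhos.append(suite["spearman"])
        return float(np.mean(rhos))

    def summary(self) -> str:
        lines = [
            "Pocket-ligand shared-embedding model",
            "=" * 52,
            f"assays:              {len(self.model.collection)}",
            f"ligands:             {len(self.model.collection.ligands)}",
            f"embedding dim d:     {self.params.d}",
            f"encoder:             {'linear' if self.params.hidden is None else f'MLP({self.params.hidden})'}",
            f"steps:               {self.config.steps}",
            f"tau (rank/contrast): {self.config.tau_rank:g} / {self.config.tau_contrast:g}",
        ]
        if self.training_log:
            first, last = self.training_log[0], self.training_log[-1]
            lines += [
                f"initial loss:        {first['loss']:.4f} "
                f"(contrastive {first['contrastive']:.4f}, ranking {first['ranking']:.4f})",
                f"final loss:          {last['loss']:.4f} "
                f"(contrastive {last['contrastive']:.4f}, ranking {last['ranking']:.4f})",
                f"wall time:           {self.wall_time:.1f} s",
            ]
        return "\n".join(lines)


@dataclass
class ImportanceReport:
    """Masking-based importance: score drop per maskable unit."""

    pair: tuple
    baseline_delta: float
    ligand_deltas: dict
    pocket_deltas: dict

    def top_ligand_units(self, k: int = 5):
        return sorted(self.ligand_deltas.items(), key=lambda kv: -kv[1])[:k]

    def top_pocket_units(self, k: int = 5):
        return sorted(self.pocket_deltas.items(), key=lambda kv: -kv[1])[:k]


def _masked_ligand_features(record: dict):
    if record.get("factor") is not None:
        fv = np.asarray(record["factor"], dtype=float)
        for i in range(fv.size):
            out = fv.copy()
            out[i] = 0.0
            yield f"feature_{i}", out
    elif "smiles" in record:
        yield from _masked_atom_fingerprints(record)
    else:
        raise ContractError("ligand record has no maskable representation")


def _masked_atom_fingerprints(record: dict):
    """Per-atom masking for fingerprint ligands: zero the count
    contributions of environments rooted at the masked atom."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    from .encoders import FP_BITS

    mol = Chem.MolFromSmiles(record["smiles"])
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FP_BITS)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    fp = gen.GetCountFingerprint(mol, additionalOutput=ao)
    full = np.zeros(FP_BITS)
    for idx, cnt in fp.GetNonzeroElements().items():
        full[idx] = cnt
    info = ao.GetBitInfoMap()
    for atom in mol.GetAtoms():
        u = atom.GetIdx()
        fv = full.copy()
        for bit, envs in info.items():
            drop = sum(1 for a, _r in envs if a == u)
            if drop:
                fv[bit] = max(0.0, fv[bit] - drop)
        yield f"atom_{u}_{atom.GetSymbol()}", fv


def _masked_pocket_records(record: dict):
    if record.get("factor") is not None:
        fv = np.asarray(record["factor"], dtype=float)
        for i in range(fv.size):
            out = dict(record)
            masked = fv.copy()
            masked[i] = 0.0
            out["factor"] = masked
            yield f"feature_{i}", out
    elif record.get("sequence"):
        seq = record["sequence"]
        for i in range(len(seq)):
            out = dict(record)
            out["sequence"] = seq[:i] + seq[i + 1 :]
            yield f"residue_{i}_{seq[i]}", out
    else:
        raise ContractError("pocket record has no maskable representation")


# ---------------------------------------------------------------------------
# spec-level procedural aliases
# ---------------------------------------------------------------------------

def pretrain(collection, labels=None, d=16, hidden=None, config=None, **kwargs):
    """Procedural entry: build the model and fit it."""
    model = PocketLigandModel(collection, d=d, hidden=hidden, labels=labels)
    return model.fit(config, **kwargs)


def finetune(results: PocketLigandResults, assay, ligand_records, support_ids, **kwargs):
    return results.finetune(assay, ligand_records, support_ids, **kwargs)


def screen(results: PocketLigandResults, pocket_record, ligand_records, **kwargs):
    return results.screen(pocket_record, ligand_records, **kwargs)


def importance_scores(results: PocketLigandResults, pocket_record, ligand_record):
    return results.importance(pocket_record, ligand_record)
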