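"""Pluggable pocket/ligand encoders over a shared embedding space.

Two independent trainable maps (one per side) send feature vectors to a
common dimension ``d``; all downstream scoring is cosine similarity in that
space.  The reference encoders are deliberately lightweight — linear maps
or small MLPs over fingerprint / composition / latent-factor features — and
hide behind a narrow contract so heavier encoders can be plugged in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Var

FP_BITS = 512  # hashed Morgan-count fingerprint length for real ligands
KMER_BITS = 64  # hashed 2-mer composition length for pocket sequences


class InputError(ValueError):
    pass


class ContractError(ValueError):
    pass


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _smiles_fingerprint(smiles: str, ligand_id: str) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES for ligand {ligand_id!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FP_BITS)
    fp = gen.GetCountFingerprint(mol)
    vec = np.zeros(FP_BITS)
    for idx, cnt in fp.GetNonzeroElements().items():
        vec[idx] = cnt
    return vec


def _sequence_features(seq: str) -> np.ndarray:
    """Residue composition (20) + hashed 2-mer counts + log-length."""
    from .data_model import ValidationError

    aa = "ACDEFGHIKLMNPQRSTVWY"
    if not seq:
        raise ValidationError("empty pocket sequence")
    comp = np.zeros(20)
    idx = {a: i for i, a in enumerate(aa)}
    for ch in seq:
        if ch in idx:
            comp[idx[ch]] += 1
    comp /= len(seq)
    kmer = np.zeros(KMER_BITS)
    for i in range(len(seq) - 1):
        h = int(hashlib.blake2s(seq[i : i + 2].encode(), digest_size=4).hexdigest(), 16)
        kmer[h % KMER_BITS] += 1
    if kmer.sum():
        kmer /= kmer.sum()
    return np.concatenate([comp, kmer, [np.log(len(seq))]])


def featurize(record: dict, side: str) -> np.ndarray:
    """Deterministic feature vector for a ligand or pocket record.

    Synthetic records carry a latent ``factor`` (pass-through mode); real
    ligands carry ``smiles`` (hashed Morgan counts) and real pockets a
    ``sequence`` or residue list (composition + 2-mer features).
    """
    if record.get("factor") is not None:
        return np.asarray(record["factor"], dtype=float).copy()
    if side == "ligand":
        if "smiles" in record:
            return _smiles_fingerprint(record["smiles"], record.get("ligand_id", "?"))
        raise InputError(f"ligand record not featurizable: {sorted(record)}")
    if "sequence" in record and record["sequence"]:
        return _sequence_features(record["sequence"])
    if "residues" in record:
        return _sequence_features("".join(r[2] for r in record["residues"]))
    raise InputError(f"pocket record not featurizable: {sorted(record)}")


def feature_matrix(records: list, side: str) -> np.ndarray:
    return np.stack([featurize(r, side) for r in records])


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

@dataclass
class EncoderParams:
    """Trainable weights of the two encoders (independent maps, shared d)."""

    ligand_dim: int
    pocket_dim: int
    d: int
    hidden: int | None  # None -> linear encoders
    params: dict = field(default_factory=dict)  # name -> Var

    def copy(self) -> "EncoderParams":
        return EncoderParams(
            ligand_dim=self.ligand_dim,
            pocket_dim=self.pocket_dim,
            d=self.d,
            hidden=self.hidden,
            params={k: Var(v.value.copy()) for k, v in self.params.items()},
        )

    def params_hash(self) -> str:
        h = hashlib.sha256()
        h.update(
            json.dumps(
                [self.ligand_dim, self.pocket_dim, self.d, self.hidden]
            ).encode()
        )
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k].value).tobytes())
        return h.hexdigest()[:16]


def init_encoder_params(
    ligand_dim: int,
    pocket_dim: int,
    d: int = 128,
    hidden: int | None = 256,
    seed: int = 0,
) -> EncoderParams:
    """Glorot-style init; linear encoders with matching dims start near the
    identity so the latent pass-through mode begins close to the oracle."""
    rng = np.random.default_rng(seed)
    params = {}

    def linear(name, n_in, n_out):
        scale = np.sqrt(2.0 / (n_in + n_out))
        w = rng.normal(0.0, scale, size=(n_in, n_out))
        if hidden is None and n_in == n_out:
            w = np.eye(n_in) + 0.05 * w
        params[f"{name}.W"] = Var(w)
        params[f"{name}.b"] = Var(np.zeros((1, n_out)))

    for side, n_in in (("lig", ligand_dim), ("poc", pocket_dim)):
        if hidden is None:
            linear(f"{side}0", n_in, d)
        else:
            linear(f"{side}0", n_in, hidden)
            linear(f"{side}1", hidden, d)
    return EncoderParams(
        ligand_dim=ligand_dim, pocket_dim=pocket_dim, d=d, hidden=hidden, params=params
    )


def encode_var(ep: EncoderParams, X, side: str) -> Var:
    """Differentiable encoder forward: (n, in_dim) -> (n, d)."""
    if side not in ("pocket", "ligand"):
        raise ContractError(f"side must be 'pocket' or 'ligand', got {side!r}")
    prefix = "poc" if side == "pocket" else "lig"
    X = X if isinstance(X, Var) else Var(np.atleast_2d(np.asarray(X, dtype=float)))
    want = ep.pocket_dim if side == "pocket" else ep.ligand_dim
    if X.shape[1] != want:
        raise ContractError(
            f"{side} feature dim {X.shape[1]} != encoder input dim {want}"
        )
    h = X @ ep.params[f"{prefix}0.W"] + ep.params[f"{prefix}0.b"]
    if ep.hidden is not None:
        h = h.relu() @ ep.params[f"{prefix}1.W"] + ep.params[f"{prefix}1.b"]
    return h


@dataclass(frozen=True)
class Embedding:
    entity_id: str
    vector: np.ndarray


def encode(ep: EncoderParams, fv: np.ndarray, side: str, entity_id: str = "") -> Embedding:
    out = encode_var(ep, np.atleast_2d(fv), side).value[0]
    return Embedding(entity_id=entity_id, vector=out)


def normalize_rows_var(E: Var, eps: float = 1e-12) -> Var:
    # eps inside the sqrt keeps the gradient finite at the origin
    norm = ((E * E).sum(axis=1, keepdims=True) + eps).sqrt()
    return E / norm


def score_pair(p, l) -> float:
    """Cosine similarity between a pocket and a ligand embedding."""
    pv = p.vector if isinstance(p, Embedding) else np.asarray(p, dtype=float)
    lv = l.vector if isinstance(l, Embedding) else np.asarray(l, dtype=float)
    np_, nl = np.linalg.norm(pv), np.linalg.norm(lv)
    if np_ == 0 or nl == 0:
        raise ContractError("cosine similarity undefined for a zero vector")
    return float(pv @ lv / (np_ * nl))


# ---------------------------------------------------------------------------
# embedding store
# ---------------------------------------------------------------------------

class StaleCacheError(RuntimeError):
    pass


class EmbeddingStore:
    """Disk cache of encoded vectors keyed by entity id, guarded by the
    encoder parameter hash (reading under a different model is an error)."""

    def __init__(self, params_hash: str, d: int):
        self.params_hash = params_hash
        self.d = d
        self._vectors: dict[str, np.ndarray] = {}

    def put(self, entity_id: str, vector: np.ndarray):
        self._vectors[entity_id] = np.asarray(vector, dtype=np.float64)

    def get(self, entity_id: str) -> np.ndarray:
        return self._vectors[entity_id]

    def __contains__(self, entity_id):
        return entity_id in self._vectors

    def __len__(self):
        return len(self._vectors)

    def save(self, path):
        path = Path(path)
        ids = sorted(self._vectors)
        arr = (
            np.stack([self._vectors[i] for i in ids])
            if ids
            else np.zeros((0, self.d))
        )
        np.save(path.with_suffix(".npy"), arr)
        sidecar = {"entity_ids": ids, "d": self.d, "params_hash": self.params_hash}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=0, sort_keys=True))

    @classmethod
    def load(cls, path, expected_params_hash: str | None = None) -> "EmbeddingStore":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if (
            expected_params_hash is not None
            and sidecar["params_hash"] != expected_params_hash
        ):
            raise StaleCacheError(
                f"embedding store written under params {sidecar['params_hash']}, "
                f"expected {expected_params_hash}"
            )
        store = cls(params_hash=sidecar["params_hash"], d=sidecar["d"])
        arr = np.load(path.with_suffix(".npy"))
        for i, eid in enumerate(sidecar["entity_ids"]):
            store._vectors[eid] = arr[i]
        return store
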