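"""Synthetic affinity landscapes with the statistical structure the model
assumes.

The ground truth is a noisy low-rank bilinear form: each pocket and each
ligand carries a latent factor, and true potency (p-scale) is an affine
function of their inner product plus Gaussian noise.  Ligand factors are
unit-normalised so that the landscape is realisable by a cosine-similarity
scoring model.  On top of the landscape the module manufactures the data
shapes the workflows consume: assays with assay-specific monotone unit
transforms, screening libraries at a fixed active:inactive ratio,
congeneric (shared-scaffold) ligand series, and active-learning pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .data_model import (
    ACTIVITY_THRESHOLD_MOLAR,
    Assay,
    AssayCollection,
    AffinityMeasurement,
    Unit,
)

ACTIVE_BOUNDARY_P = 5.0  # p-scale potency at the 10 uM activity boundary

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class WorldConfig:
    n_pockets: int = 20
    n_ligands: int = 300
    latent_dim: int = 8
    n_scaffold_clusters: int = 10
    noise_sd: float = 0.0  # p-scale units, folded into the oracle
    active_fraction_target: float = 0.3
    seed: int = 0
    n_pocket_variants: int = 3
    variant_sd: float = 0.05
    potency_gain: float = 2.0  # p-units per unit of latent inner product
    sequence_length: int = 40
    variant_mutations: int = 2

    def __post_init__(self):
        if min(self.n_pockets, self.n_ligands, self.latent_dim) <= 0:
            raise ConfigError("counts must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 < self.active_fraction_target < 1.0:
            raise ConfigError("active_fraction_target must lie in (0, 1)")


def _unit_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


@dataclass
class SyntheticWorld:
    """Latent factors, scaffold clusters and the deterministic affinity oracle."""

    config: WorldConfig
    pocket_ids: list
    ligand_ids: list
    pocket_factors: np.ndarray  # (n_pockets, d), parent pockets
    ligand_factors: np.ndarray  # (n_ligands, d), unit rows
    scaffold_of: dict  # ligand_id -> cluster id
    scaffold_centroids: np.ndarray
    pocket_variants: dict  # pocket_id -> list of variant ids
    variant_factors: dict  # variant id -> factor
    pocket_sequences: dict  # pocket id and variant id -> AA string
    intercept: float
    noise: np.ndarray  # (n_pockets, n_ligands), frozen at generation
    _pocket_index: dict = field(default_factory=dict)
    _ligand_index: dict = field(default_factory=dict)
    # ligands minted later by library/series generators: id -> (factor, {pid: potency})
    _extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self._pocket_index = {p: i for i, p in enumerate(self.pocket_ids)}
        self._ligand_index = {l: i for i, l in enumerate(self.ligand_ids)}

    # ---- oracle ----------------------------------------------------------
    def parent_of(self, pocket_or_variant: str) -> str:
        return pocket_or_variant.split("::")[0]

    def latent_inner(self, pocket_id: str, ligand_id: str) -> float:
        pi = self._pocket_index[self.parent_of(pocket_id)]
        li = self._ligand_index[ligand_id]
        return float(self.pocket_factors[pi] @ self.ligand_factors[li])

    def true_potency(self, pocket_id: str, ligand_id: str) -> float:
        """Deterministic ground-truth potency on the p-scale."""
        parent = self.parent_of(pocket_id)
        if ligand_id in self._extra:
            return self._extra[ligand_id][1][parent]
        pi = self._pocket_index[parent]
        li = self._ligand_index[ligand_id]
        base = self.intercept + self.config.potency_gain * (
            self.pocket_factors[pi] @ self.ligand_factors[li]
        )
        return float(base + self.noise[pi, li])

    def ligand_factor(self, ligand_id: str) -> np.ndarray:
        if ligand_id in self._extra:
            return self._extra[ligand_id][0]
        return self.ligand_factors[self._ligand_index[ligand_id]]

    def pocket_factor(self, pocket_or_variant: str) -> np.ndarray:
        if pocket_or_variant in self.variant_factors:
            return self.variant_factors[pocket_or_variant]
        return self.pocket_factors[self._pocket_index[pocket_or_variant]]

    def ligand_record(self, ligand_id: str) -> dict:
        return {
            "ligand_id": ligand_id,
            "factor": self.ligand_factor(ligand_id),
            "scaffold": self.scaffold_of.get(ligand_id),
        }

    def pocket_record(self, pocket_id: str) -> dict:
        return {
            "pocket_id": pocket_id,
            "factor": self.pocket_factor(pocket_id),
            "parent": self.parent_of(pocket_id),
            "sequence": self.pocket_sequences.get(pocket_id),
        }

    def assign_scaffold(self, factor: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(self.scaffold_centroids - factor, axis=1)))

    def _mint_ligand(self, prefix: str, factor: np.ndarray, rng) -> str:
        lid = f"{prefix}{len(self._extra):06d}"
        pots = {}
        for pid, pf in zip(self.pocket_ids, self.pocket_factors):
            base = self.intercept + self.config.potency_gain * float(pf @ factor)
            pots[pid] = base + (
                rng.normal(0.0, self.config.noise_sd) if self.config.noise_sd else 0.0
            )
        self._extra[lid] = (factor, pots)
        self.scaffold_of[lid] = self.assign_scaffold(factor)
        return lid


def _mutate(seq: str, n_mut: int, rng) -> str:
    s = list(seq)
    for pos in rng.choice(len(s), size=min(n_mut, len(s)), replace=False):
        s[pos] = AA20[rng.integers(len(AA20))]
    return "".join(s)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a reproducible synthetic world from its config.

    The affine intercept is calibrated empirically so that the configured
    fraction of all (parent pocket, ligand) pairs sits above the 10 uM
    activity boundary.
    """
    rng = np.random.default_rng(config.seed)
    d = config.latent_dim
    pf = rng.normal(size=(config.n_pockets, d))
    pf = _unit_rows(pf) * np.sqrt(d)  # fixed norm so pockets are exchangeable
    lf = _unit_rows(rng.normal(size=(config.n_ligands, d)))

    ip = pf @ lf.T  # (n_pockets, n_ligands)
    q = np.quantile(config.potency_gain * ip, 1.0 - config.active_fraction_target)
    intercept = ACTIVE_BOUNDARY_P - q

    noise = (
        rng.normal(0.0, config.noise_sd, size=ip.shape)
        if config.noise_sd > 0
        else np.zeros_like(ip)
    )

    pocket_ids = [f"P{i:03d}" for i in range(config.n_pockets)]
    ligand_ids = [f"L{i:05d}" for i in range(config.n_ligands)]

    k = min(config.n_scaffold_clusters, config.n_ligands)
    km = KMeans(n_clusters=k, n_init=1, random_state=config.seed).fit(lf)
    scaffold_of = {lid: int(c) for lid, c in zip(ligand_ids, km.labels_)}

    variants, vfactors, sequences = {}, {}, {}
    for i, pid in enumerate(pocket_ids):
        seq = "".join(AA20[j] for j in rng.integers(len(AA20), size=config.sequence_length))
        sequences[pid] = seq
        ids = []
        for v in range(config.n_pocket_variants):
            vid = f"{pid}::v{v}"
            vfactors[vid] = pf[i] + rng.normal(0.0, config.variant_sd, size=d)
            sequences[vid] = _mutate(seq, config.variant_mutations, rng)
            ids.append(vid)
        variants[pid] = ids

    return SyntheticWorld(
        config=config,
        pocket_ids=pocket_ids,
        ligand_ids=ligand_ids,
        pocket_factors=pf,
        ligand_factors=lf,
        scaffold_of=scaffold_of,
        scaffold_centroids=km.cluster_centers_,
        pocket_variants=variants,
        variant_factors=vfactors,
        pocket_sequences=sequences,
        intercept=float(intercept),
        noise=noise,
    )


def _percent_transform(potencies: np.ndarray, rng) -> np.ndarray:
    """Assay-specific strictly increasing piecewise-linear map onto [0, 100]."""
    lo, hi = potencies.min() - 1.0, potencies.max() + 1.0
    knots_x = np.linspace(lo, hi, 6)
    gaps = rng.uniform(0.2, 1.0, size=5)
    knots_y = np.concatenate([[0.0], np.cumsum(gaps)]) / gaps.sum() * 100.0
    return np.interp(potencies, knots_x, knots_y)


def _to_reported(potencies: np.ndarray, unit: Unit, rng) -> np.ndarray:
    if unit is Unit.PERCENT:
        return _percent_transform(potencies, rng)
    if unit is Unit.UG_ML:
        return 10.0 ** (3.0 - potencies)  # p-scale on g/L, reported in ug/mL
    # molar classes: value_in_unit = 10**(-p) / to_base
    return 10.0 ** (-potencies) / unit.to_base


def sample_assays(
    world: SyntheticWorld,
    n_assays: int,
    ligands_per_assay: int,
    unit_mix: dict | None = None,
    seed: int = 0,
    measurement_noise_sd: float = 0.0,
) -> AssayCollection:
    """Manufacture an assay collection: each assay draws one parent pocket,
    samples ligands, and reports oracle potency (plus optional measurement
    noise) through its unit's strictly monotone transform."""
    cfg = world.config
    if ligands_per_assay > cfg.n_ligands:
        raise ConfigError("ligands_per_assay exceeds world ligand count")
    unit_mix = unit_mix or {Unit.NM: 1.0}
    units, probs = zip(*sorted(unit_mix.items(), key=lambda kv: kv[0].label))
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    coll = AssayCollection()
    for a in range(n_assays):
        pid = world.pocket_ids[int(rng.integers(cfg.n_pockets))]
        lids = [
            world.ligand_ids[i]
            for i in rng.choice(cfg.n_ligands, size=ligands_per_assay, replace=False)
        ]
        unit = units[int(rng.choice(len(units), p=probs))]
        pot = np.array([world.true_potency(pid, l) for l in lids])
        if measurement_noise_sd > 0:
            pot = pot + rng.normal(0.0, measurement_noise_sd, size=pot.shape)
        values = _to_reported(pot, unit, rng)
        n_var = int(rng.integers(1, len(world.pocket_variants[pid]) + 1))
        pocket_ids = tuple(world.pocket_variants[pid][:n_var])
        assay_id = f"A{a:04d}"
        coll.assays[assay_id] = Assay(
            assay_id=assay_id,
            target_group_id=pid,  # one protein per parent pocket
            pocket_ids=pocket_ids,
            measurements=tuple(
                AffinityMeasurement(ligand_id=l, value=float(v), unit=unit)
                for l, v in zip(lids, values)
            ),
            unit=unit,
        )
        for l in lids:
            coll.ligands.setdefault(l, world.ligand_record(l))
        for p in pocket_ids:
            coll.pockets.setdefault(p, world.pocket_record(p))
    return coll


@dataclass
class ScreeningLibrary:
    """A labeled ligand list for one pocket at a fixed active:inactive ratio."""

    pocket_id: str
    ligand_records: dict  # ligand_id -> record with "factor"
    labels: dict  # ligand_id -> bool (active)
    true_potency: dict  # ligand_id -> p-scale potency

    @property
    def ligand_ids(self):
        return list(self.ligand_records)

    def __len__(self):
        return len(self.ligand_records)


def make_screening_library(
    world: SyntheticWorld,
    pocket_id: str,
    n_actives: int,
    ratio: int,
    seed: int = 0,
    scaffold_disjoint_decoys: bool = False,
    max_draws: int = 2_000_000,
) -> ScreeningLibrary:
    """Mint fresh ligands until `n_actives` above and `n_actives*ratio`
    below the activity boundary are collected for this pocket.

    With `scaffold_disjoint_decoys`, decoys are rejected unless their
    scaffold cluster is absent among the actives' clusters.
    """
    rng = np.random.default_rng(seed)
    parent = world.parent_of(pocket_id)
    d = world.config.latent_dim
    actives, decoys = [], []
    n_decoys = n_actives * ratio

    # first pass: collect actives so decoy scaffold exclusion is well defined
    draws = 0
    while len(actives) < n_actives:
        if draws >= max_draws:
            raise GenerationError("could not generate enough active ligands")
        f = _unit_rows(rng.normal(size=d))
        lid = world._mint_ligand("S", f, rng)
        draws += 1
        if world.true_potency(parent, lid) >= ACTIVE_BOUNDARY_P:
            actives.append(lid)
        else:
            del world._extra[lid], world.scaffold_of[lid]
    active_clusters = {world.scaffold_of[l] for l in actives}
    while len(decoys) < n_decoys:
        if draws >= max_draws:
            raise GenerationError("could not generate enough decoy ligands")
        f = _unit_rows(rng.normal(size=d))
        lid = world._mint_ligand("S", f, rng)
        draws += 1
        ok = world.true_potency(parent, lid) < ACTIVE_BOUNDARY_P
        if ok and scaffold_disjoint_decoys:
            ok = world.scaffold_of[lid] not in active_clusters
        if ok:
            decoys.append(lid)
        else:
            del world._extra[lid], world.scaffold_of[lid]

    lids = actives + decoys
    return ScreeningLibrary(
        pocket_id=pocket_id,
        ligand_records={l: world.ligand_record(l) for l in lids},
        labels={l: l in set(actives) for l in lids},
        true_potency={l: world.true_potency(parent, l) for l in lids},
    )


def make_congeneric_series(
    world: SyntheticWorld,
    pocket_id: str,
    n_ligands: int = 29,
    seed: int = 0,
    perturbation: float = 0.08,
) -> tuple[Assay, dict]:
    """A hit-to-lead series: `n_ligands` close analogues of one parent
    ligand (one scaffold cluster), measured in one nM-unit assay against
    `pocket_id`.  Returns (assay, ligand_records)."""
    if n_ligands < 2:
        raise ConfigError("a congeneric series needs at least 2 ligands")
    rng = np.random.default_rng(seed)
    parent_pocket = world.parent_of(pocket_id)
    d = world.config.latent_dim

    # parent hit: resample until it is comfortably active for this pocket
    for _ in range(200_000):
        parent_f = _unit_rows(rng.normal(size=d))
        pf = world.pocket_factor(parent_pocket)
        base = world.intercept + world.config.potency_gain * float(pf @ parent_f)
        if base >= ACTIVE_BOUNDARY_P + 0.5:
            break
    else:
        raise GenerationError("no active parent ligand found for this pocket")

    cluster = world.assign_scaffold(parent_f)
    records, lids, potencies = {}, [], []
    for _ in range(n_ligands):
        f = _unit_rows(parent_f + perturbation * rng.normal(size=d))
        lid = world._mint_ligand("C", f, rng)
        world.scaffold_of[lid] = cluster  # congeneric: one scaffold by construction
        lids.append(lid)
        records[lid] = world.ligand_record(lid)
        potencies.append(world.true_potency(parent_pocket, lid))

    values = _to_reported(np.asarray(potencies), Unit.NM, rng)
    assay = Assay(
        assay_id=f"series:{pocket_id}:{seed}",
        target_group_id=parent_pocket,
        pocket_ids=(pocket_id,),
        measurements=tuple(
            AffinityMeasurement(ligand_id=l, value=float(v), unit=Unit.NM)
            for l, v in zip(lids, values)
        ),
        unit=Unit.NM,
    )
    return assay, records
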