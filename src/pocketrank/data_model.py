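"""Assay-centric affinity data model.

Binding assays measure several ligands against one protein target under one
experimental protocol, so affinity values are comparable *within* an assay
but not across assays.  This module holds the assay containers, converts
reported values to a canonical potency scale (p-scale, larger = stronger),
derives active/inactive labels at the 10 uM boundary, and produces
within-assay best-first rankings with explicit tie groups.
"""

from __future__ import annotations

import enum
import io
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD_MOLAR = 1e-5  # 10 uM boundary, inclusive


class Unit(enum.Enum):
    """Measurement unit classes; the member value is the factor to mol/L or
    g/L for the concentration classes."""

    NM = ("nM", "molar", 1e-9)
    UM = ("uM", "molar", 1e-6)
    MM = ("mM", "molar", 1e-3)
    M = ("M", "molar", 1.0)
    UG_ML = ("ug/mL", "density", 1e-3)  # ug/mL -> g/L
    PERCENT = ("%", "percent", None)

    def __init__(self, label, klass, to_base):
        self.label = label
        self.klass = klass
        self.to_base = to_base

    @classmethod
    def parse(cls, text: str) -> "Unit":
        norm = (
            str(text)
            .strip()
            .replace("μ", "u")
            .replace("µ", "u")
            .lower()
            .replace(" ", "")
        )
        table = {
            "nm": cls.NM,
            "um": cls.UM,
            "umol": cls.UM,
            "mm": cls.MM,
            "m": cls.M,
            "ug/ml": cls.UG_ML,
            "%": cls.PERCENT,
            "percent": cls.PERCENT,
        }
        if norm not in table:
            raise SchemaError(f"unknown unit {text!r}")
        return table[norm]


class RANK_ONLY:
    """Marker: value usable for within-assay ordering only, no absolute scale."""


class SchemaError(ValueError):
    pass


class ValidationError(ValueError):
    pass


class Activity(enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class AffinityMeasurement:
    """One reported affinity value v_i(l) for one ligand in one assay."""

    ligand_id: str
    value: float
    unit: Unit
    measurement_kind: str = ""

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValidationError(f"non-finite value for ligand {self.ligand_id}")
        if self.unit.klass in ("molar", "density") and self.value <= 0:
            raise ValidationError(
                f"non-positive {self.unit.klass} value for ligand {self.ligand_id}"
            )
        if self.unit is Unit.PERCENT and not (-10.0 <= self.value <= 110.0):
            raise ValidationError(
                f"percent value {self.value} out of range for ligand {self.ligand_id}"
            )


@dataclass
class Assay:
    """One assay: one target group, >=1 pocket structure variants, a set of
    internally comparable measurements sharing a single unit."""

    assay_id: str
    target_group_id: str
    pocket_ids: tuple
    measurements: tuple  # of AffinityMeasurement
    unit: Unit

    def __post_init__(self):
        if not self.pocket_ids:
            raise ValidationError(f"assay {self.assay_id}: pocket_ids empty")
        units = {m.unit for m in self.measurements}
        if units and units != {self.unit}:
            raise ValidationError(
                f"assay {self.assay_id}: mixed units "
                f"{sorted(u.label for u in units)}"
            )
        ids = [m.ligand_id for m in self.measurements]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"assay {self.assay_id}: duplicate ligand measurement(s) {dup}"
            )

    @property
    def ligand_ids(self):
        return [m.ligand_id for m in self.measurements]

    def __len__(self):
        return len(self.measurements)


@dataclass
class AssayCollection:
    assays: dict = field(default_factory=dict)  # assay_id -> Assay
    ligands: dict = field(default_factory=dict)  # ligand_id -> structure record
    pockets: dict = field(default_factory=dict)  # pocket_id -> structure record

    def validate(self):
        for a in self.assays.values():
            for m in a.measurements:
                if m.ligand_id not in self.ligands:
                    raise ValidationError(
                        f"assay {a.assay_id}: ligand {m.ligand_id} not in registry"
                    )
            for p in a.pocket_ids:
                if p not in self.pockets:
                    raise ValidationError(
                        f"assay {a.assay_id}: pocket {p} not in registry"
                    )
        return self

    def __len__(self):
        return len(self.assays)


REQUIRED_COLUMNS = ["assay_id", "target_group_id", "ligand_id", "value", "unit"]


def ingest_assays(table, pocket_ids_by_assay: dict | None = None) -> AssayCollection:
    """Build an :class:`AssayCollection` from a tabular assay record set.

    `table` may be a DataFrame, a path, or a CSV/TSV text buffer with columns
    ``assay_id,target_group_id,ligand_id,value,unit[,relation,measurement_kind]``.
    Rows carrying a qualified relation ("<", ">") are dropped with a warning.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        if isinstance(table, str) and "\n" in table:
            table = io.StringIO(table)
        df = pd.read_csv(table, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise SchemaError("empty assay table")

    if "relation" in df.columns:
        rel = df["relation"].fillna("=").astype(str).str.strip()
        qualified = ~rel.isin(["=", "", "nan"])
        if qualified.any():
            logger.warning(
                "dropping %d qualified-value row(s) with relation '<' or '>'",
                int(qualified.sum()),
            )
            df = df[~qualified]

    dup = df.duplicated(subset=["assay_id", "ligand_id"], keep=False)
    if dup.any():
        pairs = sorted(
            set(map(tuple, df.loc[dup, ["assay_id", "ligand_id"]].values))
        )
        raise ValidationError(f"duplicate (assay, ligand) row(s): {pairs}")

    coll = AssayCollection()
    for assay_id, grp in df.groupby("assay_id", sort=True):
        units = {Unit.parse(u) for u in grp["unit"]}
        if len(units) > 1:
            raise ValidationError(
                f"assay {assay_id}: mixed units "
                f"{sorted(u.label for u in units)}"
            )
        unit = units.pop()
        groups = set(grp["target_group_id"])
        if len(groups) > 1:
            raise ValidationError(
                f"assay {assay_id}: multiple target_group_ids {sorted(groups)}"
            )
        meas = tuple(
            AffinityMeasurement(
                ligand_id=str(r.ligand_id),
                value=float(r.value),
                unit=unit,
                measurement_kind=str(getattr(r, "measurement_kind", "") or ""),
            )
            for r in grp.itertuples()
        )
        pocket_ids = tuple(
            (pocket_ids_by_assay or {}).get(str(assay_id), (f"pocket:{assay_id}",))
        )
        coll.assays[str(assay_id)] = Assay(
            assay_id=str(assay_id),
            target_group_id=str(groups.pop() if groups else grp["target_group_id"].iloc[0]),
            pocket_ids=pocket_ids,
            measurements=meas,
            unit=unit,
        )
        for m in meas:
            coll.ligands.setdefault(m.ligand_id, {"ligand_id": m.ligand_id})
        for p in pocket_ids:
            coll.pockets.setdefault(p, {"pocket_id": p})
    return coll


def to_collection_frame(coll: AssayCollection) -> pd.DataFrame:
    """Serialize a collection back to the canonical assay table."""
    rows = []
    for a in sorted(coll.assays.values(), key=lambda x: x.assay_id):
        for m in a.measurements:
            rows.append(
                {
                    "assay_id": a.assay_id,
                    "target_group_id": a.target_group_id,
                    "ligand_id": m.ligand_id,
                    "value": m.value,
                    "unit": a.unit.label,
                    "measurement_kind": m.measurement_kind,
                }
            )
    return pd.DataFrame(rows)


def to_potency(value: float, unit: Unit):
    """Convert a reported value to the canonical p-scale (-log10 of the
    base concentration; larger = stronger binding).

    Percent-unit values have no absolute scale: the marker :class:`RANK_ONLY`
    is returned with the raw value retained by the caller for ordering.
    Density values get a p-scale on g/L, usable for within-assay ranking only.
    """
    if unit is Unit.PERCENT:
        return RANK_ONLY
    if value <= 0:
        raise ValidationError(f"non-positive {unit.klass} value {value}")
    return -math.log10(value * unit.to_base)


def assay_potencies(assay: Assay) -> dict:
    """ligand_id -> within-assay ordering key on the potency scale.

    For percent units the raw value is the ordering key (more inhibition =
    stronger); for concentration units the p-scale value is used.
    """
    out = {}
    for m in assay.measurements:
        p = to_potency(m.value, m.unit)
        out[m.ligand_id] = m.value if p is RANK_ONLY else p
    return out


def label_activity(
    coll: AssayCollection, threshold_molar: float = ACTIVITY_THRESHOLD_MOLAR
) -> dict:
    """(target_group_id, ligand_id) -> Activity.

    Only molar-class measurements yield absolute labels (<= threshold is
    active, inclusive); percent and density measurements stay unlabeled.
    An active measurement anywhere for the pair wins over inactive ones.
    """
    labels = {}
    for a in coll.assays.values():
        for m in a.measurements:
            key = (a.target_group_id, m.ligand_id)
            if a.unit.klass != "molar":
                labels.setdefault(key, Activity.UNLABELED)
                continue
            molar = m.value * a.unit.to_base
            lab = Activity.ACTIVE if molar <= threshold_molar else Activity.INACTIVE
            prev = labels.get(key, Activity.UNLABELED)
            # precedence: ACTIVE > INACTIVE > UNLABELED
            if prev is not Activity.ACTIVE:
                labels[key] = lab
    return labels


@dataclass(frozen=True)
class Ranking:
    """Best-first ligand order with explicit tie groups."""

    tie_groups: tuple  # tuple of tuples of ligand_ids, strongest first
    potency: dict = field(hash=False, compare=False, default_factory=dict)

    @property
    def order(self):
        return [lid for grp in self.tie_groups for lid in grp]

    def __len__(self):
        return len(self.order)


def rank_ligands(assay: Assay) -> Ranking:
    """Rank an assay's ligands best-first; equal values form tie groups,
    stable by ligand_id inside a group."""
    if len(assay) == 0:
        raise ValidationError(f"assay {assay.assay_id}: no measurements")
    pot = assay_potencies(assay)
    for lid, v in pot.items():
        if not math.isfinite(v):
            raise ValidationError(f"non-finite ordering key for ligand {lid}")
    by_value = {}
    for lid, v in pot.items():
        by_value.setdefault(v, []).append(lid)
    groups = tuple(
        tuple(sorted(by_value[v])) for v in sorted(by_value, reverse=True)
    )
    return Ranking(tie_groups=groups, potency=pot)
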