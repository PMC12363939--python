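"""Shared atom-level representation and the composable transform pipeline.

Every processing step in this package reads and returns a :class:`PipelineState`
wrapping an :class:`AtomTable` — a pandas-backed table with one row per atom
plus an explicit bond table — rather than an opaque dictionary of derived
tensors. Transforms are registered by name, declare which derived-feature keys
they read and write, and compose left-to-right into serializable pipelines.
"""

from __future__ import annotations

import copy as _copy
import hashlib
import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("structforge")

ATOM_COLUMNS = [
    "atom_uid", "chain_id", "entity_id", "res_index", "comp_id", "atom_name",
    "element", "altloc", "occupancy", "formal_charge",
    "x", "y", "z", "is_resolved", "is_polymer", "annot",
]
BOND_COLUMNS = ["atom_a", "atom_b", "order", "provenance"]
BOND_ORDERS = {"single", "double", "triple", "aromatic"}
BOND_PROVENANCES = {"intra_component", "struct_conn", "inferred"}


class PipelineError(RuntimeError):
    """A transform failed; the message names the failing stage."""


class ConfigurationError(ValueError):
    """Pipeline configuration problem (unknown transform, key collision)."""


def empty_atoms() -> pd.DataFrame:
    df = pd.DataFrame({
        "atom_uid": pd.Series(dtype="int64"),
        "chain_id": pd.Series(dtype="object"),
        "entity_id": pd.Series(dtype="int64"),
        "res_index": pd.Series(dtype="int64"),
        "comp_id": pd.Series(dtype="object"),
        "atom_name": pd.Series(dtype="object"),
        "element": pd.Series(dtype="object"),
        "altloc": pd.Series(dtype="object"),
        "occupancy": pd.Series(dtype="float64"),
        "formal_charge": pd.Series(dtype="int64"),
        "x": pd.Series(dtype="float64"),
        "y": pd.Series(dtype="float64"),
        "z": pd.Series(dtype="float64"),
        "is_resolved": pd.Series(dtype="bool"),
        "is_polymer": pd.Series(dtype="bool"),
        "annot": pd.Series(dtype="object"),
    })
    return df


def empty_bonds() -> pd.DataFrame:
    return pd.DataFrame({
        "atom_a": pd.Series(dtype="int64"),
        "atom_b": pd.Series(dtype="int64"),
        "order": pd.Series(dtype="object"),
        "provenance": pd.Series(dtype="object"),
    })


@dataclass
class AtomTable:
    """Atom-level structural representation shared by every transform.

    ``atoms`` holds one row per atom keyed by a stable surrogate ``atom_uid``
    that is never positional and never reused after deletion; ``bonds`` holds
    one row per unordered atom pair. Coordinates are in Angstrom; missing
    coordinates are NaN with ``is_resolved`` False.
    """

    atoms: pd.DataFrame = field(default_factory=empty_atoms)
    bonds: pd.DataFrame = field(default_factory=empty_bonds)
    next_uid: int = 0

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[dict], bonds: Iterable[dict] = ()) -> "AtomTable":
        records = list(records)
        table = cls()
        if records:
            df = pd.DataFrame(records)
            if "atom_uid" not in df:
                df["atom_uid"] = np.arange(len(df), dtype="int64")
            defaults = {
                "entity_id": 1, "altloc": "", "occupancy": 1.0,
                "formal_charge": 0, "x": np.nan, "y": np.nan, "z": np.nan,
                "is_resolved": True, "is_polymer": False, "annot": "",
            }
            for col, val in defaults.items():
                if col not in df:
                    df[col] = val
            table.atoms = df[ATOM_COLUMNS].reset_index(drop=True)
            table.next_uid = int(table.atoms["atom_uid"].max()) + 1
        blist = list(bonds)
        if blist:
            bd = pd.DataFrame(blist)
            if "provenance" not in bd:
                bd["provenance"] = "intra_component"
            table.bonds = bd[BOND_COLUMNS].reset_index(drop=True)
        return table

    # -- accessors ---------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        self.atoms[["x", "y", "z"]] = xyz

    @property
    def uids(self) -> np.ndarray:
        return self.atoms["atom_uid"].to_numpy()

    def __len__(self) -> int:
        return len(self.atoms)

    def row_by_uid(self, uid: int) -> pd.Series:
        sel = self.atoms[self.atoms["atom_uid"] == uid]
        if sel.empty:
            raise KeyError(f"unknown atom_uid {uid}")
        return sel.iloc[0]

    def coords_by_uid(self, uids: Iterable[int]) -> np.ndarray:
        idx = self.atoms.set_index("atom_uid")
        return idx.loc[list(uids), ["x", "y", "z"]].to_numpy(dtype=float)

    def neighbors(self, uid: int) -> list[int]:
        """Atom uids bonded to ``uid``."""
        b = self.bonds
        out = list(b.loc[b["atom_a"] == uid, "atom_b"])
        out += list(b.loc[b["atom_b"] == uid, "atom_a"])
        return out

    def residues(self) -> Iterable[tuple[tuple, pd.DataFrame]]:
        """Iterate (chain_id, res_index) residue groups in table order."""
        return self.atoms.groupby(["chain_id", "res_index"], sort=False)

    # -- mutation ----------------------------------------------------------
    def allocate_uids(self, n: int) -> np.ndarray:
        out = np.arange(self.next_uid, self.next_uid + n, dtype="int64")
        self.next_uid += n
        return out

    def add_atoms(self, records: list[dict]) -> np.ndarray:
        """Append atoms; assigns fresh uids and returns them."""
        if not records:
            return np.empty(0, dtype="int64")
        uids = self.allocate_uids(len(records))
        df = pd.DataFrame(records)
        df["atom_uid"] = uids
        defaults = {
            "entity_id": 1, "altloc": "", "occupancy": 1.0, "formal_charge": 0,
            "x": np.nan, "y": np.nan, "z": np.nan,
            "is_resolved": True, "is_polymer": False, "annot": "",
        }
        for col, val in defaults.items():
            if col not in df:
                df[col] = val
        new = df[ATOM_COLUMNS]
        self.atoms = new.copy() if self.atoms.empty else pd.concat(
            [self.atoms, new], ignore_index=True)
        return uids

    def add_bond(self, a: int, b: int, order: str = "single",
                 provenance: str = "intra_component") -> bool:
        """Add a bond unless it already exists; returns True when added."""
        if a == b:
            raise ValueError("self-bonds are not allowed")
        if self.has_bond(a, b):
            return False
        row = pd.DataFrame([{"atom_a": a, "atom_b": b,
                             "order": order, "provenance": provenance}])
        self.bonds = row if self.bonds.empty else pd.concat(
            [self.bonds, row], ignore_index=True)
        return True

    def has_bond(self, a: int, b: int) -> bool:
        bd = self.bonds
        if bd.empty:
            return False
        m = (((bd["atom_a"] == a) & (bd["atom_b"] == b)) |
             ((bd["atom_a"] == b) & (bd["atom_b"] == a)))
        return bool(m.any())

    def copy(self) -> "AtomTable":
        return AtomTable(self.atoms.copy(), self.bonds.copy(), self.next_uid)

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Raise AssertionError on any violated table invariant."""
        a = self.atoms
        if a.empty:
            assert self.bonds.empty, "bonds present in an empty table"
            return
        uids = a["atom_uid"]
        assert uids.is_unique, "atom_uid values must be unique"
        occ = a["occupancy"].to_numpy(dtype=float)
        assert ((occ >= 0) & (occ <= 1)).all(), "occupancy outside [0, 1]"
        resolved = a["is_resolved"].to_numpy(dtype=bool)
        xyz = a[["x", "y", "z"]].to_numpy(dtype=float)
        assert np.isfinite(xyz[resolved]).all(), \
            "resolved atoms must have finite coordinates"
        key = a[["chain_id", "res_index", "atom_name", "altloc"]]
        assert not key.duplicated().any(), \
            "(chain_id, res_index, atom_name, altloc) must be unique"
        if not self.bonds.empty:
            known = set(uids)
            ba = self.bonds["atom_a"]
            bb = self.bonds["atom_b"]
            assert ba.isin(known).all() and bb.isin(known).all(), \
                "bond endpoint references missing atom_uid"
            assert (ba != bb).all(), "self-bond present"
            pairs = pd.DataFrame({
                "lo": np.minimum(ba, bb), "hi": np.maximum(ba, bb)})
            assert not pairs.duplicated().any(), "duplicate bond pair"
            assert self.bonds["order"].isin(BOND_ORDERS).all(), "bad bond order"


@dataclass
class PipelineState:
    """AtomTable plus derived features and the run seed.

    ``extras`` entries that index atoms must do so by ``atom_uid``, never by
    positional index, so that transforms may delete or reorder atoms safely.
    """

    table: AtomTable = field(default_factory=AtomTable)
    extras: dict[str, Any] = field(default_factory=dict)
    rng_seed: int = 0
    log: list[dict] = field(default_factory=list)

    def copy(self) -> "PipelineState":
        return PipelineState(self.table.copy(), _copy.deepcopy(self.extras),
                             self.rng_seed, list(self.log))


def derive_seed(seed: int, name: str) -> int:
    """Deterministic sub-stream seed for a named transform (< 2**31)."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# Transform registry and pipelines


@dataclass
class TransformSpec:
    name: str
    func: Callable[..., PipelineState]
    reads: tuple[str, ...] = ()
    writes: tuple[str, ...] = ()


_REGISTRY: dict[str, TransformSpec] = {}


def register_transform(name: str, reads: Iterable[str] = (),
                       writes: Iterable[str] = ()):
    """Decorator registering ``func(state, **params) -> state`` under ``name``."""
    def deco(func):
        _REGISTRY[name] = TransformSpec(name, func, tuple(reads), tuple(writes))
        return func
    return deco


def transform_registry() -> dict[str, TransformSpec]:
    return dict(_REGISTRY)


@dataclass
class Pipeline:
    """Ordered, named, serializable composition of transforms."""

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def serialize(self) -> list[dict]:
        return [{"transform": name, "params": dict(params)}
                for name, params in self.steps]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.serialize(), sort_keys=False)

    @classmethod
    def from_config(cls, config: list[dict]) -> "Pipeline":
        steps = [(entry["transform"], dict(entry.get("params") or {}))
                 for entry in config]
        return compose_pipeline(steps)

    @classmethod
    def from_yaml(cls, text: str) -> "Pipeline":
        return cls.from_config(yaml.safe_load(text) or [])


def compose_pipeline(transforms: list) -> Pipeline:
    """Build a pipeline from transform names or (name, params) pairs.

    Unknown names raise :class:`ConfigurationError`; writer-key collisions
    between two stages are an error rather than a silent overwrite.
    """
    steps: list[tuple[str, dict]] = []
    for item in transforms:
        if isinstance(item, str):
            name, params = item, {}
        else:
            name, params = item[0], dict(item[1])
        if name not in _REGISTRY:
            raise ConfigurationError(f"unknown transform name: {name!r}")
        steps.append((name, params))
    written: dict[str, str] = {}
    for name, _ in steps:
        for key in _REGISTRY[name].writes:
            if key in written and written[key] != name:
                raise ConfigurationError(
                    f"extras key {key!r} written by both {written[key]!r} "
                    f"and {name!r}")
            written[key] = name
    return Pipeline(steps)


def apply_pipeline(pipeline: Pipeline, state: PipelineState,
                   validate: bool = True) -> PipelineState:
    """Apply the composed transforms left-to-right.

    Each stage is logged with atom counts before/after; with an identical
    ``rng_seed`` the output is bit-identical across runs. A raising transform
    halts the pipeline with an error naming the failing stage.
    """
    current = state.copy()
    if validate:
        current.table.validate()
    for name, params in pipeline.steps:
        spec = _REGISTRY[name]
        n_before = len(current.table)
        try:
            current = spec.func(current, **params)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(f"transform {name!r} failed: {exc}") from exc
        current.log.append({
            "transform": name,
            "atoms_before": n_before,
            "atoms_after": len(current.table),
        })
        if validate:
            current.table.validate()
    return current


def delete_atoms(state: PipelineState, uids) -> PipelineState:
    """Remove the named atoms, all incident bonds, and stale extras entries.

    Remaining atom uids are unchanged. Extras values that are explicit uid
    collections referencing a deleted atom are dropped with a warning.
    """
    uids = set(int(u) for u in uids)
    out = state.copy()
    table = out.table
    known = set(int(u) for u in table.uids)
    missing = sorted(uids - known)
    if missing:
        raise KeyError(f"unknown atom_uid(s): {missing}")
    if not uids:
        return out
    table.atoms = table.atoms[~table.atoms["atom_uid"].isin(uids)]\
        .reset_index(drop=True)
    if not table.bonds.empty:
        b = table.bonds
        table.bonds = b[~(b["atom_a"].isin(uids) | b["atom_b"].isin(uids))]\
            .reset_index(drop=True)
    for key in list(out.extras):
        val = out.extras[key]
        if isinstance(val, (set, frozenset, list, tuple)) and \
                any(isinstance(v, (int, np.integer)) and int(v) in uids for v in val):
            logger.warning("dropping extras[%r]: references deleted atoms", key)
            del out.extras[key]
    return out


@register_transform("delete_atoms")
def _delete_atoms_transform(state: PipelineState, uids=()) -> PipelineState:
    return delete_atoms(state, uids)


@register_transform("delete_chain")
def delete_chain(state: PipelineState, chain_id: str) -> PipelineState:
    """Drop every atom of one chain (and all bonds touching it)."""
    atoms = state.table.atoms
    uids = atoms.loc[atoms["chain_id"] == chain_id, "atom_uid"]
    return delete_atoms(state, uids)


@register_transform("identity")
def identity(state: PipelineState) -> PipelineState:
    return state
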