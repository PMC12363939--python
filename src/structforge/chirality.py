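"""Chirality as signed pyramidal angles.

Handedness at a tetrahedral center is encoded by the signed angle between the
first-ranked substituent direction and the plane of the other two:

    theta = arcsin( u1 . (u2 x u3) / |u2 x u3| )

with u_i the unit vectors from the center to its three highest-ranked heavy
neighbors. The sign flips under mirror reflection and is invariant under
proper rotation and translation; perfect tetrahedral geometry gives
|theta| = arcsin(sqrt(2/3)) ~ 0.95532 rad (54.74 deg), which is the ideal
angle used for the gradient feature.

Neighbor ranking is a fixed, documented ordering — descending atomic number,
then descending sum of the neighbors'-neighbors heavy-atom atomic numbers,
then ascending atom name — so that the per-atom feature and the accuracy
metric share one self-consistent sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._chemdata import atomic_number
from .core import PipelineState, derive_seed, register_transform
from .io import ComponentDefinition

#: magnitude of the ideal pyramidal angle for tetrahedral geometry (rad)
IDEAL_ANGLE = float(np.arcsin(np.sqrt(2.0 / 3.0)))


class DegenerateGeometryError(ValueError):
    """Neighbors are (nearly) colinear; the signed angle is undefined."""


@dataclass
class ChiralCenter:
    center: int
    ordered_neighbors: tuple[int, int, int]
    reference_sign: int
    ideal_angle: float = IDEAL_ANGLE

    def __post_init__(self):
        self.ideal_angle = self.reference_sign * IDEAL_ANGLE


@dataclass
class ChiralFeature:
    """Per-atom gradient vectors of the squared ideal-angle error."""
    center: int
    gradients: dict[int, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# signed angle and its analytic gradient


def chiral_angle(center_xyz, n1_xyz, n2_xyz, n3_xyz) -> float:
    """Signed pyramidal angle (radians) at a center given its three ordered
    neighbor positions. Raises for degenerate (colinear) geometry."""
    c = np.asarray(center_xyz, dtype=float)
    us = []
    for p in (n1_xyz, n2_xyz, n3_xyz):
        v = np.asarray(p, dtype=float) - c
        us.append(v / np.linalg.norm(v))
    u1, u2, u3 = us
    n = np.cross(u2, u3)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        raise DegenerateGeometryError("u2 x u3 vanishes: degenerate geometry")
    s = float(np.dot(u1, n) / nn)
    return float(np.arcsin(np.clip(s, -1.0, 1.0)))


def chiral_error_gradient(center: ChiralCenter, center_xyz, n1_xyz, n2_xyz,
                          n3_xyz) -> ChiralFeature:
    """Analytic gradient of E = (theta - ideal_angle)^2 for the four atoms.

    The gradient is zero exactly at the ideal angle and the four vectors sum
    to zero (translation invariance of E).
    """
    c = np.asarray(center_xyz, dtype=float)
    xs = [np.asarray(p, dtype=float) for p in (n1_xyz, n2_xyz, n3_xyz)]
    vs = [x - c for x in xs]
    ls = [np.linalg.norm(v) for v in vs]
    us = [v / l for v, l in zip(vs, ls)]
    u1, u2, u3 = us
    n = np.cross(u2, u3)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        raise DegenerateGeometryError("u2 x u3 vanishes: degenerate geometry")
    m = n / nn
    s = float(np.dot(u1, m))
    s = np.clip(s, -1.0, 1.0)
    theta = float(np.arcsin(s))

    dE_dtheta = 2.0 * (theta - center.ideal_angle)
    denom = np.sqrt(max(1.0 - s * s, 1e-12))
    dE_ds = dE_dtheta / denom

    # s = u1 . m(n(u2, u3));  w = ds/dn
    w = (u1 - s * m) / nn
    ds_du = [m, np.cross(u3, w), np.cross(w, u2)]
    grads = {}
    total = np.zeros(3)
    for uid_pos, (x, u, l, dsdu) in enumerate(zip(xs, us, ls, ds_du)):
        g = dE_ds * (dsdu - np.dot(dsdu, u) * u) / l
        grads[uid_pos] = g
        total += g
    feature = ChiralFeature(center.center)
    n1, n2, n3 = center.ordered_neighbors
    feature.gradients = {n1: grads[0], n2: grads[1], n3: grads[2],
                         center.center: -total}
    return feature


# ---------------------------------------------------------------------------
# center detection


def _neighbor_rank_key(state: PipelineState, uid: int, comp=None):
    """(descending Z, descending heavy neighbors'-neighbors Z sum,
    ascending atom name) — returned as a sortable key.

    The neighbor sum is taken from the component template when the atom is
    defined there, so the ordering does not depend on linkage state (an
    internal residue ranks like a terminal one); the structure graph is the
    fallback for atoms without a template."""
    table = state.table
    row = table.row_by_uid(uid)
    name = str(row["atom_name"])
    z = atomic_number(str(row["element"]))
    nn_sum = 0
    if comp is not None and name in comp.atom_map:
        amap = comp.atom_map
        for nb in comp.neighbors(name):
            if amap[nb].element.upper() != "H":
                nn_sum += atomic_number(amap[nb].element)
    else:
        for nb in table.neighbors(uid):
            el = str(table.row_by_uid(nb)["element"])
            if el.upper() != "H":
                nn_sum += atomic_number(el)
    return (-z, -nn_sum, name)


def _branch_equivalence_key(state: PipelineState, uid: int, comp=None):
    """Depth-2 structural signature used to decide whether two substituent
    branches are genuinely indistinguishable (an unresolvable tie): the
    branch atom's Z plus the sorted multiset of its heavy neighbors' Zs."""
    table = state.table
    row = table.row_by_uid(uid)
    name = str(row["atom_name"])
    z = atomic_number(str(row["element"]))
    if comp is not None and name in comp.atom_map:
        amap = comp.atom_map
        zs = sorted(atomic_number(amap[nb].element)
                    for nb in comp.neighbors(name)
                    if amap[nb].element.upper() != "H")
    else:
        zs = sorted(atomic_number(str(table.row_by_uid(nb)["element"]))
                    for nb in table.neighbors(uid)
                    if str(table.row_by_uid(nb)["element"]).upper() != "H")
    return (z, tuple(zs))


def find_chiral_centers(state: PipelineState,
                        components: dict[str, ComponentDefinition] | None = None,
                        ) -> tuple[list[ChiralCenter], int]:
    """Detect chiral centers and fix their ordered neighbors and reference
    signs.

    An atom is a candidate when its substituent branches — heavy bonded
    neighbors plus one branch per implicit hydrogen — number exactly four,
    at least three of them heavy, and are pairwise distinguishable under the
    ranking rule. The reference sign comes from the component's ideal
    coordinates when available, else from the deposited coordinates.

    Returns (centers, n_ambiguous); centers with an unresolvable ranking tie
    are excluded and counted.
    """
    table = state.table
    idx = table.atoms.set_index("atom_uid")
    centers: list[ChiralCenter] = []
    ambiguous = 0
    for uid in table.uids:
        row = idx.loc[uid]
        if str(row["element"]).upper() == "H":
            continue
        nbs = table.neighbors(int(uid))
        heavy = [n for n in nbs
                 if str(idx.loc[n, "element"]).upper() != "H"]
        explicit_h = len(nbs) - len(heavy)
        comp = (components or {}).get(row["comp_id"])
        implicit_h = 0
        if comp is not None and explicit_h == 0:
            implicit_h = comp.implicit_h_count(str(row["atom_name"]))
        h_branches = min(1, explicit_h + implicit_h) \
            if (explicit_h + implicit_h) else 0
        if explicit_h + implicit_h > 1:
            continue  # two equivalent H branches: never chiral
        if len(heavy) + h_branches != 4 or len(heavy) < 3:
            continue
        keys = {n: _neighbor_rank_key(state, int(n), comp) for n in heavy}
        equiv = [_branch_equivalence_key(state, int(n), comp) for n in heavy]
        if len(set(equiv)) != len(equiv):
            ambiguous += 1
            continue
        ordered = sorted(heavy, key=lambda n: keys[n])[:3]
        sign = _reference_sign(state, int(uid), ordered, comp)
        if sign == 0:
            ambiguous += 1
            continue
        centers.append(ChiralCenter(int(uid), tuple(int(n) for n in ordered),
                                    sign))
    return centers, ambiguous


def _reference_sign(state, uid, ordered, comp) -> int:
    table = state.table
    idx = table.atoms.set_index("atom_uid")
    names = [str(idx.loc[u, "atom_name"]) for u in [uid] + list(ordered)]
    if comp is not None:
        ideal = comp.ideal_coords()
        if all(n in ideal for n in names):
            theta = chiral_angle(*(ideal[n] for n in names))
            return int(np.sign(theta)) or 0
    pts = [idx.loc[u, ["x", "y", "z"]].to_numpy(float)
           for u in [uid] + list(ordered)]
    if not all(np.isfinite(p).all() for p in pts):
        return 0
    theta = chiral_angle(*pts)
    return int(np.sign(theta)) or 0


def observed_sign(state: PipelineState, center: ChiralCenter) -> int:
    """Sign of the signed angle in the state's current coordinates."""
    table = state.table
    pts = table.coords_by_uid([center.center, *center.ordered_neighbors])
    return int(np.sign(chiral_angle(*pts)))


# ---------------------------------------------------------------------------
# mirror inversion and augmentation


def invert_structure(state: PipelineState) -> PipelineState:
    """Mirror all coordinates (x -> -x). Every chiral angle flips sign;
    applying twice restores the original coordinates exactly."""
    out = state.copy()
    out.table.atoms["x"] = -out.table.atoms["x"]
    return out


@register_transform("sample_inversion_augmentation")
def sample_inversion_augmentation(state: PipelineState, p: float = 0.02,
                                  seed: int | None = None) -> PipelineState:
    """Seeded Bernoulli mirror augmentation: with probability ``p`` the whole
    structure is inverted (and any chiral centers recorded in
    ``extras['chiral_centers']`` get flipped reference signs); otherwise the
    state passes through unchanged. The draw is logged."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if seed is None:
        seed = derive_seed(state.rng_seed, "sample_inversion_augmentation")
    rng = np.random.default_rng(seed)
    inverted = bool(rng.random() < p)
    out = invert_structure(state) if inverted else state.copy()
    if inverted and "chiral_centers" in out.extras:
        out.extras["chiral_centers"] = [
            ChiralCenter(c.center, c.ordered_neighbors, -c.reference_sign)
            for c in out.extras["chiral_centers"]]
    out.log.append({"transform": "sample_inversion_augmentation",
                    "inverted": inverted, "p": p, "seed": int(seed)})
    return out


# ---------------------------------------------------------------------------
# accuracy metric


def chiral_center_accuracy(pred_state: PipelineState,
                           ref_state: PipelineState,
                           clusters: dict | None = None,
                           components: dict[str, ComponentDefinition] | None = None,
                           ) -> dict:
    """Fraction of chiral centers predicted with the correct handedness.

    Centers are found on the reference; a center is correct when the sign of
    its angle in the prediction equals the reference sign. Per-molecule
    percentages (molecule = one residue instance) are averaged within each
    cluster, and the overall value is the unweighted mean across clusters.
    With ``clusters`` None each molecule's comp_id forms its own cluster
    (CCD-identity clustering).

    Returns {overall, per_cluster, n_centers, n_ambiguous}; raises if the
    reference contains no chiral centers so that "no centers" is
    distinguishable from zero accuracy.
    """
    centers, ambiguous = find_chiral_centers(ref_state, components)
    if not centers:
        raise ValueError("reference structure has no chiral centers")
    idx = ref_state.table.atoms.set_index("atom_uid")
    pred_idx = pred_state.table.atoms.set_index("atom_uid")
    per_molecule: dict[tuple, list[bool]] = {}
    for c in centers:
        if c.center not in pred_idx.index:
            continue
        row = idx.loc[c.center]
        mol_key = (str(row["chain_id"]), int(row["res_index"]),
                   str(row["comp_id"]))
        # the ground truth is the reference structure's own handedness (a
        # D-residue reference must score a D prediction as correct)
        try:
            truth = observed_sign(ref_state, c)
        except (KeyError, ValueError):
            truth = c.reference_sign
        ok = observed_sign(pred_state, c) == truth
        per_molecule.setdefault(mol_key, []).append(ok)
    mol_scores = {k: float(np.mean(v)) for k, v in per_molecule.items()}
    cluster_scores: dict[str, list[float]] = {}
    for mol_key, score in mol_scores.items():
        cid = clusters[mol_key] if clusters is not None else mol_key[2]
        cluster_scores.setdefault(str(cid), []).append(score)
    per_cluster = {cid: float(np.mean(v)) for cid, v in cluster_scores.items()}
    overall = float(np.mean(list(per_cluster.values())))
    return {"overall": overall, "per_cluster": per_cluster,
            "n_centers": len(centers), "n_ambiguous": ambiguous}
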