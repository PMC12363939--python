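"""Chemistry standardization transforms for deposited structures.

The seven operations here turn raw crystallographic content into a chemically
consistent atom table: alternate-location resolution, leaving-group removal at
covalent linkage sites, covalent-link parsing (with optional distance-based
inference), bond-order correction after nucleophilic addition, formal-charge
assignment, deduplication of ligands modelled at special (symmetry) positions,
and rigid-superposition imputation of missing intra-residue atoms.

Every operation maps PipelineState -> PipelineState, never increases the atom
count except by imputation, and records its deletions/modifications in
``state.extras['sanitize_report']`` keyed by rule name.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._chemdata import (BOND_ORDER_VALUES, COVALENT_RADII, STANDARD_VALENCES)
from ._geometry import kabsch
from .core import PipelineState, delete_atoms, register_transform
from .io import ComponentDefinition, StructConnRecord

logger = logging.getLogger("structforge")

#: element -> allowed bonded-electron-pair counts
DEFAULT_VALENCES = STANDARD_VALENCES


def _report(state: PipelineState, rule: str, **info):
    rep = state.extras.setdefault("sanitize_report", {})
    entry = rep.setdefault(rule, defaultdict(list))
    for k, v in info.items():
        entry[k].extend(v if isinstance(v, list) else [v])


# ---------------------------------------------------------------------------
# 1. multiple occupancies


@register_transform("resolve_altlocs")
def resolve_altlocs(state: PipelineState) -> PipelineState:
    """Keep one conformer per atom: highest occupancy, ties broken by the
    lexicographically smallest altloc id. The kept atom's altloc is cleared
    and its occupancy preserved. Idempotent; no-altloc input is identity."""
    atoms = state.table.atoms
    if (atoms["altloc"] == "").all():
        return state
    drop: list[int] = []
    keep_uids: list[int] = []
    for _, group in atoms.groupby(["chain_id", "res_index", "atom_name"],
                                  sort=False):
        if len(group) == 1 and group["altloc"].iloc[0] == "":
            continue
        ranked = group.sort_values(["occupancy", "altloc"],
                                   ascending=[False, True])
        keep_uids.append(int(ranked["atom_uid"].iloc[0]))
        drop.extend(int(u) for u in ranked["atom_uid"].iloc[1:])
    out = delete_atoms(state, drop)
    mask = out.table.atoms["atom_uid"].isin(keep_uids)
    out.table.atoms.loc[mask, "altloc"] = ""
    _report(out, "resolve_altlocs", deleted=drop)
    return out


# ---------------------------------------------------------------------------
# 2. covalent link parsing


def _resolve_partner(table, partner) -> int | None:
    chain, res_index, atom_name = partner
    atoms = table.atoms
    sel = atoms[(atoms["chain_id"] == chain) &
                (atoms["res_index"] == res_index) &
                (atoms["atom_name"] == atom_name)]
    if sel.empty:
        return None
    return int(sel["atom_uid"].iloc[0])


def detect_covalent_links(state: PipelineState,
                          records: list[StructConnRecord] | None = None,
                          infer_by_distance: bool = False,
                          slack: float = 0.4) -> PipelineState:
    """Materialize struct_conn records as bonds.

    covale/disulf records become single bonds with provenance ``struct_conn``
    (declared order honoured); metalc records become annotations in
    ``extras['metal_coordination']``, never bonds. With ``infer_by_distance``,
    ligand-polymer heavy-atom pairs closer than the covalent-radii sum plus
    ``slack`` (Angstrom) and with free valence on both partners become bonds
    with provenance ``inferred``. Unresolvable records are skipped with a
    warning and counted.
    """
    out = state.copy()
    table = out.table
    if records is None:
        records = out.extras.get("struct_conn_records", [])
    skipped = 0
    for rec in records:
        a = _resolve_partner(table, rec.partner1)
        b = _resolve_partner(table, rec.partner2)
        if a is None or b is None:
            logger.warning("struct_conn record %s unresolvable; skipped", rec)
            skipped += 1
            continue
        if rec.conn_type == "metalc":
            out.extras.setdefault("metal_coordination", []).append((a, b))
            continue
        table.add_bond(a, b, order=rec.order or "single",
                       provenance="struct_conn")
    out.extras["struct_conn_skipped"] = skipped

    if infer_by_distance:
        _infer_distance_bonds(out, slack)
    return out


def _free_valence(table, uid: int, element: str) -> float:
    allowed = max(STANDARD_VALENCES.get(element.upper(), (4,)))
    b = table.bonds
    orders = pd.concat([b.loc[b["atom_a"] == uid, "order"],
                        b.loc[b["atom_b"] == uid, "order"]])
    return allowed - sum(BOND_ORDER_VALUES[o] for o in orders)


def _infer_distance_bonds(state: PipelineState, slack: float):
    table = state.table
    atoms = table.atoms
    heavy = atoms[(atoms["element"] != "H") & atoms["is_resolved"]]
    lig = heavy[~heavy["is_polymer"]]
    pol = heavy[heavy["is_polymer"]]
    if lig.empty or pol.empty:
        return
    lig_xyz = lig[["x", "y", "z"]].to_numpy(float)
    pol_xyz = pol[["x", "y", "z"]].to_numpy(float)
    max_cut = 2 * max(COVALENT_RADII.values()) + slack
    tree = cKDTree(pol_xyz)
    added = []
    for i, (_, la) in enumerate(lig.iterrows()):
        for j in tree.query_ball_point(lig_xyz[i], max_cut):
            pa = pol.iloc[j]
            cut = (COVALENT_RADII.get(la["element"], 0.77) +
                   COVALENT_RADII.get(pa["element"], 0.77) + slack)
            d = float(np.linalg.norm(lig_xyz[i] - pol_xyz[j]))
            if d > cut or d < 1e-6:
                continue
            ua, ub = int(la["atom_uid"]), int(pa["atom_uid"])
            if table.has_bond(ua, ub):
                continue
            if _free_valence(table, ua, la["element"]) >= 1 and \
                    _free_valence(table, ub, pa["element"]) >= 1:
                table.add_bond(ua, ub, order="single", provenance="inferred")
                added.append((ua, ub))
    if added:
        _report(state, "detect_covalent_links", inferred=added)


@register_transform("detect_covalent_links")
def _detect_covalent_links_transform(state, infer_by_distance=False,
                                     slack=0.4):
    return detect_covalent_links(state, None, infer_by_distance, slack)


# ---------------------------------------------------------------------------
# 3. leaving groups


def _linkage_sites(table) -> dict[int, list[int]]:
    """uid -> partner uids for bonds that cross residue boundaries."""
    sites: dict[int, list[int]] = defaultdict(list)
    idx = table.atoms.set_index("atom_uid")
    for _, b in table.bonds.iterrows():
        a, c = int(b["atom_a"]), int(b["atom_b"])
        ra, rc = idx.loc[a], idx.loc[c]
        if (ra["chain_id"], ra["res_index"]) != (rc["chain_id"], rc["res_index"]):
            sites[a].append(c)
            sites[c].append(a)
    return sites


def remove_leaving_groups(state: PipelineState,
                          components: dict[str, ComponentDefinition]
                          ) -> PipelineState:
    """Delete leaving-flagged atoms at covalent linkage sites.

    For every atom participating in an inter-residue or ligand covalent bond,
    the component's leaving-flagged atoms attached to that linkage atom are
    deleted together with their hydrogens. Leaving atoms at non-linked sites
    (e.g. the chain-terminal carboxyl OXT) are retained. Idempotent.
    """
    out = state.copy()
    table = out.table
    idx = table.atoms.set_index("atom_uid")
    to_delete: set[int] = set()
    for uid in _linkage_sites(table):
        row = idx.loc[uid]
        comp = components.get(row["comp_id"])
        if comp is None:
            raise KeyError(f"no component definition for {row['comp_id']}")
        amap = comp.atom_map
        leaving_names = set()
        for nb in comp.neighbors(row["atom_name"]):
            if amap[nb].is_leaving:
                leaving_names.add(nb)
                # hydrogens riding on the departing heavy atom
                for nb2 in comp.neighbors(nb):
                    if amap[nb2].element.upper() == "H":
                        leaving_names.add(nb2)
        if not leaving_names:
            continue
        res = table.atoms[
            (table.atoms["chain_id"] == row["chain_id"]) &
            (table.atoms["res_index"] == row["res_index"]) &
            (table.atoms["atom_name"].isin(leaving_names))]
        to_delete.update(int(u) for u in res["atom_uid"])
    out = delete_atoms(out, to_delete)
    _report(out, "remove_leaving_groups", deleted=sorted(to_delete))
    return out


# ---------------------------------------------------------------------------
# 4. bond order correction


def _implicit_h(comp: ComponentDefinition | None, atom_name: str,
                linked: bool) -> int:
    """Implicit hydrogen count from the component template. On linkage atoms
    the leaving-flagged hydrogens are excluded (they depart with the bond)."""
    if comp is None or atom_name not in comp.atom_map:
        return 0
    amap = comp.atom_map
    n = 0
    for nb in comp.neighbors(atom_name):
        if amap[nb].element.upper() != "H":
            continue
        if linked and amap[nb].is_leaving:
            continue
        n += 1
    return n


def _order_sum(table, uid: int) -> float:
    b = table.bonds
    orders = pd.concat([b.loc[b["atom_a"] == uid, "order"],
                        b.loc[b["atom_b"] == uid, "order"]])
    return float(sum(BOND_ORDER_VALUES[o] for o in orders))


def correct_bond_order_after_addition(
        state: PipelineState,
        components: dict[str, ComponentDefinition] | None = None,
        valences: dict = DEFAULT_VALENCES) -> PipelineState:
    """Demote double bonds at atoms whose valence is exceeded by a new link.

    Nucleophilic addition converts a multiple bond to a single bond at the
    attacked atom; for each linkage atom whose bond-order sum (plus implicit
    hydrogens) exceeds its allowed valence, one double bond is demoted to
    single, preferring a C=O partner, then C=N, then any double bond. An
    over-valent atom with no demotable double bond raises, signalling an
    upstream chemistry problem.
    """
    out = state.copy()
    table = out.table
    idx = table.atoms.set_index("atom_uid")
    changed = []
    for uid in sorted(_linkage_sites(table)):
        row = idx.loc[uid]
        element = str(row["element"]).upper()
        if element not in valences:
            raise KeyError(f"element {element!r} missing from valence table")
        comp = (components or {}).get(row["comp_id"])
        allowed = max(valences[element])
        total = _order_sum(table, uid) + _implicit_h(comp, row["atom_name"], True)
        while total > allowed + 1e-9:
            b = table.bonds
            at_uid = (b["atom_a"] == uid) | (b["atom_b"] == uid)
            doubles = b[at_uid & (b["order"] == "double")]
            if doubles.empty:
                raise ValueError(
                    f"atom_uid {uid} ({row['comp_id']}.{row['atom_name']}): "
                    f"valence {total} exceeds {allowed} with no demotable "
                    f"double bond")

            def partner_rank(bond_row):
                other = int(bond_row["atom_b"] if bond_row["atom_a"] == uid
                            else bond_row["atom_a"])
                el = str(idx.loc[other, "element"]).upper()
                return {"O": 0, "N": 1}.get(el, 2)

            ranked = doubles.assign(
                _rank=[partner_rank(r) for _, r in doubles.iterrows()])
            target = ranked.sort_values("_rank").index[0]
            table.bonds.loc[target, "order"] = "single"
            changed.append((uid, int(b.loc[target, "atom_a"]),
                            int(b.loc[target, "atom_b"])))
            total -= 1.0
    if changed:
        _report(out, "correct_bond_order", demoted=changed)
    return out


# ---------------------------------------------------------------------------
# 5. formal charges


def assign_formal_charges(state: PipelineState,
                          components: dict[str, ComponentDefinition] | None = None,
                          valences: dict = DEFAULT_VALENCES) -> PipelineState:
    """Set formal charges from bond orders and (implicit) hydrogen counts.

    charge = (bond-order sum + implicit H) - allowed valence, where the
    allowed valence is the element's closest permitted bonding state; an
    under-valent oxygen reads -1 (carboxylate), a four-coordinate nitrogen
    +1. Unbonded atoms (free ions, waters before bond attachment) keep their
    deposited charge. Elements absent from the valence table raise.
    """
    out = state.copy()
    table = out.table
    if table.bonds.empty:
        return out
    bonded_uids = set(table.bonds["atom_a"]) | set(table.bonds["atom_b"])
    links = _linkage_sites(table)
    charges = {}
    for _, row in table.atoms.iterrows():
        uid = int(row["atom_uid"])
        if uid not in bonded_uids:
            continue
        element = str(row["element"]).upper()
        if element == "H":
            continue
        if element not in valences:
            raise KeyError(f"element {element!r} missing from valence table")
        comp = (components or {}).get(row["comp_id"])
        total = _order_sum(table, uid) + \
            _implicit_h(comp, row["atom_name"], uid in links)
        cands = sorted(valences[element], key=lambda v: (abs(total - v), v))
        charges[uid] = int(round(total - cands[0]))
    mask = table.atoms["atom_uid"].isin(charges)
    table.atoms.loc[mask, "formal_charge"] = \
        table.atoms.loc[mask, "atom_uid"].map(charges).astype(int)
    _report(out, "assign_formal_charges", changed=sorted(charges))
    return out


# ---------------------------------------------------------------------------
# 6. ligands at symmetry centers


def deduplicate_symmetry_ligands(state: PipelineState,
                                 centroid_tol: float = 1.0) -> PipelineState:
    """Collapse duplicate partial-occupancy ligand copies at special positions.

    Non-polymer residues sharing a comp_id, each with mean occupancy <= 0.5
    and centroids within ``centroid_tol`` Angstrom, are reduced to a single
    copy: the highest mean occupancy wins, ties go to the lowest res_index.
    Full-occupancy or well-separated copies are untouched. Idempotent.
    """
    out = state.copy()
    atoms = out.table.atoms
    lig = atoms[(~atoms["is_polymer"]) & atoms["is_resolved"]]
    drop: list[int] = []
    for comp_id, group in lig.groupby("comp_id", sort=False):
        residues = []
        for (chain, res), g in group.groupby(["chain_id", "res_index"],
                                             sort=False):
            occ = float(g["occupancy"].mean())
            centroid = g[["x", "y", "z"]].to_numpy(float).mean(axis=0)
            residues.append({"chain": chain, "res": res, "occ": occ,
                             "centroid": centroid,
                             "uids": [int(u) for u in g["atom_uid"]]})
        cand = [r for r in residues if r["occ"] <= 0.5]
        if len(cand) < 2:
            continue
        # union-find over centroid proximity
        parent = list(range(len(cand)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(cand)):
            for j in range(i + 1, len(cand)):
                if np.linalg.norm(cand[i]["centroid"] - cand[j]["centroid"]) \
                        <= centroid_tol:
                    parent[find(i)] = find(j)
        groups = defaultdict(list)
        for i in range(len(cand)):
            groups[find(i)].append(cand[i])
        for members in groups.values():
            if len(members) < 2:
                continue
            members.sort(key=lambda r: (-r["occ"], r["res"]))
            for loser in members[1:]:
                drop.extend(loser["uids"])
    out = delete_atoms(out, drop)
    _report(out, "deduplicate_symmetry_ligands", deleted=drop)
    return out


# ---------------------------------------------------------------------------
# 7. missing-coordinate imputation


def impute_missing_intra_residue(state: PipelineState,
                                 components: dict[str, ComponentDefinition]
                                 ) -> PipelineState:
    """Place missing heavy atoms by rigid superposition of ideal coordinates.

    For each residue with at least three resolved heavy atoms shared with its
    component's ideal coordinates, the ideal fragment is least-squares
    superposed onto the resolved atoms and the missing heavy atoms are placed
    from it. Placed atoms are flagged unresolved with an ``imputed``
    annotation. Residues with fewer than three shared atoms are reported in
    ``extras['imputation_skipped']`` and left unchanged.
    """
    out = state.copy()
    table = out.table
    skipped = []
    new_atoms = []
    filled: dict[int, np.ndarray] = {}
    for (chain, res), group in table.residues():
        comp_id = group["comp_id"].iloc[0]
        comp = components.get(comp_id)
        if comp is None:
            raise KeyError(f"no component definition for {comp_id}")
        ideal = comp.ideal_coords()
        resolved = group[group["is_resolved"] &
                         np.isfinite(group[["x", "y", "z"]].to_numpy(float))
                         .all(axis=1)]
        shared = [n for n in resolved["atom_name"] if n in ideal]
        heavy_target = set(comp.heavy_atom_names(include_leaving=False))
        have = set(resolved["atom_name"])
        placeholders = group[~group["is_resolved"]]
        missing_names = (heavy_target - set(group["atom_name"])) | \
            set(placeholders["atom_name"])
        missing_names = {n for n in missing_names if n in ideal}
        if not missing_names:
            continue
        if len(shared) < 3:
            skipped.append((chain, int(res), comp_id))
            continue
        res_xyz = resolved.set_index("atom_name")
        mobile = np.array([ideal[n] for n in shared])
        target = res_xyz.loc[shared, ["x", "y", "z"]].to_numpy(float)
        R, t = kabsch(mobile, target)
        ph_by_name = dict(zip(placeholders["atom_name"],
                              placeholders["atom_uid"]))
        for name in sorted(missing_names):
            pos = ideal[name] @ R.T + t
            if name in ph_by_name:
                filled[int(ph_by_name[name])] = pos
            else:
                new_atoms.append({
                    "chain_id": chain, "res_index": int(res),
                    "entity_id": int(group["entity_id"].iloc[0]),
                    "comp_id": comp_id, "atom_name": name,
                    "element": comp.atom_map[name].element.upper(),
                    "occupancy": 0.0, "x": pos[0], "y": pos[1], "z": pos[2],
                    "is_resolved": False,
                    "is_polymer": bool(group["is_polymer"].iloc[0]),
                    "annot": "imputed",
                })
    if filled:
        atoms = table.atoms
        for uid, pos in filled.items():
            m = atoms["atom_uid"] == uid
            atoms.loc[m, ["x", "y", "z"]] = pos
            atoms.loc[m, "annot"] = "imputed"
    if new_atoms:
        table.add_atoms(new_atoms)
    out.extras["imputation_skipped"] = skipped
    _report(out, "impute_missing", placed=len(new_atoms) + len(filled),
            skipped=skipped)
    return out


# ---------------------------------------------------------------------------
# canonical ordering


def sanitize_state(state: PipelineState,
                   components: dict[str, ComponentDefinition],
                   infer_covalent: bool = False,
                   impute: bool = True) -> PipelineState:
    """Run the full standardization chain in its canonical order.

    Order matters: links must exist before leaving groups can be identified,
    leaving groups must depart before valences are audited (a peptide bond
    is satisfied by losing OXT, not by demoting C=O), and charges are
    assigned only once bond orders are final.
    """
    from .io import attach_intra_component_bonds
    out = resolve_altlocs(state)
    out = attach_intra_component_bonds(out, components)
    out = detect_covalent_links(out, infer_by_distance=infer_covalent)
    out = remove_leaving_groups(out, components)
    out = correct_bond_order_after_addition(out, components)
    out = assign_formal_charges(out, components)
    out = deduplicate_symmetry_ligands(out)
    if impute:
        out = impute_missing_intra_residue(out, components)
    return out


# ---------------------------------------------------------------------------
# transform registration (component dictionary flows through extras)


def _components_from_extras(state: PipelineState):
    comps = state.extras.get("component_dictionary")
    if comps is None:
        raise KeyError("extras['component_dictionary'] required; run the "
                       "'load_components' transform first")
    return comps


@register_transform("load_components", writes=("component_dictionary",))
def load_components_transform(state: PipelineState, path: str) -> PipelineState:
    from .io import read_component_dictionary
    out = state.copy()
    out.extras["component_dictionary"] = read_component_dictionary(path)
    return out


@register_transform("remove_leaving_groups", reads=("component_dictionary",))
def _remove_leaving_groups_transform(state):
    return remove_leaving_groups(state, _components_from_extras(state))


@register_transform("attach_intra_component_bonds",
                    reads=("component_dictionary",))
def _attach_bonds_transform(state):
    from .io import attach_intra_component_bonds
    return attach_intra_component_bonds(state, _components_from_extras(state))


@register_transform("correct_bond_order_after_addition",
                    reads=("component_dictionary",))
def _correct_bond_order_transform(state):
    return correct_bond_order_after_addition(
        state, state.extras.get("component_dictionary"))


@register_transform("assign_formal_charges", reads=("component_dictionary",))
def _assign_charges_transform(state):
    return assign_formal_charges(
        state, state.extras.get("component_dictionary"))


@register_transform("deduplicate_symmetry_ligands")
def _dedup_transform(state, centroid_tol=1.0):
    return deduplicate_symmetry_ligands(state, centroid_tol)


@register_transform("impute_missing_intra_residue",
                    reads=("component_dictionary",))
def _impute_transform(state):
    return impute_missing_intra_residue(state, _components_from_extras(state))
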