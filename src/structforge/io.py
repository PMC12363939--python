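"""mmCIF / PDB structure ingestion and CCD-style component dictionaries.

Parsing and serialization are backed by gemmi's CIF reader at the category
level; supported categories are ``atom_site``, ``struct_conn``,
``entity_poly_seq`` plus ``chem_comp_atom`` / ``chem_comp_bond`` for component
dictionaries. All other categories are ignored with a debug log.

Unresolved polymer residues — present in ``entity_poly_seq`` but absent from
``atom_site`` — are appended as placeholder atoms with ``is_resolved`` False
and missing coordinates so that downstream imputation and disorder extension
have slots to fill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from ._chemdata import ATOMIC_NUMBERS
from .core import AtomTable, PipelineState

logger = logging.getLogger("structforge")

_CCD_ORDER = {"SING": "single", "DOUB": "double", "TRIP": "triple",
              "AROM": "aromatic", "single": "single", "double": "double",
              "triple": "triple", "aromatic": "aromatic"}
_ORDER_CCD = {"single": "SING", "double": "DOUB", "triple": "TRIP",
              "aromatic": "AROM"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class FormatError(ValueError):
    """Structure file does not contain the required categories."""


@dataclass
class ComponentAtom:
    name: str
    element: str
    formal_charge: int = 0
    ideal: np.ndarray | None = None
    is_leaving: bool = False


@dataclass
class ComponentBond:
    atom_a: str
    atom_b: str
    order: str = "single"
    is_aromatic: bool = False


@dataclass
class ComponentDefinition:
    """Per-residue chemical template: atoms, bonds, ideal coordinates and
    leaving-atom flags, mirroring CCD conventions."""

    comp_id: str
    atoms: list[ComponentAtom] = field(default_factory=list)
    bonds: list[ComponentBond] = field(default_factory=list)

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.comp_id}: duplicate atom names")
        for b in self.bonds:
            if b.atom_a not in names or b.atom_b not in names:
                raise ValueError(
                    f"{self.comp_id}: bond references unknown atom "
                    f"{b.atom_a}-{b.atom_b}")

    @property
    def atom_map(self) -> dict[str, ComponentAtom]:
        return {a.name: a for a in self.atoms}

    def heavy_atom_names(self, include_leaving: bool = True) -> list[str]:
        return [a.name for a in self.atoms if a.element.upper() != "H"
                and (include_leaving or not a.is_leaving)]

    def neighbors(self, name: str) -> list[str]:
        out = []
        for b in self.bonds:
            if b.atom_a == name:
                out.append(b.atom_b)
            elif b.atom_b == name:
                out.append(b.atom_a)
        return out

    def implicit_h_count(self, name: str) -> int:
        amap = self.atom_map
        return sum(1 for n in self.neighbors(name)
                   if amap[n].element.upper() == "H")

    def ideal_coords(self) -> dict[str, np.ndarray]:
        return {a.name: a.ideal for a in self.atoms if a.ideal is not None}


# ---------------------------------------------------------------------------
# struct_conn records


@dataclass
class StructConnRecord:
    """One inter-residue linkage from the ``struct_conn`` category."""

    conn_type: str  # covale | disulf | metalc
    partner1: tuple[str, int, str]  # (chain_id, res_index, atom_name)
    partner2: tuple[str, int, str]
    order: str | None = None


# ---------------------------------------------------------------------------
# mmCIF reading


def _cell(value: str) -> str:
    if value is None:
        return ""
    v = gemmi.cif.as_string(value)
    return "" if v in (".", "?") else v


def read_mmcif(path, components: dict[str, ComponentDefinition] | None = None,
               rng_seed: int = 0) -> PipelineState:
    """Parse an mmCIF file into a pipeline state.

    One atom row per ``atom_site`` record, altlocs preserved; ``struct_conn``
    records are parsed into ``extras['struct_conn_records']``. When
    ``components`` is given, placeholder atoms for unresolved polymer
    residues carry the component's full non-leaving heavy-atom set; otherwise
    the standard protein backbone (N, CA, C, O).
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    site = block.find("_atom_site.", [
        "label_atom_id", "label_comp_id", "label_asym_id", "label_seq_id",
        "type_symbol", "Cartn_x", "Cartn_y", "Cartn_z",
        "?label_alt_id", "?occupancy", "?label_entity_id", "?auth_seq_id",
        "?pdbx_formal_charge", "?group_PDB",
    ])
    if len(site) == 0:
        raise FormatError(f"{path}: no atom_site category")

    records = []
    for i, row in enumerate(site):
        element = _cell(row[4]).upper()
        if element not in ATOMIC_NUMBERS:
            raise FormatError(
                f"{path}: unknown element symbol {element!r} in atom_site "
                f"row {i + 1}")
        seq = _cell(row[3])
        auth_seq = _cell(row[11]) if row.has(11) else ""
        is_polymer = seq != ""
        res_index = int(seq) if is_polymer else int(auth_seq or 0)
        entity = _cell(row[10]) if row.has(10) else ""
        charge = _cell(row[12]) if row.has(12) else ""
        records.append({
            "chain_id": _cell(row[1 + 1]),
            "entity_id": int(entity) if entity else 1,
            "res_index": res_index,
            "comp_id": _cell(row[1]),
            "atom_name": _cell(row[0]),
            "element": element,
            "altloc": _cell(row[8]) if row.has(8) else "",
            "occupancy": float(_cell(row[9]) or 1.0) if row.has(9) else 1.0,
            "formal_charge": int(charge) if charge not in ("", "?") else 0,
            "x": float(row[5]), "y": float(row[6]), "z": float(row[7]),
            "is_resolved": True,
            "is_polymer": is_polymer,
            "annot": "",
        })
    table = AtomTable.from_records(records)

    _append_unresolved(table, block, components)

    extras: dict = {}
    conns = _read_struct_conn(block)
    if conns:
        extras["struct_conn_records"] = conns
    state = PipelineState(table=table, extras=extras, rng_seed=rng_seed)
    state.table.validate()
    return state


def _append_unresolved(table: AtomTable, block,
                       components: dict[str, ComponentDefinition] | None):
    poly = block.find("_entity_poly_seq.", ["entity_id", "num", "mon_id"])
    if len(poly) == 0:
        return
    seq_by_entity: dict[int, list[tuple[int, str]]] = {}
    for row in poly:
        seq_by_entity.setdefault(int(_cell(row[0])), []).append(
            (int(_cell(row[1])), _cell(row[2])))
    atoms = table.atoms
    chains = atoms.loc[atoms["is_polymer"]]\
        .groupby("chain_id")["entity_id"].first()
    new_records = []
    for chain_id, entity_id in chains.items():
        present = set(atoms.loc[(atoms["chain_id"] == chain_id),
                                "res_index"])
        for num, mon in seq_by_entity.get(int(entity_id), []):
            if num in present:
                continue
            if components and mon in components:
                names = components[mon].heavy_atom_names(include_leaving=False)
                elements = [components[mon].atom_map[n].element.upper()
                            for n in names]
            else:
                names = list(BACKBONE_ATOMS)
                elements = ["N", "C", "C", "O"]
            for name, element in zip(names, elements):
                new_records.append({
                    "chain_id": chain_id, "entity_id": int(entity_id),
                    "res_index": num, "comp_id": mon, "atom_name": name,
                    "element": element, "occupancy": 0.0,
                    "is_resolved": False, "is_polymer": True,
                })
    if new_records:
        table.add_atoms(new_records)


def _read_struct_conn(block) -> list[StructConnRecord]:
    conn = block.find("_struct_conn.", [
        "conn_type_id",
        "ptnr1_label_asym_id", "?ptnr1_label_seq_id", "ptnr1_label_atom_id",
        "ptnr2_label_asym_id", "?ptnr2_label_seq_id", "ptnr2_label_atom_id",
        "?ptnr1_auth_seq_id", "?ptnr2_auth_seq_id", "?pdbx_value_order",
    ])
    records = []
    for row in conn:
        def seqno(label_i, auth_i):
            v = _cell(row[label_i]) if row.has(label_i) else ""
            if not v and row.has(auth_i):
                v = _cell(row[auth_i])
            return int(v) if v else 0
        order = _cell(row[9]).lower() if row.has(9) else ""
        records.append(StructConnRecord(
            conn_type=_cell(row[0]).lower(),
            partner1=(_cell(row[1]), seqno(2, 7), _cell(row[3])),
            partner2=(_cell(row[4]), seqno(5, 8), _cell(row[6])),
            order=_CCD_ORDER.get(order.upper(), None) if order else None,
        ))
    return records


# ---------------------------------------------------------------------------
# mmCIF writing


def _is_backbone_link(table: AtomTable, a_uid: int, b_uid: int) -> bool:
    a = table.row_by_uid(a_uid)
    b = table.row_by_uid(b_uid)
    if a["chain_id"] != b["chain_id"]:
        return False
    pair = {(a["atom_name"], b["atom_name"]), (b["atom_name"], a["atom_name"])}
    linked = {("C", "N"), ("O3'", "P")}
    return abs(int(a["res_index"]) - int(b["res_index"])) == 1 and \
        bool(pair & linked)


def write_mmcif(state: PipelineState, path, block_name: str = "structforge") -> None:
    """Serialize the atom table to mmCIF (atom_site + struct_conn +
    entity_poly_seq). Atoms without coordinates are omitted from atom_site
    but retained in entity_poly_seq so a round-trip recreates them."""
    table = state.table
    atoms = table.atoms
    writable = atoms[np.isfinite(atoms[["x", "y", "z"]].to_numpy(float)).all(axis=1)]
    if writable.empty:
        raise ValueError("refusing to write a structure with no placed atoms")

    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)

    loop = block.init_loop("_atom_site.", [
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
        "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "pdbx_formal_charge",
        "auth_seq_id", "auth_asym_id",
    ])
    for _, r in writable.iterrows():
        loop.add_row([
            "ATOM" if r["is_polymer"] else "HETATM",
            str(int(r["atom_uid"])),
            r["element"],
            gemmi.cif.quote(r["atom_name"]),
            r["altloc"] or ".",
            r["comp_id"],
            r["chain_id"],
            str(int(r["entity_id"])),
            str(int(r["res_index"])) if r["is_polymer"] else ".",
            f"{r['x']:.4f}", f"{r['y']:.4f}", f"{r['z']:.4f}",
            f"{r['occupancy']:.3f}",
            str(int(r["formal_charge"])) if r["formal_charge"] else "0",
            str(int(r["res_index"])),
            r["chain_id"],
        ])

    poly = atoms[atoms["is_polymer"]]
    if not poly.empty:
        ploop = block.init_loop("_entity_poly_seq.", ["entity_id", "num", "mon_id"])
        seen = poly.drop_duplicates(["entity_id", "res_index"])\
            .sort_values(["entity_id", "res_index"])
        for _, r in seen.iterrows():
            ploop.add_row([str(int(r["entity_id"])), str(int(r["res_index"])),
                           r["comp_id"]])

    conn_rows = []
    seen_pairs = set()
    for _, b in table.bonds.iterrows():
        if b["provenance"] == "struct_conn" or (
                b["provenance"] == "inferred" and
                not _is_backbone_link(table, b["atom_a"], b["atom_b"])):
            ra = table.row_by_uid(b["atom_a"])
            rb = table.row_by_uid(b["atom_b"])
            conn_type = "disulf" if (ra["element"] == "S" and rb["element"] == "S") \
                else "covale"
            conn_rows.append((conn_type, ra, rb, b["order"]))
            seen_pairs.add(frozenset([int(b["atom_a"]), int(b["atom_b"])]))
    # struct_conn records parsed at ingestion but not (yet) turned into bonds
    for rec in state.extras.get("struct_conn_records", []):
        atoms_all = table.atoms

        def _find(partner):
            chain, res, name = partner
            sel = atoms_all[(atoms_all["chain_id"] == chain) &
                            (atoms_all["res_index"] == res) &
                            (atoms_all["atom_name"] == name)]
            return sel.iloc[0] if not sel.empty else None

        ra = _find(rec.partner1)
        rb = _find(rec.partner2)
        if ra is None or rb is None:
            continue
        pair = frozenset([int(ra["atom_uid"]), int(rb["atom_uid"])])
        if pair in seen_pairs:
            continue
        conn_rows.append((rec.conn_type, ra, rb, rec.order or "single"))
        seen_pairs.add(pair)
    if conn_rows:
        cloop = block.init_loop("_struct_conn.", [
            "id", "conn_type_id",
            "ptnr1_label_asym_id", "ptnr1_label_seq_id", "ptnr1_label_atom_id",
            "ptnr2_label_asym_id", "ptnr2_label_seq_id", "ptnr2_label_atom_id",
            "ptnr1_auth_seq_id", "ptnr2_auth_seq_id", "pdbx_value_order",
        ])
        for i, (conn_type, ra, rb, order) in enumerate(conn_rows):
            cloop.add_row([
                f"conn{i + 1}", conn_type,
                ra["chain_id"],
                str(int(ra["res_index"])) if ra["is_polymer"] else ".",
                gemmi.cif.quote(ra["atom_name"]),
                rb["chain_id"],
                str(int(rb["res_index"])) if rb["is_polymer"] else ".",
                gemmi.cif.quote(rb["atom_name"]),
                str(int(ra["res_index"])), str(int(rb["res_index"])),
                _ORDER_CCD.get(order, "SING"),
            ])
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# PDB reading (read-only convenience path)


def read_pdb(path, rng_seed: int = 0) -> PipelineState:
    """Read a PDB-format file. SSBOND/LINK records become struct_conn-style
    records; no further connectivity is inferred."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    records = []
    for model in st:
        for chain in model:
            for ri, res in enumerate(chain):
                for atom in res:
                    element = atom.element.name.upper()
                    records.append({
                        "chain_id": chain.name,
                        "entity_id": 1,
                        "res_index": res.seqid.num,
                        "comp_id": res.name,
                        "atom_name": atom.name,
                        "element": element,
                        "altloc": atom.altloc or "",
                        "occupancy": float(atom.occ),
                        "formal_charge": int(atom.charge),
                        "x": atom.pos.x, "y": atom.pos.y, "z": atom.pos.z,
                        "is_resolved": True,
                        "is_polymer": res.is_amino_acid() or res.is_nucleic_acid(),
                        "annot": "",
                    })
        break  # first model only
    table = AtomTable.from_records(records)
    conns = []
    for con in st.connections:
        conn_type = {gemmi.ConnectionType.Disulf: "disulf",
                     gemmi.ConnectionType.Covale: "covale",
                     gemmi.ConnectionType.MetalC: "metalc"}.get(con.type, "covale")
        conns.append(StructConnRecord(
            conn_type=conn_type,
            partner1=(con.partner1.chain_name, con.partner1.res_id.seqid.num,
                      con.partner1.atom_name),
            partner2=(con.partner2.chain_name, con.partner2.res_id.seqid.num,
                      con.partner2.atom_name)))
    extras = {"struct_conn_records": conns} if conns else {}
    return PipelineState(table=table, extras=extras, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Component dictionaries


def read_component_dictionary(path) -> dict[str, ComponentDefinition]:
    """Parse a CCD-style CIF into a map comp_id -> ComponentDefinition.

    Leaving flags come from ``pdbx_leaving_atom_flag``; ideal coordinates
    from ``pdbx_model_Cartn_*_ideal`` when present. An empty file yields an
    empty map with a warning.
    """
    doc = gemmi.cif.read(str(path))
    out: dict[str, ComponentDefinition] = {}
    for block in doc:
        atoms_loop = block.find("_chem_comp_atom.", [
            "comp_id", "atom_id", "type_symbol", "?charge",
            "?pdbx_model_Cartn_x_ideal", "?pdbx_model_Cartn_y_ideal",
            "?pdbx_model_Cartn_z_ideal", "?pdbx_leaving_atom_flag",
        ])
        if len(atoms_loop) == 0:
            continue
        atoms: list[ComponentAtom] = []
        comp_id = ""
        for row in atoms_loop:
            comp_id = _cell(row[0])
            ideal = None
            if row.has(4) and _cell(row[4]) != "":
                ideal = np.array([float(row[4]), float(row[5]), float(row[6])])
            charge = _cell(row[3]) if row.has(3) else ""
            atoms.append(ComponentAtom(
                name=_cell(row[1]),
                element=_cell(row[2]).upper(),
                formal_charge=int(charge) if charge else 0,
                ideal=ideal,
                is_leaving=(row.has(7) and _cell(row[7]).upper() == "Y"),
            ))
        bonds: list[ComponentBond] = []
        bonds_loop = block.find("_chem_comp_bond.", [
            "comp_id", "atom_id_1", "atom_id_2", "?value_order",
            "?pdbx_aromatic_flag",
        ])
        for row in bonds_loop:
            raw_order = (_cell(row[3]) if row.has(3) else "SING").upper()
            if raw_order not in _CCD_ORDER:
                raise ValueError(
                    f"{comp_id}: unknown bond order {raw_order!r}")
            bonds.append(ComponentBond(
                atom_a=_cell(row[1]), atom_b=_cell(row[2]),
                order=_CCD_ORDER[raw_order],
                is_aromatic=(row.has(4) and _cell(row[4]).upper() == "Y"),
            ))
        out[comp_id] = ComponentDefinition(comp_id, atoms, bonds)
    if not out:
        logger.warning("component dictionary %s contains no components", path)
    return out


def write_component_dictionary(components: dict[str, ComponentDefinition],
                               path) -> None:
    """Emit components as CCD-style CIF (inverse of
    :func:`read_component_dictionary`)."""
    doc = gemmi.cif.Document()
    for comp_id, comp in components.items():
        block = doc.add_new_block(comp_id)
        loop = block.init_loop("_chem_comp_atom.", [
            "comp_id", "atom_id", "type_symbol", "charge",
            "pdbx_model_Cartn_x_ideal", "pdbx_model_Cartn_y_ideal",
            "pdbx_model_Cartn_z_ideal", "pdbx_leaving_atom_flag",
        ])
        for a in comp.atoms:
            xyz = (["?"] * 3 if a.ideal is None
                   else [f"{v:.4f}" for v in a.ideal])
            loop.add_row([comp_id, gemmi.cif.quote(a.name), a.element,
                          str(a.formal_charge), *xyz,
                          "Y" if a.is_leaving else "N"])
        bloop = block.init_loop("_chem_comp_bond.", [
            "comp_id", "atom_id_1", "atom_id_2", "value_order",
            "pdbx_aromatic_flag",
        ])
        for b in comp.bonds:
            bloop.add_row([comp_id, gemmi.cif.quote(b.atom_a),
                           gemmi.cif.quote(b.atom_b), _ORDER_CCD[b.order],
                           "Y" if b.is_aromatic else "N"])
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# Bond attachment


def attach_intra_component_bonds(state: PipelineState,
                                 components: dict[str, ComponentDefinition]
                                 ) -> PipelineState:
    """Add intra-residue bonds from the component templates plus polymer
    backbone links (C-N, O3'-P) between consecutive residues of a chain.

    Bonds to atoms absent from the table (unresolved or removed) are
    skipped; a component code missing from the dictionary raises with the
    full list of missing codes.
    """
    out = state.copy()
    table = out.table
    atoms = table.atoms
    missing = sorted(set(atoms["comp_id"]) - set(components))
    if missing:
        raise KeyError(f"components missing from dictionary: {missing}")

    for (chain_id, res_index), group in table.residues():
        comp = components[group["comp_id"].iloc[0]]
        by_name = dict(zip(group["atom_name"], group["atom_uid"]))
        for b in comp.bonds:
            if b.atom_a in by_name and b.atom_b in by_name:
                order = "aromatic" if b.is_aromatic else b.order
                table.add_bond(int(by_name[b.atom_a]), int(by_name[b.atom_b]),
                               order=order, provenance="intra_component")

    poly = atoms[atoms["is_polymer"]]
    for chain_id, chain in poly.groupby("chain_id", sort=False):
        idx = dict(zip(zip(chain["res_index"], chain["atom_name"]),
                       chain["atom_uid"]))
        for res_index in sorted(chain["res_index"].unique()):
            for a_name, b_name in (("C", "N"), ("O3'", "P")):
                a = idx.get((res_index, a_name))
                b = idx.get((res_index + 1, b_name))
                if a is not None and b is not None:
                    table.add_bond(int(a), int(b), order="single",
                                   provenance="inferred")
    return out
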