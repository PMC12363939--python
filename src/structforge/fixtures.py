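"""Synthetic structure and component-dictionary generator.

Everything the test suite needs is generated programmatically here: a mini
chemical-component dictionary (a few amino acids, water, and toy ligands,
mirroring CCD conventions for leaving flags and ideal coordinates), toy
peptides with controllable torsions and local D-residue mirroring, and
minimal pathological structures where exactly one sanitization rule must
fire, each accompanied by a machine-readable expectation.

Ideal coordinates are embedded at run time with RDKit's deterministic ETKDG
from seeded SMILES, so every fixture regenerates bit-identically from its
(spec, seed) and nothing needs to be downloaded or vendored.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._geometry import kabsch, reflect_through_plane
from .core import AtomTable, PipelineState, derive_seed
from .distill import IdealGeometry, place_chain_internal
from .io import (ComponentAtom, ComponentBond, ComponentDefinition,
                 StructConnRecord, write_component_dictionary, write_mmcif)

_RD_ORDER = {Chem.BondType.SINGLE: "single", Chem.BondType.DOUBLE: "double",
             Chem.BondType.TRIPLE: "triple", Chem.BondType.AROMATIC: "aromatic"}

#: comp_id -> (smiles, heavy-atom names in SMILES order, leaving-atom names)
_COMPONENT_SPECS: dict[str, tuple[str, list[str], set[str]]] = {
    "ALA": ("N[C@@H](C)C(=O)O", ["N", "CA", "CB", "C", "O", "OXT"],
            {"OXT", "HXT", "H2"}),
    "GLY": ("NCC(=O)O", ["N", "CA", "C", "O", "OXT"], {"OXT", "HXT", "H2"}),
    "CYS": ("N[C@@H](CS)C(=O)O", ["N", "CA", "CB", "SG", "C", "O", "OXT"],
            {"OXT", "HXT", "H2", "HG"}),
    "SER": ("N[C@@H](CO)C(=O)O", ["N", "CA", "CB", "OG", "C", "O", "OXT"],
            {"OXT", "HXT", "H2"}),
    "HOH": ("O", ["O"], set()),
    # toy triol ligand with three stereocenters (C1, C2, C3)
    "LIG": ("N[C@@H](O)[C@H](O)[C@@H](O)F",
            ["N1", "C1", "O1", "C2", "O2", "C3", "O3", "F1"], set()),
    "ETH": ("CCO", ["C1", "C2", "O1"], set()),
    # methyl ketone: carbonyl carbon has no hydrogen, so a nucleophilic
    # addition at C2 must demote the C2=O1 double bond
    "KET": ("CC(=O)C", ["C1", "C2", "O1", "C3"], set()),
    # acetate: O2 carries the -1 charge (no hydrogen in the template)
    "ACT": ("CC(=O)[O-]", ["C1", "C2", "O1", "O2"], set()),
    # ethylenediamine, neutral (correct) and doubly protonated (mis-charged)
    "EDN": ("NCCN", ["N1", "C1", "C2", "N2"], set()),
    "EDP": ("[NH3+]CC[NH3+]", ["N1", "C1", "C2", "N2"], set()),
}

AMINO_ACIDS = {"A": "ALA", "G": "GLY", "C": "CYS", "S": "SER"}
_H_NAME_OVERRIDES = {"N": ["H", "H2", "H3"], "OXT": ["HXT"], "SG": ["HG"],
                     "OG": ["HG"], "O": ["H1", "H2"]}
PATHOLOGICAL_CASES = ("altloc", "leaving_group", "covalent_ligand",
                      "symmetry_ligand", "unresolved_region",
                      "miscounted_charge")


def _h_names(parent: str, count: int) -> list[str]:
    if parent in _H_NAME_OVERRIDES:
        return _H_NAME_OVERRIDES[parent][:count]
    suffix = parent[1:] if len(parent) > 1 else parent
    # amino-acid style (CA -> HA); ligand style keeps the element (C1 -> HC1)
    base = "H" + (suffix if suffix.isalpha() else parent)
    if count == 1:
        return [base]
    return [f"{base}{i + 1}" for i in range(count)]


def _build_component(comp_id: str, smiles: str, heavy_names: list[str],
                     leaving: set[str], seed: int) -> ComponentDefinition:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"{comp_id}: bad SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = derive_seed(seed, f"component:{comp_id}")
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"{comp_id}: embedding failed")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()

    names: dict[int, str] = {}
    n_heavy = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            names[atom.GetIdx()] = heavy_names[n_heavy]
            n_heavy += 1
    assert n_heavy == len(heavy_names), f"{comp_id}: heavy-atom name mismatch"
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            hs = [nb.GetIdx() for nb in atom.GetNeighbors()
                  if nb.GetAtomicNum() == 1]
            for h_idx, h_name in zip(hs, _h_names(names[atom.GetIdx()],
                                                  len(hs))):
                names[h_idx] = h_name

    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        name = names[atom.GetIdx()]
        atoms.append(ComponentAtom(
            name=name, element=atom.GetSymbol().upper(),
            formal_charge=atom.GetFormalCharge(),
            ideal=np.array([pos.x, pos.y, pos.z]),
            is_leaving=name in leaving))
    bonds = [ComponentBond(names[b.GetBeginAtomIdx()], names[b.GetEndAtomIdx()],
                           _RD_ORDER[b.GetBondType()], b.GetIsAromatic())
             for b in mol.GetBonds()]
    return ComponentDefinition(comp_id, atoms, bonds)


@lru_cache(maxsize=8)
def make_components(seed: int = 0) -> dict[str, ComponentDefinition]:
    """The bundled mini component dictionary (deterministic per seed)."""
    return {cid: _build_component(cid, *spec, seed=seed)
            for cid, spec in _COMPONENT_SPECS.items()}


# ---------------------------------------------------------------------------
# ligand / component states


def component_state(comp: ComponentDefinition, chain_id: str = "L",
                    res_index: int = 1, coords: dict | None = None,
                    rng_seed: int = 0) -> PipelineState:
    """One-residue heavy-atom state for a component (ideal coords by
    default), with intra-component bonds attached."""
    coords = coords or comp.ideal_coords()
    records = []
    for a in comp.atoms:
        if a.element.upper() == "H" or a.name not in coords:
            continue
        x, y, z = coords[a.name]
        records.append({
            "chain_id": chain_id, "res_index": res_index,
            "comp_id": comp.comp_id, "atom_name": a.name,
            "element": a.element.upper(), "formal_charge": a.formal_charge,
            "x": x, "y": y, "z": z, "is_polymer": False,
        })
    table = AtomTable.from_records(records)
    by_name = dict(zip(table.atoms["atom_name"], table.atoms["atom_uid"]))
    for b in comp.bonds:
        if b.atom_a in by_name and b.atom_b in by_name:
            table.add_bond(int(by_name[b.atom_a]), int(by_name[b.atom_b]),
                           order="aromatic" if b.is_aromatic else b.order)
    return PipelineState(table=table, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# toy peptides


def make_toy_peptide(sequence: str, d_positions=(), torsions=(-57.0, -47.0, 180.0),
                     seed: int = 0, chain_id: str = "A",
                     include_oxt: str = "terminal", unresolved=(),
                     ) -> tuple[PipelineState, dict[str, ComponentDefinition]]:
    """Heavy-atom peptide built by the internal-coordinate chain builder.

    ``sequence`` uses one-letter codes over the bundled amino acids;
    1-based ``d_positions`` are mirrored locally at CA (side chain reflected
    through the N-CA-C plane) so their chiral sign is opposite the L form.
    ``torsions`` is a (phi, psi, omega) triple, default alpha-helical.
    ``include_oxt`` is 'terminal', 'all' or 'none'.
    """
    comps = make_components(seed)
    try:
        comp_ids = [AMINO_ACIDS[c] for c in sequence]
    except KeyError as exc:
        raise KeyError(f"unknown residue code {exc.args[0]!r}; "
                       f"known: {sorted(AMINO_ACIDS)}") from None
    n = len(comp_ids)
    phi, psi, omega = torsions
    geometry = IdealGeometry(phi=phi, psi=psi, omega=omega)
    backbone = place_chain_internal(geometry, n)

    records = []
    for i, comp_id in enumerate(comp_ids):
        comp = comps[comp_id]
        ideal = comp.ideal_coords()
        placed = {"N": backbone[i, 0], "CA": backbone[i, 1],
                  "C": backbone[i, 2]}
        mobile = np.array([ideal[nm] for nm in ("N", "CA", "C")])
        R, t = kabsch(mobile, np.array([placed[nm] for nm in ("N", "CA", "C")]))
        want_oxt = include_oxt == "all" or \
            (include_oxt == "terminal" and i == n - 1)
        for name in comp.heavy_atom_names():
            if name in placed:
                continue
            if name == "OXT" and not want_oxt:
                continue
            placed[name] = ideal[name] @ R.T + t
        if (i + 1) in set(d_positions):
            side = [nm for nm in placed
                    if nm not in ("N", "CA", "C", "O", "OXT")]
            if side:
                pts = np.array([placed[nm] for nm in side])
                mirrored = reflect_through_plane(
                    pts, placed["N"], placed["CA"], placed["C"])
                for nm, p in zip(side, mirrored):
                    placed[nm] = p
        for name, pos in placed.items():
            records.append({
                "chain_id": chain_id, "res_index": i + 1, "comp_id": comp_id,
                "atom_name": name,
                "element": comp.atom_map[name].element.upper(),
                "x": pos[0], "y": pos[1], "z": pos[2], "is_polymer": True,
            })
    state = PipelineState(table=AtomTable.from_records(records),
                          rng_seed=seed)
    if unresolved:
        atoms = state.table.atoms
        m = atoms["res_index"].isin(set(unresolved))
        atoms.loc[m, ["x", "y", "z"]] = np.nan
        atoms.loc[m, "is_resolved"] = False
        atoms.loc[m, "occupancy"] = 0.0
    return state, comps


def perturb_structure(state: PipelineState, sigma: float,
                      seed: int = 0) -> PipelineState:
    """Add seeded isotropic Gaussian noise to resolved coordinates."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = state.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(derive_seed(seed, "perturb_structure"))
    atoms = out.table.atoms
    mask = atoms["is_resolved"].to_numpy(bool)
    xyz = atoms[["x", "y", "z"]].to_numpy(float)
    xyz[mask] += rng.normal(0.0, sigma, (mask.sum(), 3))
    out.table.set_coords(xyz)
    return out


# ---------------------------------------------------------------------------
# pathological cases


def _add_ligand(state: PipelineState, comp: ComponentDefinition,
                chain_id: str, res_index: int, offset: np.ndarray,
                occupancy: float = 1.0) -> None:
    ideal = comp.ideal_coords()
    records = []
    for name in comp.heavy_atom_names():
        pos = ideal[name] + offset
        records.append({
            "chain_id": chain_id, "res_index": res_index,
            "comp_id": comp.comp_id, "atom_name": name,
            "element": comp.atom_map[name].element.upper(),
            "occupancy": occupancy,
            "x": pos[0], "y": pos[1], "z": pos[2], "is_polymer": False,
        })
    state.table.add_atoms(records)


def make_pathological_case(case: str, seed: int = 0
                           ) -> tuple[PipelineState,
                                      dict[str, ComponentDefinition], dict]:
    """Minimal structure where exactly one sanitization rule must fire.

    Returns (state, components, expectation); the expectation dict is
    machine-readable and states which atoms the rule must change.
    """
    comps = make_components(seed)
    if case == "altloc":
        state, _ = make_toy_peptide("AAA", seed=seed)
        atoms = state.table.atoms
        m = (atoms["res_index"] == 2) & (atoms["atom_name"] == "CB")
        atoms.loc[m, ["altloc", "occupancy"]] = ["A", 0.6]
        cb = atoms.loc[m, ["x", "y", "z"]].to_numpy(float)[0]
        state.table.add_atoms([{
            "chain_id": "A", "res_index": 2, "comp_id": "ALA",
            "atom_name": "CB", "element": "C", "altloc": "B",
            "occupancy": 0.4, "x": cb[0] + 0.8, "y": cb[1], "z": cb[2],
            "is_polymer": True}])
        expect = {"rule": "resolve_altlocs",
                  "deleted": [["A", 2, "CB", "B"]],
                  "kept": [["A", 2, "CB", "A"]]}
        return state, comps, expect

    if case == "leaving_group":
        state, _ = make_toy_peptide("AA", seed=seed, include_oxt="all")
        expect = {"rule": "remove_leaving_groups",
                  "deleted": [["A", 1, "OXT", ""]],
                  "kept": [["A", 2, "OXT", ""]]}
        return state, comps, expect

    if case == "covalent_ligand":
        state, _ = make_toy_peptide("ACA", seed=seed)
        atoms = state.table.atoms
        sg = atoms[(atoms["res_index"] == 2) & (atoms["atom_name"] == "SG")]
        sg_pos = sg[["x", "y", "z"]].to_numpy(float)[0]
        ket = comps["KET"]
        c2_ideal = ket.atom_map["C2"].ideal
        # put the carbonyl carbon 1.8 A from SG, ligand pointing away
        direction = sg_pos / np.linalg.norm(sg_pos) if np.linalg.norm(sg_pos) \
            else np.array([1.0, 0.0, 0.0])
        offset = sg_pos + 1.8 * direction - c2_ideal
        _add_ligand(state, ket, "L", 1, offset)
        state.extras["struct_conn_records"] = [StructConnRecord(
            conn_type="covale", partner1=("A", 2, "SG"),
            partner2=("L", 1, "C2"))]
        expect = {"rule": "detect_covalent_links+correct_bond_order",
                  "bond_added": [["A", 2, "SG"], ["L", 1, "C2"]],
                  "demoted": [["L", 1, "C2"], ["L", 1, "O1"]],
                  "charges": {"L:1:O1": -1}}
        return state, comps, expect

    if case == "symmetry_ligand":
        state, _ = make_toy_peptide("AAA", seed=seed)
        _add_ligand(state, comps["ETH"], "L", 1, np.array([12.0, 0, 0]),
                    occupancy=0.5)
        _add_ligand(state, comps["ETH"], "L", 2, np.array([12.4, 0.2, 0]),
                    occupancy=0.5)
        expect = {"rule": "deduplicate_symmetry_ligands",
                  "kept_res": ["L", 1], "deleted_res": ["L", 2]}
        return state, comps, expect

    if case == "unresolved_region":
        state, _ = make_toy_peptide("AAAAA", seed=seed)
        atoms = state.table.atoms
        m = atoms["res_index"].isin([4, 5])
        atoms.loc[m, ["x", "y", "z"]] = np.nan
        atoms.loc[m, "is_resolved"] = False
        atoms.loc[m, "occupancy"] = 0.0
        expect = {"rule": "unresolved_ingestion", "n_unresolved_residues": 2,
                  "unresolved": [["A", 4], ["A", 5]]}
        return state, comps, expect

    if case == "miscounted_charge":
        state, _ = make_toy_peptide("AAA", seed=seed)
        _add_ligand(state, comps["ACT"], "L", 1, np.array([12.0, 0, 0]))
        atoms = state.table.atoms
        atoms.loc[atoms["comp_id"] == "ACT", "formal_charge"] = 0  # the error
        expect = {"rule": "assign_formal_charges",
                  "charges": {"L:1:O2": -1}}
        return state, comps, expect

    raise ValueError(f"unknown case {case!r}; known: {PATHOLOGICAL_CASES}")


def make_pathological_cif(case: str, out_dir, seed: int = 0) -> dict:
    """Write structure + component CIFs for a pathological case; returns the
    expectation dict augmented with the file paths."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state, comps, expect = make_pathological_case(case, seed)
    structure = out_dir / f"{case}.cif"
    components = out_dir / f"{case}_components.cif"
    write_mmcif(state, structure, block_name=case)
    write_component_dictionary(comps, components)
    expect["structure"] = str(structure)
    expect["components"] = str(components)
    return expect
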