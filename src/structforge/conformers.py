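"""Reference conformer generation by embedding + force-field minimization.

A reference conformer is built from the component's chemical graph alone
(never from deposited coordinates): the graph is handed to RDKit, stereo is
perceived from the component's ideal coordinates so the embedded conformer
reproduces the template chirality, 3D coordinates are generated with the
deterministic ETKDG distance-geometry embedder, and the result is minimized
with MMFF94 (falling back to UFF when MMFF parameters are missing). Energies
are reported in kJ/mol. Erroneous charge or bond-order annotations surface
directly as force-field setup failures or inflated energies, which is what
makes conformer energy a useful end-to-end probe of sanitization quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .io import ComponentDefinition

KCAL_TO_KJ = 4.184

_BOND_TYPES = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}


class EmbeddingError(RuntimeError):
    pass


class ForceFieldError(RuntimeError):
    """Force-field setup failed — usually an upstream sanitization bug
    (bad valence, impossible charge)."""


@dataclass
class ConformerResult:
    comp_id: str
    coords: dict[str, np.ndarray]
    initial_energy: float
    final_energy: float
    converged: bool
    seed: int
    forcefield: str = "MMFF94"


def _mol_from_component(component: ComponentDefinition) -> Chem.RWMol:
    mol = Chem.RWMol()
    index = {}
    for a in component.atoms:
        atom = Chem.Atom(a.element.capitalize())
        atom.SetFormalCharge(int(a.formal_charge))
        atom.SetNoImplicit(True)
        index[a.name] = mol.AddAtom(atom)
    for b in component.bonds:
        order = "aromatic" if b.is_aromatic else b.order
        mol.AddBond(index[b.atom_a], index[b.atom_b], _BOND_TYPES[order])
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ForceFieldError(
            f"{component.comp_id}: chemistry rejected by perception "
            f"({exc}); check charges/bond orders upstream") from exc
    return mol


def _set_conformer(mol: Chem.Mol, component: ComponentDefinition,
                   coords: dict[str, np.ndarray]) -> None:
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, a in enumerate(component.atoms):
        x, y, z = (float(v) for v in coords[a.name])
        conf.SetAtomPosition(i, Point3D(x, y, z))
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)


def _forcefield(mol: Chem.Mol):
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is not None and AllChem.MMFFHasAllMoleculeParams(mol):
        ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        name = "MMFF94"
    else:
        ff = AllChem.UFFGetMoleculeForceField(mol)
        name = "UFF"
    if ff is None:
        raise ForceFieldError("force-field setup failed")
    return ff, name


def generate_reference_conformer(component: ComponentDefinition, seed: int,
                                 max_iters: int = 2000) -> ConformerResult:
    """Embed and minimize one reference conformer for a component.

    Deterministic for a fixed (component, seed). Stereocenters of the
    embedded conformer match the chirality of the component's ideal
    coordinates, enforced by perceiving chiral tags from those coordinates
    before embedding.
    """
    mol = _mol_from_component(component)
    ideal = component.ideal_coords()
    if len(ideal) == len(component.atoms):
        _set_conformer(mol, component, ideal)
        Chem.AssignStereochemistryFrom3D(mol)

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31)
    params.enforceChirality = True
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise EmbeddingError(f"{component.comp_id}: 3D embedding failed")

    ff, name = _forcefield(mol)
    initial = ff.CalcEnergy() * KCAL_TO_KJ
    not_converged = ff.Minimize(maxIts=max_iters)
    final = ff.CalcEnergy() * KCAL_TO_KJ
    conf = mol.GetConformer()
    coords = {a.name: np.array(conf.GetAtomPosition(i))
              for i, a in enumerate(component.atoms)}
    return ConformerResult(
        comp_id=component.comp_id, coords=coords,
        initial_energy=float(initial), final_energy=float(final),
        converged=(not_converged == 0), seed=int(seed), forcefield=name)


def conformer_energy(coords: dict[str, np.ndarray],
                     component: ComponentDefinition) -> float:
    """Single-point energy (kJ/mol) of the given coordinates under the same
    force field used for minimization. ``coords`` must cover every atom of
    the component (hydrogens included); missing atoms are listed."""
    missing = [a.name for a in component.atoms if a.name not in coords]
    if missing:
        raise ValueError(
            f"{component.comp_id}: coordinates missing for atoms {missing}")
    mol = _mol_from_component(component)
    _set_conformer(mol, component, coords)
    ff, _ = _forcefield(mol)
    return float(ff.CalcEnergy() * KCAL_TO_KJ)
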