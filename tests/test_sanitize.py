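import numpy as np
import pytest

from structforge.fixtures import make_pathological_case, make_toy_peptide
from structforge.io import StructConnRecord, attach_intra_component_bonds
from structforge.sanitize import (assign_formal_charges,
                                  correct_bond_order_after_addition,
                                  deduplicate_symmetry_ligands,
                                  detect_covalent_links,
                                  impute_missing_intra_residue,
                                  remove_leaving_groups, resolve_altlocs,
                                  sanitize_state)


def names_of(state, mask_fn):
    a = state.table.atoms
    return set(map(tuple, a[mask_fn(a)]
                   [["res_index", "atom_name", "altloc"]].itertuples(
                       index=False, name=None)))


class TestResolveAltlocs:
    def test_highest_occupancy_kept(self):
        state, comps, expect = make_pathological_case("altloc")
        out = resolve_altlocs(state)
        a = out.table.atoms
        cb = a[(a["res_index"] == 2) & (a["atom_name"] == "CB")]
        assert len(cb) == 1
        assert cb["occupancy"].iloc[0] == pytest.approx(0.6)
        assert cb["altloc"].iloc[0] == ""

    def test_tie_takes_smallest_altloc(self):
        state, _, _ = make_pathological_case("altloc")
        a = state.table.atoms
        a.loc[a["altloc"] != "", "occupancy"] = 0.5
        out = resolve_altlocs(state)
        cb = out.table.atoms[(out.table.atoms["res_index"] == 2) &
                             (out.table.atoms["atom_name"] == "CB")]
        # altloc A sits at the original CB position; B is displaced +0.8 x
        ref = state.table.atoms
        a_x = ref[(ref["altloc"] == "A")]["x"].iloc[0]
        assert cb["x"].iloc[0] == pytest.approx(a_x)

    def test_no_altloc_identity_and_idempotent(self, peptide):
        out = resolve_altlocs(peptide)
        assert out.table.atoms.equals(peptide.table.atoms)
        state, _, _ = make_pathological_case("altloc")
        once = resolve_altlocs(state)
        twice = resolve_altlocs(once)
        assert once.table.atoms.equals(twice.table.atoms)


class TestRemoveLeavingGroups:
    def test_linked_oxt_deleted_terminal_retained(self, components):
        state, comps, expect = make_pathological_case("leaving_group")
        state = attach_intra_component_bonds(state, comps)
        out = remove_leaving_groups(state, comps)
        a = out.table.atoms
        oxt = a[a["atom_name"] == "OXT"]
        assert list(oxt["res_index"]) == [2]
        # second application is identity
        again = remove_leaving_groups(out, comps)
        assert again.table.atoms.equals(out.table.atoms)

    def test_free_ligand_untouched(self, components):
        from structforge.fixtures import component_state
        state = component_state(components["ACT"])
        out = remove_leaving_groups(state, components)
        assert len(out.table) == len(state.table)

    def test_leaving_hydrogen_at_link_atom(self, components):
        # CYS SG carries a leaving-flagged HG; a covalent ligand link at SG
        # must remove it while conserving heavy atoms
        state, comps, _ = make_pathological_case("covalent_ligand")
        state = attach_intra_component_bonds(state, comps)
        state = detect_covalent_links(state)
        n_heavy = (state.table.atoms["element"] != "H").sum()
        out = remove_leaving_groups(state, comps)
        assert (out.table.atoms["element"] != "H").sum() == n_heavy


class TestDetectCovalentLinks:
    def test_disulfide_record_one_bond(self, components):
        state, _ = make_toy_peptide("CAC", chain_id="A")
        other, _ = make_toy_peptide("C", chain_id="B")
        other.table.atoms[["x", "y", "z"]] += 6.0
        state.table.add_atoms(other.table.atoms.drop(columns=["atom_uid"])
                              .to_dict("records"))
        state = attach_intra_component_bonds(state, components)
        rec = StructConnRecord("disulf", ("A", 1, "SG"), ("B", 1, "SG"))
        out = detect_covalent_links(state, [rec])
        sc = out.table.bonds[out.table.bonds["provenance"] == "struct_conn"]
        assert len(sc) == 1

    def test_distance_inference_flag(self, components):
        state, comps, _ = make_pathological_case("covalent_ligand")
        state = attach_intra_component_bonds(state, comps)
        state.extras.pop("struct_conn_records", None)
        off = detect_covalent_links(state, [], infer_by_distance=False)
        assert (off.table.bonds["provenance"] == "inferred").sum() == \
            (state.table.bonds["provenance"] == "inferred").sum()
        on = detect_covalent_links(state, [], infer_by_distance=True)
        new = len(on.table.bonds) - len(state.table.bonds)
        # SG...C2 at 1.8 A < r_S + r_C + 0.4 = 1.05 + 0.76 + 0.4 = 2.21 A
        assert new == 1

    def test_unresolvable_record_skipped(self, peptide):
        rec = StructConnRecord("covale", ("Z", 9, "XX"), ("A", 1, "CA"))
        out = detect_covalent_links(peptide, [rec])
        assert out.extras["struct_conn_skipped"] == 1
        assert len(out.table.bonds) == len(peptide.table.bonds)

    def test_metalc_is_annotation_not_bond(self, peptide):
        rec = StructConnRecord("metalc", ("A", 1, "N"), ("A", 2, "O"))
        out = detect_covalent_links(peptide, [rec])
        assert len(out.table.bonds) == len(peptide.table.bonds)
        assert len(out.extras["metal_coordination"]) == 1


class TestBondOrderCorrection:
    def test_carbonyl_demoted_after_addition(self):
        state, comps, _ = make_pathological_case("covalent_ligand")
        state = attach_intra_component_bonds(state, comps)
        state = detect_covalent_links(state)
        out = correct_bond_order_after_addition(state, comps)
        a = out.table.atoms
        c2 = a[(a["comp_id"] == "KET") & (a["atom_name"] == "C2")]
        uid = int(c2["atom_uid"].iloc[0])
        b = out.table.bonds
        orders = b[(b["atom_a"] == uid) | (b["atom_b"] == uid)]["order"]
        assert set(orders) == {"single"}

    @staticmethod
    def _linked_carbon(n_substituents):
        """A carbon with n single-bonded carbons plus one covalent link to a
        second residue (no component template, so no implicit hydrogens)."""
        from structforge.core import AtomTable, PipelineState
        records = [{"chain_id": "L", "res_index": 1, "comp_id": "TOY",
                    "atom_name": "C0", "element": "C",
                    "x": 0.0, "y": 0.0, "z": 0.0}]
        for i in range(n_substituents):
            records.append({"chain_id": "L", "res_index": 1,
                            "comp_id": "TOY", "atom_name": f"C{i + 1}",
                            "element": "C", "x": float(i + 1), "y": 0.0,
                            "z": 0.0})
        records.append({"chain_id": "P", "res_index": 1, "comp_id": "NUC",
                        "atom_name": "SG", "element": "S",
                        "x": 0.0, "y": 2.0, "z": 0.0})
        t = AtomTable.from_records(records)
        for i in range(n_substituents):
            t.add_bond(0, i + 1)
        t.add_bond(0, n_substituents + 1, provenance="struct_conn")
        return PipelineState(table=t)

    def test_sp3_carbon_with_free_valence_unchanged(self):
        state = self._linked_carbon(3)  # 3 + link = 4: valence satisfied
        out = correct_bond_order_after_addition(state)
        assert out.table.bonds.equals(state.table.bonds)

    def test_quaternary_carbon_without_double_bond_is_error(self):
        state = self._linked_carbon(4)  # 4 + link = 5, nothing to demote
        with pytest.raises(ValueError, match="C0"):
            correct_bond_order_after_addition(state)


class TestFormalCharges:
    def test_carboxylate_oxygen(self):
        state, comps, expect = make_pathological_case("miscounted_charge")
        state = attach_intra_component_bonds(state, comps)
        out = assign_formal_charges(state, comps)
        a = out.table.atoms
        act = a[a["comp_id"] == "ACT"].set_index("atom_name")
        assert act.loc["O2", "formal_charge"] == -1
        assert act.loc["O1", "formal_charge"] == 0
        assert act.loc["C2", "formal_charge"] == 0

    def test_quaternary_nitrogen_positive(self, components):
        from structforge.core import AtomTable, PipelineState
        records = [{"chain_id": "L", "res_index": 1, "comp_id": "QUA",
                    "atom_name": n, "element": e, "x": float(i), "y": 0.0,
                    "z": 0.0}
                   for i, (n, e) in enumerate(
                       [("N1", "N"), ("C1", "C"), ("C2", "C"), ("C3", "C"),
                        ("C4", "C")])]
        t = AtomTable.from_records(records)
        for j in range(1, 5):
            t.add_bond(0, j)
        out = assign_formal_charges(PipelineState(table=t))
        assert out.table.atoms.iloc[0]["formal_charge"] == 1

    def test_water_neutral(self, components):
        from structforge.fixtures import component_state
        state = component_state(components["HOH"])
        out = assign_formal_charges(state, components)
        assert (out.table.atoms["formal_charge"] == 0).all()

    def test_total_charge_matches_component_definitions(self, components):
        from structforge.fixtures import component_state
        for cid in ("ACT", "ETH", "LIG", "EDP"):
            state = component_state(components[cid])
            out = assign_formal_charges(state, components)
            expected = sum(a.formal_charge for a in components[cid].atoms)
            assert out.table.atoms["formal_charge"].sum() == expected, cid

    def test_unknown_element_is_error(self):
        from structforge.core import AtomTable, PipelineState
        t = AtomTable.from_records([
            {"chain_id": "L", "res_index": 1, "comp_id": "X",
             "atom_name": "FE", "element": "FE", "x": 0, "y": 0, "z": 0},
            {"chain_id": "L", "res_index": 1, "comp_id": "X",
             "atom_name": "O1", "element": "O", "x": 2, "y": 0, "z": 0}])
        t.add_bond(0, 1)
        with pytest.raises(KeyError, match="FE"):
            assign_formal_charges(PipelineState(table=t))


class TestSymmetryLigands:
    def test_overlapping_half_occupancy_collapsed(self):
        state, comps, expect = make_pathological_case("symmetry_ligand")
        out = deduplicate_symmetry_ligands(state)
        eth = out.table.atoms[out.table.atoms["comp_id"] == "ETH"]
        assert sorted(eth["res_index"].unique()) == [1]
        # idempotent
        again = deduplicate_symmetry_ligands(out)
        assert again.table.atoms.equals(out.table.atoms)

    def test_distant_copies_kept(self, components):
        state, comps, _ = make_pathological_case("symmetry_ligand")
        a = state.table.atoms
        a.loc[(a["comp_id"] == "ETH") & (a["res_index"] == 2),
              ["x", "y", "z"]] += 20.0
        out = deduplicate_symmetry_ligands(state)
        eth = out.table.atoms[out.table.atoms["comp_id"] == "ETH"]
        assert sorted(eth["res_index"].unique()) == [1, 2]

    def test_full_occupancy_identity(self, components):
        state, comps, _ = make_pathological_case("symmetry_ligand")
        a = state.table.atoms
        a.loc[a["comp_id"] == "ETH", "occupancy"] = 1.0
        out = deduplicate_symmetry_ligands(state)
        assert len(out.table) == len(state.table)


class TestImputation:
    def test_missing_cb_placed_near_ideal_length(self, components):
        state, _ = make_toy_peptide("AAA")
        atoms = state.table.atoms
        m = (atoms["res_index"] == 2) & (atoms["atom_name"] == "CB")
        state.table.atoms = atoms[~m].reset_index(drop=True)
        out = impute_missing_intra_residue(state, components)
        a = out.table.atoms
        res2 = a[a["res_index"] == 2].set_index("atom_name")
        assert "CB" in res2.index
        assert res2.loc["CB", "annot"] == "imputed"
        d = np.linalg.norm(res2.loc["CB", ["x", "y", "z"]].to_numpy(float) -
                           res2.loc["CA", ["x", "y", "z"]].to_numpy(float))
        ideal = components["ALA"].ideal_coords()
        d_ideal = np.linalg.norm(ideal["CB"] - ideal["CA"])
        assert abs(d - d_ideal) < 0.05

    def test_fully_resolved_identity(self, components):
        state, _ = make_toy_peptide("AA")
        out = impute_missing_intra_residue(state, components)
        assert len(out.table) == len(state.table)

    def test_too_few_shared_atoms_reported(self, components):
        state, _ = make_toy_peptide("AA")
        atoms = state.table.atoms
        keep = ~((atoms["res_index"] == 1) &
                 ~atoms["atom_name"].isin(["N", "CA"]))
        state.table.atoms = atoms[keep].reset_index(drop=True)
        out = impute_missing_intra_residue(state, components)
        assert ("A", 1, "ALA") in out.extras["imputation_skipped"]
        a = out.table.atoms
        assert len(a[a["res_index"] == 1]) == 2


class TestFullChain:
    def test_atom_count_only_grows_by_imputation(self):
        for case in ("altloc", "leaving_group", "covalent_ligand",
                     "symmetry_ligand", "miscounted_charge"):
            state, comps, _ = make_pathological_case(case)
            out = sanitize_state(state, comps, impute=False)
            assert len(out.table) <= len(state.table), case

    def test_full_chain_idempotent(self):
        state, comps, _ = make_pathological_case("covalent_ligand")
        once = sanitize_state(state, comps)
        twice = sanitize_state(once, comps)
        assert once.table.atoms[["chain_id", "res_index", "atom_name",
                                 "formal_charge"]].equals(
            twice.table.atoms[["chain_id", "res_index", "atom_name",
                               "formal_charge"]])
        assert np.allclose(once.table.coords, twice.table.coords,
                           equal_nan=True)
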