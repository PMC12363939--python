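import numpy as np
import pytest

from structforge.core import AtomTable, PipelineState
from structforge.fixtures import (component_state, make_toy_peptide,
                                  perturb_structure)
from structforge.metrics import (NoInterfaceError, backbone_rmsd,
                                 cluster_members, clustered_mean,
                                 interface_lddt, lddt, mean_rasa,
                                 per_atom_sasa)

from conftest import random_rotation


def lddt_oracle(pred, ref, radius=15.0, thresholds=(0.5, 1, 2, 4),
                pair_filter=None):
    """Brute-force all-pairs reimplementation (plain loops)."""
    a = ref.table.atoms
    keep = (a["element"].str.upper() != "H") & a["is_resolved"]
    rxyz = {}
    for _, r in a[keep].iterrows():
        rxyz[(r["chain_id"], r["res_index"], r["atom_name"])] = \
            np.array([r["x"], r["y"], r["z"]], dtype=float)
    pxyz = {}
    for _, r in pred.table.atoms.iterrows():
        pxyz[(r["chain_id"], r["res_index"], r["atom_name"])] = \
            np.array([r["x"], r["y"], r["z"]], dtype=float)
    keys = [k for k in rxyz if k in pxyz]
    scores = {k: [] for k in keys}
    for i, ki in enumerate(keys):
        for kj in keys[i + 1:]:
            if (ki[0], ki[1]) == (kj[0], kj[1]):
                continue
            d_ref = np.linalg.norm(rxyz[ki] - rxyz[kj])
            if d_ref >= radius:
                continue
            if pair_filter is not None and not pair_filter(ki, kj):
                continue
            d_pred = np.linalg.norm(pxyz[ki] - pxyz[kj])
            s = np.mean([abs(d_pred - d_ref) < t for t in thresholds])
            scores[ki].append(s)
            scores[kj].append(s)
    per_atom = [np.mean(v) for v in scores.values() if v]
    return float(np.mean(per_atom))


def line_state(xs, chain="A"):
    records = [{"chain_id": chain, "res_index": i + 1, "comp_id": "GLY",
                "atom_name": "CA", "element": "C", "x": float(x),
                "y": 0.0, "z": 0.0, "is_polymer": True}
               for i, x in enumerate(xs)]
    return PipelineState(table=AtomTable.from_records(records))


class TestLddt:
    def test_identity_scores_one(self, peptide):
        assert lddt(peptide, peptide).global_score == 1.0

    def test_rigid_rotation_scores_one(self, peptide, rng):
        moved = peptide.copy()
        moved.table.set_coords(
            moved.table.coords @ random_rotation(rng).T + [5, 6, 7])
        assert lddt(moved, peptide).global_score == pytest.approx(1.0)

    def test_three_atom_line_example(self):
        ref = line_state([0.0, 4.0, 8.0])
        pred = line_state([0.0, 4.0, 9.2])
        result = lddt(pred, ref)
        assert result.global_score == pytest.approx(2.0 / 3.0)
        assert result.n_pairs == 3

    def test_equals_oracle_on_random_fixtures(self, rng):
        for trial in range(10):
            n = int(rng.integers(5, 25))
            ref = PipelineState(table=AtomTable.from_records([
                {"chain_id": "A", "res_index": i + 1, "comp_id": "GLY",
                 "atom_name": "CA", "element": "C",
                 "x": v[0], "y": v[1], "z": v[2], "is_polymer": True}
                for i, v in enumerate(rng.uniform(0, 20, (n, 3)))]))
            pred = perturb_structure(ref, sigma=0.5, seed=trial)
            assert lddt(pred, ref).global_score == pytest.approx(
                lddt_oracle(pred, ref), abs=1e-12)

    def test_zero_pairs_is_error(self):
        ref = line_state([0.0, 100.0])
        with pytest.raises(ValueError, match="pairs"):
            lddt(ref, ref)


class TestInterfaceLddt:
    def test_identical_two_chain_scores_one(self, two_chain):
        res = interface_lddt(two_chain, two_chain, "A", "B")
        assert res.global_score == 1.0

    def test_far_chains_raise_no_interface(self, two_chain):
        far = two_chain.copy()
        a = far.table.atoms
        a.loc[a["chain_id"] == "B", ["x", "y", "z"]] += 100.0
        with pytest.raises(NoInterfaceError):
            interface_lddt(far, far, "A", "B")

    def test_translated_chain_matches_oracle_and_symmetric(self, two_chain):
        pred = two_chain.copy()
        a = pred.table.atoms
        a.loc[a["chain_id"] == "B", ["x", "y", "z"]] += [1.5, 0, 0]
        res_ab = interface_lddt(pred, two_chain, "A", "B")
        res_ba = interface_lddt(pred, two_chain, "B", "A")
        assert 0.0 < res_ab.global_score < 1.0
        assert res_ab.global_score == res_ba.global_score

        def cross(ki, kj):
            return {ki[0], kj[0]} == {"A", "B"}

        assert res_ab.global_score == pytest.approx(
            lddt_oracle(pred, two_chain, pair_filter=cross), abs=1e-12)


class TestBackboneRmsd:
    def test_identity_zero(self, peptide):
        assert backbone_rmsd(peptide, peptide) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_zero(self, peptide, rng):
        moved = peptide.copy()
        moved.table.set_coords(
            moved.table.coords @ random_rotation(rng).T + [1, 2, 3])
        assert backbone_rmsd(moved, peptide) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_strictly_positive(self, peptide):
        from structforge.chirality import invert_structure
        assert backbone_rmsd(invert_structure(peptide), peptide) > 0.1

    def test_too_few_atoms_is_error(self):
        s = line_state([0.0, 4.0])
        with pytest.raises(ValueError, match="3"):
            backbone_rmsd(s, s, atom_set=("CA",))


class TestSasa:
    def test_single_atom_closed_form(self):
        s = PipelineState(table=AtomTable.from_records([
            {"chain_id": "L", "res_index": 1, "comp_id": "X",
             "atom_name": "C1", "element": "C", "x": 0, "y": 0, "z": 0}]))
        area = per_atom_sasa(s)[0]
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=1e-3)

    def test_enclosed_atom_near_zero(self):
        from structforge._geometry import fibonacci_sphere
        shell = 3.0 * fibonacci_sphere(60)
        records = [{"chain_id": "L", "res_index": 1, "comp_id": "X",
                    "atom_name": "C0", "element": "C",
                    "x": 0.0, "y": 0.0, "z": 0.0}]
        records += [{"chain_id": "L", "res_index": 2, "comp_id": "X",
                     "atom_name": f"C{i + 1}", "element": "C",
                     "x": p[0], "y": p[1], "z": p[2]}
                    for i, p in enumerate(shell)]
        s = PipelineState(table=AtomTable.from_records(records))
        assert per_atom_sasa(s)[0] < 1.0

    def test_contact_reduces_total_area(self, components):
        apart, _ = make_toy_peptide("A", chain_id="A")
        other, _ = make_toy_peptide("A", chain_id="B")
        far = apart.copy()
        o = other.table.atoms.drop(columns=["atom_uid"]).copy()
        o[["x", "y", "z"]] += 50.0
        far.table.add_atoms(o.to_dict("records"))
        near = apart.copy()
        o2 = other.table.atoms.drop(columns=["atom_uid"]).copy()
        o2[["x", "y", "z"]] += 4.0
        near.table.add_atoms(o2.to_dict("records"))
        assert sum(per_atom_sasa(near).values()) < \
            sum(per_atom_sasa(far).values())

    def test_agrees_with_biotite_shrake_rupley(self, components):
        """Independent cross-check against biotite's Shrake-Rupley: the two
        samplers use different sphere point sets, so agreement is checked at
        the 2% level on the total and 15% per atom."""
        import biotite.structure as struc
        st, _ = make_toy_peptide("ACSAG")
        a = st.table.atoms
        arr = struc.AtomArray(len(a))
        arr.coord = a[["x", "y", "z"]].to_numpy(float)
        arr.chain_id = a["chain_id"].to_numpy()
        arr.res_id = a["res_index"].to_numpy()
        arr.res_name = a["comp_id"].to_numpy()
        arr.atom_name = a["atom_name"].to_numpy()
        arr.element = a["element"].to_numpy()
        ref = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                         vdw_radii="Single")
        mine = per_atom_sasa(st, n_sphere_points=1000)
        ours = np.array([mine[int(u)] for u in a["atom_uid"]])
        assert abs(ours.sum() - ref.sum()) / ref.sum() < 0.02
        big = ref > 5.0
        assert (np.abs(ours[big] - ref[big]) / ref[big] < 0.15).all()

    def test_identical_coordinates_rejected(self):
        s = PipelineState(table=AtomTable.from_records([
            {"chain_id": "L", "res_index": 1, "comp_id": "X",
             "atom_name": "C1", "element": "C", "x": 0, "y": 0, "z": 0},
            {"chain_id": "L", "res_index": 1, "comp_id": "X",
             "atom_name": "C2", "element": "C", "x": 0, "y": 0, "z": 0}]))
        with pytest.raises(ValueError, match="share coordinates"):
            per_atom_sasa(s)


class TestMeanRasa:
    def test_extended_center_highly_exposed(self, components):
        state, _ = make_toy_peptide("GAG", torsions=(180, 180, 180))
        assert mean_rasa(state, [("A", 2)]) > 0.7

    def test_buried_residue_low_rasa(self, components):
        import pandas as pd
        base, _ = make_toy_peptide("A" * 15)
        frames = []
        for gx in (-1, 0, 1):
            for gy in (-1, 0, 1):
                t = base.table.atoms.copy()
                t["chain_id"] = f"C{gx + 1}{gy + 1}"
                t[["x", "y"]] += np.array([gx * 7.0, gy * 7.0])
                frames.append(t)
        allat = pd.concat(frames, ignore_index=True)
        allat["atom_uid"] = np.arange(len(allat))
        state = PipelineState(table=AtomTable(
            allat, base.table.bonds.iloc[0:0], len(allat)))
        assert mean_rasa(state, [("C11", 8)]) < 0.25

    def test_empty_region_is_error(self, peptide):
        with pytest.raises(ValueError, match="empty"):
            mean_rasa(peptide, [])

    def test_unknown_residue_type_is_error(self, components):
        state = component_state(components["ETH"], chain_id="L")
        with pytest.raises(KeyError, match="ETH"):
            mean_rasa(state, [("L", 1)])


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        ca = cluster_members({f"m{i}": seq for i in range(3)},
                             mode="sequence_identity_40")
        assert ca.n_clusters == 1

    def test_ccd_identity_partition(self):
        ca = cluster_members({"x": "ATP", "y": "ATP", "z": "GTP"})
        assert ca.n_clusters == 2
        assert ca["x"] == ca["y"] != ca["z"]

    def test_unrelated_sequences_split(self, rng):
        from structforge.metrics import _alignment_identity
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        s1 = "".join(rng.choice(alphabet, 50))
        s2 = "".join(rng.choice(alphabet, 50))
        assert _alignment_identity(s1, s2) < 0.40
        ca = cluster_members({"a": s1, "b": s2},
                             mode="sequence_identity_40")
        assert ca.n_clusters == 2

    def test_representatives_are_members(self):
        ca = cluster_members({"x": "ATP", "y": "GTP"})
        for cid, rep in ca.representatives.items():
            assert ca[rep] == cid

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            cluster_members({})


class TestClusteredMean:
    def test_worked_example(self):
        scores = {"m1": 1.0, "m2": 0.5, "m3": 0.8}
        clusters = {"m1": "a", "m2": "a", "m3": "b"}
        assert clustered_mean(scores, clusters) == pytest.approx(0.775)

    def test_singletons_equal_plain_mean(self, rng):
        scores = {f"m{i}": float(v)
                  for i, v in enumerate(rng.uniform(0, 1, 7))}
        clusters = {k: k for k in scores}
        assert clustered_mean(scores, clusters) == pytest.approx(
            np.mean(list(scores.values())))

    def test_permutation_invariant(self):
        scores = {"m1": 1.0, "m2": 0.5, "m3": 0.8}
        clusters = {"m1": "a", "m2": "a", "m3": "b"}
        rev = dict(reversed(list(scores.items())))
        assert clustered_mean(scores, clusters) == \
            clustered_mean(rev, clusters)

    def test_missing_cluster_is_error(self):
        with pytest.raises(KeyError, match="m2"):
            clustered_mean({"m1": 1.0, "m2": 0.5}, {"m1": "a"})
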