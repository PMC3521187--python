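import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semihot import geometry
from semihot.features import (
    ASA_ATTRS,
    DI_ATTRS,
    ResidueStructFeatures,
    aggregate_residue,
    compute_kfc2_features,
    compute_neighbor_features,
    compute_rasa,
    compute_relative_changes,
    compute_state_features,
    extract_structure_features,
    identify_interface_residues,
    structure_feature_names,
)
from semihot.pdbio import Atom, Chain, Residue, Structure, read_structure
from semihot.synthetic import generate_toy_complex


def _residue(flags):
    """Residue from (is_backbone, element) specs, 2 A apart on a line."""
    res = Residue(key=("A", 1, ""), name="ALA")
    for i, (bb, el) in enumerate(flags):
        res.atoms.append(
            Atom(serial=i + 1, name=f"X{i}", element=el,
                 coords=np.array([2.0 * i, 0.0, 0.0]), vdw_radius=1.8,
                 is_backbone=bb, is_polar=el in ("N", "O"), residue_key=res.key)
        )
    return res


class TestAggregateResidue:
    def test_asa_sums_by_atom_class(self):
        res = _residue([(False, "C"), (False, "C"), (False, "C")])
        agg = aggregate_residue(res, [2.0, 3.0, 5.0], "asa")
        assert agg == {"total": 10.0, "backbone": 0.0, "side_chain": 10.0,
                       "polar": 0.0, "non_polar": 10.0}

    def test_di_mean_max_min(self):
        res = _residue([(True, "N"), (False, "C"), (False, "O")])
        agg = aggregate_residue(res, [1.0, 2.0, 3.0], "di")
        assert agg["total_mean"] == pytest.approx(2.0)
        assert agg["side_chain_mean"] == pytest.approx(2.5)
        assert agg["max"] == 3.0 and agg["min"] == 1.0

    def test_single_atom_degenerate(self):
        res = _residue([(True, "C")])
        agg = aggregate_residue(res, [4.2], "pi")
        assert agg["total_mean"] == agg["max"] == agg["min"] == 4.2
        assert agg["side_chain_mean"] == 0.0  # glycine-like: no side chain

    def test_empty_residue_rejected(self):
        res = Residue(key=("A", 1, ""), name="GLY")
        with pytest.raises(ValueError):
            aggregate_residue(res, [], "asa")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=12), st.randoms(use_true_random=False))
    def test_agrees_with_bruteforce_loop(self, values, rnd):
        flags = [(rnd.random() < 0.5, rnd.choice("CNOS")) for _ in values]
        res = _residue(flags)
        agg = aggregate_residue(res, values, "asa")
        brute = {"total": 0.0, "backbone": 0.0, "side_chain": 0.0, "polar": 0.0, "non_polar": 0.0}
        for (bb, el), v in zip(flags, values):
            brute["total"] += v
            brute["backbone" if bb else "side_chain"] += v
            if el in "NO":
                brute["polar"] += v
            if el == "C":
                brute["non_polar"] += v
        for k in brute:
            assert agg[k] == pytest.approx(brute[k])


class TestRasa:
    def test_equal_to_reference_gives_one(self):
        from semihot.tables import rasa_reference_table
        ref = rasa_reference_table()["ALA"]
        rasa = compute_rasa(dict(ref), "ALA")
        for attr in ASA_ATTRS:
            assert rasa[attr] == pytest.approx(1.0)

    def test_zero_asa_gives_zero(self):
        rasa = compute_rasa({a: 0.0 for a in ASA_ATTRS}, "TRP")
        assert all(v == 0.0 for v in rasa.values())

    def test_plain_division(self):
        from semihot.tables import rasa_reference_table
        ref_total = rasa_reference_table()["GLY"]["total"]
        asa = {a: 0.0 for a in ASA_ATTRS}
        asa["total"] = ref_total / 4.0
        assert compute_rasa(asa, "GLY")["total"] == pytest.approx(0.25)

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            compute_rasa({a: 1.0 for a in ASA_ATTRS}, "XYZ")


def _state(key, asa_total, di=None, pi=None, state="bound", **asa_extra):
    asa = {a: 0.0 for a in ASA_ATTRS}
    asa["total"] = asa_total
    asa.update(asa_extra)
    zeros = {a: 0.0 for a in DI_ATTRS}
    return ResidueStructFeatures(
        key=key, residue_name="ALA", state=state,
        asa=asa, rasa={a: 0.0 for a in ASA_ATTRS},
        di=di or dict(zeros), pi=pi or dict(zeros),
    )


class TestRelativeChanges:
    def test_direct_formula(self):
        key = ("A", 1, "")
        b = _state(key, 40.0)
        u = _state(key, 100.0, state="unbound")
        rc = compute_relative_changes(b, u)
        assert rc["rc_asa"]["total"] == pytest.approx(0.6)

    def test_identical_states_give_zero(self):
        key = ("A", 1, "")
        b = _state(key, 55.0, di={a: 2.0 for a in DI_ATTRS}, pi={a: 3.0 for a in DI_ATTRS})
        u = _state(key, 55.0, di={a: 2.0 for a in DI_ATTRS}, pi={a: 3.0 for a in DI_ATTRS},
                   state="unbound")
        rc = compute_relative_changes(b, u)
        for group in rc.values():
            assert all(v == 0.0 for v in group.values())

    def test_di_change_uses_bound_denominator(self):
        key = ("A", 1, "")
        b = _state(key, 1.0, di={"total_mean": 2.0, "side_chain_mean": 2.0, "max": 4.0, "min": 1.0})
        u = _state(key, 1.0, di={"total_mean": 1.0, "side_chain_mean": 1.0, "max": 1.0, "min": 1.0},
                   state="unbound")
        rc = compute_relative_changes(b, u)
        assert rc["rc_di"]["max"] == pytest.approx(0.75)

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            compute_relative_changes(_state(("A", 1, ""), 1.0), _state(("A", 2, ""), 1.0))

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.1, 500), st.floats(0.0, 500))
    def test_scalar_reevaluation(self, unb, bnd):
        key = ("A", 1, "")
        rc = compute_relative_changes(_state(key, bnd), _state(key, unb, state="unbound"))
        assert rc["rc_asa"]["total"] == pytest.approx((unb - bnd) / unb)


class TestKfc2Features:
    def test_hand_worked_example(self):
        key = ("A", 1, "")
        out = compute_kfc2_features(_state(key, 40.0), _state(key, 100.0, state="unbound"),
                                    "ALA", seq_index=5, n_interface=10)
        assert out["delta_tot"] == pytest.approx(60.0)
        assert out["core_rim"] == pytest.approx(0.6)
        assert out["sa_ratio5"] == pytest.approx(60.0 * 129.0 / 100.0)
        assert out["pos_per"] == pytest.approx(0.3)

    def test_fully_buried_gives_core_rim_one(self):
        key = ("A", 1, "")
        out = compute_kfc2_features(_state(key, 0.0), _state(key, 80.0, state="unbound"),
                                    "GLY", 1, 1)
        assert out["core_rim"] == pytest.approx(1.0)

    def test_no_change_gives_zeros(self):
        key = ("A", 1, "")
        out = compute_kfc2_features(_state(key, 70.0), _state(key, 70.0, state="unbound"),
                                    "SER", 2, 4)
        assert out["delta_tot"] == out["core_rim"] == out["sa_ratio5"] == out["pos_per"] == 0.0

    def test_zero_unbound_asa_rejected(self):
        key = ("A", 1, "")
        with pytest.raises(ValueError):
            compute_kfc2_features(_state(key, 0.0), _state(key, 0.0, state="unbound"), "ALA", 1, 1)

    def test_alternative_sa_ratio_reading(self):
        key = ("A", 1, "")
        out = compute_kfc2_features(_state(key, 40.0), _state(key, 100.0, state="unbound"),
                                    "ALA", 1, 2, sa_ratio_form="delta_over_max")
        assert out["sa_ratio5"] == pytest.approx(60.0 / 129.0)


def _two_residue_structure(d_closest, neighbor_name="LYS"):
    """Target ALA at origin, one neighbor whose nearest atom is d_closest away."""
    target = Residue(key=("A", 1, ""), name="ALA")
    target.atoms.append(Atom(serial=1, name="CA", element="C", coords=np.zeros(3),
                             vdw_radius=1.87, is_backbone=True, is_polar=False,
                             residue_key=target.key))
    nb = Residue(key=("A", 2, ""), name=neighbor_name)
    nb.atoms.append(Atom(serial=2, name="CA", element="C",
                         coords=np.array([d_closest, 0.0, 0.0]), vdw_radius=1.87,
                         is_backbone=True, is_polar=False, residue_key=nb.key))
    return Structure(chains=[Chain(chain_id="A", residues=[target, nb])])


class TestNeighborFeatures:
    def test_isolated_residue_all_zero(self):
        st = _two_residue_structure(100.0)
        out = compute_neighbor_features(st, ("A", 1, ""))
        for k in ("rot4", "rot5", "hp5", "atmn4", "atmn5", "plast4", "plast5"):
            assert out[k] == 0.0

    def test_lysine_neighbor_weighted_rotatable_bonds(self):
        # Lys has 4 rotatable side-chain bonds; w(2 A, r=4) = 0.5
        st = _two_residue_structure(2.0, "LYS")
        out = compute_neighbor_features(st, ("A", 1, ""))
        assert out["rot4"] == 4.0
        assert out["wt_rot4"] == pytest.approx(4.0 * (1 - 2.0 / 4.0))
        assert out["atmn4"] == 1.0
        # PLAST4 = wt_rot4/atmn4 * maxASA(ALA)
        assert out["plast4"] == pytest.approx(2.0 * 129.0)

    def test_hydrophobic_neighborhood_sum(self):
        # ILE (4.5) and ARG (-4.5) within 5 A -> HP5 = 0; swap ARG for ASN (-3.5)
        target = Residue(key=("A", 1, ""), name="GLY")
        target.atoms.append(Atom(serial=1, name="CA", element="C", coords=np.zeros(3),
                                 vdw_radius=1.87, is_backbone=True, is_polar=False,
                                 residue_key=target.key))
        chains = [Chain(chain_id="A", residues=[target])]
        for i, (name, x) in enumerate([("ILE", 3.0), ("ASN", -3.0)], start=2):
            r = Residue(key=("A", i, ""), name=name)
            r.atoms.append(Atom(serial=i, name="CA", element="C",
                                coords=np.array([x, 0.0, 0.0]), vdw_radius=1.87,
                                is_backbone=True, is_polar=False, residue_key=r.key))
            chains[0].residues.append(r)
        out = compute_neighbor_features(Structure(chains=chains), ("A", 1, ""))
        assert out["hp5"] == pytest.approx(4.5 - 3.5)

    def test_shell_density_counts(self):
        st = _two_residue_structure(8.0)
        out = compute_neighbor_features(st, ("A", 1, ""))
        assert out["fp9n"] == 1.0 and out["fp10n"] == 1.0
        assert out["fp9e"] == pytest.approx(1.0 / (4 / 3 * np.pi * 9**3))


class TestInterfaceIdentification:
    def test_distant_chains_have_no_interface(self, three_residue_structure):
        assert identify_interface_residues(three_residue_structure, ["A"], ["B"]) == []

    def test_toy_contacts_match_bruteforce_asa_difference(self, toy_complex):
        iface = identify_interface_residues(toy_complex, ["A"], ["B"])
        keys = {r.key for r in iface}
        # brute-force oracle: per-residue summed SASA in complex vs alone
        from semihot.features import _per_residue_total_asa
        bound = _per_residue_total_asa(toy_complex, 1.4, 960)
        expected = set()
        for side in (["A"], ["B"]):
            sub = toy_complex.subset(side)
            unbound = _per_residue_total_asa(sub, 1.4, 960)
            for key, u in unbound.items():
                if u - bound[key] > 0.1:
                    expected.add(key)
        assert keys == expected
        # the construction puts the 4 contact residues of each side there
        for chain in ("A", "B"):
            for num in (1, 2, 3, 4):
                assert (chain, num, "") in keys

    def test_remote_residues_excluded(self, toy_complex):
        iface = identify_interface_residues(toy_complex, ["A"], ["B"])
        keys = {r.key for r in iface}
        for chain in ("A", "B"):
            for num in (5, 6, 7):
                assert (chain, num, "") not in keys

    def test_indices_are_ordered_ranks(self, toy_complex):
        iface = identify_interface_residues(toy_complex, ["A"], ["B"])
        assert [r.seq_index for r in iface] == list(range(1, len(iface) + 1))
        assert all(r.n_interface == len(iface) for r in iface)
        assert [r.key for r in iface] == sorted(r.key for r in iface)

    def test_unknown_chain_rejected(self, toy_complex):
        with pytest.raises(KeyError):
            identify_interface_residues(toy_complex, ["A"], ["Z"])

    def test_single_chain_without_partition_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            identify_interface_residues(toy_complex, ["A"], [])


class TestStateAndTable:
    def test_bound_asa_never_exceeds_unbound(self, toy_complex):
        bound = compute_state_features(toy_complex, "bound", n_sphere_points=240)
        for side in (["A"], ["B"]):
            sub = toy_complex.subset(side)
            unbound = compute_state_features(sub, "unbound", n_sphere_points=240)
            for key, u in unbound.items():
                assert bound[key].asa["total"] <= u.asa["total"] + 1e-9

    def test_struct_invariants_hold(self, toy_complex):
        feats = compute_state_features(toy_complex, "bound", n_sphere_points=240)
        for f in feats.values():
            assert all(v >= 0 for v in f.asa.values())
            assert all(v >= 0 for v in f.di.values())
            assert f.di["min"] <= f.di["total_mean"] <= f.di["max"] + 1e-12
            assert f.pi["min"] <= f.pi["total_mean"] <= f.pi["max"] + 1e-12

    def test_feature_table_covers_schema(self, toy_complex):
        df = extract_structure_features(toy_complex, ["A"], ["B"], n_sphere_points=240)
        assert len(df) > 0
        for name in structure_feature_names():
            assert name in df.columns
        assert (df["delta_tot"] > 0).all()
        assert df["core_rim"].between(0, 1).all()
        np.testing.assert_allclose(
            df["pos_per"], df["core_rim"] * df["seq_index"] / df["n_interface"]
        )
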