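"""Building-block classification, parameter accounting and ITP round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgcalib.config import load_representation
from cgcalib.topology import (
    BeadSpec,
    BuildingBlock,
    BuildingBlockLibrary,
    EncodingError,
    LipidTopology,
    ParameterVector,
    TopologyError,
    canonical_key,
    classify_terms,
    count_free_parameters,
    decode,
    encode,
    parameter_bounds,
    read_itp,
    write_itp,
)


class TestTypes:
    def test_size_class_inferred_from_type_prefix(self):
        assert BeadSpec("a", "Q1", (0,)).size_class == "regular"
        assert BeadSpec("b", "SN4a", (0,)).size_class == "small"
        assert BeadSpec("c", "TC2", (0,)).size_class == "tiny"

    def test_size_class_conflict_rejected(self):
        with pytest.raises(TopologyError):
            BeadSpec("a", "SN4a", (0,), size_class="regular")

    def test_angle_middle_bead_must_bond_both_flanks(self):
        beads = tuple(BeadSpec(f"B{i}", "C1", (i,)) for i in range(4))
        with pytest.raises(TopologyError, match="middle bead"):
            LipidTopology("BAD", beads, ((0, 1), (1, 2), (2, 3)), ((0, 2, 3),))

    def test_disconnected_graph_rejected(self):
        beads = tuple(BeadSpec(f"B{i}", "C1", (i,)) for i in range(4))
        with pytest.raises(TopologyError, match="not connected"):
            LipidTopology("BAD", beads, ((0, 1), (2, 3)))

    def test_fixed_equilibrium_only_for_angles(self):
        with pytest.raises(TopologyError):
            BuildingBlock("bond", ("C1", "C1"), 0.4, 1000.0, equilibrium_fixed=True)
        blk = BuildingBlock("angle", ("C1", "C1", "C1"), 120.0, 50.0,
                            equilibrium_fixed=True)
        assert blk.equilibrium == 180.0


class TestClassify:
    def test_two_bead_lipid_gives_single_bond_type(self, two_bead_lipid):
        lib = classify_terms([two_bead_lipid])
        assert len(lib.bonds()) == 1
        assert len(lib.angles()) == 0

    def test_reversed_angle_orientation_shares_canonical_type(self):
        # same chemistry traversed in opposite directions in two lipids
        l1 = LipidTopology.from_chain("L1", ("Q1", "Q5", "SN4a"))
        l2 = LipidTopology.from_chain("L2", ("SN4a", "Q5", "Q1"))
        lib = classify_terms([l1, l2])
        assert len(lib.angles()) == 1
        assert lib.angles()[0].key == canonical_key(("Q1", "Q5", "SN4a"))
        assert lib.angles()[0].n_instances == 2

    def test_classification_invariant_under_bond_reversal(self):
        assert canonical_key(("Q5", "Q1")) == canonical_key(("Q1", "Q5"))
        assert canonical_key(("SN4a", "Q5", "Q1")) == ("Q1", "Q5", "SN4a")

    def test_sharing_never_increases_parameter_count(self, small_library):
        _, (t1, t2) = small_library
        combined = count_free_parameters(classify_terms([t1, t2]))
        separate = count_free_parameters(classify_terms([t1])) + \
            count_free_parameters(classify_terms([t2]))
        assert combined <= separate

    def test_unknown_fixed_angle_key_rejected(self, two_bead_lipid):
        with pytest.raises(TopologyError):
            classify_terms([two_bead_lipid], fixed_angle_keys=[("X", "Y", "Z")])


class TestAccounting:
    @pytest.mark.parametrize(
        "n_bonds,n_angles,n_fixed,expected",
        [(16, 27, 9, 77), (13, 12, 2, 48), (0, 0, 0, 0)],
    )
    def test_free_parameter_formula(self, n_bonds, n_angles, n_fixed, expected):
        lib = BuildingBlockLibrary()
        for i in range(n_bonds):
            lib.add(BuildingBlock("bond", (f"B{i}", f"B{i}x"), 0.4, 1000.0))
        for i in range(n_angles):
            lib.add(
                BuildingBlock(
                    "angle", (f"A{i}", f"A{i}y", f"A{i}z"), 120.0, 50.0,
                    equilibrium_fixed=i < n_fixed,
                )
            )
        assert count_free_parameters(lib) == expected

    @pytest.mark.parametrize(
        "rep,counts",
        [
            ("representation1_synthetic", (16, 27, 9, 77)),
            ("representation2_synthetic", (13, 12, 2, 48)),
        ],
    )
    def test_bundled_representations_reproduce_accounting(self, rep, counts):
        lib = load_representation(rep).build_library()
        n_fixed = sum(1 for a in lib.angles() if a.equilibrium_fixed)
        assert (len(lib.bonds()), len(lib.angles()), n_fixed,
                count_free_parameters(lib)) == counts


class TestEncodeDecode:
    def test_round_trip_identity(self, small_library):
        lib, _ = small_library
        restored = decode(encode(lib), lib)
        for k, blk in lib.blocks.items():
            assert restored.blocks[k].equilibrium == blk.equilibrium
            assert restored.blocks[k].force_constant == blk.force_constant

    def test_single_value_change_is_local(self, small_library):
        lib, _ = small_library
        vec = encode(lib)
        values = vec.values.copy()
        idx = next(i for i, (_, _, role) in enumerate(vec.layout)
                   if role == "force_constant")
        values[idx] += 123.0
        changed = decode(ParameterVector(values, vec.layout), lib)
        kind, key, _ = vec.layout[idx]
        for k, blk in lib.blocks.items():
            if k == (kind, key):
                assert changed.blocks[k].force_constant == blk.force_constant + 123.0
            else:
                assert changed.blocks[k].force_constant == blk.force_constant
            assert changed.blocks[k].equilibrium == blk.equilibrium

    def test_layout_stable_across_encodings(self, small_library):
        lib, _ = small_library
        assert encode(lib).layout == encode(lib).layout
        assert np.array_equal(encode(lib).values, encode(lib).values)

    def test_fixed_equilibrium_not_encoded(self):
        lib = BuildingBlockLibrary()
        lib.add(BuildingBlock("angle", ("C1", "C1", "C1"), 120.0, 50.0,
                              equilibrium_fixed=True))
        vec = encode(lib)
        assert len(vec) == 1
        assert vec.layout[0][2] == "force_constant"
        restored = decode(vec, lib)
        assert restored.blocks[("angle", ("C1", "C1", "C1"))].equilibrium == 180.0

    def test_length_mismatch_rejected(self, small_library):
        lib, _ = small_library
        vec = encode(lib)
        with pytest.raises(EncodingError):
            ParameterVector(vec.values[:-1], vec.layout)

    def test_bounds_follow_layout_order(self, small_library):
        lib, _ = small_library
        b = parameter_bounds(lib)
        assert b.shape == (count_free_parameters(lib), 2)
        assert np.all(b[:, 0] < b[:, 1])

    @given(st.lists(st.floats(0.21, 0.79), min_size=2, max_size=2),
           st.floats(510.0, 9000.0))
    @settings(max_examples=25, deadline=None)
    def test_decode_encode_bijection_on_free_subspace(self, eqs, force):
        lib = BuildingBlockLibrary()
        lib.add(BuildingBlock("bond", ("A", "B"), eqs[0], force))
        lib.add(BuildingBlock("bond", ("B", "C"), eqs[1], 2 * force))
        vec = encode(lib)
        assert np.array_equal(encode(decode(vec, lib)).values, vec.values)


class TestItp:
    def test_two_bead_lipid_itp_has_single_bond_line(self, two_bead_lipid):
        lib = classify_terms([two_bead_lipid])
        blk = lib.bonds()[0]
        text = write_itp(lib, two_bead_lipid)
        bond_lines = [l for l in text.splitlines()
                      if l.strip() and l.split()[0] == "1" and "[" not in l]
        assert f"{blk.equilibrium:.6g}" in text
        assert f"{blk.force_constant:.6g}" in text
        assert "[ bonds ]" in text and "[ angles ]" not in text

    def test_representation2_dppc_round_trips(self):
        rep = load_representation("representation2_synthetic")
        lib = rep.build_library()
        rng = np.random.default_rng(0)
        for blk in lib:  # non-default parameters so the round-trip is informative
            if not blk.equilibrium_fixed:
                blk.equilibrium = float(rng.uniform(*blk.equilibrium_bounds))
            blk.force_constant = float(rng.uniform(*blk.force_bounds))
        dppc = next(t for t in rep.topologies if t.lipid_name == "DPPC")
        lib2, topo2 = read_itp(write_itp(lib, dppc))
        assert topo2.lipid_name == "DPPC"
        assert topo2.bonds == dppc.bonds and topo2.angles == dppc.angles
        for i, j in dppc.bonds:
            orig = lib.get("bond", dppc.bead_types((i, j)))
            back = lib2.get("bond", topo2.bead_types((i, j)))
            assert back.equilibrium == pytest.approx(orig.equilibrium, rel=1e-5)
            assert back.force_constant == pytest.approx(orig.force_constant, rel=1e-5)
        for i, j, k in dppc.angles:
            orig = lib.get("angle", dppc.bead_types((i, j, k)))
            back = lib2.get("angle", topo2.bead_types((i, j, k)))
            assert back.equilibrium == pytest.approx(orig.equilibrium, rel=1e-5)

    def test_fixed_angle_written_with_theta0_180(self):
        topo = LipidTopology.from_chain("LIN", ("C1", "C1", "C1"))
        lib = classify_terms([topo], fixed_angle_keys=[("C1", "C1", "C1")])
        text = write_itp(lib, topo)
        angle_line = [l for l in text.splitlines()
                      if l.strip().startswith("1") and len(l.split()) == 6]
        assert any(float(l.split()[4]) == 180.0 for l in angle_line)

    def test_unresolvable_term_raises(self, two_bead_lipid):
        empty = BuildingBlockLibrary()
        with pytest.raises(TopologyError):
            write_itp(empty, two_bead_lipid)
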