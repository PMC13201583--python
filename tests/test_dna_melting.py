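import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ringmetrics.dna_melting import (
    ContactCriteria,
    DuplexError,
    engaged_nucleotides,
    find_register,
    melted_count,
)
from ringmetrics.synthetic import (
    DnaSpec,
    RingSpec,
    engage_dna,
    make_bdna,
    make_ring,
    merge_models,
)

SEQ = "ACTGACTGACTGACTGACTGA"  # 21-mer


class TestRegister:
    def test_fully_paired_duplex(self, duplex_21):
        register = find_register(duplex_21, "X", "Y")
        assert len(register.pair_map) == 21
        assert register.unpaired_a == () and register.unpaired_b == ()

    def test_register_is_antiparallel(self, duplex_21):
        register = find_register(duplex_21, "X", "Y")
        nums_a = [a for a, _ in register.pair_map]
        nums_b = [b for _, b in register.pair_map]
        assert nums_a == sorted(nums_a)
        assert nums_b == sorted(nums_b, reverse=True)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 7])
    def test_deleted_partners_populate_unpaired_list(self, k):
        model = make_bdna(DnaSpec(sequence=SEQ, melted_5prime=k))
        register = find_register(model, "X", "Y")
        assert register.unpaired_a == tuple(range(1, k + 1))
        assert register.unpaired_b == ()
        assert len(register.pair_map) == 21 - k

    def test_invariant_under_rigid_motion(self, melted_duplex):
        base = find_register(melted_duplex, "X", "Y")
        R = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = melted_duplex.transformed(R, np.array([40.0, -12.0, 7.0]))
        after = find_register(moved, "X", "Y")
        assert after.pair_map == base.pair_map
        assert after.unpaired_a == base.unpaired_a

    def test_separated_strands_are_not_a_duplex(self):
        model = make_bdna(DnaSpec(sequence=SEQ))
        for res in model.chain("Y").residues:
            res.atoms = {k: v + np.array([200.0, 0, 0]) for k, v in res.atoms.items()}
        with pytest.raises(DuplexError, match="not a duplex"):
            find_register(model, "X", "Y")

    def test_too_few_nucleotides_rejected(self):
        model = make_bdna(DnaSpec(sequence="ACGTAC", melted_5prime=4))
        with pytest.raises(DuplexError, match="need >= 4"):
            find_register(model, "X", "Y")

    def test_tightened_criteria_exclude_pairs(self, duplex_21):
        with pytest.raises(DuplexError):
            find_register(duplex_21, "X", "Y", ContactCriteria(n1n3_max=0.5))


class TestMeltedCount:
    def test_fully_paired_is_zero(self, duplex_21):
        assert melted_count(find_register(duplex_21, "X", "Y"), "a") == 0

    @pytest.mark.parametrize("k", [0, 1, 2, 4, 6])
    def test_counts_programmed_melting(self, k):
        model = make_bdna(DnaSpec(sequence=SEQ, melted_5prime=k))
        register = find_register(model, "X", "Y")
        assert melted_count(register, "a") == k
        assert melted_count(register, "a", end="5prime") == k
        assert melted_count(register, "a", end="3prime") == 0

    def test_one_more_deleted_partner_increments_by_one(self):
        counts = [
            melted_count(
                find_register(make_bdna(DnaSpec(sequence=SEQ, melted_5prime=k)), "X", "Y"),
                "a",
            )
            for k in range(6)
        ]
        assert counts == list(range(6))

    def test_melted_plus_paired_bounded_by_modeled(self):
        for k in range(5):
            model = make_bdna(DnaSpec(sequence=SEQ, melted_5prime=k))
            register = find_register(model, "X", "Y")
            modeled = len(model.chain("X").residues)
            assert melted_count(register, "a") + len(register.pair_map) <= modeled


class TestEngagement:
    @pytest.fixture()
    def engaged_scene(self, archaeal_anchors):
        ring_model, truth = make_ring(RingSpec(seed=17))
        dna = make_bdna(DnaSpec(sequence=SEQ, melted_5prime=4))
        programmed = engage_dna(
            ring_model, truth.ring_map(), archaeal_anchors, dna, "X", 5
        )
        merged = merge_models("scene", ring_model, dna)
        return merged, truth.ring_map(), programmed

    def test_programmed_engagement_recovered_exactly(
        self, engaged_scene, archaeal_anchors
    ):
        merged, ring, programmed = engaged_scene
        count, resnums = engaged_nucleotides(merged, ring, archaeal_anchors, "X")
        assert count == len(programmed) == 5
        assert resnums == programmed

    def test_count_monotone_in_engagement_cutoff(self, engaged_scene, archaeal_anchors):
        merged, ring, _ = engaged_scene
        counts = [
            engaged_nucleotides(
                merged, ring, archaeal_anchors, "X",
                ContactCriteria(engagement_max=cutoff),
            )[0]
            for cutoff in (2.0, 3.0, 3.6, 5.0, 8.0)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("n", [1, 3, 7])
    def test_varied_programmed_counts(self, n, archaeal_anchors):
        ring_model, truth = make_ring(RingSpec(seed=29))
        dna = make_bdna(DnaSpec(sequence=SEQ))
        engage_dna(ring_model, truth.ring_map(), archaeal_anchors, dna, "X", n)
        merged = merge_models("scene", ring_model, dna)
        count, _ = engaged_nucleotides(merged, truth.ring_map(), archaeal_anchors, "X")
        assert count == n

    def test_unengaged_ring_counts_zero(self, archaeal_anchors):
        ring_model, truth = make_ring(RingSpec(seed=19))
        dna = make_bdna(DnaSpec(sequence=SEQ))
        merged = merge_models("scene", ring_model, dna)
        count, resnums = engaged_nucleotides(
            merged, truth.ring_map(), archaeal_anchors, "X"
        )
        assert count == 0 and resnums == []

    def test_missing_dna_errors(self, uniform_ring, archaeal_anchors):
        model, truth = uniform_ring
        with pytest.raises(Exception):
            engaged_nucleotides(model, truth.ring_map(), archaeal_anchors, "X")
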