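import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringmetrics.interfaces import (
    ClassificationCriteria,
    classify_from_distance_table,
    classify_ring,
    measure_interface,
    printed_distance_table,
    ring_report_tsv,
)
from ringmetrics.synthetic import RingSpec, make_ring

# tight counts implied by the published interface-distance table under
# the dual strict thresholds (<6.8 Å ATP site, <8.0 Å h2i-ps1beta)
EXPECTED_TIGHT = {
    "Class1a": 0, "Class2a": 2, "Class2b": 3,
    "7W1Y": 4, "5BK4": 1, "9GJW": 2, "9E2X": 1,
    "7PMN": 2, "7PMK": 3, "7Z13": 3,
}


class TestPrintedTable:
    @pytest.mark.parametrize("structure,expected", sorted(EXPECTED_TIGHT.items()))
    def test_tight_counts_from_published_distances(self, structure, expected):
        table = printed_distance_table()
        result = classify_from_distance_table(
            table[structure]["pairs"], names=table[structure]["interfaces"]
        )
        assert result.tight_count == expected

    def test_single_criterion_interface_is_loose(self):
        # 5BK4's 4:7 interface passes only the ATP-site criterion
        table = printed_distance_table()
        idx = table["5BK4"]["interfaces"].index("4:7")
        atp, h2i = table["5BK4"]["pairs"][idx]
        assert atp == pytest.approx(6.337) and h2i == pytest.approx(8.68)
        result = classify_from_distance_table(table["5BK4"]["pairs"])
        assert result.measurements[idx].tight is False

    def test_all_small_pairs_all_tight(self):
        result = classify_from_distance_table([(1.0, 1.0)] * 6)
        assert result.tight_count == 6

    def test_non_positive_distance_rejected(self):
        pairs = [(5.0, 7.0)] * 5 + [(0.0, 7.0)]
        with pytest.raises(ValueError, match="non-positive"):
            classify_from_distance_table(pairs)


class TestBoundary:
    def test_exact_threshold_values_are_loose(self):
        result = classify_from_distance_table([(6.8, 8.0)] * 6)
        assert result.tight_count == 0
        just_under = classify_from_distance_table([(6.7999, 7.9999)] * 6)
        assert just_under.tight_count == 6


class TestCoordinateClassification:
    def test_programmed_distances_recovered_exactly(self, archaeal_anchors):
        model, truth = make_ring(
            RingSpec(interface_atp_distances=5.0, interface_h2i_distances=7.0, seed=2)
        )
        m = measure_interface(model, truth.ring_map(), archaeal_anchors, 1)
        assert m.atp_site_distance == pytest.approx(5.0, abs=1e-6)
        assert m.h2i_ps1b_distance == pytest.approx(7.0, abs=1e-6)
        assert m.tight is True

    def test_mixed_ring_counts_match_programmed_pattern(self, asym_ring, archaeal_anchors):
        model, truth = asym_ring
        result = classify_ring(model, truth.ring_map(), archaeal_anchors)
        expected = sum(
            1
            for atp, h2i in zip(truth.atp_distances, truth.h2i_distances)
            if atp < 6.8 and h2i < 8.0
        )
        assert result.tight_count == expected
        measured = [
            (m.atp_site_distance, m.h2i_ps1b_distance) for m in result.measurements
        ]
        for (atp, h2i), (patp, ph2i) in zip(
            measured, zip(truth.atp_distances, truth.h2i_distances)
        ):
            assert atp == pytest.approx(patp, abs=1e-6)
            assert h2i == pytest.approx(ph2i, abs=1e-6)

    def test_coordinate_and_table_routes_agree(self, asym_ring, archaeal_anchors):
        model, truth = asym_ring
        by_coords = classify_ring(model, truth.ring_map(), archaeal_anchors)
        pairs = [
            (m.atp_site_distance, m.h2i_ps1b_distance) for m in by_coords.measurements
        ]
        by_table = classify_from_distance_table(pairs)
        assert [m.tight for m in by_table.measurements] == [
            m.tight for m in by_coords.measurements
        ]

    def test_disordered_domain_reports_unmeasurable_not_loose(self, archaeal_anchors):
        model, truth = make_ring(RingSpec(seed=9))
        # remove chain C's entire ATPase domain
        chain = model.chain("C")
        for resnum in [r.seqid for r in chain.residues if r.seqid >= 1319]:
            chain.remove_residue(resnum)
        result = classify_ring(model, truth.ring_map(), archaeal_anchors)
        unmeasurable = result.unmeasurable
        # both interfaces flanking chain C fail, with the anchor named
        assert {m.name for m in unmeasurable} == {"B:C", "C:D"}
        assert all("C/" in m.failure for m in unmeasurable)
        assert result.tight_count == 4
        report = ring_report_tsv(model.id, result)
        assert "unmeasurable" in report and "tight_count=4" in report

    def test_distance_symmetric_in_argument_order(self, uniform_ring, archaeal_anchors):
        model, truth = uniform_ring
        m = measure_interface(model, truth.ring_map(), archaeal_anchors, 3)
        a = model.get_atom(m.walkerA_chain, 1330, "CA")
        b = model.get_atom(m.argF_chain, 1824, "CA")
        assert np.linalg.norm(a - b) == np.linalg.norm(b - a)


@given(
    pairs=st.lists(
        st.tuples(
            st.floats(0.5, 25.0, allow_nan=False), st.floats(0.5, 25.0, allow_nan=False)
        ),
        min_size=6,
        max_size=6,
    ),
    bump_atp=st.floats(0.0, 5.0),
    bump_h2i=st.floats(0.0, 5.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_tight_count_monotone_in_thresholds(pairs, bump_atp, bump_h2i):
    base = classify_from_distance_table(pairs)
    raised = classify_from_distance_table(
        pairs, ClassificationCriteria(6.8 + bump_atp, 8.0 + bump_h2i)
    )
    assert raised.tight_count >= base.tight_count
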