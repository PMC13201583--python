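import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ringmetrics.geometry import superpose
from ringmetrics.setting_rmsd import (
    CoreBuildError,
    CoreHexamer,
    SettingRmsdTable,
    all_setting_rmsds,
    bin_and_sort,
    build_core_hexamer,
    extract_core_template,
    setting_rmsd,
)
from ringmetrics.synthetic import RingSpec, make_ring


@pytest.fixture()
def asym_hexamer(asym_ring, archaeal_anchors):
    model, truth = asym_ring
    template = extract_core_template(model, "A", archaeal_anchors["archaeal"])
    return build_core_hexamer(model, truth.ring_map(), template, anchors=archaeal_anchors)


class TestBuild:
    def test_own_chain_template_fits_exactly(self, uniform_ring, archaeal_anchors):
        model, truth = uniform_ring
        template = extract_core_template(model, "F", archaeal_anchors["archaeal"])
        hexamer = build_core_hexamer(
            model, truth.ring_map(), template, anchors=archaeal_anchors
        )
        assert hexamer.per_copy_fit_rmsd[5] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_ring_recovered_within_tolerance(
        self, uniform_ring, archaeal_anchors
    ):
        # a C6-symmetric ring is six exact rigid copies of one template;
        # the recovered copies must coincide with the programmed placements
        model, truth = uniform_ring
        assert truth.rigid_copies
        template = extract_core_template(model, "A", archaeal_anchors["archaeal"])
        hexamer = build_core_hexamer(
            model, truth.ring_map(), template, anchors=archaeal_anchors
        )
        for i, copy in enumerate(hexamer.copies):
            expected = hexamer.copies[0] @ truth.placements[i].rotation.T
            assert np.max(np.abs(copy - expected)) < 1e-6
        assert all(r < 1e-9 for r in hexamer.per_copy_fit_rmsd)

    def test_fit_rmsds_finite_and_reported_in_ring_order(self, asym_hexamer):
        assert len(asym_hexamer.per_copy_fit_rmsd) == 6
        assert all(np.isfinite(asym_hexamer.per_copy_fit_rmsd))
        assert asym_hexamer.chain_ids == ("A", "B", "C", "D", "E", "F")

    def test_coverage_floor_enforced(self, archaeal_anchors):
        model, truth = make_ring(RingSpec(seed=13))
        chain = model.chain("E")
        for resnum in [r.seqid for r in chain.residues if 1729 <= r.seqid <= 1748]:
            chain.remove_residue(resnum)  # drop 20 of 152 core residues
        template = extract_core_template(model, "A", archaeal_anchors["archaeal"])
        with pytest.raises(CoreBuildError, match="chain E"):
            build_core_hexamer(model, truth.ring_map(), template, anchors=archaeal_anchors)

    def test_missing_correspondence_errors(self, uniform_ring, archaeal_anchors):
        model, truth = uniform_ring
        template = extract_core_template(model, "A", archaeal_anchors["archaeal"])
        identity = {rn: rn for rn in template.resnums}
        partial = {c: identity for c in "ABCDE"}  # chain F missing
        with pytest.raises(CoreBuildError, match="correspondence supplied for chain F"):
            build_core_hexamer(model, truth.ring_map(), template, correspondence=partial)


class TestSettingRmsd:
    def test_self_identity_zero_at_setting_one(self, asym_hexamer):
        table = all_setting_rmsds(asym_hexamer, asym_hexamer)
        assert table.rmsd_by_setting[1] == pytest.approx(0.0, abs=1e-9)
        assert table.best_setting == 1
        assert all(table.rmsd_by_setting[s] > 1e-4 for s in range(2, 7))

    def test_relabel_equivariance(self, asym_hexamer):
        for k in range(1, 6):
            rotated = asym_hexamer.rotated_labels(k)
            table = all_setting_rmsds(asym_hexamer, rotated)
            assert table.best_setting == k + 1
            assert table.best_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_rigid_motion_of_target(self, asym_hexamer):
        base = all_setting_rmsds(asym_hexamer, asym_hexamer)
        R = Rotation.from_rotvec([0.2, 0.9, -0.4]).as_matrix()
        t = np.array([30.0, -7.0, 12.0])
        moved = CoreHexamer(
            "moved",
            tuple(c @ R.T + t for c in asym_hexamer.copies),
            asym_hexamer.per_copy_fit_rmsd,
            asym_hexamer.chain_ids,
        )
        after = all_setting_rmsds(asym_hexamer, moved)
        for s in range(1, 7):
            assert after.rmsd_by_setting[s] == pytest.approx(
                base.rmsd_by_setting[s], abs=1e-8
            )

    def test_global_rmsd_at_least_best_single_copy(self, asym_hexamer):
        # the 912-point one-shot superposition cannot beat the best
        # individually superposed copy pair
        rng = np.random.default_rng(31)
        target = CoreHexamer(
            "perturbed",
            tuple(c + rng.normal(scale=0.5, size=c.shape) for c in asym_hexamer.copies),
            (0.0,) * 6,
        )
        whole = setting_rmsd(asym_hexamer, target, 1)
        parts = [
            superpose(r, t)[1] for r, t in zip(asym_hexamer.copies, target.copies)
        ]
        assert whole >= min(parts) - 1e-9

    def test_invalid_setting_rejected(self, asym_hexamer):
        with pytest.raises(ValueError, match="setting"):
            setting_rmsd(asym_hexamer, asym_hexamer, 0)
        with pytest.raises(ValueError, match="setting"):
            setting_rmsd(asym_hexamer, asym_hexamer, 7)


class TestBinAndSort:
    @staticmethod
    def _table(target: str, best: int, value: float) -> SettingRmsdTable:
        by_setting = {s: value + (0.0 if s == best else 1.0) for s in range(1, 7)}
        return SettingRmsdTable("ref", target, by_setting)

    def test_staggered_records_subbin_by_setting(self):
        rows = bin_and_sort(
            [
                ("form2_like", "staggered", self._table("form2_like", 1, 1.0)),
                ("form1_like", "staggered", self._table("form1_like", 4, 1.2)),
            ]
        )
        assert [r["best_setting"] for r in rows] == [1, 4]

    def test_reverse_sorted_within_subbin_and_class_order(self):
        rows = bin_and_sort(
            [
                ("s_low", "staggered", self._table("s_low", 1, 0.5)),
                ("s_high", "staggered", self._table("s_high", 1, 2.5)),
                ("e_one", "eclipsed", self._table("e_one", 2, 1.0)),
            ]
        )
        assert [r["structure_id"] for r in rows] == ["e_one", "s_high", "s_low"]

    def test_ties_stable_by_structure_id(self):
        rows = bin_and_sort(
            [
                ("zeta", "staggered", self._table("zeta", 1, 1.0)),
                ("alpha", "staggered", self._table("alpha", 1, 1.0)),
            ]
        )
        assert [r["structure_id"] for r in rows] == ["alpha", "zeta"]

    def test_empty_input_empty_report(self):
        assert bin_and_sort([]) == []
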