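"""Permuted hexamer-core RMSD: comparing rings in all six cyclic settings.

A hexamer is reduced to six rigid copies of one 152-residue ATPase-core
template, each copy placed by least-squares superposition onto the
corresponding subunit.  Two such idealized core hexamers are compared by
relabelling the reference's copies through each of the six cyclic ring
rotations ("settings"), concatenating all 6 x 152 = 912 Cα pairs, and
performing a single global superposition per setting.  The setting with
the lowest RMSD identifies which rotational register of the reference
the target most resembles; among staggered eukaryotic Mcm2-7 rings this
separates the two principal forms (offset by 180° from one another).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import CORE_SIZE, RingMap, SubunitAnchors
from .geometry import GeometryError, superpose
from .model_io import StructureModel, get_calpha

__all__ = [
    "CoreTemplate",
    "CoreHexamer",
    "SettingRmsdTable",
    "CoreBuildError",
    "extract_core_template",
    "build_core_hexamer",
    "setting_rmsd",
    "all_setting_rmsds",
    "bin_and_sort",
    "MIN_CORE_COVERAGE",
]

# minimum number of the 152 core residues a chain must resolve for a
# template fit; tolerates local disorder without letting a fragment
# masquerade as a core
MIN_CORE_COVERAGE = 140


class CoreBuildError(ValueError):
    """Core hexamer could not be constructed."""


@dataclass(frozen=True)
class CoreTemplate:
    """A 152-point Cα template with its source residue numbering."""

    resnums: tuple[int, ...]
    coords: np.ndarray  # (152, 3)
    source: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if len(self.resnums) != CORE_SIZE or coords.shape != (CORE_SIZE, 3):
            raise CoreBuildError(
                f"core template must have exactly {CORE_SIZE} residues/points"
            )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "resnums", tuple(int(r) for r in self.resnums))


@dataclass(frozen=True)
class CoreHexamer:
    """Six rigid template copies in ring order, with per-copy fit RMSDs."""

    source_id: str
    copies: tuple[np.ndarray, ...]      # six (152, 3) arrays
    per_copy_fit_rmsd: tuple[float, ...]
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.copies) != 6 or len(self.per_copy_fit_rmsd) != 6:
            raise CoreBuildError("core hexamer requires exactly six copies")
        copies = tuple(np.asarray(c, dtype=float) for c in self.copies)
        for c in copies:
            if c.shape != (CORE_SIZE, 3):
                raise CoreBuildError(f"each copy must be {CORE_SIZE} x 3")
        if not all(np.isfinite(r) for r in self.per_copy_fit_rmsd):
            raise CoreBuildError("non-finite per-copy fit RMSD")
        object.__setattr__(self, "copies", copies)

    def rotated_labels(self, k: int) -> "CoreHexamer":
        """Ring labels rotated by ``k`` positions (copy j -> position j-k)."""
        idx = [(j + k) % 6 for j in range(6)]
        return CoreHexamer(
            self.source_id,
            tuple(self.copies[i] for i in idx),
            tuple(self.per_copy_fit_rmsd[i] for i in idx),
            tuple(self.chain_ids[i] for i in idx) if self.chain_ids else (),
        )


@dataclass(frozen=True)
class SettingRmsdTable:
    reference_id: str
    target_id: str
    rmsd_by_setting: dict[int, float]

    @property
    def best_setting(self) -> int:
        # ties break to the lowest setting index
        return min(sorted(self.rmsd_by_setting), key=lambda s: self.rmsd_by_setting[s])

    @property
    def best_rmsd(self) -> float:
        return self.rmsd_by_setting[self.best_setting]


def extract_core_template(
    model: StructureModel, chain_id: str, anchors: SubunitAnchors
) -> CoreTemplate:
    """Pull the full 152-residue Cα core of one chain as a template."""
    resnums = anchors.residues_in("core_ranges")
    coords = [get_calpha(model, chain_id, rn) for rn in resnums]
    return CoreTemplate(tuple(resnums), np.array(coords), f"{model.id}/{chain_id}")


def build_core_hexamer(
    model: StructureModel,
    ring: RingMap,
    template: CoreTemplate,
    correspondence: dict[str, dict[int, int]] | None = None,
    anchors: dict[str, SubunitAnchors] | None = None,
) -> CoreHexamer:
    """Place the core template rigidly onto each subunit of a ring.

    For each chain the template is superposed onto the chain's matching
    core Cα (matched through ``correspondence[chain]``, a template-resnum
    -> chain-resnum map; or through the subunit's own ``core_ranges``
    from ``anchors``; or identity numbering).  At least
    ``MIN_CORE_COVERAGE`` of the 152 residues must resolve; missing
    residues are dropped from the fit, but the stored copy is always the
    complete transformed 152-point template.
    """
    if len(ring) != 6:
        raise CoreBuildError(f"hexameric ring required, got {len(ring)}")
    copies, fit_rmsds = [], []
    for chain_id, label in ring.ordered_chains:
        if correspondence is not None:
            if chain_id not in correspondence:
                raise CoreBuildError(f"no core correspondence supplied for chain {chain_id}")
            mapping = correspondence[chain_id]
        elif anchors is not None and anchors[label].core_ranges:
            sub_res = anchors[label].residues_in("core_ranges")
            mapping = dict(zip(template.resnums, sub_res))
        else:
            mapping = {rn: rn for rn in template.resnums}

        t_xyz, s_xyz = [], []
        chain = model.chain(chain_id)
        for i, trn in enumerate(template.resnums):
            srn = mapping.get(trn)
            if srn is None:
                continue
            sres = chain.get(srn)
            if sres is None or "CA" not in sres.atoms:
                continue
            t_xyz.append(template.coords[i])
            s_xyz.append(sres.atoms["CA"])
        if len(s_xyz) < MIN_CORE_COVERAGE:
            raise CoreBuildError(
                f"chain {chain_id}: only {len(s_xyz)}/{CORE_SIZE} core Cα resolved "
                f"(floor {MIN_CORE_COVERAGE})"
            )
        try:
            xform, fit = superpose(np.array(s_xyz), np.array(t_xyz))
        except GeometryError as exc:
            raise CoreBuildError(f"chain {chain_id}: core fit failed: {exc}") from exc
        copies.append(xform.apply(template.coords))
        fit_rmsds.append(fit)
    return CoreHexamer(model.id, tuple(copies), tuple(fit_rmsds), ring.chain_ids)


def setting_rmsd(reference: CoreHexamer, target: CoreHexamer, setting: int) -> float:
    """Global 912-point RMSD of ``target`` against one reference setting.

    Setting ``k`` pairs target position *j* with reference position
    *j + k - 1* (cyclic); setting 1 is the direct pairing.  All 912 Cα
    pairs are superposed in a single global fit — the ring is compared
    as a unit, not copy by copy.
    """
    if setting not in range(1, 7):
        raise ValueError(f"setting must be 1-6, got {setting}")
    ref_pts = np.vstack([reference.copies[(j + setting - 1) % 6] for j in range(6)])
    tgt_pts = np.vstack(target.copies)
    _, value = superpose(ref_pts, tgt_pts)
    return value


def all_setting_rmsds(reference: CoreHexamer, target: CoreHexamer) -> SettingRmsdTable:
    return SettingRmsdTable(
        reference.source_id,
        target.source_id,
        {s: setting_rmsd(reference, target, s) for s in range(1, 7)},
    )


def bin_and_sort(
    records: list[tuple[str, str, SettingRmsdTable]],
) -> list[dict]:
    """Order structures for a survey report.

    ``records`` holds (structure_id, tier_class, rmsd table).  Structures
    are binned by tier class (eclipsed, staggered, indeterminate), then
    sub-binned by best-fitting setting, and each sub-bin is reverse-sorted
    by its best RMSD; equal RMSDs order stably by structure id.
    """
    class_order = {"eclipsed": 0, "staggered": 1, "indeterminate": 2}
    rows = [
        {
            "structure_id": sid,
            "tier_class": tier_class,
            "best_setting": table.best_setting,
            "best_rmsd": table.best_rmsd,
            "rmsd_by_setting": dict(table.rmsd_by_setting),
        }
        for sid, tier_class, table in records
    ]
    rows.sort(
        key=lambda r: (
            class_order.get(r["tier_class"], 3),
            r["best_setting"],
            -r["best_rmsd"],
            r["structure_id"],
        )
    )
    return rows
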