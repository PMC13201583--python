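"""Inter-tier dihedral statistic: eclipsed versus staggered rings.

MCM rings stack an N-terminal-domain tier on an ATPase tier.  The
rotational register between the tiers is quantified per subunit by a
four-point torsion: N-tier anchor Cα of the subunit, the pooled N-tier
centroid, the pooled C-tier centroid, and the subunit's C-tier anchor
Cα.  A mean near 0° means the inter-subunit seams of the two tiers
align (eclipsed); strongly negative means they are offset (staggered).
Structures bin as eclipsed when the mean exceeds −15° and staggered
below −25°; the band between is reported as indeterminate rather than
force-binned.

Two centroid modes are supported.  *Direct* mode pools the actual OB
(107-residue) and ATPase-core (152-residue) Cα positions of each chain,
which requires per-chain residue ranges (available for the archaeal
chimera).  *Template* mode superposes a reference OB-fold and core onto
each subunit and pools the transformed template copies, transferring the
template's anchor points the same way — this is how heterohexamers
whose per-chain numbering is unknown are handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import RingMap, SubunitAnchors
from .geometry import GeometryError, centroid, dihedral, superpose, wrap_angle
from .model_io import AtomLookupError, StructureModel, get_calpha

__all__ = [
    "DihedralResult",
    "TierError",
    "ECLIPSED_THRESHOLD",
    "STAGGERED_THRESHOLD",
    "collect_ca",
    "tier_centroids",
    "subunit_dihedral",
    "mean_and_classify",
    "analyze_ring",
]

ECLIPSED_THRESHOLD = -15.0   # mean dihedral above this: eclipsed
STAGGERED_THRESHOLD = -25.0  # mean dihedral below this: staggered

# fraction of a tier's residue range that must be modeled for the
# tier to count as resolved in direct mode
MIN_TIER_COVERAGE = 0.5


class TierError(ValueError):
    """Tier geometry could not be established (e.g. missing OB-folds)."""


@dataclass(frozen=True)
class DihedralResult:
    structure_id: str
    per_subunit: dict[str, float]
    omitted: tuple[str, ...] = ()

    @property
    def mean_dihedral(self) -> float:
        return mean_and_classify(list(self.per_subunit.values()))[0]

    @property
    def tier_class(self) -> str:
        return mean_and_classify(list(self.per_subunit.values()))[1]


def collect_ca(
    model: StructureModel, chain_id: str, resnums: list[int]
) -> tuple[np.ndarray, list[int]]:
    """Cα coordinates present for ``resnums``; returns (coords, found resnums)."""
    coords, found = [], []
    chain = model.chain(chain_id)
    for rn in resnums:
        res = chain.get(rn)
        if res is not None and "CA" in res.atoms:
            coords.append(res.atoms["CA"])
            found.append(rn)
    return np.array(coords, dtype=float).reshape(-1, 3), found


def _direct_tier_points(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    which: str,
) -> np.ndarray:
    pooled = []
    for chain_id, label in ring.ordered_chains:
        resnums = anchors[label].residues_in(which)
        coords, found = collect_ca(model, chain_id, resnums)
        if len(found) < MIN_TIER_COVERAGE * len(resnums):
            raise TierError(
                f"chain {chain_id}: only {len(found)}/{len(resnums)} Cα resolved in "
                f"{which}; tier not resolvable for all subunits"
            )
        pooled.append(coords)
    return np.vstack(pooled)


@dataclass(frozen=True)
class _TierGeometry:
    """Internal: tier centroids plus per-chain anchor points."""

    n_centroid: np.ndarray
    c_centroid: np.ndarray
    ob_anchor: dict[str, np.ndarray]
    aaa_anchor: dict[str, np.ndarray]
    omitted: tuple[str, ...] = ()


def tier_centroids(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    template: StructureModel | None = None,
    template_chain: str | None = None,
    template_anchors: SubunitAnchors | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """N-tier and C-tier centroids of the pooled six-subunit Cα sets."""
    geo = _tier_geometry(model, ring, anchors, template, template_chain, template_anchors)
    return geo.n_centroid, geo.c_centroid


def _tier_geometry(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    template: StructureModel | None = None,
    template_chain: str | None = None,
    template_anchors: SubunitAnchors | None = None,
) -> _TierGeometry:
    if template is None:
        n_cent = centroid(_direct_tier_points(model, ring, anchors, "ob_ranges"))
        c_cent = centroid(_direct_tier_points(model, ring, anchors, "core_ranges"))
        ob_pts: dict[str, np.ndarray] = {}
        aaa_pts: dict[str, np.ndarray] = {}
        omitted = []
        for chain_id, label in ring.ordered_chains:
            anc = anchors[label]
            if anc.ob_anchor is None or anc.aaa_anchor is None:
                omitted.append(chain_id)
                continue
            try:
                ob_pts[chain_id] = get_calpha(model, chain_id, anc.ob_anchor)
                aaa_pts[chain_id] = get_calpha(model, chain_id, anc.aaa_anchor)
            except AtomLookupError:
                omitted.append(chain_id)
        return _TierGeometry(n_cent, c_cent, ob_pts, aaa_pts, tuple(omitted))
    return _template_tier_geometry(
        model, ring, anchors, template, template_chain, template_anchors
    )


def _template_tier_geometry(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    template: StructureModel,
    template_chain: str | None,
    template_anchors: SubunitAnchors | None,
) -> _TierGeometry:
    """Template mode: fit a reference OB-fold and core onto each subunit.

    The template chain's OB and core Cα sets are superposed onto the
    matching Cα of each target subunit (matched by residue number via the
    target subunit's own ranges, which must correspond 1:1 to the
    template ranges in length).  The transformed template copies are
    pooled for the tier centroids, and the template's two anchor Cα are
    carried through each subunit's fitted transform.
    """
    if template_chain is None:
        template_chain = template.chains[0].chain_id
    t_anc = template_anchors or next(iter(anchors.values()))
    t_ob_res = t_anc.residues_in("ob_ranges")
    t_core_res = t_anc.residues_in("core_ranges")
    if t_anc.ob_anchor is None or t_anc.aaa_anchor is None:
        raise TierError("template anchors must define ob_anchor and aaa_anchor")
    t_ob_anchor = get_calpha(template, template_chain, t_anc.ob_anchor)
    t_aaa_anchor = get_calpha(template, template_chain, t_anc.aaa_anchor)

    n_pool, c_pool = [], []
    ob_pts: dict[str, np.ndarray] = {}
    aaa_pts: dict[str, np.ndarray] = {}
    omitted: list[str] = []
    for chain_id, label in ring.ordered_chains:
        anc = anchors[label]
        sub_ob = anc.residues_in("ob_ranges")
        sub_core = anc.residues_in("core_ranges")
        fits = []
        for t_res, s_res in ((t_ob_res, sub_ob), (t_core_res, sub_core)):
            t_xyz, s_xyz = [], []
            chain = model.chain(chain_id)
            for tr, sr in zip(t_res, s_res):
                sres = chain.get(sr)
                if sres is None or "CA" not in sres.atoms:
                    continue
                t_xyz.append(get_calpha(template, template_chain, tr))
                s_xyz.append(sres.atoms["CA"])
            if len(s_xyz) < MIN_TIER_COVERAGE * len(s_res):
                raise TierError(
                    f"chain {chain_id}: {len(s_xyz)}/{len(s_res)} Cα matched to template"
                )
            try:
                xform, _ = superpose(np.array(s_xyz), np.array(t_xyz))
            except GeometryError as exc:
                raise TierError(f"chain {chain_id}: template fit failed: {exc}") from exc
            fits.append((xform, np.array(t_xyz)))
        (ob_fit, t_ob_xyz), (core_fit, t_core_xyz) = fits
        n_pool.append(ob_fit.apply(t_ob_xyz))
        c_pool.append(core_fit.apply(t_core_xyz))
        ob_pts[chain_id] = ob_fit.apply(t_ob_anchor)
        aaa_pts[chain_id] = core_fit.apply(t_aaa_anchor)
    return _TierGeometry(
        centroid(np.vstack(n_pool)), centroid(np.vstack(c_pool)),
        ob_pts, aaa_pts, tuple(omitted),
    )


def subunit_dihedral(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    chain_id: str,
    **tier_kwargs,
) -> float:
    """The four-point inter-tier torsion for one subunit, degrees."""
    geo = _tier_geometry(model, ring, anchors, **tier_kwargs)
    if chain_id not in geo.ob_anchor:
        raise AtomLookupError(f"anchors unresolvable for chain {chain_id}")
    return dihedral(
        geo.ob_anchor[chain_id], geo.n_centroid, geo.c_centroid, geo.aaa_anchor[chain_id]
    )


def mean_and_classify(values: list[float]) -> tuple[float, str]:
    """Arithmetic mean of wrapped angles and the eclipsed/staggered bin.

    Angles are wrapped into (−180, 180] then averaged arithmetically; in
    practice the per-subunit values of real rings sit within a narrow
    band, where the arithmetic and circular means agree (see the methods
    note for the pathological-input caveat).
    """
    if not values:
        raise ValueError("no dihedrals to average")
    mean = float(np.mean([wrap_angle(v) for v in values]))
    if mean > ECLIPSED_THRESHOLD:
        tier_class = "eclipsed"
    elif mean < STAGGERED_THRESHOLD:
        tier_class = "staggered"
    else:
        tier_class = "indeterminate"
    return mean, tier_class


def analyze_ring(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    **tier_kwargs,
) -> DihedralResult:
    """Per-subunit dihedrals, their mean, and the tier class for one ring."""
    geo = _tier_geometry(model, ring, anchors, **tier_kwargs)
    per_subunit = {
        chain_id: dihedral(
            geo.ob_anchor[chain_id], geo.n_centroid, geo.c_centroid, geo.aaa_anchor[chain_id]
        )
        for chain_id, _ in ring.ordered_chains
        if chain_id in geo.ob_anchor and chain_id in geo.aaa_anchor
    }
    if not per_subunit:
        raise TierError("no subunit with both tier anchors resolvable")
    return DihedralResult(model.id, per_subunit, geo.omitted)
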