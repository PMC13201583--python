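"""Synthetic two-tier hexamer rings and idealized B-DNA duplexes.

These generators produce coordinate models whose analysis results are
known *by construction*, so every metric in the package can be validated
at desk scale without any deposited structure:

* :func:`make_ring` builds an n-subunit two-tier ring in which each
  subunit's inter-tier dihedral equals its programmed twist exactly and
  each ATPase interface's two anchor distances equal their programmed
  values exactly.
* :func:`make_bdna` builds an idealized B-form duplex with a chosen
  number of 5′-terminal nucleotides whose complements are omitted,
  emulating terminal melting with disordered partners.

Construction notes.  Subunit *i* sits at azimuth ``360·i/n`` about the
z-axis; the bulk of each tier is a rigid rotated copy of one local
template, so the pooled tier centroids land exactly on the axis (the
rotation matrices of equally spaced azimuths sum to zero in xy).  The
interface and dihedral anchor atoms are placed at exact programmed
positions; wherever such a free placement would shift a tier centroid
off-axis, a designated partner residue is displaced by the equal and
opposite amount so the pooled sum — and hence the centroid — is
unchanged.  Pseudo-residues use real amino-acid names (PRO/THR/LEU/LYS/
SER/TYR at anchor positions, ALA elsewhere) and the deposited numbering
scheme, so fixtures exercise the same lookup paths as real depositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchors import RingMap, SubunitAnchors, builtin_anchor_set
from .geometry import RigidTransform
from .model_io import ChainModel, ResidueModel, StructureModel

__all__ = [
    "RingSpec",
    "DnaSpec",
    "RingGroundTruth",
    "InfeasibleGeometry",
    "make_ring",
    "make_bdna",
    "merge_models",
    "engage_dna",
    "DEFAULT_CHAIN_IDS",
]

DEFAULT_CHAIN_IDS = "ABCDEFGHIJ"

# deposited-style residue numbering of the archaeal chimera
OB_RANGES = ((105, 130), (185, 265))
CORE_RANGES = ((1319, 1361), (1729, 1837))
RES_OB_ANCHOR = 201       # N-tier dihedral anchor (PRO)
RES_WALKER_A = 1330       # Walker-A proline
RES_H2I_LEU = 1361        # h2i leucine
RES_H2I_HYDROXYL = 1357   # h2i serine (DNA-binding hydroxyl)
RES_H2I_AMIDE = 1732      # h2i backbone-amide donor
RES_AAA_ANCHOR = 1755     # C-tier dihedral anchor (TYR)
RES_PS1B_LYS = 1785       # ps1beta lysine
RES_PS1B_AMIDE = 1786     # ps1beta backbone-amide donor
RES_ARGF_M4 = 1824        # arginine-finger minus 4 (THR)
# partner residues that absorb free-placement offsets
COMPENSATORS = {RES_ARGF_M4: 1825, RES_PS1B_LYS: 1786, RES_AAA_ANCHOR: 1756}

ANCHOR_NAMES = {
    RES_OB_ANCHOR: "PRO", RES_WALKER_A: "PRO", RES_H2I_LEU: "LEU",
    RES_H2I_HYDROXYL: "SER", RES_AAA_ANCHOR: "TYR", RES_PS1B_LYS: "LYS",
    RES_ARGF_M4: "THR",
}


class InfeasibleGeometry(ValueError):
    """Ring parameters cannot be realized geometrically."""


def _aslist(value, n: int, name: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    out = [float(v) for v in value]
    if len(out) != n:
        raise InfeasibleGeometry(f"{name} must have length {n}, got {len(out)}")
    return out


@dataclass
class RingSpec:
    """Parameters of a synthetic two-tier ring.

    ``per_subunit_twist`` is the inter-tier azimuthal offset in degrees
    (one value per subunit, or a scalar broadcast to all); it equals the
    inter-tier dihedral the analysis recovers.  The two distance lists
    give the ATP-site and h2i–ps1β anchor Cα–Cα distances of each
    interface in Å (interface *i* joins subunit *i* to *i+1*).
    """

    n_subunits: int = 6
    ring_radius: float = 40.0
    tier_separation: float = 45.0
    per_subunit_twist: object = 0.0
    interface_atp_distances: object = 5.0
    interface_h2i_distances: object = 7.0
    seed: int = 0
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = self.n_subunits
        if n < 3:
            raise InfeasibleGeometry("need at least 3 subunits to form a ring")
        if not (self.ring_radius > 0 and self.tier_separation > 0):
            raise InfeasibleGeometry("ring_radius and tier_separation must be positive")
        self.per_subunit_twist = _aslist(self.per_subunit_twist, n, "per_subunit_twist")
        self.interface_atp_distances = _aslist(
            self.interface_atp_distances, n, "interface_atp_distances"
        )
        self.interface_h2i_distances = _aslist(
            self.interface_h2i_distances, n, "interface_h2i_distances"
        )
        for t in self.per_subunit_twist:
            if not (-180.0 < t <= 180.0):
                raise InfeasibleGeometry(f"twist {t} outside (-180, 180]")
        for d in self.interface_atp_distances + self.interface_h2i_distances:
            if not (0 < d < 2 * self.ring_radius):
                raise InfeasibleGeometry(
                    f"interface distance {d} infeasible for ring radius {self.ring_radius}"
                )
        if not self.chain_ids:
            self.chain_ids = tuple(DEFAULT_CHAIN_IDS[:n])
        elif len(self.chain_ids) != n:
            raise InfeasibleGeometry("chain_ids length must equal n_subunits")


@dataclass
class RingGroundTruth:
    """Programmed values recorded at construction time."""

    spec: RingSpec
    chain_ids: tuple[str, ...]
    twists: list[float]
    atp_distances: list[float]
    h2i_distances: list[float]
    anchor_positions: dict[tuple[str, int], np.ndarray]
    placements: list[RigidTransform]
    rigid_copies: bool

    def ring_map(self, label: str = "archaeal") -> RingMap:
        return RingMap(tuple((c, label) for c in self.chain_ids))


def _rz(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _cyl(radius: float, azimuth_deg: float, z: float) -> np.ndarray:
    a = np.radians(azimuth_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def _expand(ranges) -> list[int]:
    return [r for lo, hi in ranges for r in range(lo, hi + 1)]


def _local_templates(spec: RingSpec, rng: np.random.Generator):
    """Chain-0 local coordinates for every residue (subunit azimuth 0)."""
    R, h = spec.ring_radius, spec.tier_separation
    step = 360.0 / spec.n_subunits
    half = step / 2.0
    boundary_prev = -half  # interface boundary shared with the previous subunit

    local: dict[int, np.ndarray] = {}
    # fixed anchor positions (chain 0)
    local[RES_OB_ANCHOR] = _cyl(0.55 * R, 0.0, 2.0)
    local[RES_WALKER_A] = _cyl(R, half, h + 2.0)
    local[RES_H2I_LEU] = _cyl(R, half, h - 2.0)
    local[RES_H2I_HYDROXYL] = _cyl(0.45 * R, 0.0, h - 4.0)
    local[RES_H2I_AMIDE] = _cyl(0.45 * R, 0.0, h - 6.0)
    local[RES_AAA_ANCHOR] = _cyl(0.55 * R, spec.per_subunit_twist[0], h + 6.0)
    # chain 0 receives its arginine-finger-side anchors from the last interface
    u_prev = np.array([-np.sin(np.radians(boundary_prev)), np.cos(np.radians(boundary_prev)), 0.0])
    local[RES_ARGF_M4] = _cyl(R, boundary_prev, h + 2.0) + spec.interface_atp_distances[-1] * u_prev
    local[RES_PS1B_LYS] = _cyl(R, boundary_prev, h - 2.0) + spec.interface_h2i_distances[-1] * u_prev
    local[COMPENSATORS[RES_ARGF_M4]] = local[RES_ARGF_M4] + np.array([1.5, 0.0, 0.0])
    local[COMPENSATORS[RES_PS1B_LYS]] = local[RES_PS1B_LYS] + np.array([1.5, 0.0, 0.0])
    local[COMPENSATORS[RES_AAA_ANCHOR]] = local[RES_AAA_ANCHOR] + np.array([0.0, 0.0, 1.5])

    # deterministic bulk clouds around the subunit body
    for resnum in _expand(OB_RANGES):
        if resnum not in local:
            local[resnum] = _cyl(R, 0.0, 0.0) + rng.uniform(-4.0, 4.0, size=3)
    for resnum in _expand(CORE_RANGES):
        if resnum not in local:
            local[resnum] = _cyl(R, 0.0, h) + rng.uniform(-4.0, 4.0, size=3)
    return local


def make_ring(spec: RingSpec) -> tuple[StructureModel, RingGroundTruth]:
    """Build a synthetic ring model and its ground truth.

    Every subunit's inter-tier dihedral (OB anchor → N-tier centroid →
    C-tier centroid → AAA anchor) equals ``per_subunit_twist[i]`` and
    every interface's anchor distances equal the programmed values, to
    numerical precision far below measurement tolerances.
    """
    rng = np.random.default_rng(spec.seed)
    local = _local_templates(spec, rng)
    n = spec.n_subunits
    step = 360.0 / n
    half = step / 2.0
    R, h = spec.ring_radius, spec.tier_separation

    chains: list[ChainModel] = []
    anchor_positions: dict[tuple[str, int], np.ndarray] = {}
    placements: list[RigidTransform] = []
    uniform = (
        len(set(spec.per_subunit_twist)) == 1
        and len(set(spec.interface_atp_distances)) == 1
        and len(set(spec.interface_h2i_distances)) == 1
    )

    for i, chain_id in enumerate(spec.chain_ids):
        theta = i * step
        Rz = _rz(theta)
        placements.append(RigidTransform(Rz, np.zeros(3)))

        # exact free placements for this chain
        free: dict[int, np.ndarray] = {}
        free[RES_AAA_ANCHOR] = _cyl(0.55 * R, theta + spec.per_subunit_twist[i], h + 6.0)
        prev = (i - 1) % n
        psi_prev = prev * step + half  # boundary between subunit i-1 and i
        u_prev = np.array(
            [-np.sin(np.radians(psi_prev)), np.cos(np.radians(psi_prev)), 0.0]
        )
        free[RES_ARGF_M4] = (
            _cyl(R, psi_prev, h + 2.0) + spec.interface_atp_distances[prev] * u_prev
        )
        free[RES_PS1B_LYS] = (
            _cyl(R, psi_prev, h - 2.0) + spec.interface_h2i_distances[prev] * u_prev
        )

        residues = []
        for resnum in _expand(OB_RANGES) + _expand(CORE_RANGES):
            rigid_pos = Rz @ local[resnum]
            if resnum in free:
                pos = free[resnum]
            elif resnum in COMPENSATORS.values():
                anchor = next(k for k, v in COMPENSATORS.items() if v == resnum)
                # displace by the anchor's rigid-minus-free offset so the
                # pair sum (and the pooled tier centroid) is unchanged
                pos = rigid_pos + (Rz @ local[anchor] - free[anchor])
            else:
                pos = rigid_pos
            name = ANCHOR_NAMES.get(resnum, "ALA")
            atoms = {"CA": pos}
            if resnum == RES_PS1B_LYS:
                inward = -pos[:2] / np.linalg.norm(pos[:2])
                atoms["NZ"] = pos + np.array([*(1.5 * inward), -0.5])
            elif resnum == RES_H2I_HYDROXYL:
                atoms["OG"] = pos + np.array([0.0, 0.0, 1.4])
            elif resnum in (RES_H2I_AMIDE, RES_PS1B_AMIDE):
                atoms["N"] = pos + np.array([0.0, 0.0, 1.2])
            residues.append(ResidueModel(resnum, name, atoms))
        chains.append(ChainModel(chain_id, residues))

        for resnum in (
            RES_OB_ANCHOR, RES_WALKER_A, RES_H2I_LEU, RES_AAA_ANCHOR,
            RES_ARGF_M4, RES_PS1B_LYS,
        ):
            res = chains[-1].get(resnum)
            anchor_positions[(chain_id, resnum)] = res.atoms["CA"]

    model = StructureModel(f"synthetic_ring_seed{spec.seed}", chains, "mmcif")
    truth = RingGroundTruth(
        spec=spec,
        chain_ids=spec.chain_ids,
        twists=list(spec.per_subunit_twist),
        atp_distances=list(spec.interface_atp_distances),
        h2i_distances=list(spec.interface_h2i_distances),
        anchor_positions=anchor_positions,
        placements=placements,
        rigid_copies=uniform,
    )
    return model, truth


@dataclass
class DnaSpec:
    """Idealized B-DNA duplex: sequence of the tracked strand (5′→3′),
    helical rise and twist, and the number of 5′-terminal nucleotides of
    the tracked strand whose complements are omitted (melted)."""

    sequence: str = "ACTGACTGACTGACTGACTG"
    rise: float = 3.38
    twist_per_bp: float = 36.0
    melted_5prime: int = 0
    strand_a_id: str = "X"
    strand_b_id: str = "Y"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad or not self.sequence:
            raise ValueError(f"sequence must be non-empty over A/C/G/T (bad: {sorted(bad)})")
        if not (0 <= self.melted_5prime <= len(self.sequence)):
            raise ValueError("melted_5prime must be between 0 and the sequence length")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


_BASE3 = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

_R_C1 = 5.2   # C1' half-separation across a pair (C1'-C1' 10.4 Å)
_R_N = 1.45   # glycosidic-N half-separation (N1-N3 2.9 Å)
_R_P = 8.9    # phosphate radius


def _nucleotide_atoms(base: str, u: np.ndarray, z: float, sign: float) -> dict[str, np.ndarray]:
    """Atoms of one nucleotide; ``sign`` +1 for strand a, -1 for strand b."""
    center = np.array([0.0, 0.0, z])
    c1 = center + sign * _R_C1 * u
    glyco = center + sign * _R_N * u
    # phosphate offset azimuthally from the pair axis, opposite sense per strand
    perp = np.array([-u[1], u[0], 0.0])
    p = center + sign * (_R_P * 0.97) * u + sign * 2.2 * perp + np.array([0.0, 0.0, 1.7 * sign])
    out_dir = (p - np.array([0.0, 0.0, p[2]]))
    out_dir = out_dir / np.linalg.norm(out_dir)
    atoms = {
        "C1'": c1,
        "P": p,
        "OP1": p + 1.48 * out_dir,
        "OP2": p + np.array([0.0, 0.0, 1.48]),
        "O4'": c1 + 0.7 * (p - c1) / np.linalg.norm(p - c1),
    }
    atoms["N1" if base in "AG" else "N3"] = glyco
    return atoms


def make_bdna(spec: DnaSpec) -> StructureModel:
    """Build an idealized duplex model along the z-axis.

    The tracked strand (chain ``strand_a_id``) runs 5′→3′ with ascending
    residue numbers and ascending z; its complement runs antiparallel.
    The complements of the first ``melted_5prime`` tracked-strand
    nucleotides are omitted entirely, modelling disordered melted
    partners.
    """
    n = len(spec.sequence)
    res_a: list[ResidueModel] = []
    res_b: list[ResidueModel] = []
    for m, base in enumerate(spec.sequence, start=1):
        az = (m - 1) * spec.twist_per_bp
        z = (m - 1) * spec.rise
        u = np.array([np.cos(np.radians(az)), np.sin(np.radians(az)), 0.0])
        res_a.append(ResidueModel(m, _BASE3[base], _nucleotide_atoms(base, u, z, +1.0)))
        if m > spec.melted_5prime:
            comp = _COMP[base]
            res_b.append(
                ResidueModel(n + 1 - m, _BASE3[comp], _nucleotide_atoms(comp, u, z, -1.0))
            )
    res_b.sort(key=lambda r: r.seqid)
    chains = [ChainModel(spec.strand_a_id, res_a), ChainModel(spec.strand_b_id, res_b)]
    return StructureModel(f"synthetic_bdna_{n}bp_melt{spec.melted_5prime}", chains, "mmcif")


def merge_models(model_id: str, *models: StructureModel) -> StructureModel:
    """Combine chains of several models into one (chain ids must not clash)."""
    chains: list[ChainModel] = []
    for m in models:
        chains.extend(m.chains)
    return StructureModel(model_id, chains, "mmcif")


def engage_dna(
    ring_model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    dna_model: StructureModel,
    tracked_strand: str,
    n_engaged: int,
    contact_distance: float = 3.0,
) -> list[int]:
    """Reposition hairpin donor atoms onto the first ``n_engaged``
    tracked-strand nucleotides, one donor per nucleotide, at exactly
    ``contact_distance`` from the nucleotide's OP1 oxygen.

    Mutates ``ring_model`` in place and returns the engaged residue
    numbers (the ground truth for :func:`~ringmetrics.dna_melting.engaged_nucleotides`).
    """
    donors: list[tuple[str, int, str]] = []
    for chain_id, label in ring.ordered_chains:
        anc = anchors[label]
        ps1b_amide = anc.ps1b_amide if anc.ps1b_amide is not None else anc.ps1b_lys + 1
        donors.extend(
            [
                (chain_id, anc.ps1b_lys, "NZ"),
                (chain_id, ps1b_amide, "N"),
                (chain_id, anc.h2i_hydroxyl, "OG"),
                (chain_id, anc.h2i_amide, "N"),
            ]
        )
    nucleotides = sorted(
        (r for r in dna_model.chain(tracked_strand).residues if r.is_dna),
        key=lambda r: r.seqid,
    )
    if n_engaged > len(nucleotides):
        raise ValueError("cannot engage more nucleotides than are modeled")
    if n_engaged > len(donors):
        raise ValueError("not enough hairpin donors in the ring")

    engaged = []
    for k in range(n_engaged):
        chain_id, resnum, atom = donors[k]
        acceptor = nucleotides[k].atoms["OP1"]
        out = acceptor[:2]
        out = out / np.linalg.norm(out) if np.linalg.norm(out) > 1e-9 else np.array([1.0, 0.0])
        target = acceptor + contact_distance * np.array([out[0], out[1], 0.0])
        ring_model.chain(chain_id).get(resnum).atoms[atom] = target
        engaged.append(nucleotides[k].seqid)
    return engaged
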