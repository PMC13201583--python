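"""Duplex register, melted-base counting, and hairpin engagement.

The melting extent of a ring-encircled duplex is read off the
coordinate model itself: the DNA used experimentally is fully
base-paired, so any modeled nucleotide whose Watson–Crick partner is
absent from the model (disordered) has genuinely melted.  The duplex
register is recovered geometrically — complementary bases whose
C1′–C1′ and purine-N1/pyrimidine-N3 distances fall within canonical
Watson–Crick bounds, chained into the longest consistent antiparallel
run — and melted nucleotides are the contiguous unpaired run of the
tracked strand at the duplex terminus facing the ATPase tier.

Engagement counts how many tracked-strand nucleotides are gripped by
the ring's DNA-binding hairpins: a nucleotide is engaged when any of
its phosphate/sugar oxygens sits within hydrogen-bonding reach of one
of the hairpin donor atoms (the ps1β lysine side-chain amine and the
following backbone amide, the h2i hydroxyl side chain and its partner
backbone amide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchors import RingMap, SubunitAnchors
from .model_io import ChainModel, ResidueModel, StructureModel

__all__ = [
    "ContactCriteria",
    "DuplexRegister",
    "DuplexError",
    "find_register",
    "melted_count",
    "engaged_nucleotides",
    "auto_tracked_strand",
    "dna_chain_ids",
    "WC_COMPLEMENT",
]

WC_COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG"}
PURINES = {"DA", "DG"}
PYRIMIDINES = {"DT", "DC"}

# phosphate and sugar oxygens that can accept a hairpin hydrogen bond
ACCEPTOR_ATOMS = ("OP1", "OP2", "O5'", "O3'", "O4'")
# side-chain donor atom by residue type (hydroxyl or amine)
SIDECHAIN_DONOR = {"LYS": "NZ", "SER": "OG", "THR": "OG1", "TYR": "OH"}


class DuplexError(ValueError):
    """No valid duplex register could be established."""


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs (Å) for pairing and hairpin engagement.

    ``c1c1_max`` and ``n1n3_max`` bound the C1′–C1′ separation and the
    central Watson–Crick hydrogen bond (purine N1 to pyrimidine N3) of
    an accepted base pair; ``engagement_max`` bounds a donor–acceptor
    contact between a hairpin atom and a DNA oxygen.
    """

    c1c1_max: float = 11.0
    n1n3_max: float = 3.5
    engagement_max: float = 3.6

    def __post_init__(self) -> None:
        if min(self.c1c1_max, self.n1n3_max, self.engagement_max) <= 0:
            raise ValueError("all contact criteria must be positive")


DEFAULT_CONTACTS = ContactCriteria()


@dataclass(frozen=True)
class DuplexRegister:
    strand_a: str
    strand_b: str
    pair_map: tuple[tuple[int, int], ...]
    unpaired_a: tuple[int, ...] = ()
    unpaired_b: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        nums_a = [a for a, _ in self.pair_map]
        nums_b = [b for _, b in self.pair_map]
        if nums_a != sorted(nums_a) or nums_b != sorted(nums_b, reverse=True):
            raise DuplexError("pair map must be monotone and antiparallel")
        if set(nums_a) & set(self.unpaired_a) or set(nums_b) & set(self.unpaired_b):
            raise DuplexError("residue cannot be both paired and unpaired")


def _dna_residues(model: StructureModel, chain_id: str) -> list[ResidueModel]:
    chain = model.chain(chain_id)
    residues = [r for r in chain.residues if r.is_dna]
    if len(residues) < 4:
        raise DuplexError(
            f"chain {chain_id} has {len(residues)} modeled nucleotides; need >= 4"
        )
    return sorted(residues, key=lambda r: r.seqid)


def _glycosidic_n(res: ResidueModel) -> np.ndarray | None:
    """The Watson–Crick central H-bond nitrogen: purine N1 or pyrimidine N3."""
    name = "N1" if res.name in PURINES else "N3"
    return res.atoms.get(name)


def _is_wc_pair(ra: ResidueModel, rb: ResidueModel, crit: ContactCriteria) -> bool:
    if WC_COMPLEMENT.get(ra.name) != rb.name:
        return False
    c1a, c1b = ra.atoms.get("C1'"), rb.atoms.get("C1'")
    na, nb = _glycosidic_n(ra), _glycosidic_n(rb)
    if c1a is None or c1b is None or na is None or nb is None:
        return False
    if np.linalg.norm(c1a - c1b) > crit.c1c1_max:
        return False
    return bool(np.linalg.norm(na - nb) <= crit.n1n3_max)


def find_register(
    model: StructureModel,
    strand_a: str,
    strand_b: str,
    criteria: ContactCriteria = DEFAULT_CONTACTS,
) -> DuplexRegister:
    """Recover the Watson–Crick register between two modeled DNA strands.

    All geometrically acceptable complementary pairs are enumerated, and
    the longest antiparallel monotone chain (strand-a numbering ascending
    while strand-b numbering descends, each residue used once) defines
    the duplex.  Modeled nucleotides outside that run — their partner is
    either unmodeled or fails the pairing geometry — populate the
    unpaired lists.
    """
    res_a = _dna_residues(model, strand_a)
    res_b = _dna_residues(model, strand_b)

    candidates = [
        (ra.seqid, rb.seqid)
        for ra in res_a
        for rb in res_b
        if _is_wc_pair(ra, rb, criteria)
    ]
    if not candidates:
        raise DuplexError(
            f"no Watson–Crick pairs between chains {strand_a} and {strand_b}: not a duplex"
        )

    # longest strictly antiparallel chain: a ascending, b descending
    candidates.sort(key=lambda p: (p[0], -p[1]))
    best_len = [1] * len(candidates)
    parent = [-1] * len(candidates)
    for i, (ai, bi) in enumerate(candidates):
        for j in range(i):
            aj, bj = candidates[j]
            if aj < ai and bj > bi and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                parent[i] = j
    end = int(np.argmax(best_len))
    chain_idx = []
    while end != -1:
        chain_idx.append(end)
        end = parent[end]
    pair_map = tuple(candidates[i] for i in reversed(chain_idx))

    paired_a = {a for a, _ in pair_map}
    paired_b = {b for _, b in pair_map}
    return DuplexRegister(
        strand_a,
        strand_b,
        pair_map,
        tuple(r.seqid for r in res_a if r.seqid not in paired_a),
        tuple(r.seqid for r in res_b if r.seqid not in paired_b),
    )


def melted_count(
    register: DuplexRegister,
    tracked_strand: str = "a",
    end: str = "auto",
) -> int:
    """Melted nucleotides of the tracked strand.

    Counts modeled tracked-strand nucleotides whose partner is missing,
    in the contiguous run adjoining one duplex terminus.  ``end`` selects
    the 5′ or 3′ terminus of the tracked strand; ``"auto"`` takes the
    terminus with the longer unpaired run, which in ATPase-tier melting
    is the end gripped by the hairpins.
    """
    if tracked_strand not in ("a", "b"):
        raise ValueError("tracked_strand must be 'a' or 'b'")
    paired = sorted(
        (a if tracked_strand == "a" else b) for a, b in register.pair_map
    )
    unpaired = set(register.unpaired_a if tracked_strand == "a" else register.unpaired_b)
    if not unpaired:
        return 0
    modeled = sorted(set(paired) | unpaired)

    first_paired = modeled.index(paired[0])
    last_paired = modeled.index(paired[-1])
    run5 = sum(1 for i in range(first_paired) if modeled[i] in unpaired)
    run3 = sum(1 for i in range(last_paired + 1, len(modeled)) if modeled[i] in unpaired)
    # only runs contiguous with the duplex terminus count; interior
    # unpaired residues (paired flanks on both sides) are distortions,
    # not terminal melting
    if end == "5prime":
        return run5
    if end == "3prime":
        return run3
    if end == "auto":
        return max(run5, run3)
    raise ValueError("end must be '5prime', '3prime' or 'auto'")


def dna_chain_ids(model: StructureModel) -> list[str]:
    """Chain ids of all DNA polymer chains in the model."""
    return [c.chain_id for c in model.chains if c.polymer_kind == "dna"]


def auto_tracked_strand(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    criteria: ContactCriteria = DEFAULT_CONTACTS,
) -> str:
    """Pick the DNA strand with more hairpin engagement contacts.

    The strand gripped by the spiral staircase of ps1β/h2i hairpins is
    the tracked (future leading-strand template) strand; ties or zero
    engagement fall back to the first DNA chain in the file.
    """
    candidates = dna_chain_ids(model)
    if not candidates:
        raise DuplexError("model contains no DNA chains")
    best, best_count = candidates[0], -1
    for chain_id in candidates:
        try:
            count, _ = engaged_nucleotides(model, ring, anchors, chain_id, criteria)
        except DuplexError:
            continue
        if count > best_count:
            best, best_count = chain_id, count
    return best


def _donor_atoms(
    model: StructureModel, ring: RingMap, anchors: dict[str, SubunitAnchors]
) -> list[tuple[str, int, str, np.ndarray]]:
    donors = []
    for chain_id, label in ring.ordered_chains:
        if not model.has_chain(chain_id):
            continue
        chain = model.chain(chain_id)
        anc = anchors[label]
        spots = [
            (anc.ps1b_lys, "sidechain"),
            (anc.ps1b_amide if anc.ps1b_amide is not None else anc.ps1b_lys + 1, "amide"),
            (anc.h2i_hydroxyl, "sidechain"),
            (anc.h2i_amide, "amide"),
        ]
        for resnum, kind in spots:
            if resnum is None:
                continue
            res = chain.get(resnum)
            if res is None:
                continue
            atom_name = "N" if kind == "amide" else SIDECHAIN_DONOR.get(res.name)
            if atom_name and atom_name in res.atoms:
                donors.append((chain_id, resnum, atom_name, res.atoms[atom_name]))
    return donors


def engaged_nucleotides(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    tracked_strand: str,
    criteria: ContactCriteria = DEFAULT_CONTACTS,
) -> tuple[int, list[int]]:
    """Count tracked-strand nucleotides bound by the DNA-binding hairpins.

    Returns ``(count, residue numbers)`` of nucleotides with at least one
    phosphate/sugar oxygen within ``engagement_max`` of a hairpin donor
    atom of any subunit.
    """
    residues = _dna_residues(model, tracked_strand)
    donors = _donor_atoms(model, ring, anchors)
    if not donors:
        raise DuplexError("no hairpin donor atoms resolvable in any subunit")
    donor_xyz = np.array([d[3] for d in donors])

    engaged = []
    for res in residues:
        acceptors = [res.atoms[a] for a in ACCEPTOR_ATOMS if a in res.atoms]
        if not acceptors:
            continue
        dists = np.linalg.norm(
            donor_xyz[:, None, :] - np.array(acceptors)[None, :, :], axis=-1
        )
        if np.any(dists <= criteria.engagement_max):
            engaged.append(res.seqid)
    return len(engaged), engaged
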