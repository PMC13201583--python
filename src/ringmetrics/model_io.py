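"""Coordinate model input/output and atom lookup.

Wraps gemmi for mmCIF/PDB parsing but exposes a deliberately small
container (:class:`StructureModel`) that the measurement modules consume,
keyed by author chain id, author residue number and atom name.

Residue numbers follow the author numbering throughout, because the
anchor tables used for interface and dihedral measurements are quoted in
author numbers.  The chimeric archaeal construct studied here fuses a
*Saccharolobus solfataricus* N-terminal domain to a *Pyrococcus furiosus*
ATPase domain; :func:`map_chimera_numbering` converts between construct
numbering and the numbering used in the deposited coordinate files
(*Pf* residues are offset by +1000 in the depositions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "StructureModel",
    "ChainModel",
    "ResidueModel",
    "StructureParseError",
    "AtomLookupError",
    "NumberingError",
    "load_structure",
    "write_mmcif",
    "get_calpha",
    "map_chimera_numbering",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}
DNA_RES = {"DA", "DC", "DG", "DT", "DU", "DI"}
RNA_RES = {"A", "C", "G", "U", "I"}


class StructureParseError(ValueError):
    """File could not be read as a coordinate model."""


class AtomLookupError(KeyError):
    """A requested chain / residue / atom does not resolve."""


class NumberingError(ValueError):
    """Residue number outside the declared numbering domain."""


@dataclass
class ResidueModel:
    seqid: int
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    het: bool = False

    @property
    def is_protein(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def is_dna(self) -> bool:
        return self.name in DNA_RES


@dataclass
class ChainModel:
    chain_id: str
    residues: list[ResidueModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[int, ResidueModel] = {}
        for res in self.residues:
            if res.seqid in self._index:
                raise StructureParseError(
                    f"duplicate residue number {res.seqid} in chain {self.chain_id}"
                )
            self._index[res.seqid] = res

    @property
    def polymer_kind(self) -> str:
        names = [r.name for r in self.residues if not r.het]
        n_prot = sum(1 for n in names if n in STANDARD_AA)
        n_dna = sum(1 for n in names if n in DNA_RES)
        if n_prot > max(n_dna, 0):
            return "protein"
        if n_dna > 0:
            return "dna"
        return "other"

    def get(self, resnum: int) -> ResidueModel | None:
        return self._index.get(resnum)

    def add_residue(self, res: ResidueModel) -> None:
        if res.seqid in self._index:
            raise StructureParseError(
                f"duplicate residue number {res.seqid} in chain {self.chain_id}"
            )
        self.residues.append(res)
        self._index[res.seqid] = res

    def remove_residue(self, resnum: int) -> None:
        res = self._index.pop(resnum, None)
        if res is not None:
            self.residues.remove(res)

    def resnums(self) -> list[int]:
        return [r.seqid for r in self.residues]


@dataclass
class StructureModel:
    id: str
    chains: list[ChainModel] = field(default_factory=list)
    source_format: str = "mmcif"

    def __post_init__(self) -> None:
        self._chain_index = {c.chain_id: c for c in self.chains}
        if len(self._chain_index) != len(self.chains):
            raise StructureParseError("duplicate chain ids in model")

    def chain(self, chain_id: str) -> ChainModel:
        try:
            return self._chain_index[chain_id]
        except KeyError:
            raise AtomLookupError(
                f"chain {chain_id!r} absent from model {self.id!r}"
            ) from None

    def has_chain(self, chain_id: str) -> bool:
        return chain_id in self._chain_index

    def add_chain(self, chain: ChainModel) -> None:
        if chain.chain_id in self._chain_index:
            raise StructureParseError(f"duplicate chain id {chain.chain_id}")
        self.chains.append(chain)
        self._chain_index[chain.chain_id] = chain

    def get_atom(self, chain_id: str, resnum: int, atom_name: str) -> np.ndarray:
        chain = self.chain(chain_id)
        res = chain.get(resnum)
        if res is None:
            raise AtomLookupError(
                f"residue {resnum} not modeled in chain {chain_id} of {self.id!r} "
                "(chain present; residue disordered or out of range)"
            )
        try:
            return res.atoms[atom_name]
        except KeyError:
            raise AtomLookupError(
                f"atom {atom_name!r} absent from {chain_id}/{res.name}{resnum} in {self.id!r}"
            ) from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every atom mapped through ``R @ x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains = []
        for ch in self.chains:
            residues = [
                ResidueModel(r.seqid, r.name, {k: R @ v + t for k, v in r.atoms.items()}, r.het)
                for r in ch.residues
            ]
            chains.append(ChainModel(ch.chain_id, residues))
        return StructureModel(self.id, chains, self.source_format)


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        fmt = format_hint.lower()
        if fmt not in {"mmcif", "pdb"}:
            raise StructureParseError(f"unknown format hint {format_hint!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    # fall back to content sniffing
    head = path.read_text(errors="replace")[:2048]
    return "mmcif" if head.lstrip().startswith("data_") or "_atom_site" in head else "pdb"


def load_structure(path: str | Path, format_hint: str | None = None) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Polymer atoms and heteroatoms (ligands, waters, nucleotides bound at
    ATPase sites) are all retained; heteroatoms are flagged ``het`` and
    ignored by the polymer-kind classification.  Only the first model of a
    multi-model file is used (a warning is emitted).  Altloc ambiguity is
    resolved to the highest-occupancy conformer (first in file on ties).
    Insertion codes are rejected: none occur in the supported structures
    and silently reinterpreting them would corrupt author numbering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _detect_format(path, format_hint)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path} contains no models")
    if len(st) > 1:
        warnings.warn(
            f"{path.name}: {len(st)} models present; using the first", stacklevel=2
        )
    st.setup_entities()
    model = st[0]

    chains: list[ChainModel] = []
    for gchain in model:
        residues: list[ResidueModel] = []
        for gres in gchain:
            if gres.seqid.icode not in ("", " ", "\x00"):
                raise StructureParseError(
                    f"insertion code {gres.seqid.icode!r} at {gchain.name}/{gres.seqid.num}: "
                    "insertion codes are not supported"
                )
            het = gres.het_flag == "H" and gres.name not in STANDARD_AA | DNA_RES
            atoms: dict[str, np.ndarray] = {}
            best_occ: dict[str, float] = {}
            for atom in gres:
                occ = atom.occ if atom.altloc else float("inf")
                if atom.name in atoms and occ <= best_occ[atom.name]:
                    continue
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                best_occ[atom.name] = occ
            residues.append(ResidueModel(gres.seqid.num, gres.name, atoms, het))
        if residues:
            chains.append(ChainModel(gchain.name, residues))

    if not chains or all(not c.residues for c in chains):
        raise StructureParseError(f"{path} parsed but contains no atoms")
    result = StructureModel(path.stem, chains, fmt)
    for ch in result.chains:
        for res in ch.residues:
            for xyz in res.atoms.values():
                if not np.all(np.isfinite(xyz)):
                    raise StructureParseError(
                        f"non-finite coordinate at {ch.chain_id}/{res.seqid}"
                    )
    return result


def write_mmcif(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as mmCIF (PDBx) via gemmi."""
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqid, " ")
            gres.het_flag = "H" if res.het else "A"
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(_guess_element(name))
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(Path(path)))


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'\"*")
    if not stripped:
        return "X"
    if stripped[0] in "CNOSPH":
        return stripped[0]
    return stripped[:2].capitalize()


def get_calpha(model: StructureModel, chain: str, resnum: int) -> np.ndarray:
    """Cα coordinate of one residue (author numbering).

    Error messages distinguish an absent chain from a disordered residue
    from a residue modeled without its Cα, so that interface measurements
    bordering a disordered ATPase domain can report precisely what failed.
    """
    return model.get_atom(chain, resnum, "CA")


# Construct residue spans of the chimeric fusion protein.  The construct
# carries Sso residues 1-269 followed by Pf 257-361 and Pf 729-966 (the Pf
# intein 362-728 is genetically removed, so 361 links directly to 729).
_SSO_SPAN = (1, 269)
_PF_SPANS = ((257, 361), (729, 966))
_PF_OFFSET = 1000


def map_chimera_numbering(construct_resnum: int, protein: str = "auto") -> int:
    """Map a construct residue number to its deposited-file number.

    Sso residues keep their numbers; Pf residues ``r`` are deposited as
    ``1000 + r``.  Because the Sso span 1-269 and the Pf span 257-361
    overlap numerically, the caller must name the protein when the number
    is ambiguous (``protein`` one of ``"sso"``, ``"pf"``; ``"auto"`` is
    accepted only where a single span matches).
    """
    protein = protein.lower()
    in_sso = _SSO_SPAN[0] <= construct_resnum <= _SSO_SPAN[1]
    in_pf = any(lo <= construct_resnum <= hi for lo, hi in _PF_SPANS)
    if protein == "sso":
        if not in_sso:
            raise NumberingError(f"residue {construct_resnum} outside Sso span 1-269")
        return construct_resnum
    if protein == "pf":
        if not in_pf:
            raise NumberingError(
                f"residue {construct_resnum} outside Pf spans 257-361 / 729-966"
            )
        return _PF_OFFSET + construct_resnum
    if protein != "auto":
        raise NumberingError(f"unknown protein {protein!r}; expected 'sso' or 'pf'")
    if in_sso and in_pf:
        raise NumberingError(
            f"residue {construct_resnum} lies in both Sso and Pf spans; "
            "state protein='sso' or protein='pf'"
        )
    if in_sso:
        return construct_resnum
    if in_pf:
        return _PF_OFFSET + construct_resnum
    raise NumberingError(f"residue {construct_resnum} outside all construct spans")
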