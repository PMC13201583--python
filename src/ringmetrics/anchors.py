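"""Residue-anchor tables and ring orderings for MCM hexamer analysis.

The interface, dihedral and core-RMSD measurements are all defined
through a handful of conserved anchor residues per subunit (the Walker-A
P-loop proline, the residue four before the arginine finger, the h2i
leucine, the ps1beta lysine, and two tier anchors) plus the residue
ranges of the 107-aa OB-fold and the 152-aa ATPase core.  Built-in
tables ship for the archaeal chimeric homohexamer and for yeast and
human Mcm2-7; users can point at their own TOML file with the same
layout to add species.

A :class:`RingMap` fixes the cyclic order of subunits around the ring in
the direction in which the Walker-A face of position *i* meets the
arginine-finger face of position *i+1*.  For eukaryotic Mcm2-7 the
canonical order is 2, 6, 4, 7, 3, 5 placed on chain positions A-F; the
six cyclic rotations of that assignment are the six "settings" used in
the permuted core-RMSD comparison.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "SubunitAnchors",
    "RingMap",
    "AnchorError",
    "builtin_anchor_set",
    "builtin_ring",
    "load_anchor_file",
    "enumerate_settings",
    "BUILTIN_SETS",
    "OB_SIZE",
    "CORE_SIZE",
]

OB_SIZE = 107
CORE_SIZE = 152

BUILTIN_SETS = {
    "archaeal_chimera": "archaeal_chimera.toml",
    "ScMcm2-7": "sc_mcm2_7.toml",
    "HsMcm2-7": "hs_mcm2_7.toml",
}


class AnchorError(ValueError):
    """Invalid or incomplete anchor specification."""


def _ranges_len(ranges: tuple[tuple[int, int], ...]) -> int:
    return sum(hi - lo + 1 for lo, hi in ranges)


@dataclass(frozen=True)
class SubunitAnchors:
    """Anchor residues (author numbering) for one subunit type."""

    subunit_label: str
    walkerA_pro: int
    argfinger_minus4: int
    h2i_leu: int
    ps1b_lys: int
    ob_anchor: int | None = None
    aaa_anchor: int | None = None
    h2i_hydroxyl: int | None = None
    h2i_amide: int | None = None
    ps1b_amide: int | None = None
    ob_ranges: tuple[tuple[int, int], ...] = ()
    core_ranges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for name in ("walkerA_pro", "argfinger_minus4", "h2i_leu", "ps1b_lys"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise AnchorError(f"{self.subunit_label}: {name} must be a positive residue number")
        for attr, expected in (("ob_ranges", OB_SIZE), ("core_ranges", CORE_SIZE)):
            ranges = tuple(tuple(r) for r in getattr(self, attr))
            object.__setattr__(self, attr, ranges)
            for lo, hi in ranges:
                if lo > hi:
                    raise AnchorError(f"{self.subunit_label}: empty interval in {attr}")
            if ranges and _ranges_len(ranges) != expected:
                raise AnchorError(
                    f"{self.subunit_label}: {attr} spans {_ranges_len(ranges)} residues, "
                    f"expected {expected}"
                )

    def residues_in(self, which: str) -> list[int]:
        """Expand ``ob_ranges`` or ``core_ranges`` into a residue list."""
        ranges = getattr(self, which)
        if not ranges:
            raise AnchorError(f"{self.subunit_label}: {which} not defined")
        return [r for lo, hi in ranges for r in range(lo, hi + 1)]


@dataclass(frozen=True)
class RingMap:
    """Cyclic assignment of subunit labels to chain ids, in ring order.

    ``ordered_chains[i]`` is a ``(chain_id, subunit_label)`` pair;
    interface *i* pairs the Walker-A face of position *i* with the
    arginine-finger face of position *i+1* (position 6 wraps to 1).
    """

    ordered_chains: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        oc = tuple((str(c), str(s)) for c, s in self.ordered_chains)
        object.__setattr__(self, "ordered_chains", oc)
        chain_ids = [c for c, _ in oc]
        if len(set(chain_ids)) != len(chain_ids):
            raise AnchorError("duplicate chain id in ring map")

    def __len__(self) -> int:
        return len(self.ordered_chains)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.ordered_chains)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.ordered_chains)

    def position(self, i: int) -> tuple[str, str]:
        """1-based cyclic lookup."""
        return self.ordered_chains[(i - 1) % len(self.ordered_chains)]

    def interface(self, i: int) -> tuple[tuple[str, str], tuple[str, str]]:
        """Walker-A-side and arginine-finger-side (chain, label) of interface *i*."""
        return self.position(i), self.position(i + 1)


def _anchors_from_table(label: str, table: dict) -> SubunitAnchors:
    known = {
        "walkerA_pro", "argfinger_minus4", "h2i_leu", "ps1b_lys",
        "ob_anchor", "aaa_anchor", "h2i_hydroxyl", "h2i_amide",
        "ps1b_amide", "ob_ranges", "core_ranges",
    }
    unknown = set(table) - known
    if unknown:
        raise AnchorError(f"{label}: unknown anchor keys {sorted(unknown)}")
    kwargs = dict(table)
    for attr in ("ob_ranges", "core_ranges"):
        if attr in kwargs:
            kwargs[attr] = tuple(tuple(r) for r in kwargs[attr])
    return SubunitAnchors(subunit_label=label, **kwargs)


def load_anchor_file(path: str | Path) -> tuple[dict[str, SubunitAnchors], tuple[str, ...]]:
    """Parse a TOML anchor file; returns (label -> anchors, ring label order)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "subunits" not in data:
        raise AnchorError(f"{path}: missing [subunits] tables")
    anchors = {
        label: _anchors_from_table(label, table) for label, table in data["subunits"].items()
    }
    ring_order = tuple(data.get("ring", ()))
    for label in ring_order:
        if label not in anchors:
            raise AnchorError(f"{path}: ring references unknown subunit {label!r}")
    return anchors, ring_order


def _builtin_path(name: str):
    if name not in BUILTIN_SETS:
        raise AnchorError(
            f"unknown anchor set {name!r}; available: {sorted(BUILTIN_SETS)}"
        )
    return resources.files("ringmetrics.data") / BUILTIN_SETS[name]


def builtin_anchor_set(name: str) -> dict[str, SubunitAnchors]:
    """Built-in anchor tables by name (see ``BUILTIN_SETS``)."""
    with resources.as_file(_builtin_path(name)) as path:
        anchors, _ = load_anchor_file(path)
    return anchors


def builtin_ring(name: str, chain_ids: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")) -> RingMap:
    """Default :class:`RingMap` for a built-in anchor set on chains A-F."""
    with resources.as_file(_builtin_path(name)) as path:
        _, ring_order = load_anchor_file(path)
    if len(ring_order) != len(chain_ids):
        raise AnchorError(
            f"{name}: ring order has {len(ring_order)} entries for {len(chain_ids)} chains"
        )
    return RingMap(tuple(zip(chain_ids, ring_order)))


def enumerate_settings(ring: RingMap) -> list[RingMap]:
    """The six cyclic rotations of the subunit-label assignment.

    Setting 1 is the input assignment itself; setting *k* places on each
    chain position the label that setting 1 puts *k-1* positions further
    around the ring.  Only rotations are produced — reflections would
    invert the physical handedness of the ring and are excluded.
    """
    n = len(ring)
    if n != 6:
        raise AnchorError(f"settings are defined for hexamers, got {n} positions")
    chains = ring.chain_ids
    labels = ring.labels
    return [
        RingMap(tuple((chains[j], labels[(j + k) % n]) for j in range(n)))
        for k in range(n)
    ]
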