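"""Tight/loose classification of the six bipartite ATPase interfaces.

Each inter-subunit ATPase site of an MCM hexamer is scored by two
Cα–Cα distances:

* the ATP-site distance, from the Walker-A P-loop proline of the
  Walker-A-side subunit to the residue four before the arginine finger
  of the neighbouring subunit; and
* the h2i–ps1β distance, from the conserved h2i leucine of the same
  Walker-A-side subunit to the ps1β lysine of the neighbour.

An interface is *tight* when both distances fall strictly below their
thresholds (defaults 6.8 Å and 8.0 Å); boundary equality is loose.
Tight interfaces correlate with ATP-bound, DNA-engaged states; loose
ones with empty sites.  Interfaces bordering a disordered ATPase domain
are reported *unmeasurable*, never silently classified.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources

from .anchors import RingMap, SubunitAnchors
from .model_io import AtomLookupError, StructureModel, get_calpha

import numpy as np

__all__ = [
    "ClassificationCriteria",
    "InterfaceMeasurement",
    "RingClassification",
    "measure_interface",
    "classify_ring",
    "classify_from_distance_table",
    "printed_distance_table",
    "ring_report_tsv",
    "DEFAULT_CRITERIA",
]


@dataclass(frozen=True)
class ClassificationCriteria:
    """Strict upper thresholds (Å) for the two interface distances."""

    atp_threshold: float = 6.8
    h2i_threshold: float = 8.0

    def __post_init__(self) -> None:
        if self.atp_threshold <= 0 or self.h2i_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def is_tight(self, atp: float, h2i: float) -> bool:
        return atp < self.atp_threshold and h2i < self.h2i_threshold


DEFAULT_CRITERIA = ClassificationCriteria()


@dataclass(frozen=True)
class InterfaceMeasurement:
    """One bipartite ATPase site: two anchor distances and the verdict.

    ``tight`` is None when the interface is unmeasurable (an anchor Cα
    could not be resolved); ``failure`` then names the missing anchor.
    """

    walkerA_chain: str
    argF_chain: str
    walkerA_label: str = ""
    argF_label: str = ""
    atp_site_distance: float | None = None
    h2i_ps1b_distance: float | None = None
    tight: bool | None = None
    criteria: ClassificationCriteria = DEFAULT_CRITERIA
    failure: str | None = None

    @property
    def measurable(self) -> bool:
        return self.failure is None

    @property
    def verdict(self) -> str:
        if not self.measurable:
            return "unmeasurable"
        return "tight" if self.tight else "loose"

    @property
    def name(self) -> str:
        return f"{self.walkerA_chain}:{self.argF_chain}"


@dataclass(frozen=True)
class RingClassification:
    measurements: tuple[InterfaceMeasurement, ...]
    criteria: ClassificationCriteria = DEFAULT_CRITERIA

    @property
    def tight_count(self) -> int:
        return sum(1 for m in self.measurements if m.measurable and m.tight)

    @property
    def loose_count(self) -> int:
        return sum(1 for m in self.measurements if m.measurable and not m.tight)

    @property
    def unmeasurable(self) -> tuple[InterfaceMeasurement, ...]:
        return tuple(m for m in self.measurements if not m.measurable)


def measure_interface(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    position: int,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> InterfaceMeasurement:
    """Measure interface ``position`` (1-6) of a hexameric ring.

    The Walker-A-side subunit is ring position *i*, the
    arginine-finger side is position *i+1*.  A missing anchor Cα yields
    an unmeasurable verdict naming the failed anchor rather than an
    exception, so rings with a disordered ATPase domain classify the
    remaining interfaces honestly.
    """
    (chain_a, label_a), (chain_b, label_b) = ring.interface(position)
    try:
        anc_a = anchors[label_a]
        anc_b = anchors[label_b]
    except KeyError as exc:
        raise KeyError(f"no anchors for subunit label {exc.args[0]!r}") from None

    points = {}
    for key, chain, resnum in (
        ("walkerA_pro", chain_a, anc_a.walkerA_pro),
        ("h2i_leu", chain_a, anc_a.h2i_leu),
        ("argfinger_minus4", chain_b, anc_b.argfinger_minus4),
        ("ps1b_lys", chain_b, anc_b.ps1b_lys),
    ):
        try:
            points[key] = get_calpha(model, chain, resnum)
        except AtomLookupError as exc:
            return InterfaceMeasurement(
                walkerA_chain=chain_a,
                argF_chain=chain_b,
                walkerA_label=label_a,
                argF_label=label_b,
                criteria=criteria,
                failure=f"{key} ({chain}/{resnum}): {exc.args[0]}",
            )

    atp = float(np.linalg.norm(points["walkerA_pro"] - points["argfinger_minus4"]))
    h2i = float(np.linalg.norm(points["h2i_leu"] - points["ps1b_lys"]))
    return InterfaceMeasurement(
        walkerA_chain=chain_a,
        argF_chain=chain_b,
        walkerA_label=label_a,
        argF_label=label_b,
        atp_site_distance=atp,
        h2i_ps1b_distance=h2i,
        tight=criteria.is_tight(atp, h2i),
        criteria=criteria,
    )


def classify_ring(
    model: StructureModel,
    ring: RingMap,
    anchors: dict[str, SubunitAnchors],
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> RingClassification:
    """Measure and classify all six interfaces of a hexameric ring."""
    if len(ring) != 6:
        raise ValueError(f"hexameric ring required, got {len(ring)} positions")
    measurements = tuple(
        measure_interface(model, ring, anchors, pos, criteria) for pos in range(1, 7)
    )
    return RingClassification(measurements, criteria)


def classify_from_distance_table(
    pairs: list[tuple[float, float]],
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
    names: list[str] | None = None,
) -> RingClassification:
    """Re-apply the dual threshold to six printed (atp, h2i) distance pairs.

    Pure arithmetic on published numbers — no coordinates involved — so a
    printed interface-distance table can be re-classified directly.
    """
    if len(pairs) != 6:
        raise ValueError(f"expected 6 distance pairs, got {len(pairs)}")
    names = names or [f"{i}:{i % 6 + 1}" for i in range(1, 7)]
    measurements = []
    for name, (atp, h2i) in zip(names, pairs):
        atp = float(atp)
        h2i = float(h2i)
        if atp <= 0 or h2i <= 0:
            raise ValueError(f"interface {name}: non-positive distance")
        wa, _, af = name.partition(":")
        measurements.append(
            InterfaceMeasurement(
                walkerA_chain=wa or name,
                argF_chain=af or name,
                atp_site_distance=atp,
                h2i_ps1b_distance=h2i,
                tight=criteria.is_tight(atp, h2i),
                criteria=criteria,
            )
        )
    return RingClassification(tuple(measurements), criteria)


def printed_distance_table() -> dict[str, dict]:
    """The packaged interface-distance table for reference structures.

    Returns ``{structure: {"interfaces": [name, ...], "pairs": [(atp, h2i), ...],
    "dna_melted": str}}`` in ring order, as published for the archaeal
    melting series and comparative eukaryotic depositions.
    """
    text = (resources.files("ringmetrics.data") / "interface_distances.tsv").read_text()
    table: dict[str, dict] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        entry = table.setdefault(
            row["structure"], {"interfaces": [], "pairs": [], "dna_melted": row["dna_melted"]}
        )
        entry["interfaces"].append(row["interface"])
        entry["pairs"].append((float(row["atp_site"]), float(row["h2i_ps1b"])))
    return table


def ring_report_tsv(structure_id: str, result: RingClassification) -> str:
    """TSV report: one row per interface plus a tight-count summary row."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(
        ["structure", "interface", "walkerA_subunit", "argF_subunit",
         "atp_site_A", "h2i_ps1b_A", "verdict"]
    )
    for m in result.measurements:
        writer.writerow([
            structure_id,
            m.name,
            m.walkerA_label,
            m.argF_label,
            f"{m.atp_site_distance:.3f}" if m.measurable else "NA",
            f"{m.h2i_ps1b_distance:.3f}" if m.measurable else "NA",
            m.verdict if m.measurable else f"unmeasurable: {m.failure}",
        ])
    writer.writerow(
        [structure_id, "summary", "", "", "", "",
         f"tight_count={result.tight_count} loose_count={result.loose_count} "
         f"unmeasurable={len(result.unmeasurable)}"]
    )
    return out.getvalue()
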