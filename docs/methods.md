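# Methods

This note documents the geometric definitions, numerical choices, and
synthetic-data design behind `ringmetrics`, and what its tests do and
do not establish.

## Coordinate model and numbering

Structures are parsed with gemmi; the package keeps a minimal
container keyed by author chain id, author residue number, and atom
name, because all anchor tables in the field are quoted in author
numbering.  Altloc ambiguity resolves to the highest-occupancy
conformer (first in file on ties).  Insertion codes are rejected
outright: none occur in the supported structures, and silently
reinterpreting them would corrupt the numbering the anchors rely on.
Multi-model files use the first model with a warning.

The archaeal chimera fuses a *Saccharolobus solfataricus* N-terminal
domain (residues 1–269) to a *Pyrococcus furiosus* ATPase domain
(residues 257–361 and 729–966; the intervening intein is absent, so
361 bonds directly to 729).  Deposited files renumber the *Pf* spans
with a +1000 offset.  `map_chimera_numbering` implements this mapping
and refuses ambiguous inputs: the numeric overlap between the Sso span
and the first Pf span (257–269) means a bare number in that range
cannot be mapped without naming the protein.

## Interface classification

Each of the six bipartite ATPase sites is measured by two Cα–Cα
distances between conserved anchors (Walker-A proline → arginine-finger
minus 4; h2i leucine → ps1β lysine).  Defaults 6.8 Å and 8.0 Å are the
empirical thresholds separating the tight (ATP-bound, hairpin-engaged)
and loose populations; both are exposed as parameters.  Inequalities
are strict — a distance exactly at threshold classifies loose — and
classification always uses full-precision computed distances, never
rounded ones; the two choices only matter within ~1 mÅ of a threshold.

An interface bordering a disordered ATPase domain is reported
**unmeasurable**, carrying the name of the anchor that failed, and is
excluded from both the tight and loose counts.  Collapsing it to
"loose" would manufacture a verdict for a site the model does not
resolve.

## Inter-tier dihedral

Per subunit the torsion is taken over four points: the subunit's
N-tier anchor Cα, the pooled N-tier centroid, the pooled C-tier
centroid, and the subunit's C-tier anchor Cα.  Centroids pool the Cα
of all six OB-folds (107 residues each) and all six 152-residue
ATPase cores, in one of two modes: *direct* (the chain's own residues,
requiring per-chain ranges) or *template* (a reference OB-fold/core
superposed onto each subunit, with the reference's anchor points
carried through each fitted transform) for rings whose per-chain
numbering is not tabulated.  A tier is accepted when at least half of
its residue range is modeled per chain; fewer than six resolvable
OB-folds is an error, not a silent partial mean.

The torsion sign convention is fixed constructively: rotating the
first point about the central axis by +x° and using the image as the
fourth point yields +x.  The mean is the arithmetic mean after
wrapping each angle into (−180°, 180°].  A circular mean would differ
only for dispersions approaching the wrap point; observed rings sit
within a ±40° band where the two agree to well under a degree.  For
pathological synthetic inputs spanning the wrap, the arithmetic mean
is not meaningful — this is a documented limitation, not a guarded
case.  Bins: eclipsed above −15°, staggered below −25°; means falling
in the gap are reported as indeterminate rather than force-binned,
since both bins are empirically well-separated and a value between
them is information, not noise.

## Setting RMSD

A ring is idealized as six rigid placements of a single 152-point
core template, each fitted by closed-form Kabsch superposition (SVD
with a determinant guard so reflections are never produced; collinear
or undersized point sets are errors).  Missing residues (up to 12 of
152 per chain) are dropped from the fit; the stored copy is always the
complete transformed template, so all copies are congruent by
construction and per-copy fit RMSDs are reported for audit.

Comparing reference and target in setting *k* relabels the reference's
copies by a cyclic rotation of *k*−1 positions, concatenates all
6 × 152 = 912 Cα pairs, and performs one global superposition.  The
single global fit — rather than per-copy fits averaged — is the
package's definition of ring-as-a-unit similarity: it is the quantity
that distinguishes rotational registers, since each per-copy fit alone
is nearly register-blind.  Settings are rotations only; reflections
would invert the physical handedness of the ring.  Ties in the best
setting break to the lowest index and are visible in the full
six-value table.  Survey reports bin by tier class, sub-bin by best
setting, and reverse-sort by best RMSD, with ties ordered stably by
structure id.

## DNA register, melting, engagement

Pairing criteria are canonical Watson–Crick geometry: complementary
bases, C1′–C1′ ≤ 11.0 Å, and purine-N1–pyrimidine-N3 ≤ 3.5 Å (the
central hydrogen bond).  These defaults are package choices — melting
in the source structures was assessed by model inspection, with no
numeric rule published — and both cutoffs are configurable.  The
duplex register is the longest antiparallel monotone chain of
accepted pairs (ascending in one strand, descending in the other, each
nucleotide used once), found by dynamic programming; no chain at all
means the two strands are not a duplex.

"Melted" is operationalized as *partner absent from the model*: the
experimental substrates are fully base-paired, so a modeled nucleotide
whose complement is unmodeled has genuinely lost its pair.  The count
is the contiguous unpaired run of the tracked strand adjoining a
duplex terminus (the 5′ or 3′ end may be requested explicitly; the
default takes the longer terminal run, which is the hairpin-gripped
end in melting-stage structures).  Interior unpaired residues —
flanked by pairs on both sides — are distortions, not terminal
melting, and are never counted.

Engagement uses the four conserved hairpin donors per subunit (ps1β
lysine side-chain amine, the following backbone amide, the h2i
hydroxyl side chain, and its partner backbone amide) against the
nucleotide's phosphate/sugar oxygens, with a 3.6 Å donor–acceptor
cutoff.  The tracked strand can be named or auto-picked as the strand
with more engagement contacts.

## Synthetic generator

`make_ring` emulates the geometric degrees of freedom the metrics
measure: n subunits (default 6) at equally spaced azimuths on a ring
(default radius 40 Å), two tiers separated by 45 Å, a per-subunit
inter-tier twist, and per-interface anchor distances.  Defaults
(twist 0, interfaces 5.0/7.0 Å) give an eclipsed, all-tight C6 ring;
the staggered melting-stage analogues used in tests program twists of
about −31° and the published distance patterns.  Each tier's bulk is a
rigid rotated copy of one local template, so the pooled tier centroids
fall exactly on the ring axis (rotation matrices at equally spaced
azimuths sum to zero in the plane).  Interface and dihedral anchors
are placed at exact programmed positions; each such free placement is
paired with a designated partner residue displaced by the equal and
opposite amount, leaving the pooled centroid unchanged.  Consequently
programmed twists and distances are recovered by the analysis modules
to ~1e−12, and with uniform parameters every chain is an exact rigid
copy of chain 0 (recorded in the ground truth, and exploited by the
setting-RMSD recovery test).

What the generator does *not* emulate: side-chain packing, sterics,
solvent, realistic backbone connectivity, or density-derived disorder.
Passing tests therefore establish the correctness of the geometric
definitions and their implementations, not the empirical adequacy of
the thresholds on real depositions — the latter is checked by the
integration tests that run when deposited files are present locally.

`make_bdna` is likewise a geometric idealization: base-pair frames
stacked with 3.38 Å rise and 36° twist, carrying only the atoms the
criteria read (P, OP1/OP2, C1′, O4′, and the glycosidic N1/N3), with
Watson–Crick N–N separation 2.9 Å and C1′–C1′ 10.4 Å so default
criteria accept every intact pair without tuning.  Melting removes the
complements of the first k 5′-terminal tracked-strand nucleotides
entirely, mirroring disordered partners.  Generation is fully
deterministic: a fixed seed reproduces byte-identical mmCIF output.

## Problem sizes

All shipped tests and the acceptance script run on six-subunit rings
(912 core points), 21-bp duplexes, and point sets of ≤ 50 points;
the full suite completes in a few seconds on one CPU.  The PDB-wide
survey (dozens of structures) uses the identical code path via the
`survey` command and scales linearly in the number of files; its
published census numbers depend on a PDB snapshot and are intentionally
out of scope for automated checks.

## Known limitations

* Eukaryotic 152-residue core and 107-residue OB correspondences are
  not shipped; setting-RMSD and direct-mode dihedrals on Mcm2–7 require
  a user-supplied correspondence table (template mode needs only the
  ranges on the template side).
* Heptameric rings are supported generically by the generator and the
  dihedral/interface code, but settings are defined for hexamers only.
* Hoogsteen or quadruplex base pairing is not detected; the register
  finder is strictly Watson–Crick.
* Aromatic-wedge stacking geometry (the h2i aromatic residue on melted
  sugars) is not scored; no published numeric criterion exists yet.
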