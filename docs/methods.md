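# Methods

## Data model

A tracked dataset is a list of frames (1-based `time`), each a list of
nucleus records (1-based in-frame `index`). Records link forward with up to
two successor indices into the next frame and backward with one predecessor
index; two successors encode a division. Tracks are the maximal chains
between divisions; the forest of tracks is the lineage. Records flagged
invalid stay in their frames (files round-trip byte-for-byte) but belong to
no track. Link validation is report-based and distinguishes errors
(out-of-range indices, non-reciprocal links, links on or to invalid
records, successor-slot misuse) from informational findings (tracks lost
before the end of the movie, which are legal). `build_tracks` succeeds
exactly when the report has no errors.

## Canonical alignment

The canonical embryo frame is AP = (1,0,0) (anterior at low x),
DV = (0,1,0) (dorsal at low y; image y grows downward), LR = (0,0,1);
(AP, DV, LR) is right-handed, asserted at import. Expected division
directions are stored in this frame, so naming an arbitrarily mounted
embryo needs the rotation taking its image-space AP and LR vectors onto the
canonical axes.

Positions are first made isotropic — (x·xy_res, y·xy_res, z·z_res), in
micrometers — because angles in raw pixel/plane coordinates are
meaningless when plane spacing differs from pixel pitch. The alignment is
`R = R_LR · R_AP`: the minimal axis-angle rotation taking the supplied AP
vector onto canonical AP (axis = from × to, angle = atan2(‖from × to‖,
from·to)), followed by a rotation about the canonical AP axis taking the
image of the LR vector onto canonical LR. Degenerate collinear inputs are
handled explicitly: parallel gives the identity, anti-parallel a 180°
rotation about the canonical basis vector least collinear with the input
(deterministic). The result always maps both supplied axes onto their
canonical counterparts to 1e−9 and is always a proper rotation — never a
reflection — including in both degenerate branches.

The supplied LR vector need not be exactly perpendicular to AP: it is
Gram–Schmidt-orthogonalized first. A deviation beyond 15° from
perpendicular logs a warning and beyond 30° is an error; both thresholds
are keyword-configurable. Directions transform with the rotation only;
translation is carried in the transform type for point use but is zero
throughout this release.

## Naming

A division's direction is the unit displacement from daughter 1's first
(newborn) position to daughter 2's, isotropized and rotated to canonical
space. Classification has three tiers:

1. **Founder table.** P0 → AB/P1, P1 → EMS/P2, EMS → MS/E, P2 → C/P3,
   P3 → D/P4, P4 → Z2/Z3, each ordered along a stated canonical axis.
2. **Expected-axis table.** Per-parent empirical division directions with
   their own suffix pair. No empirical table ships with the package — the
   table is an input (CSV), since published per-parent expectations are
   not available in a machine-readable normative form; the synthetic
   generator provides one for tests and an absent entry is never an error.
3. **Body-axis fallback.** The canonical axis with the largest absolute
   component of the division vector picks the suffix pair a/p, d/v or l/r;
   exact component ties break deterministically AP > DV > LR. This is the
   documented behaviour for parents missing from the table (historically
   many tenth-round divisions).

One sign convention covers all tiers: the daughter on the negative side of
the classification axis (anterior, dorsal, left) takes the first suffix or
name. Ordering is by geometry, never by record or file order, so results do
not depend on how the tracker happened to number sisters.

Founders are seeded either manually (track key → name) or positionally at
the first frame containing exactly four cells: P2 is the most posterior in
canonical space, EMS the most ventral of the rest, ABa the more anterior of
the remaining pair. Unseeded roots get deterministic `Nuc-<k>` tags
(ordered by birth time, then canonical AP position) and their divisions are
suffixed off the tag, so entirely manual or non-*elegans* datasets still
name cleanly. Force-naming replaces a track's stem and re-derives all of
its descendants (provenance `propagated_from_forced`); ancestors and
unrelated subtrees are untouched, and collisions with existing names are
errors.

Assignment is breadth-first and fully deterministic, which yields the two
properties the package leans on: names are invariant under any joint rigid
motion of positions and metadata vectors, and re-naming after an edit
(dropping seed/forced entries whose record no longer starts a track) agrees
exactly with a from-scratch assignment of the final structure — unchanged
subtrees keep identical names without any explicit caching.

## Editing

Five commands (ADD, DELETE, LINK, UNLINK, SET_POSITION) address records by
(frame, index), forming a minimal closed set under which any link structure
is reachable. DELETE marks records invalid rather than removing lines,
preserving traceability; LINK fills the lowest free successor slot, and
UNLINK of slot 1 shifts slot 2 down to keep the successor-order invariant —
so a severed-and-restored division is equivalent up to slot order, which
naming ignores. Every command validates the resulting link structure before
committing; scripts apply commands in order, re-name after each one, and a
failing command aborts with the state after the last good command.

## Synthetic embryos

The generator emulates StarryNite output from the 4-cell stage (the stage
at which orientation vectors are defined): a canonical diamond (ABa
anterior-dorsal, ABp posterior-dorsal, EMS ventral, P2 posterior, cell
centres ~6–12 µm apart), dividing synchronously every `cell_cycle_frames`
frames along per-name axes from a synthetic expected-axis table —
canonical-axis-aligned for the founders, thereafter a canonical axis tilted
≤ 25° by a deterministic hash of the parent name, with the suffix pair of
the dominant axis (so fallback agrees with the table at zero noise).
Founder-table parents divide exactly along their classification axis.
Daughters appear at ± half the division distance along the axis; positions
are constant between divisions.

Defaults, chosen once as typical confocal lineaging numbers: 5 frames per
cell cycle at 1 min/frame, 4 µm between newborn sisters, 0.1 µm/pixel
laterally, 1.0 µm/plane axially, positional noise 0 (idealized detection;
tests pass noise explicitly, and names survive Gaussian jitter up to 20 %
of the division distance on table-driven divisions). Noise is applied in
embryo space before the rigid orientation — it models detection jitter on
the specimen; the order changes nothing statistically but fixes the byte
stream. A single seeded NumPy generator is consumed frame by frame in
record order, so equal seeds give byte-identical bundles. Problem sizes
used by the test suite and the acceptance script (up to 6 rounds, 256
leaves, 508 tracks) keep every run in seconds while exercising all three
classification tiers.

What the simulator deliberately does not model — cell death, inter-division
motion, detection failure, asynchronous cycles, the mounting-dependent
deviation of real division axes from body axes — bounds what passing tests
show: they certify the geometry, bookkeeping and determinism of the
pipeline, not naming accuracy on real embryos, which depends on the quality
of the expected-axis table supplied.

## Display mapping

`display = round(255·(v − black)/(white − black))`, clamped, per channel,
with round-half-away-from-zero (stated explicitly since conventions
differ); black = 0, white = 255 is an exact identity on 8-bit data. No
gamma. The `render-check` command proposes black/white points at the
0.1/99.9 intensity percentiles of a stack.

## Numerical choices

Orthonormality and properness of rotations are enforced at 1e−8
construction tolerance and asserted to 1e−9 in tests; collinearity cutoffs
are 1e−12 (axis-angle sine), 1e−6 (orthogonalized LR norm), 1e−9 µm
(degenerate division); fallback tie threshold 1e−12. Floats serialize via
`repr` (shortest round-tripping decimal form, locale-independent), which is
what makes write→read bit-exact.

## Known limitations

* The record dialect is this project's normative specification, not a
  claimed bit-compatible reading of historical archives; the column-map
  hook is the interoperability escape hatch.
* No estimation of AP/LR vectors from nuclear positions; they are inputs.
* Expected-axis tables are trusted as given (unit-norm checked, nothing
  else); no correction for mounting-dependent axis deviation is applied.
* Seed and forced names are keyed to a track's first record; an edit that
  removes that record drops the entry (with a warning) rather than
  guessing a new anchor.
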