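"""In-memory model of tracked nuclei and the lineage forest built from them.

Conventions (stated once, used everywhere):

* Frames (``time``) and in-frame record indices (``index``) are **1-based**,
  matching the per-timepoint nuclei files this model mirrors.  A list of
  frames uses Python 0-based list positions, so ``frames[t - 1]`` is frame
  ``t``.
* A record links forward with up to two successor indices into the next
  frame (two successors = a cell division) and backward with a single
  predecessor index into the previous frame.  Absent links are ``None``.
* Records flagged ``valid=False`` are retained in frames (so files round-trip
  byte-for-byte) but never belong to a track.
* There is no cap on the number of frames, planes or records anywhere in
  this model; readers provide per-frame lazy access for large archives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "NucleusRecord",
    "CellTrack",
    "LineageTree",
    "Finding",
    "ValidationReport",
    "LineageError",
    "LinkValidationError",
    "AmbiguousNameError",
    "build_tracks",
    "validate_links",
    "flatten",
    "lookup",
    "to_newick",
]


class LineageError(Exception):
    """Base class for all domain errors raised by this package."""


class LinkValidationError(LineageError):
    """Raised when temporal links are structurally inconsistent.

    Carries the full :class:`ValidationReport` in ``report``.
    """

    def __init__(self, report: "ValidationReport"):
        self.report = report
        msgs = "; ".join(str(f) for f in report.errors[:5])
        extra = "" if len(report.errors) <= 5 else f" (+{len(report.errors) - 5} more)"
        super().__init__(f"inconsistent links: {msgs}{extra}")


class AmbiguousNameError(LineageError):
    """A functional name resolves to more than one cell in the tree."""

    def __init__(self, query: str, candidates: Sequence[str]):
        self.query = query
        self.candidates = list(candidates)
        super().__init__(
            f"functional name {query!r} is ambiguous; candidates: "
            + ", ".join(self.candidates)
        )


@dataclass
class NucleusRecord:
    """One detected nucleus at one timepoint.

    ``x``/``y`` are in pixels, ``z`` in image planes (fractional allowed),
    ``diameter`` in pixels and ``weight`` is the summed intensity reported by
    the tracker.  ``identity`` holds the cell name (systematic, forced, or an
    auto-generated tag) or the empty string when unnamed.
    """

    time: int
    index: int
    valid: bool = True
    predecessor: Optional[int] = None
    successor1: Optional[int] = None
    successor2: Optional[int] = None
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    diameter: float = 0.0
    identity: str = ""
    weight: float = 0.0

    def __post_init__(self) -> None:
        # keep plain Python scalars so equality and serialization are canonical
        self.x, self.y, self.z = float(self.x), float(self.y), float(self.z)
        self.diameter = float(self.diameter)
        self.weight = float(self.weight)
        if self.time < 1:
            raise ValueError(f"time must be >= 1, got {self.time}")
        if self.index < 1:
            raise ValueError(f"index must be >= 1, got {self.index}")
        if self.diameter < 0:
            raise ValueError(f"diameter must be >= 0, got {self.diameter}")

    @property
    def n_successors(self) -> int:
        return (self.successor1 is not None) + (self.successor2 is not None)


@dataclass
class CellTrack:
    """A maximal chain of records between divisions (one cell's lifetime).

    ``daughters`` is empty (the track ends by loss or end of movie) or has
    exactly two entries (a division).  ``positions`` covers every frame of
    ``[birth_time, end_time]`` exactly once, in order.
    """

    name: str = ""
    birth_time: int = 0
    end_time: int = 0
    parent: Optional["CellTrack"] = None
    daughters: list["CellTrack"] = field(default_factory=list)
    positions: list[tuple[int, NucleusRecord]] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, int]:
        """Stable identifier: (time, in-frame index) of the first record."""
        t, rec = self.positions[0]
        return (t, rec.index)

    @property
    def first_record(self) -> NucleusRecord:
        return self.positions[0][1]

    @property
    def last_record(self) -> NucleusRecord:
        return self.positions[-1][1]

    @property
    def duration(self) -> int:
        """Track length in frames (inclusive of both endpoints)."""
        return self.end_time - self.birth_time + 1

    def __repr__(self) -> str:  # keep hashing by identity, repr readable
        return (
            f"CellTrack(name={self.name!r}, birth={self.birth_time}, "
            f"end={self.end_time}, daughters={len(self.daughters)})"
        )


@dataclass
class LineageTree:
    """Forest of cell tracks over per-frame record lists."""

    frames: list[list[NucleusRecord]]
    roots: list[CellTrack]
    tracks: list[CellTrack]
    name_index: dict[str, CellTrack] = field(default_factory=dict)

    def track_by_key(self, key: tuple[int, int]) -> Optional[CellTrack]:
        for tr in self.tracks:
            if tr.key == key:
                return tr
        return None

    def alive_at(self, time: int) -> list[CellTrack]:
        return [t for t in self.tracks if t.birth_time <= time <= t.end_time]

    def rebuild_name_index(self) -> None:
        """Rebuild the name → track map (keys unique by construction).

        Identities read from files can be stale mid-edit (e.g. a severed
        daughter still carrying its old name), so duplicates here are not an
        error: the earliest-born track wins and later ones are left out of
        the index.  Freshly *assigned* names are collision-checked upstream.
        """
        idx: dict[str, CellTrack] = {}
        for tr in sorted(self.tracks, key=lambda t: (t.birth_time, t.key)):
            if tr.name and tr.name not in idx:
                idx[tr.name] = tr
        self.name_index = idx


class Severity(Enum):
    ERROR = "error"
    INFO = "info"


@dataclass(frozen=True)
class Finding:
    kind: str
    time: int
    index: int
    message: str
    severity: Severity = Severity.ERROR

    def __str__(self) -> str:
        return f"[{self.severity.value}] t={self.time} index={self.index}: {self.message}"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity is Severity.ERROR]

    @property
    def infos(self) -> list[Finding]:
        return [f for f in self.findings if f.severity is Severity.INFO]

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "findings": [
                {
                    "kind": f.kind,
                    "time": f.time,
                    "index": f.index,
                    "severity": f.severity.value,
                    "message": f.message,
                }
                for f in self.findings
            ],
        }


def _get(frames: Sequence[Sequence[NucleusRecord]], time: int, index: int):
    """Record at 1-based (time, index), or None when out of range."""
    if not (1 <= time <= len(frames)):
        return None
    frame = frames[time - 1]
    if not (1 <= index <= len(frame)):
        return None
    return frame[index - 1]


def validate_links(frames: Sequence[Sequence[NucleusRecord]]) -> ValidationReport:
    """Check every temporal link for range and reciprocity.

    Errors reported:

    * ``out_of_range`` — a predecessor/successor index that does not name a
      record in the adjacent frame (including any link out of the first or
      last frame).
    * ``non_reciprocal`` — B's predecessor does not point back at the record
      naming B as successor, or vice versa.
    * ``invalid_linked`` — an invalid record carrying links, or a link that
      targets an invalid record.
    * ``duplicate_successor`` — successor1 == successor2.
    * ``successor_order`` — successor2 set while successor1 is unset.

    Lost tracks (a valid record with no successor before the last frame) are
    reported as informational ``lost_track`` findings, never as errors.
    An error-free report is exactly the precondition of :func:`build_tracks`.
    """
    report = ValidationReport()
    add = report.findings.append

    for t0, frame in enumerate(frames):
        t = t0 + 1
        for rec in frame:
            if not rec.valid:
                if rec.predecessor is not None or rec.n_successors:
                    add(Finding("invalid_linked", t, rec.index,
                                "invalid record carries temporal links"))
                continue

            if rec.successor2 is not None and rec.successor1 is None:
                add(Finding("successor_order", t, rec.index,
                            "successor2 set while successor1 is unset"))
            if (rec.successor1 is not None and rec.successor1 == rec.successor2):
                add(Finding("duplicate_successor", t, rec.index,
                            f"both successors point at index {rec.successor1}"))

            if rec.predecessor is not None:
                prev = _get(frames, t - 1, rec.predecessor)
                if prev is None:
                    add(Finding("out_of_range", t, rec.index,
                                f"predecessor {rec.predecessor} not in frame {t - 1}"))
                elif not prev.valid:
                    add(Finding("invalid_linked", t, rec.index,
                                f"predecessor {rec.predecessor} is an invalid record"))
                elif rec.index not in (prev.successor1, prev.successor2):
                    add(Finding("non_reciprocal", t, rec.index,
                                f"predecessor {rec.predecessor} does not list "
                                f"index {rec.index} as a successor"))

            for succ in (rec.successor1, rec.successor2):
                if succ is None:
                    continue
                nxt = _get(frames, t + 1, succ)
                if nxt is None:
                    add(Finding("out_of_range", t, rec.index,
                                f"successor {succ} not in frame {t + 1}"))
                elif not nxt.valid:
                    add(Finding("invalid_linked", t, rec.index,
                                f"successor {succ} is an invalid record"))
                elif nxt.predecessor != rec.index:
                    add(Finding("non_reciprocal", t, rec.index,
                                f"successor {succ} does not point back "
                                f"(its predecessor is {nxt.predecessor})"))

            if rec.n_successors == 0 and t < len(frames):
                add(Finding("lost_track", t, rec.index,
                            "track ends before the last frame",
                            Severity.INFO))
    return report


def build_tracks(frames: Sequence[Sequence[NucleusRecord]]) -> LineageTree:
    """Assemble the lineage forest from per-frame records.

    Tracks are maximal chains: a record with two successors ends its track
    and starts two daughter tracks; a valid record with no predecessor starts
    a root track.  Track names are taken from the first record's ``identity``
    (empty string = unnamed).  Raises :class:`LinkValidationError` when
    :func:`validate_links` reports any error.
    """
    frames = [list(f) for f in frames]
    report = validate_links(frames)
    if not report.ok:
        raise LinkValidationError(report)

    roots: list[CellTrack] = []
    tracks: list[CellTrack] = []

    def follow(time: int, rec: NucleusRecord, parent: Optional[CellTrack]) -> CellTrack:
        track = CellTrack(name=rec.identity, birth_time=time, parent=parent)
        tracks.append(track)
        while True:
            track.positions.append((time, rec))
            track.end_time = time
            if rec.n_successors != 1:
                break
            nxt = _get(frames, time + 1, rec.successor1)
            time, rec = time + 1, nxt
        if rec.n_successors == 2:
            d1 = _get(frames, time + 1, rec.successor1)
            d2 = _get(frames, time + 1, rec.successor2)
            track.daughters = [
                follow(time + 1, d1, track),
                follow(time + 1, d2, track),
            ]
        return track

    for t0, frame in enumerate(frames):
        for rec in frame:
            if rec.valid and rec.predecessor is None:
                roots.append(follow(t0 + 1, rec, None))

    tree = LineageTree(frames=frames, roots=roots, tracks=tracks)
    tree.rebuild_name_index()
    return tree


def flatten(tree: LineageTree) -> list[list[NucleusRecord]]:
    """Per-frame record lists underlying the tree (the inverse of building)."""
    return tree.frames


def lookup(tree: LineageTree, query: str, parts_list=None) -> Optional[CellTrack]:
    """Resolve a cell by systematic or functional name, case-insensitively.

    Systematic names are tried first; if a Parts List is supplied the query
    is then treated as a functional name and mapped through it.  A functional
    name mapping to several systematic names that are all present raises
    :class:`AmbiguousNameError`.
    """
    folded = {name.casefold(): track for name, track in tree.name_index.items()}
    hit = folded.get(query.casefold())
    if hit is not None:
        return hit
    if parts_list is None:
        return None
    candidates = [
        s for s in parts_list.systematic_for(query) if s.casefold() in folded
    ]
    if len(candidates) > 1:
        raise AmbiguousNameError(query, candidates)
    if candidates:
        return folded[candidates[0].casefold()]
    return None


_NEWICK_SAFE = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-")


def _newick_label(name: str) -> str:
    if name and all(c in _NEWICK_SAFE for c in name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _newick_node(track: CellTrack, time_res: float) -> str:
    length = track.duration * time_res
    # trim trailing zeros so unit time resolution prints integers
    blen = f"{length:g}"
    label = _newick_label(track.name) if track.name else ""
    if track.daughters:
        inner = ",".join(_newick_node(d, time_res) for d in track.daughters)
        return f"({inner}){label}:{blen}"
    return f"{label}:{blen}"


def to_newick(tree: LineageTree, time_res: float = 1.0) -> str:
    """Serialize the forest as one Newick tree per root, newline-separated.

    Node labels are cell names; branch lengths are track durations in frames
    multiplied by ``time_res`` (minutes per frame; 1.0 keeps plain frames).
    """
    return "\n".join(_newick_node(r, time_res) + ";" for r in tree.roots)
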