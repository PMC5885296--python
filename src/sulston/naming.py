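"""Systematic (Sulston-style) lineage name assignment from division axes.

A cell's daughters are named by appending a direction suffix to the parent
name: ``a``/``p`` for anterior/posterior, ``d``/``v`` for dorsal/ventral,
``l``/``r`` for left/right.  The direction of a division is the displacement
between the two newborn daughter nuclei, mapped into the canonical embryo
frame (see :mod:`sulston.transform`).  Classification proceeds in three
tiers:

1. **Founder-style special daughters** — a fixed table of early divisions
   whose daughters carry their own names (P0 → AB/P1, P1 → EMS/P2,
   EMS → MS/E, P2 → C/P3, P3 → D/P4, P4 → Z2/Z3), ordered along a stated
   canonical axis.
2. **Expected-axis table** — per-parent empirical division directions in
   canonical space, each with its own suffix pair; the daughter on the
   negative side of the expected axis takes the first suffix.
3. **Body-axis fallback** — when no expectation exists for a parent
   (historically the case for many tenth-round divisions), the canonical
   axis with the largest absolute component of the division vector decides
   the suffix pair, ties broken AP > DV > LR.

Sign convention, used identically in all three tiers: the division vector
points from daughter 1 to daughter 2, and the daughter on the *negative*
side of the classification axis (anterior / dorsal / left) takes the first
suffix or name.  Ordering is by geometry, never by record order in files.

Roots with no seeded or forced name get deterministic ``Nuc-<k>`` tags so
that naming works even when no *C. elegans* 4-cell stage is present; their
divisions still receive suffixes off the tag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np

from .model import CellTrack, LineageError, LineageTree
from .starrynite import EmbryoMetadata, ExpectedAxis
from .transform import RigidTransform, isotropize

__all__ = [
    "Provenance",
    "SeedMode",
    "NamingRuleSet",
    "NameAssignment",
    "DegenerateDivisionError",
    "NameCollisionError",
    "SeedingError",
    "CELEGANS_SPECIAL_DAUGHTERS",
    "FALLBACK_SUFFIXES",
    "seed_founders",
    "division_vector",
    "classify_division",
    "assign_names",
    "force_name",
    "rename_after_edit",
]

logger = logging.getLogger(__name__)

AXIS_AP, AXIS_DV, AXIS_LR = 0, 1, 2

#: Per-canonical-axis suffix pairs: first suffix = negative side of the axis.
FALLBACK_SUFFIXES: tuple[tuple[str, str], ...] = (("a", "p"), ("d", "v"), ("l", "r"))

#: parent → (first daughter, second daughter, classification axis index);
#: the first daughter lies on the negative side of the axis (e.g. AB is the
#: anterior daughter of P0).
CELEGANS_SPECIAL_DAUGHTERS: dict[str, tuple[str, str, int]] = {
    "P0": ("AB", "P1", AXIS_AP),
    "P1": ("EMS", "P2", AXIS_AP),
    "EMS": ("MS", "E", AXIS_AP),
    "P2": ("C", "P3", AXIS_AP),
    "P3": ("D", "P4", AXIS_AP),
    "P4": ("Z2", "Z3", AXIS_AP),
}


class DegenerateDivisionError(LineageError):
    """Newborn daughters coincide; no division direction exists."""


class NameCollisionError(LineageError):
    def __init__(self, name: str, key_a, key_b):
        self.name, self.key_a, self.key_b = name, key_a, key_b
        super().__init__(
            f"name {name!r} assigned to two tracks (starting {key_a} and {key_b})"
        )


class SeedingError(LineageError):
    pass


class Provenance(Enum):
    SEED = "seed"
    EXPECTED_AXIS = "expected_axis"
    BODY_AXIS_FALLBACK = "body_axis_fallback"
    FORCED = "forced"
    PROPAGATED_FROM_FORCED = "propagated_from_forced"
    AUTO_TAG = "auto_tag"


class SeedMode(Enum):
    AUTO_4CELL = "auto_4cell"
    MANUAL = "manual"


@dataclass
class NamingRuleSet:
    """Everything the classifier needs besides geometry."""

    special_daughters: dict[str, tuple[str, str, int]] = field(
        default_factory=lambda: dict(CELEGANS_SPECIAL_DAUGHTERS)
    )
    expected_axes: dict[str, ExpectedAxis] = field(default_factory=dict)
    fallback_suffixes: tuple[tuple[str, str], ...] = FALLBACK_SUFFIXES
    seed_mode: SeedMode = SeedMode.AUTO_4CELL

    def __post_init__(self) -> None:
        for pair in self.fallback_suffixes:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise LineageError("fallback suffix pairs must be two distinct characters")


@dataclass(frozen=True)
class NameAssignment:
    key: tuple[int, int]  # (birth time, first in-frame index) of the track
    name: str
    provenance: Provenance

    def __post_init__(self) -> None:
        if not self.name:
            raise LineageError("assigned names must be nonempty")


# ---------------------------------------------------------------------------
# geometry

def division_vector(
    parent: CellTrack, transform: RigidTransform, meta: EmbryoMetadata
) -> np.ndarray:
    """Unit division direction in canonical space, daughter 1 → daughter 2.

    Daughter positions are the first (newborn) records of each daughter
    track, made isotropic in micrometers before rotation.
    """
    if len(parent.daughters) != 2:
        raise LineageError(f"track {parent.key} has {len(parent.daughters)} daughters, need 2")
    d1, d2 = parent.daughters
    p1 = isotropize(d1.first_record, meta)
    p2 = isotropize(d2.first_record, meta)
    v = transform.apply_direction(p2 - p1)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateDivisionError(
            f"degenerate division: daughters of track {parent.key} coincide"
        )
    return v / norm


TIE_EPS = 1e-12


def classify_division(
    parent_name: str, v: np.ndarray, rules: NamingRuleSet
) -> tuple[str, str, Provenance]:
    """Names for (daughter 1, daughter 2) of ``parent_name`` dividing along ``v``.

    ``v`` is the unit daughter1→daughter2 direction in canonical space.  See
    the module docstring for the three classification tiers and the sign
    convention.
    """
    special = rules.special_daughters.get(parent_name)
    if special is not None:
        first, second, axis = special
        if v[axis] >= 0:
            return first, second, Provenance.EXPECTED_AXIS
        return second, first, Provenance.EXPECTED_AXIS

    expected = rules.expected_axes.get(parent_name)
    if expected is not None:
        s1, s2 = expected.suffix_pair
        if float(v @ expected.vector) >= 0:
            return parent_name + s1, parent_name + s2, Provenance.EXPECTED_AXIS
        return parent_name + s2, parent_name + s1, Provenance.EXPECTED_AXIS

    comps = np.abs(v)
    order = np.argsort(comps)[::-1]
    axis = int(order[0])
    if comps[order[0]] - comps[order[1]] < TIE_EPS:
        # exact tie: deterministic priority AP > DV > LR
        tied = [int(i) for i in (AXIS_AP, AXIS_DV, AXIS_LR)
                if comps[order[0]] - comps[i] < TIE_EPS]
        axis = tied[0]
        logger.info(
            "division of %r ties between axes %s; using priority AP>DV>LR",
            parent_name, tied,
        )
    s1, s2 = rules.fallback_suffixes[axis]
    if v[axis] >= 0:
        return parent_name + s1, parent_name + s2, Provenance.BODY_AXIS_FALLBACK
    return parent_name + s2, parent_name + s1, Provenance.BODY_AXIS_FALLBACK


# ---------------------------------------------------------------------------
# seeding

def _canonical_position(rec, transform: RigidTransform, meta: EmbryoMetadata) -> np.ndarray:
    return transform.apply_direction(isotropize(rec, meta))


def seed_founders(
    tree: LineageTree,
    transform: RigidTransform,
    meta: EmbryoMetadata,
    mode: SeedMode = SeedMode.AUTO_4CELL,
    manual: Optional[Mapping[tuple[int, int], str]] = None,
) -> dict[tuple[int, int], str]:
    """Seed founder names, returning a track-key → name map.

    AUTO_4CELL finds the first frame with exactly four live tracks and names
    them by canonical position: P2 is the most posterior (largest AP
    coordinate); of the rest EMS is the most ventral (largest DV coordinate);
    of the last two ABa is the more anterior, ABp the other.  MANUAL applies
    the caller-supplied (track key → name) pairs verbatim.
    """
    if mode is SeedMode.MANUAL:
        if not manual:
            raise SeedingError("manual seed mode requires at least one seed")
        names = list(manual.values())
        if len(set(names)) != len(names):
            raise SeedingError(f"duplicate seed names: {sorted(names)}")
        for key in manual:
            if tree.track_by_key(key) is None:
                raise SeedingError(f"seed key {key} does not start a track")
        return dict(manual)

    for t in range(1, len(tree.frames) + 1):
        alive = tree.alive_at(t)
        if len(alive) == 4:
            pos = {
                tr.key: _canonical_position(
                    dict(tr.positions)[t], transform, meta
                )
                for tr in alive
            }
            remaining = sorted(alive, key=lambda tr: pos[tr.key][AXIS_AP])
            p2 = remaining.pop()  # most posterior
            remaining.sort(key=lambda tr: pos[tr.key][AXIS_DV])
            ems = remaining.pop()  # most ventral of the rest
            remaining.sort(key=lambda tr: pos[tr.key][AXIS_AP])
            aba, abp = remaining
            return {aba.key: "ABa", abp.key: "ABp", ems.key: "EMS", p2.key: "P2"}
    raise SeedingError(
        "no frame with exactly 4 cells found; use MANUAL seeding for this dataset"
    )


# ---------------------------------------------------------------------------
# assignment

def assign_names(
    tree: LineageTree,
    transform: RigidTransform,
    rules: NamingRuleSet,
    meta: EmbryoMetadata,
    seeds: Optional[Mapping[tuple[int, int], str]] = None,
    forced: Optional[Mapping[tuple[int, int], str]] = None,
) -> dict[tuple[int, int], NameAssignment]:
    """Deterministically name every track in the forest.

    Breadth-first over divisions.  A track's stem is, in priority order: its
    forced name, its seeded name, the name derived from its parent's stem
    and division direction, or (for unseeded roots) an auto tag ``Nuc-<k>``
    with ``k`` ordered by (birth time, canonical AP coordinate).  Forced
    names start new stems; their descendants are re-derived from them and
    tagged ``PROPAGATED_FROM_FORCED``.

    The same input always yields the same names (no randomness anywhere);
    a name ending up on two tracks raises :class:`NameCollisionError`.
    Assigned names are written back to ``track.name``, every record's
    ``identity``, and the tree's name index.
    """
    seeds = dict(seeds or {})
    forced = dict(forced or {})

    auto_roots = [
        r for r in tree.roots if r.key not in seeds and r.key not in forced
    ]
    auto_roots.sort(
        key=lambda r: (
            r.birth_time,
            float(_canonical_position(r.first_record, transform, meta)[AXIS_AP]),
            r.key,
        )
    )
    auto_tag = {r.key: f"Nuc-{k}" for k, r in enumerate(auto_roots, start=1)}

    assignments: dict[tuple[int, int], NameAssignment] = {}
    by_name: dict[str, tuple[int, int]] = {}

    def record(track: CellTrack, name: str, prov: Provenance) -> None:
        if name in by_name and by_name[name] != track.key:
            raise NameCollisionError(name, by_name[name], track.key)
        by_name[name] = track.key
        assignments[track.key] = NameAssignment(track.key, name, prov)

    queue: list[tuple[CellTrack, str, Provenance, bool]] = []
    for root in tree.roots:
        if root.key in forced:
            queue.append((root, forced[root.key], Provenance.FORCED, True))
        elif root.key in seeds:
            queue.append((root, seeds[root.key], Provenance.SEED, False))
        else:
            queue.append((root, auto_tag[root.key], Provenance.AUTO_TAG, False))

    i = 0
    while i < len(queue):
        track, name, prov, under_forced = queue[i]
        i += 1
        record(track, name, prov)
        if not track.daughters:
            continue
        v = division_vector(track, transform, meta)
        n1, n2, div_prov = classify_division(name, v, rules)
        for daughter, derived in zip(track.daughters, (n1, n2)):
            if daughter.key in forced:
                queue.append((daughter, forced[daughter.key], Provenance.FORCED, True))
            elif daughter.key in seeds:
                queue.append((daughter, seeds[daughter.key], Provenance.SEED, False))
            else:
                p = Provenance.PROPAGATED_FROM_FORCED if under_forced else div_prov
                queue.append((daughter, derived, p, under_forced))

    for track in tree.tracks:
        a = assignments[track.key]
        track.name = a.name
        for _, rec in track.positions:
            rec.identity = a.name
    tree.rebuild_name_index()
    return assignments


def force_name(
    tree: LineageTree,
    track: CellTrack,
    name: str,
    rules: NamingRuleSet,
    transform: RigidTransform,
    meta: EmbryoMetadata,
    seeds: Optional[Mapping[tuple[int, int], str]] = None,
    forced: Optional[dict[tuple[int, int], str]] = None,
) -> tuple[dict[tuple[int, int], NameAssignment], dict[tuple[int, int], str]]:
    """Manually name ``track`` and re-derive all of its descendants.

    Returns the new full assignment map and the updated forced-name map
    (callers keep the latter so the name survives later edits).  Ancestors
    and unrelated subtrees are untouched; a collision with an existing
    unrelated name is an error.
    """
    if not name:
        raise LineageError("forced name must be nonempty")
    forced = dict(forced or {})
    forced[track.key] = name
    assignments = assign_names(tree, transform, rules, meta, seeds=seeds, forced=forced)
    return assignments, forced


def rename_after_edit(
    tree: LineageTree,
    transform: RigidTransform,
    rules: NamingRuleSet,
    meta: EmbryoMetadata,
    seeds: Optional[Mapping[tuple[int, int], str]] = None,
    forced: Optional[Mapping[tuple[int, int], str]] = None,
) -> dict[tuple[int, int], NameAssignment]:
    """Recompute names on an edited tree, keeping surviving seeds and stems.

    Seed/forced entries are keyed by the (time, index) of a track's first
    record; an entry whose record no longer *starts* a track (it was deleted,
    or an edit extended its chain upward) is dropped with a warning.  Because
    assignment is deterministic, tracks whose ancestry and link structure are
    unchanged keep byte-identical names, and incremental renaming after each
    edit agrees exactly with a from-scratch assignment on the final
    structure.
    """
    starts = {tr.key for tr in tree.tracks}

    def surviving(entries: Optional[Mapping[tuple[int, int], str]], what: str):
        out = {}
        for key, name in (entries or {}).items():
            if key in starts:
                out[key] = name
            else:
                warnings.warn(
                    f"{what} name {name!r} at {key} no longer starts a track; dropped",
                    stacklevel=2,
                )
        return out

    return assign_names(
        tree, transform, rules, meta,
        seeds=surviving(seeds, "seeded"),
        forced=surviving(forced, "forced"),
    )
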