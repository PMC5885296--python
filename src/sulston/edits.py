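"""Curation edits on tracked nuclei, with automatic re-naming.

Five commands form a closed set under which any link structure is reachable:

* ``ADD <t> <x> <y> <z> [diameter]`` — append a new, unlinked record to
  frame ``t`` with a fresh in-frame index.
* ``DELETE <t>:<i>`` — mark the record invalid and sever all of its links
  bidirectionally (the line itself is retained for file-level traceability).
* ``LINK <t>:<i> <t+1>:<j>`` — link a record to a partner in the next frame;
  the partner must have no predecessor and the record a free successor slot.
* ``UNLINK <t>:<i> <t+1>:<j>`` — sever one existing link bidirectionally.
* ``SET_POSITION <t>:<i> <x> <y> <z>`` — move a record (non-structural).

Commands address records by (time, index) coordinates, never by name, so
they are meaningful before any naming and on non-*elegans* data.  Every
applied command leaves the frames link-consistent (validated before
returning) and yields a :class:`ChangeSet`; scripts re-run naming after each
structural command so that names are always up to date with the lineage.
"""

from __future__ import annotations

import copy
import shlex
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from . import naming
from .model import (
    LineageError,
    NucleusRecord,
    build_tracks,
    validate_links,
)

__all__ = [
    "EditKind",
    "EditCommand",
    "ChangeSet",
    "EditError",
    "EditScriptError",
    "apply_edit",
    "edit_script",
    "parse_edit_script",
]


class EditError(LineageError):
    pass


class EditScriptError(LineageError):
    """A script command failed; state is rolled back to the last good point.

    ``applied`` is the number of commands successfully applied and ``frames``
    the (validated) state they produced.
    """

    def __init__(self, index: int, reason: Exception, frames, applied: int):
        self.index = index
        self.reason = reason
        self.frames = frames
        self.applied = applied
        super().__init__(f"command {index + 1} failed: {reason}")


class EditKind(Enum):
    ADD = "ADD"
    DELETE = "DELETE"
    LINK = "LINK"
    UNLINK = "UNLINK"
    SET_POSITION = "SET_POSITION"


@dataclass(frozen=True)
class EditCommand:
    kind: EditKind
    time: int
    index: Optional[int] = None
    partner_time: Optional[int] = None
    partner_index: Optional[int] = None
    x: Optional[float] = None
    y: Optional[float] = None
    z: Optional[float] = None
    diameter: float = 0.0
    identity: str = ""


@dataclass
class ChangeSet:
    """Coordinates touched by an edit and whether links changed."""

    affected: set = field(default_factory=set)
    structural: bool = False

    def merge(self, other: "ChangeSet") -> "ChangeSet":
        return ChangeSet(self.affected | other.affected, self.structural or other.structural)


def _require(frames, time: int, index: int) -> NucleusRecord:
    if not 1 <= time <= len(frames):
        raise EditError(f"frame {time} does not exist (1..{len(frames)})")
    frame = frames[time - 1]
    if not 1 <= index <= len(frame):
        raise EditError(f"record {time}:{index} does not exist ({len(frame)} records in frame)")
    return frame[index - 1]


def _sever_successor(parent: NucleusRecord, index: int) -> None:
    if parent.successor1 == index:
        parent.successor1, parent.successor2 = parent.successor2, None
    elif parent.successor2 == index:
        parent.successor2 = None


def apply_edit(frames, cmd: EditCommand):
    """Apply one command to a copy of ``frames``; return (frames', ChangeSet).

    The input is never mutated.  The result is validated before returning;
    a command that would leave links inconsistent raises :class:`EditError`.
    """
    frames = copy.deepcopy(list(frames))
    cs = ChangeSet()

    if cmd.kind is EditKind.ADD:
        if not 1 <= cmd.time <= len(frames):
            raise EditError(f"frame {cmd.time} does not exist (1..{len(frames)})")
        if cmd.x is None or cmd.y is None or cmd.z is None:
            raise EditError("ADD requires x, y and z")
        frame = frames[cmd.time - 1]
        rec = NucleusRecord(
            time=cmd.time, index=len(frame) + 1,
            x=cmd.x, y=cmd.y, z=cmd.z,
            diameter=cmd.diameter, identity=cmd.identity,
        )
        frame.append(rec)
        cs.affected.add((cmd.time, rec.index))
        cs.structural = True

    elif cmd.kind is EditKind.DELETE:
        rec = _require(frames, cmd.time, cmd.index)
        if not rec.valid:
            raise EditError(f"record {cmd.time}:{cmd.index} is already invalid")
        if rec.predecessor is not None:
            parent = _require(frames, cmd.time - 1, rec.predecessor)
            _sever_successor(parent, rec.index)
            cs.affected.add((cmd.time - 1, parent.index))
        for succ in (rec.successor1, rec.successor2):
            if succ is not None:
                child = _require(frames, cmd.time + 1, succ)
                child.predecessor = None
                cs.affected.add((cmd.time + 1, child.index))
        rec.predecessor = rec.successor1 = rec.successor2 = None
        rec.valid = False
        cs.affected.add((cmd.time, rec.index))
        cs.structural = True

    elif cmd.kind is EditKind.LINK:
        if cmd.partner_time != cmd.time + 1:
            raise EditError(
                f"LINK must join consecutive frames, got {cmd.time} and {cmd.partner_time}"
            )
        rec = _require(frames, cmd.time, cmd.index)
        partner = _require(frames, cmd.partner_time, cmd.partner_index)
        if not rec.valid or not partner.valid:
            raise EditError("LINK endpoints must be valid records")
        if partner.predecessor is not None:
            raise EditError(
                f"record {cmd.partner_time}:{cmd.partner_index} already has a predecessor"
            )
        if rec.successor1 is None:
            rec.successor1 = partner.index
        elif rec.successor2 is None:
            rec.successor2 = partner.index
        else:
            raise EditError(
                f"record {cmd.time}:{cmd.index} already has two successors"
            )
        partner.predecessor = rec.index
        cs.affected |= {(cmd.time, rec.index), (cmd.partner_time, partner.index)}
        cs.structural = True

    elif cmd.kind is EditKind.UNLINK:
        if cmd.partner_time != cmd.time + 1:
            raise EditError(
                f"UNLINK must name consecutive frames, got {cmd.time} and {cmd.partner_time}"
            )
        rec = _require(frames, cmd.time, cmd.index)
        partner = _require(frames, cmd.partner_time, cmd.partner_index)
        if partner.index not in (rec.successor1, rec.successor2) or \
                partner.predecessor != rec.index:
            raise EditError(
                f"no link between {cmd.time}:{cmd.index} and "
                f"{cmd.partner_time}:{cmd.partner_index}"
            )
        _sever_successor(rec, partner.index)
        partner.predecessor = None
        cs.affected |= {(cmd.time, rec.index), (cmd.partner_time, partner.index)}
        cs.structural = True

    elif cmd.kind is EditKind.SET_POSITION:
        rec = _require(frames, cmd.time, cmd.index)
        if cmd.x is None or cmd.y is None or cmd.z is None:
            raise EditError("SET_POSITION requires x, y and z")
        rec.x, rec.y, rec.z = cmd.x, cmd.y, cmd.z
        cs.affected.add((cmd.time, rec.index))

    else:  # pragma: no cover - enum is closed
        raise EditError(f"unknown edit kind {cmd.kind}")

    report = validate_links(frames)
    if not report.ok:
        raise EditError(f"edit leaves links inconsistent: {report.errors[0]}")
    return frames, cs


@dataclass
class EditScriptResult:
    frames: list
    changes: ChangeSet
    assignments: Optional[dict] = None
    tree: Optional[object] = None


def edit_script(
    frames,
    commands: Sequence[EditCommand],
    *,
    transform=None,
    rules=None,
    meta=None,
    seeds=None,
    forced=None,
) -> EditScriptResult:
    """Apply commands in order, re-naming after every structural command.

    Naming runs when ``transform``, ``rules`` and ``meta`` are all supplied;
    seed/forced entries that stop resolving after an edit are dropped (see
    :func:`sulston.naming.rename_after_edit`).  The first failing command
    aborts with :class:`EditScriptError` carrying the index, the reason and
    the state after the last successful command.
    """
    state = copy.deepcopy(list(frames))
    merged = ChangeSet()
    want_names = transform is not None and rules is not None and meta is not None
    assignments = None
    tree = None

    for i, cmd in enumerate(commands):
        try:
            new_state, cs = apply_edit(state, cmd)
            if cs.structural and want_names:
                tree = build_tracks(new_state)
                assignments = naming.rename_after_edit(
                    tree, transform, rules, meta, seeds=seeds, forced=forced
                )
        except LineageError as exc:
            raise EditScriptError(i, exc, state, i) from exc
        state, _ = new_state, None
        merged = merged.merge(cs)

    if want_names:
        # final pass also covers trailing attribute-only commands, whose
        # position changes can move a division vector
        tree = build_tracks(state)
        assignments = naming.rename_after_edit(
            tree, transform, rules, meta, seeds=seeds, forced=forced
        )
    return EditScriptResult(frames=state, changes=merged, assignments=assignments, tree=tree)


# ---------------------------------------------------------------------------
# script parsing:  KIND t:index [args...]

def _coord(token: str) -> tuple[int, int]:
    try:
        t, i = token.split(":")
        return int(t), int(i)
    except ValueError as exc:
        raise EditError(f"bad coordinate {token!r}, expected t:index") from exc


def parse_edit_script(text: str) -> list[EditCommand]:
    """Parse the line-oriented edit grammar (see module docstring).

    Blank lines and ``#`` comments are ignored.  Errors name the line.
    """
    commands: list[EditCommand] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            tokens = shlex.split(line)
            kind = EditKind(tokens[0].upper())
            if kind is EditKind.ADD:
                if len(tokens) not in (5, 6):
                    raise EditError("ADD takes: t x y z [diameter]")
                commands.append(EditCommand(
                    kind, time=int(tokens[1]),
                    x=float(tokens[2]), y=float(tokens[3]), z=float(tokens[4]),
                    diameter=float(tokens[5]) if len(tokens) == 6 else 0.0,
                ))
            elif kind is EditKind.DELETE:
                t, i = _coord(tokens[1])
                commands.append(EditCommand(kind, time=t, index=i))
            elif kind in (EditKind.LINK, EditKind.UNLINK):
                t, i = _coord(tokens[1])
                pt, pi = _coord(tokens[2])
                commands.append(EditCommand(
                    kind, time=t, index=i, partner_time=pt, partner_index=pi
                ))
            elif kind is EditKind.SET_POSITION:
                t, i = _coord(tokens[1])
                commands.append(EditCommand(
                    kind, time=t, index=i,
                    x=float(tokens[2]), y=float(tokens[3]), z=float(tokens[4]),
                ))
        except (ValueError, IndexError, KeyError) as exc:
            raise EditError(f"script line {lineno}: {raw!r}: {exc}") from exc
        except EditError as exc:
            raise EditError(f"script line {lineno}: {exc}") from exc
    return commands
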