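"""Readers and writers for tracker output and its side-car tables.

Four external surfaces:

* **Nuclei archive** — a ZIP with one comma-separated text file per frame,
  named ``t%05d.csv`` (the reader accepts any zero-padded integer stem).
  One line per record, fields in this order::

      time, index, valid, predecessor, successor1, successor2,
      x, y, z, diameter, identity, weight

  ``valid`` is ``1``/``0``; absent links are ``-1``; numbers are serialized
  locale-independently (decimal point, full precision); ``identity`` is
  CSV-quoted so arbitrary (unicode, forced) names survive.  This dialect is
  the project's normative record format (documented in ``docs/formats.md``);
  a column-map hook re-orders columns for legacy archives.

* **AuxInfo_v2.xml** — embryo metadata: either explicit image-space AP and
  LR orientation vectors or a legacy canonical-orientation keyword, plus
  voxel/time resolutions, bit depth and channel count.

* **Parts List** — TSV mapping systematic to functional names.

* **Expected-axis table** — CSV of per-parent expected division directions
  in canonical space (``parent_name, ex, ey, ez, suffix_pair``).

All readers are total on the writers' output (bit-exact round trips), and
archive reading is streaming-safe: frames load lazily from the ZIP index.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from lxml import etree

from .model import LineageError, NucleusRecord

__all__ = [
    "AxisMode",
    "EmbryoMetadata",
    "PartsListEntry",
    "PartsList",
    "ExpectedAxis",
    "ArchiveFormatError",
    "MetadataError",
    "PartsListError",
    "NUCLEI_FIELDS",
    "NucleiArchive",
    "read_nuclei_archive",
    "write_nuclei_archive",
    "read_aux_info",
    "write_aux_info",
    "read_parts_list",
    "read_expected_axes",
    "write_expected_axes",
]


class ArchiveFormatError(LineageError):
    pass


class MetadataError(LineageError):
    pass


class PartsListError(LineageError):
    pass


class AxisMode(Enum):
    CANONICAL_KEYWORD = "canonical_keyword"
    EXPLICIT_VECTORS = "explicit_vectors"


@dataclass
class EmbryoMetadata:
    """Embryo orientation and acquisition metadata (AuxInfo_v2 content)."""

    ap_vector: Optional[np.ndarray] = None
    lr_vector: Optional[np.ndarray] = None
    xy_res: float = 1.0
    z_res: float = 1.0
    time_res: Optional[float] = None
    axis_mode: AxisMode = AxisMode.CANONICAL_KEYWORD
    bit_depth: int = 16
    channels: int = 1

    def __post_init__(self) -> None:
        if self.xy_res <= 0 or self.z_res <= 0:
            raise MetadataError("xy_res and z_res must be positive")
        if self.time_res is not None and self.time_res <= 0:
            raise MetadataError("time_res must be positive when set")
        if self.bit_depth not in (8, 16):
            raise MetadataError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.channels < 1:
            raise MetadataError("channels must be >= 1")
        if self.axis_mode is AxisMode.EXPLICIT_VECTORS:
            for name, v in (("ap_vector", self.ap_vector), ("lr_vector", self.lr_vector)):
                if v is None:
                    raise MetadataError(f"{name} required in explicit-vectors mode")
                arr = np.asarray(v, dtype=float)
                if arr.shape != (3,):
                    raise MetadataError(f"{name} must have 3 components")
                if np.linalg.norm(arr) == 0.0:
                    raise MetadataError(f"{name} must be nonzero")
                setattr(self, name.replace("-", "_"), arr)


@dataclass(frozen=True)
class PartsListEntry:
    systematic: str
    functional: str = ""
    description: str = ""


class PartsList:
    """Bidirectional systematic ↔ functional name maps.

    systematic → functional is one-to-one (duplicate systematic names are
    rejected at read time); functional → systematic may be one-to-many and
    is returned as a list.  Lookups are case-insensitive.
    """

    def __init__(self, entries: Sequence[PartsListEntry]):
        self.entries = list(entries)
        self._by_sys: dict[str, PartsListEntry] = {}
        self._by_func: dict[str, list[str]] = {}
        for e in self.entries:
            self._by_sys[e.systematic.casefold()] = e
            if e.functional:
                self._by_func.setdefault(e.functional.casefold(), []).append(e.systematic)

    def __len__(self) -> int:
        return len(self.entries)

    def functional_for(self, systematic: str) -> Optional[str]:
        e = self._by_sys.get(systematic.casefold())
        return e.functional if e else None

    def systematic_for(self, functional: str) -> list[str]:
        return list(self._by_func.get(functional.casefold(), []))


@dataclass(frozen=True)
class ExpectedAxis:
    """Expected division direction for one parent, in canonical space."""

    vector: np.ndarray
    suffix_pair: tuple[str, str]

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        n = np.linalg.norm(v)
        if abs(n - 1.0) > 1e-6:
            raise LineageError(f"expected-axis vector must be unit length, |v| = {n:g}")
        object.__setattr__(self, "vector", v)
        if len(self.suffix_pair) != 2 or self.suffix_pair[0] == self.suffix_pair[1]:
            raise LineageError("suffix_pair must be two distinct characters")


# ---------------------------------------------------------------------------
# nuclei archive

NUCLEI_FIELDS = (
    "time", "index", "valid", "predecessor", "successor1", "successor2",
    "x", "y", "z", "diameter", "identity", "weight",
)

_FRAME_RE = re.compile(r"^\D*0*(\d+)$")


def _record_to_row(rec: NucleusRecord) -> list[str]:
    def link(v: Optional[int]) -> str:
        return "-1" if v is None else str(v)

    return [
        str(rec.time), str(rec.index), "1" if rec.valid else "0",
        link(rec.predecessor), link(rec.successor1), link(rec.successor2),
        repr(float(rec.x)), repr(float(rec.y)), repr(float(rec.z)),
        repr(float(rec.diameter)), rec.identity, repr(float(rec.weight)),
    ]


def _row_to_record(row: Sequence[str], where: str) -> NucleusRecord:
    if len(row) != len(NUCLEI_FIELDS):
        raise ArchiveFormatError(
            f"{where}: expected {len(NUCLEI_FIELDS)} fields, got {len(row)}"
        )

    def link(s: str) -> Optional[int]:
        v = int(s)
        return None if v == -1 else v

    try:
        return NucleusRecord(
            time=int(row[0]),
            index=int(row[1]),
            valid=row[2] == "1",
            predecessor=link(row[3]),
            successor1=link(row[4]),
            successor2=link(row[5]),
            x=float(row[6]),
            y=float(row[7]),
            z=float(row[8]),
            diameter=float(row[9]),
            identity=row[10],
            weight=float(row[11]),
        )
    except ValueError as exc:
        raise ArchiveFormatError(f"{where}: {exc}") from exc


def _apply_column_map(row: Sequence[str], column_map: Sequence[int]) -> list[str]:
    return [row[i] for i in column_map]


class NucleiArchive(Sequence):
    """Lazy, sequence-like view of a nuclei ZIP archive.

    ``archive[t0]`` (0-based list position) parses frame ``t0 + 1`` on
    demand, so peak memory is one frame plus the ZIP index regardless of the
    number of frames.  Frames missing from a contiguous range are substituted
    with empty lists after a warning.
    """

    def __init__(self, path, column_map: Optional[Sequence[int]] = None):
        self.path = Path(path)
        self.column_map = list(column_map) if column_map is not None else None
        try:
            self._zf = zipfile.ZipFile(self.path)
        except (OSError, zipfile.BadZipFile) as exc:
            raise ArchiveFormatError(f"{self.path}: {exc}") from exc
        self._members: dict[int, str] = {}
        for name in self._zf.namelist():
            stem = Path(name).stem
            m = _FRAME_RE.match(stem)
            if m and not name.endswith("/"):
                self._members[int(m.group(1))] = name
        self._n = max(self._members) if self._members else 0
        missing = [t for t in range(1, self._n + 1) if t not in self._members]
        if missing:
            warnings.warn(
                f"{self.path.name}: missing frame file(s) {missing}; "
                "substituting empty frames",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return self._n

    def frame(self, time: int) -> list[NucleusRecord]:
        """Records of 1-based frame ``time``."""
        member = self._members.get(time)
        if member is None:
            return []
        records: list[NucleusRecord] = []
        with self._zf.open(member) as fh:
            text = io.TextIOWrapper(fh, encoding="utf-8", newline="")
            for lineno, row in enumerate(csv.reader(text), start=1):
                if not row:
                    continue
                if self.column_map is not None:
                    row = _apply_column_map(row, self.column_map)
                records.append(_row_to_record(row, f"{member}:{lineno}"))
        return records

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        if i < 0:
            i += len(self)
        if not 0 <= i < len(self):
            raise IndexError(i)
        return self.frame(i + 1)

    def close(self) -> None:
        self._zf.close()

    def __enter__(self) -> "NucleiArchive":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_nuclei_archive(
    path, column_map: Optional[Sequence[int]] = None, lazy: bool = False
):
    """Read a nuclei ZIP archive into per-frame record lists.

    With ``lazy=True`` returns the :class:`NucleiArchive` view itself (one
    frame in memory at a time); otherwise a fully materialized list.
    ``column_map`` maps legacy column orders onto the project dialect:
    ``column_map[k]`` is the source column holding field ``NUCLEI_FIELDS[k]``.
    """
    archive = NucleiArchive(path, column_map=column_map)
    if lazy:
        return archive
    with archive:
        return [archive.frame(t) for t in range(1, len(archive) + 1)]


def write_nuclei_archive(frames: Sequence[Sequence[NucleusRecord]], path) -> None:
    """Write per-frame record lists as a ZIP of ``t%05d.csv`` members."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for t0, frame in enumerate(frames):
                buf = io.StringIO()
                writer = csv.writer(buf, lineterminator="\n")
                for rec in frame:
                    writer.writerow(_record_to_row(rec))
                zf.writestr(f"t{t0 + 1:05d}.csv", buf.getvalue())
    except OSError as exc:
        raise ArchiveFormatError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# AuxInfo_v2.xml

def _parse_vector(text: str, what: str) -> np.ndarray:
    try:
        parts = [float(p) for p in text.split()]
    except ValueError as exc:
        raise MetadataError(f"{what}: {exc}") from exc
    if len(parts) != 3:
        raise MetadataError(f"{what} must have 3 space-separated components")
    v = np.array(parts)
    if np.linalg.norm(v) == 0.0:
        raise MetadataError(f"{what} must be nonzero")
    return v


def read_aux_info(path) -> EmbryoMetadata:
    """Parse an AuxInfo_v2.xml metadata file.

    Exactly one orientation style must be present: explicit ``ap_vector`` +
    ``lr_vector`` elements, or the legacy ``orientation`` keyword meaning the
    embryo is already canonically oriented.
    """
    try:
        root = etree.parse(str(path)).getroot()
    except (OSError, etree.XMLSyntaxError) as exc:
        raise MetadataError(f"{path}: {exc}") from exc

    def text(tag: str) -> Optional[str]:
        el = root.find(tag)
        return None if el is None or el.text is None else el.text.strip()

    ap, lr, keyword = text("ap_vector"), text("lr_vector"), text("orientation")
    has_vectors = ap is not None or lr is not None
    if has_vectors and keyword is not None:
        raise MetadataError(f"{path}: both explicit vectors and legacy orientation present")
    if not has_vectors and keyword is None:
        raise MetadataError(f"{path}: no orientation given (vectors or legacy keyword)")
    if has_vectors and (ap is None or lr is None):
        raise MetadataError(f"{path}: both ap_vector and lr_vector are required")

    kwargs = {}
    for tag, conv in (("xy_res", float), ("z_res", float), ("time_res", float),
                      ("bit_depth", int), ("channels", int)):
        val = text(tag)
        if val is not None:
            try:
                kwargs[tag] = conv(val)
            except ValueError as exc:
                raise MetadataError(f"{path}: bad {tag}: {exc}") from exc

    if has_vectors:
        return EmbryoMetadata(
            ap_vector=_parse_vector(ap, "ap_vector"),
            lr_vector=_parse_vector(lr, "lr_vector"),
            axis_mode=AxisMode.EXPLICIT_VECTORS,
            **kwargs,
        )
    return EmbryoMetadata(axis_mode=AxisMode.CANONICAL_KEYWORD, **kwargs)


def write_aux_info(meta: EmbryoMetadata, path) -> None:
    root = etree.Element("auxinfo", version="2")

    def add(tag: str, value: str) -> None:
        etree.SubElement(root, tag).text = value

    if meta.axis_mode is AxisMode.EXPLICIT_VECTORS:
        add("ap_vector", " ".join(repr(float(c)) for c in meta.ap_vector))
        add("lr_vector", " ".join(repr(float(c)) for c in meta.lr_vector))
    else:
        add("orientation", "canonical")
    add("xy_res", repr(meta.xy_res))
    add("z_res", repr(meta.z_res))
    if meta.time_res is not None:
        add("time_res", repr(meta.time_res))
    add("bit_depth", str(meta.bit_depth))
    add("channels", str(meta.channels))
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Parts List (TSV) and expected-axis table (CSV)

def read_parts_list(path) -> PartsList:
    """Read a tab-separated Parts List (systematic, functional, description).

    Rows with a missing functional column yield entries with an empty
    functional name.  Duplicate systematic names are an error naming the
    offending line.
    """
    entries: list[PartsListEntry] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            systematic = row[0].strip()
            key = systematic.casefold()
            if key in seen:
                raise PartsListError(
                    f"{path}: duplicate systematic name {systematic!r} "
                    f"(lines {seen[key]} and {lineno})"
                )
            seen[key] = lineno
            functional = row[1].strip() if len(row) > 1 else ""
            description = row[2].strip() if len(row) > 2 else ""
            entries.append(PartsListEntry(systematic, functional, description))
    return PartsList(entries)


def read_expected_axes(path) -> dict[str, ExpectedAxis]:
    """Read the per-parent expected division axis table.

    CSV columns: ``parent_name, ex, ey, ez, suffix_pair`` with an optional
    header line; vectors are in canonical space and must be unit length.
    """
    table: dict[str, ExpectedAxis] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            if lineno == 1 and row[0].strip().lower() == "parent_name":
                continue
            if len(row) < 5:
                raise LineageError(f"{path}:{lineno}: expected 5 columns")
            name = row[0].strip()
            if name in table:
                raise LineageError(f"{path}:{lineno}: duplicate parent {name!r}")
            try:
                vec = np.array([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as exc:
                raise LineageError(f"{path}:{lineno}: {exc}") from exc
            pair = row[4].strip()
            if len(pair) != 2:
                raise LineageError(f"{path}:{lineno}: suffix_pair must be 2 characters")
            table[name] = ExpectedAxis(vec, (pair[0], pair[1]))
    return table


def write_expected_axes(table: dict[str, ExpectedAxis], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["parent_name", "ex", "ey", "ez", "suffix_pair"])
        for name in sorted(table):
            ax = table[name]
            writer.writerow(
                [name, repr(float(ax.vector[0])), repr(float(ax.vector[1])),
                 repr(float(ax.vector[2])), ax.suffix_pair[0] + ax.suffix_pair[1]]
            )
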