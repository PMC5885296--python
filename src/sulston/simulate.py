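"""Synthetic tracked-embryo generator with ground-truth names.

Emits exactly the surfaces the readers consume — a nuclei archive, an
AuxInfo_v2 metadata file, an expected-axis table and a ground-truth name
map — so every other module can be exercised end to end without any real
microscopy data.

The simulation starts at the canonical 4-cell diamond (ABa anterior-dorsal,
ABp posterior-dorsal, EMS ventral, P2 posterior) and divides every cell
synchronously every ``cell_cycle_frames`` frames.  Division directions come
from a *synthetic* expected-axis table: exactly canonical-axis-aligned for
the four founders' divisions, and thereafter a canonical axis tilted by a
deterministic ≤ 25° angle derived from a hash of the parent name (so the
dominant component always remains the base axis and body-axis fallback
agrees with the table at zero noise).  Founder-style special daughters
(EMS → MS/E, P2 → C/P3, ...) divide exactly along their classification
axis and are not entered in the table.

Daughters appear at ± half the division distance along the division axis;
positions are constant between divisions.  Gaussian positional noise (in
embryo space, i.e. before the rigid orientation is applied — it models
detection jitter on the specimen) perturbs every record independently.
Finally an arbitrary proper rigid orientation maps embryo space to image
space, and the AuxInfo AP/LR vectors are that rotation applied to the
canonical axes.  A single NumPy generator keyed by ``seed`` drives all
randomness, consumed frame by frame in record order, so equal seeds give
byte-identical archives.

Not modelled (extension hooks, not silent omissions): cell death, motion
between divisions, detection failure, asynchronous cycles.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .model import NucleusRecord
from .naming import CELEGANS_SPECIAL_DAUGHTERS, FALLBACK_SUFFIXES
from .starrynite import (
    AxisMode,
    EmbryoMetadata,
    ExpectedAxis,
    write_aux_info,
    write_expected_axes,
    write_nuclei_archive,
)
from .transform import RigidTransform

__all__ = ["SimConfig", "SimResult", "generate", "random_orientation", "write_bundle"]

MAX_TRACKS = 2 ** 12

# canonical 4-cell diamond, micrometers (AP: +x posterior, DV: +y ventral,
# LR: +z right); ABa is the anterior-dorsal cell, P2 the posterior pole
FOUR_CELL_UM = {
    "ABa": np.array([15.0, 10.0, 15.0]),
    "ABp": np.array([27.0, 10.0, 15.0]),
    "EMS": np.array([21.0, 20.0, 15.0]),
    "P2": np.array([33.0, 18.0, 15.0]),
}

_BASIS = np.eye(3)


@dataclass
class SimConfig:
    seed: int = 0
    n_rounds: int = 3
    cell_cycle_frames: int = 5
    division_distance: float = 4.0       # µm between newborn sisters
    position_noise_sd: float = 0.0       # µm, per coordinate
    orientation: RigidTransform = field(default_factory=RigidTransform.identity)
    xy_res: float = 0.1                  # µm per pixel
    z_res: float = 1.0                   # µm per plane
    time_res: float = 1.0                # minutes per frame

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if self.cell_cycle_frames < 2:
            raise ValueError("cell_cycle_frames must be >= 2")
        if self.division_distance <= 0:
            raise ValueError("division_distance must be positive")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be >= 0")
        total_tracks = 4 * (2 ** (self.n_rounds + 1) - 1)
        if total_tracks > MAX_TRACKS:
            raise ValueError(
                f"n_rounds={self.n_rounds} would create {total_tracks} tracks "
                f"(cap {MAX_TRACKS})"
            )


@dataclass
class SimResult:
    frames: list
    metadata: EmbryoMetadata
    truth: dict              # track key (birth_time, first index) → name
    expected_axes: dict      # parent name → ExpectedAxis
    config: SimConfig


def _name_hash(name: str) -> int:
    return int.from_bytes(hashlib.md5(name.encode()).digest()[:8], "big")


def _axis_for(name: str, founder: bool) -> tuple[np.ndarray, tuple[str, str]]:
    """Deterministic division axis and suffix pair for a parent name."""
    h = _name_hash(name)
    base = h % 3
    pair = FALLBACK_SUFFIXES[base]
    vec = _BASIS[base].copy()
    if founder:
        return vec, pair
    # tilt ≤ 25° about a deterministic axis perpendicular to the base axis,
    # keeping the base component dominant (cos 25° ≈ 0.91)
    angle = np.radians(((h // 3) % 1000) / 999.0 * 25.0)
    perp = _BASIS[(base + 1 + (h // 3000) % 2) % 3]
    tilted = Rotation.from_rotvec(angle * perp).as_matrix() @ vec
    return tilted / np.linalg.norm(tilted), pair


def build_expected_axes(n_rounds: int) -> dict[str, ExpectedAxis]:
    """Synthetic expected-axis table for every non-special parent name.

    Covers all parents that divide within ``n_rounds`` rounds from the
    4-cell stage.
    """
    table: dict[str, ExpectedAxis] = {}
    current = list(FOUR_CELL_UM)
    for r in range(n_rounds):
        nxt = []
        for name in current:
            d1, d2, _ = _daughters(name, table_round=r)
            nxt.extend([d1, d2])
            if name in CELEGANS_SPECIAL_DAUGHTERS or name in table:
                continue
            vec, pair = _axis_for(name, founder=(r == 0))
            table[name] = ExpectedAxis(vec, pair)
        current = nxt
    return table


def _daughters(name: str, table_round: int) -> tuple[str, str, np.ndarray]:
    """Ground-truth daughter names and the division axis for a parent."""
    special = CELEGANS_SPECIAL_DAUGHTERS.get(name)
    if special is not None:
        first, second, axis = special
        return first, second, _BASIS[axis].copy()
    vec, pair = _axis_for(name, founder=(table_round == 0))
    return name + pair[0], name + pair[1], vec


def random_orientation(rng: np.random.Generator, translation_um: float = 0.0) -> RigidTransform:
    """Uniformly random proper rotation (plus optional random translation)."""
    rot = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-translation_um, translation_um, 3) if translation_um else np.zeros(3)
    return RigidTransform(rot, t)


def generate(config: SimConfig) -> SimResult:
    """Simulate the embryo and return frames, metadata and ground truth.

    Frame layout: round ``p`` (0-based) occupies frames
    ``p·L + 1 .. (p+1)·L`` with ``L = cell_cycle_frames``; divisions happen
    across each round boundary.  Ground truth maps a track's key (its birth
    frame and first in-frame index) to the systematic name.
    """
    rng = np.random.default_rng(config.seed)
    L = config.cell_cycle_frames
    half = config.division_distance / 2.0

    # cells of the current round, in creation order: (name, embryo-space µm)
    cells: list[tuple[str, np.ndarray]] = [
        (n, FOUR_CELL_UM[n].copy()) for n in ("ABa", "ABp", "EMS", "P2")
    ]
    frames: list[list[NucleusRecord]] = []
    truth: dict[tuple[int, int], str] = {}

    def emit_frame(time: int, positions: list[np.ndarray]) -> list[NucleusRecord]:
        recs = []
        for i, pos in enumerate(positions, start=1):
            noisy = pos + rng.normal(0.0, config.position_noise_sd, 3) \
                if config.position_noise_sd > 0 else pos
            img = config.orientation.apply_point(noisy)
            recs.append(NucleusRecord(
                time=time, index=i,
                x=img[0] / config.xy_res,
                y=img[1] / config.xy_res,
                z=img[2] / config.z_res,
                diameter=25.0, weight=5000.0,
            ))
        frames.append(recs)
        return recs

    born_of_division = False
    for round_idx in range(config.n_rounds + 1):
        birth = round_idx * L + 1
        for i, (name, _) in enumerate(cells, start=1):
            truth[(birth, i)] = name
        for step in range(L):
            time = birth + step
            recs = emit_frame(time, [pos for _, pos in cells])
            if step > 0:
                # continuation links within the round
                prev = frames[time - 2]
                for i, rec in enumerate(recs, start=1):
                    rec.predecessor = i
                    prev[i - 1].successor1 = i
            elif born_of_division:
                # first frame after a division: daughters 2p-1, 2p ← parent p
                for i, rec in enumerate(recs, start=1):
                    rec.predecessor = (i + 1) // 2

        if round_idx == config.n_rounds:
            break

        # divide every cell across the round boundary
        parent_recs = frames[-1]
        parents, cells = cells, []
        for pi, (name, pos) in enumerate(parents, start=1):
            first, second, axis = _daughters(name, table_round=round_idx)
            cells.append((first, pos - half * axis))
            cells.append((second, pos + half * axis))
            parent_recs[pi - 1].successor1 = 2 * pi - 1
            parent_recs[pi - 1].successor2 = 2 * pi
        born_of_division = True

    metadata = EmbryoMetadata(
        ap_vector=config.orientation.apply_direction([1.0, 0.0, 0.0]),
        lr_vector=config.orientation.apply_direction([0.0, 0.0, 1.0]),
        xy_res=config.xy_res,
        z_res=config.z_res,
        time_res=config.time_res,
        axis_mode=AxisMode.EXPLICIT_VECTORS,
        bit_depth=16,
        channels=1,
    )
    return SimResult(
        frames=frames,
        metadata=metadata,
        truth=truth,
        expected_axes=build_expected_axes(config.n_rounds),
        config=config,
    )


def write_bundle(result: SimResult, outdir) -> dict[str, Path]:
    """Write the archive, metadata, expected-axis table and truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "archive": outdir / "nuclei.zip",
        "auxinfo": outdir / "AuxInfo_v2.xml",
        "expected_axes": outdir / "expected_axes.csv",
        "truth": outdir / "truth.csv",
    }
    write_nuclei_archive(result.frames, paths["archive"])
    write_aux_info(result.metadata, paths["auxinfo"])
    write_expected_axes(result.expected_axes, paths["expected_axes"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("birth_time,first_index,name\n")
        for (t, i), name in sorted(result.truth.items()):
            fh.write(f"{t},{i},{name}\n")
    return paths
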