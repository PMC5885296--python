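"""16-bit → 8-bit display mapping with per-channel black/white points.

Modern sensors deliver 16-bit intensities; display surfaces want 8 bits.
Each channel maps linearly between a black point (everything at or below it
shows as 0) and a white point (everything at or above shows as 255):

    display = round(255 · (value − black) / (white − black))

clamped to [0, 255], with round-half-away-from-zero.  The mapping is
monotone non-decreasing in the input, and ``black=0, white=255`` is an exact
identity on 8-bit data.  No gamma is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LineageError

__all__ = ["DisplayMapping", "map_to_display", "suggest_display_mapping", "read_tiff_stack"]


@dataclass(frozen=True)
class DisplayMapping:
    """Black/white intensity points for one channel."""

    black: int = 0
    white: int = 65535

    def __post_init__(self) -> None:
        if not 0 <= self.black:
            raise LineageError("black point must be >= 0")
        if self.white > 65535:
            raise LineageError("white point must be <= 65535")
        if self.black >= self.white:
            raise LineageError(
                f"black point ({self.black}) must be below white point ({self.white})"
            )


def map_to_display(value, mapping: DisplayMapping):
    """Map 16-bit intensities to 8-bit display values.

    Accepts a scalar or any ndarray; returns ``uint8`` of the same shape
    (a Python int for scalar input).
    """
    v = np.asarray(value, dtype=np.float64)
    scaled = 255.0 * (v - mapping.black) / (mapping.white - mapping.black)
    out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).astype(np.uint8)
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(out)
    return out


def suggest_display_mapping(stack, low_pct: float = 0.1, high_pct: float = 99.9) -> DisplayMapping:
    """Propose black/white points at intensity percentiles of a stack."""
    arr = np.asarray(stack)
    black = int(np.percentile(arr, low_pct))
    white = int(np.ceil(np.percentile(arr, high_pct)))
    if white <= black:
        white = black + 1
    return DisplayMapping(black=black, white=min(white, 65535))


def read_tiff_stack(path) -> np.ndarray:
    """Convenience reader for single-channel 8/16-bit TIFF stacks (plane per page)."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.dtype not in (np.uint8, np.uint16):
        raise LineageError(f"{path}: expected 8- or 16-bit data, got {arr.dtype}")
    return arr
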