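"""Compact 16-bit picometer coordinate encoding.

Distance histograms at 1 pm resolution only need coordinates to the nearest
picometer, so a cloud whose largest pairwise distance stays below 65,536 pm
fits in unsigned 16-bit integers after two steps: convert meters to
picometers (factor 1e12) and round to the nearest integer, then add a
per-axis shift that makes every coordinate non-negative.  The shift cancels
in coordinate differences, so pairwise distances are preserved up to the
+/-0.5 pm per-component rounding (at most sqrt(3) pm per distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ParticleCloud

__all__ = [
    "COMPACT_MAX_PM",
    "CapacityError",
    "CompactCloud",
    "compact_encode",
    "compact_decode",
    "save_compact",
    "load_compact",
]

#: largest coordinate representable by the compact format, in pm
COMPACT_MAX_PM = np.iinfo(np.uint16).max  # 65,535


class CapacityError(ValueError):
    """Cloud extent exceeds what 16-bit picometer coordinates can hold."""


@dataclass
class CompactCloud:
    """Quantized cloud: uint16 picometer coordinates in a shifted frame.

    ``shift`` records the per-axis offset (pm) that was added before
    quantization; it is stored so runs are reproducible, but it is never
    removed on decode because distances are shift-invariant.
    """

    q_positions: np.ndarray
    weights: np.ndarray
    shift: np.ndarray

    def __post_init__(self) -> None:
        self.q_positions = np.asarray(self.q_positions, dtype=np.uint16).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        self.shift = np.asarray(self.shift, dtype=np.float64).reshape(3)
        if len(self.q_positions) != len(self.weights):
            raise ValueError("q_positions and weights must have equal length")

    def __len__(self) -> int:
        return len(self.weights)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; the format is defined with ties away from zero
    # (half-up), which for the already-shifted non-negative frame is floor(x+0.5)
    return np.floor(x + 0.5)


def compact_encode(cloud: ParticleCloud) -> CompactCloud:
    """Quantize a cloud to the shifted uint16 picometer representation.

    The per-axis shift is the ceiling of the largest absolute negative
    coordinate (zero for axes with no negative values).  Raises
    :class:`CapacityError`, naming the offending extent, if any shifted
    coordinate would exceed 65,535 pm.
    """
    cloud = cloud.to_pm()
    pos = cloud.positions
    if len(cloud) == 0:
        return CompactCloud(np.empty((0, 3), np.uint16), cloud.weights, np.zeros(3))
    shift = np.ceil(np.maximum(-pos.min(axis=0), 0.0))
    shifted = _round_half_up(pos + shift)
    top = shifted.max(axis=0)
    if (top > COMPACT_MAX_PM).any():
        axis = int(np.argmax(top))
        raise CapacityError(
            f"cloud spans {top[axis]:.0f} pm on axis {axis} after shifting; "
            f"the 16-bit picometer format holds at most {COMPACT_MAX_PM} pm"
        )
    return CompactCloud(shifted.astype(np.uint16), cloud.weights.copy(), shift)


def compact_decode(ccloud: CompactCloud) -> ParticleCloud:
    """Back to a real-valued picometer cloud, still in the shifted frame."""
    return ParticleCloud(
        ccloud.q_positions.astype(np.float64), ccloud.weights.copy(), "pm"
    )


# ---------------------------------------------------------------------------
# binary interchange: little-endian uint16 triplets + float64 weights
# ---------------------------------------------------------------------------

_MAGIC = b"PPSAXSC1"


def save_compact(ccloud: CompactCloud, path) -> None:
    """Dump a CompactCloud to a little-endian binary file (bit-exact)."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(np.uint64(len(ccloud)).tobytes())
        fh.write(ccloud.shift.astype("<f8").tobytes())
        fh.write(ccloud.q_positions.astype("<u2").tobytes())
        fh.write(ccloud.weights.astype("<f8").tobytes())


def load_compact(path) -> CompactCloud:
    with open(path, "rb") as fh:
        if fh.read(8) != _MAGIC:
            raise ValueError(f"{path} is not a compact-cloud file")
        n = int(np.frombuffer(fh.read(8), "<u8")[0])
        shift = np.frombuffer(fh.read(24), "<f8").copy()
        qpos = np.frombuffer(fh.read(6 * n), "<u2").copy().reshape(n, 3)
        weights = np.frombuffer(fh.read(8 * n), "<f8").copy()
    return CompactCloud(qpos, weights, shift)
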