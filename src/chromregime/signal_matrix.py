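"""Peak-summit-centred binned read-count matrices.

Each track's matrix has one row per peak summit and one column per
non-overlapping bin (defaults: 51-bp bins spanning +/- 5100 bp, i.e. 200
columns). ChIP read 5' ends are shifted 100 bp downstream before counting
(accessibility tracks use shift 0). Matrices are clip-normalized at the
99.9% count quantile and divided by it, then concatenated across tracks as
input to the regime clustering.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import PeakSummit, ReadTag


class GeometryError(ValueError):
    """Inconsistent window/bin geometry."""


@dataclass(frozen=True)
class MatrixGeometry:
    """Window geometry: half-width ``flank``, ``bin_size`` bp bins, 5' ``shift``."""

    flank: int = 5100
    bin_size: int = 51
    shift: int = 100

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.bin_size <= 0:
            raise GeometryError("flank and bin_size must be positive")
        if (2 * self.flank) % self.bin_size != 0:
            raise GeometryError(
                f"window width {2 * self.flank} not divisible by bin size "
                f"{self.bin_size}"
            )
        if self.shift < 0:
            raise GeometryError("shift must be >= 0")

    @property
    def n_bins(self) -> int:
        return (2 * self.flank) // self.bin_size


@dataclass
class SignalMatrix:
    """Per-track peaks x bins matrix with its geometry and clip state."""

    track: str
    summits: list[PeakSummit]
    values: np.ndarray
    geometry: MatrixGeometry
    clip_value: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.summits), self.geometry.n_bins):
            raise GeometryError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.summits)} peaks x {self.geometry.n_bins} bins"
            )

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready frame: peak id column then bin columns labelled by offset."""
        g = self.geometry
        cols = [f"bin_{-g.flank + j * g.bin_size}" for j in range(g.n_bins)]
        frame = pd.DataFrame(self.values, columns=cols)
        frame.insert(0, "peak", [f"{s.chrom}:{s.pos}" for s in self.summits])
        return frame


def shift_tags(tags: Iterable[ReadTag], shift: int) -> list[ReadTag]:
    """Shift 5' ends ``shift`` bp downstream: + strand right, - strand left.

    Positions are clamped at the chromosome start (0).
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if shift == 0:
        return list(tags)
    out = []
    for t in tags:
        pos = t.five_prime + shift if t.strand == "+" else t.five_prime - shift
        out.append(ReadTag(t.chrom, max(0, pos), t.strand))
    return out


def count_matrix(
    tags: Sequence[ReadTag],
    summits: Sequence[PeakSummit],
    geometry: MatrixGeometry = MatrixGeometry(),
    track: str = "track",
    apply_shift: bool = True,
) -> SignalMatrix:
    """Count shifted tag 5' ends in summit-centred bins.

    This is the single counting entry point: ``geometry.shift`` is applied
    here (set ``apply_shift=False`` for pre-shifted tags). Bin ``j`` of a
    summit at ``pos`` covers ``[pos - flank + j*bin_size,
    pos - flank + (j+1)*bin_size)``; tags outside the window are ignored.
    Windows overhanging the chromosome start are kept and count whatever
    falls in the valid part. Overlapping windows each count independently.
    """
    if not summits:
        raise GeometryError("no summits supplied")
    if apply_shift:
        tags = shift_tags(tags, geometry.shift)

    by_chrom: dict[str, np.ndarray] = {}
    positions = defaultdict(list)
    for t in tags:
        positions[t.chrom].append(t.five_prime)
    for chrom, pos in positions.items():
        by_chrom[chrom] = np.sort(np.asarray(pos, dtype=np.int64))

    width = 2 * geometry.flank
    values = np.zeros((len(summits), geometry.n_bins), dtype=float)
    for i, summit in enumerate(summits):
        pos = by_chrom.get(summit.chrom)
        if pos is None:
            continue
        w_start = summit.pos - geometry.flank  # may be negative near chrom start
        lo = np.searchsorted(pos, w_start, side="left")
        hi = np.searchsorted(pos, w_start + width, side="left")
        if hi > lo:
            bins = (pos[lo:hi] - w_start) // geometry.bin_size
            values[i] = np.bincount(bins, minlength=geometry.n_bins)
    return SignalMatrix(track, list(summits), values, geometry)


def clip_normalize(matrix: SignalMatrix, q: float = 0.999) -> SignalMatrix:
    """Clip at the q-quantile of all entries and divide by it.

    The quantile uses linear interpolation between order statistics (the
    numpy default). The result lies in [0, 1] with maximum exactly 1 for
    any matrix containing an entry at or above the clip value. An all-zero
    matrix is an error: the track has no signal to normalize by.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("quantile must lie in (0, 1]")
    if matrix.values.size == 0:
        raise GeometryError("empty matrix")
    clip_value = float(np.quantile(matrix.values, q))
    if clip_value <= 0.0:
        raise ValueError(f"track {matrix.track!r} has no signal")
    values = np.minimum(matrix.values, clip_value) / clip_value
    return replace(matrix, values=values, clip_value=clip_value)


def concat_tracks(
    matrices: Sequence[SignalMatrix], exclude: Iterable[str] = ()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate per-track matrices horizontally, dropping excluded tracks.

    All matrices must share peak list and geometry. Returns the combined
    matrix and a column map recording (track, bin index) per column.
    """
    exclude = set(exclude)
    kept = [m for m in matrices if m.track not in exclude]
    if not kept:
        raise ValueError("no tracks remain after exclusion")
    ref = kept[0]
    for m in kept[1:]:
        if m.summits != ref.summits:
            raise ValueError(
                f"peak lists differ between tracks {ref.track!r} and {m.track!r}"
            )
        # the 5' shift may differ per track (accessibility tracks are
        # unshifted); only the window/bin geometry must agree
        if (m.geometry.flank, m.geometry.bin_size) != (
            ref.geometry.flank, ref.geometry.bin_size,
        ):
            raise ValueError("matrix geometries differ between tracks")
    combined = np.hstack([m.values for m in kept])
    column_map = pd.DataFrame(
        [
            {"column": col, "track": m.track, "bin": j}
            for col, (m, j) in enumerate(
                (m, j) for m in kept for j in range(m.geometry.n_bins)
            )
        ]
    )
    return combined, column_map
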