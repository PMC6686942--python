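"""Sex-chromosome identification from female vs male sequencing depth.

An X-linked scaffold is present in two copies in XX females but one in
XO males, so after library-size normalization its female:male depth
ratio sits near 2 (log2 ratio near 1) while autosomes sit near 1 (log2
near 0). This module computes windowed depth for each sample, normalizes
each track by its own median window value (robust to the X being a
minority of windows), forms the per-window log2(F/M) ratio track, and
calls each scaffold X-linked / autosomal / ambiguous from the median of
its unmasked window ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import pysam

from .windows import WindowGrid, make_windows

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import ReadPlacementSet

__all__ = [
    "CoverageTrack",
    "RatioTrack",
    "make_windows",
    "coverage_from_alignments",
    "coverage_from_placements",
    "coverage_from_bedgraph",
    "normalize_pair",
    "ratio_track",
    "call_scaffolds",
    "ratio_table",
]

X_LINKED = "X-linked"
AUTOSOMAL = "autosomal"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CoverageTrack:
    """Per-window mean depth (attributed bases / window length) for one sample.

    ``scale`` is the multiplier that restores raw depth after
    normalization (``raw = values * scale``); it is 1.0 for raw tracks.
    """

    grid: WindowGrid
    values: np.ndarray
    sample_label: str
    library_size: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.values) != self.grid.n_windows:
            raise ValueError("values length does not match grid")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be >= 0")

    @property
    def raw_values(self) -> np.ndarray:
        return self.values * self.scale


@dataclass(frozen=True)
class RatioTrack:
    """Per-window log2(normalized female depth / normalized male depth).

    Masked windows (either sample under the raw-depth floor, or zero
    depth) carry NaN in ``log2_ratio``; unmasked entries are finite.
    """

    grid: WindowGrid
    log2_ratio: np.ndarray
    masked: np.ndarray


# ---------------------------------------------------------------------------
# Coverage computation

def _attribute_interval(
    bases: np.ndarray, grid: WindowGrid, scaffold: str, start: int, end: int
) -> int:
    """Distribute an aligned reference interval across windows pro rata.

    Returns the number of bases attributed.
    """
    ws = grid.window_size
    offset = grid.offset(scaffold)
    end = min(end, grid.scaffold_lengths[scaffold])
    total = 0
    pos = start
    while pos < end:
        widx = pos // ws
        wend = min((widx + 1) * ws, end)
        bases[offset + widx] += wend - pos
        total += wend - pos
        pos = wend
    return total


def coverage_from_alignments(
    alignments: str | Path | pysam.AlignmentFile,
    grid: WindowGrid,
    min_mapq: int = 0,
    sample_label: str | None = None,
) -> CoverageTrack:
    """Windowed mean depth from SAM/BAM alignments.

    Every aligned reference base of every mapped record with
    ``MAPQ >= min_mapq`` is attributed to the window containing it; reads
    spanning a window boundary contribute to both windows pro rata by
    overlap, so total attributed bases equal total aligned bases exactly.
    Unmapped and sub-``min_mapq`` records are skipped.
    """
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    label = sample_label or (str(alignments) if own else "alignments")
    bases = np.zeros(grid.n_windows, dtype=np.float64)
    n_used = 0
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            name = read.reference_name
            if name not in grid:
                raise ValueError(f"alignment to unknown scaffold {name!r}")
            for bstart, bend in read.get_blocks():
                _attribute_interval(bases, grid, name, bstart, bend)
            n_used += 1
    finally:
        if own:
            af.close()
    if n_used == 0:
        warnings.warn(f"no usable alignments in {label}; coverage track is all zero")
    return CoverageTrack(
        grid=grid,
        values=bases / grid.window_lengths(),
        sample_label=label,
        library_size=float(bases.sum()),
    )


def coverage_from_placements(reads: "ReadPlacementSet", grid: WindowGrid) -> CoverageTrack:
    """Windowed mean depth directly from simulated read placements.

    Same base-attribution rule as :func:`coverage_from_alignments`
    (pro-rata split at window boundaries), vectorized for millions of
    placements.
    """
    ws = grid.window_size
    rl = reads.read_length
    bases = np.zeros(grid.n_windows, dtype=np.float64)
    for scaffold, starts in reads.starts.items():
        if scaffold not in grid:
            raise ValueError(f"placements on unknown scaffold {scaffold!r}")
        if len(starts) == 0:
            continue
        starts = np.asarray(starts, dtype=np.int64)
        length = grid.scaffold_lengths[scaffold]
        ends = np.minimum(starts + rl, length)
        if rl <= ws:
            offset = grid.offset(scaffold)
            w1 = starts // ws
            w2 = (ends - 1) // ws
            same = w1 == w2
            np.add.at(bases, offset + w1[same], (ends - starts)[same])
            if not same.all():
                cut = w2[~same] * ws
                np.add.at(bases, offset + w1[~same], cut - starts[~same])
                np.add.at(bases, offset + w2[~same], ends[~same] - cut)
        else:  # reads longer than a window: general per-read split
            for s, e in zip(starts, ends):
                _attribute_interval(bases, grid, scaffold, int(s), int(e))
    return CoverageTrack(
        grid=grid,
        values=bases / grid.window_lengths(),
        sample_label=reads.sample_sex,
        library_size=float(bases.sum()),
    )


def coverage_from_bedgraph(
    track: str | Path, grid: WindowGrid, sample_label: str | None = None
) -> CoverageTrack:
    """Windowed mean depth from a BEDGRAPH depth track.

    Window value is the length-weighted mean of interval depths
    overlapping the window; positions covered by no interval count as
    depth 0. Overlapping intervals on a scaffold are rejected.
    """
    df = pd.read_csv(
        track, sep="\t", comment="#",
        names=["scaffold", "start", "end", "depth"],
        dtype={"scaffold": str, "start": np.int64, "end": np.int64, "depth": float},
    )
    bases = np.zeros(grid.n_windows, dtype=np.float64)
    for scaffold, sub in df.groupby("scaffold", sort=False):
        if scaffold not in grid:
            raise ValueError(f"BEDGRAPH interval on unknown scaffold {scaffold!r}")
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping BEDGRAPH intervals on scaffold {scaffold!r}")
        ws = grid.window_size
        offset = grid.offset(scaffold)
        for start, end, depth in zip(sub["start"], sub["end"], sub["depth"]):
            pos = int(start)
            end = int(min(end, grid.scaffold_lengths[scaffold]))
            while pos < end:
                widx = pos // ws
                wend = min((widx + 1) * ws, end)
                bases[offset + widx] += depth * (wend - pos)
                pos = wend
    return CoverageTrack(
        grid=grid,
        values=bases / grid.window_lengths(),
        sample_label=sample_label or str(track),
        library_size=float(bases.sum()),
    )


# ---------------------------------------------------------------------------
# Normalization, ratio, calling

def _median_scale(track: CoverageTrack) -> float:
    values = track.values
    if not np.any(values > 0):
        raise ValueError(f"cannot normalize all-zero track {track.sample_label!r}")
    med = float(np.median(values))
    if med == 0.0:  # more than half the windows empty: fall back to covered windows
        med = float(np.median(values[values > 0]))
    return med


def normalize_pair(female: CoverageTrack, male: CoverageTrack) -> tuple[CoverageTrack, CoverageTrack]:
    """Scale each track by its own median window value.

    After normalization each sample's median window value is 1, making
    the two samples comparable regardless of library size: scaling either
    input's raw depths by any positive constant leaves its output
    unchanged. The median (not the mean) is used because X windows are a
    minority and should not drag the autosomal baseline.
    """
    if female.grid != male.grid:
        raise ValueError("female and male tracks use different window grids")
    out = []
    for track in (female, male):
        med = _median_scale(track)
        out.append(
            replace(track, values=track.values / med, scale=track.scale * med)
        )
    return out[0], out[1]


def ratio_track(
    female_norm: CoverageTrack,
    male_norm: CoverageTrack,
    min_depth: float = 1.0,
) -> RatioTrack:
    """Per-window log2(F/M) of normalized depths, with low-depth masking.

    Windows where either sample's *raw* mean depth is below ``min_depth``
    (or zero, which would make the log undefined) are masked rather than
    reported; degenerate windows are never fatal.
    """
    if female_norm.grid != male_norm.grid:
        raise ValueError("tracks use different window grids")
    f, m = female_norm.values, male_norm.values
    masked = (
        (female_norm.raw_values < min_depth)
        | (male_norm.raw_values < min_depth)
        | (f == 0)
        | (m == 0)
    )
    log2 = np.full(len(f), np.nan)
    ok = ~masked
    # as a difference of logs so that swapping samples negates it bit-exactly
    log2[ok] = np.log2(f[ok]) - np.log2(m[ok])
    return RatioTrack(grid=female_norm.grid, log2_ratio=log2, masked=masked)


def call_scaffolds(
    ratio: RatioTrack,
    x_band: tuple[float, float] = (0.6, 1.4),
    autosome_band: tuple[float, float] = (-0.4, 0.4),
    min_unmasked_fraction: float = 0.5,
) -> pd.DataFrame:
    """Classify each scaffold as X-linked, autosomal or ambiguous.

    The per-scaffold statistic is the median of its unmasked log2(F/M)
    windows (numpy median: midpoint of the two central values for even
    counts). X-linked if the median falls in ``x_band`` (default
    [0.6, 1.4], centered on the twofold-ratio expectation log2(2) = 1);
    autosomal if in ``autosome_band`` (default [-0.4, 0.4]); otherwise —
    or when fewer than ``min_unmasked_fraction`` of the scaffold's
    windows are unmasked — ambiguous.

    Returns a table with one row per grid scaffold: ``scaffold``,
    ``length``, ``n_windows``, ``n_unmasked``, ``median_log2_ratio``
    (NaN when no unmasked window), ``call``.
    """
    lo_x, hi_x = x_band
    if not lo_x < hi_x:
        raise ValueError(f"x_band low must be < high, got {x_band}")
    rows = []
    for scaffold in ratio.grid.scaffolds:
        sl = ratio.grid.scaffold_slice(scaffold)
        vals = ratio.log2_ratio[sl]
        unmasked = vals[~ratio.masked[sl]]
        n, n_ok = len(vals), len(unmasked)
        if n_ok == 0:
            med, call = math.nan, AMBIGUOUS
        else:
            med = float(np.median(unmasked))
            if n_ok / n < min_unmasked_fraction:
                call = AMBIGUOUS
            elif lo_x <= med <= hi_x:
                call = X_LINKED
            elif autosome_band[0] <= med <= autosome_band[1]:
                call = AUTOSOMAL
            else:
                call = AMBIGUOUS
        rows.append(
            {
                "scaffold": scaffold,
                "length": ratio.grid.scaffold_lengths[scaffold],
                "n_windows": n,
                "n_unmasked": n_ok,
                "median_log2_ratio": med,
                "call": call,
            }
        )
    return pd.DataFrame(rows)


def ratio_table(
    female: CoverageTrack, male: CoverageTrack, ratio: RatioTrack
) -> pd.DataFrame:
    """Per-window TSV-ready table: depths, log2 ratio and mask flag."""
    grid = ratio.grid
    return pd.DataFrame(
        {
            "scaffold": grid.window_scaffold_names(),
            "start": grid.window_starts(),
            "end": grid.window_ends(),
            "depth_f": female.raw_values,
            "depth_m": male.raw_values,
            "log2_ratio": ratio.log2_ratio,
            "masked": ratio.masked.astype(int),
        }
    )
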