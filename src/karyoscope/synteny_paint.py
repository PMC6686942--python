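"""Macrosynteny chromosome painting against a reference karyotype.

Each fixed window (default 500 kb) of the focal genome is "painted" by
the fractions of its one-to-one orthologs whose partners lie on each
reference chromosome; windows with no orthologs are flagged no-synteny.
Per-window dominant labels are then aggregated into per-scaffold
homology spans, and a scaffold whose spans attribute multi-megabase
regions to two or more reference chromosomes carries a fusion/
translocation signature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .windows import WindowGrid

__all__ = [
    "REFERENCE_ORDER",
    "NO_LABEL",
    "OrthologTable",
    "PaintingMatrix",
    "load_orthologs",
    "paint",
    "window_dominant_labels",
    "summarize_homology",
    "estimate_breakpoints",
]

#: Canonical reference-chromosome display and tie-break order
#: (the C. elegans karyotype); labels outside this list sort after it.
REFERENCE_ORDER = ("I", "II", "III", "IV", "V", "X")

NO_LABEL = "none"

_COLUMNS = ["focal_gene", "focal_scaffold", "focal_start", "ref_gene", "ref_chromosome"]


def _ordered_labels(labels: set[str]) -> tuple[str, ...]:
    canonical = [l for l in REFERENCE_ORDER if l in labels]
    extra = sorted(l for l in labels if l not in REFERENCE_ORDER)
    return tuple(canonical + extra)


@dataclass(frozen=True)
class OrthologTable:
    """Validated one-to-one ortholog pairs with an ordered label set."""

    pairs: pd.DataFrame
    reference_chromosomes: tuple[str, ...]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologTable":
        for col, ids in (("focal_gene", frame["focal_gene"]), ("ref_gene", frame["ref_gene"])):
            dup = ids[ids.duplicated()]
            if len(dup):
                raise ValueError(
                    f"duplicate {col} {dup.iloc[0]!r} violates the one-to-one invariant"
                )
        return cls(
            pairs=frame.reset_index(drop=True),
            reference_chromosomes=_ordered_labels(set(frame["ref_chromosome"])),
        )

    @classmethod
    def from_pairs(cls, pairs: Sequence) -> "OrthologTable":
        from .synthetic_data import orthologs_to_frame

        return cls.from_frame(orthologs_to_frame(pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PaintingMatrix:
    """Per-window ortholog counts and fractions per reference chromosome.

    ``counts`` is (n_windows, n_labels); ``fractions`` rows sum to 1 for
    windows with at least one ortholog and are NaN for no-synteny
    windows (``no_synteny`` is exactly ``totals == 0``).
    """

    grid: WindowGrid
    labels: tuple[str, ...]
    counts: np.ndarray
    totals: np.ndarray
    fractions: np.ndarray
    no_synteny: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "scaffold": self.grid.window_scaffold_names(),
                "window_start": self.grid.window_starts(),
                "window_end": self.grid.window_ends(),
                "total": self.totals,
            }
        )
        for j, label in enumerate(self.labels):
            df[f"frac_{label}"] = self.fractions[:, j]
        df["no_synteny"] = self.no_synteny.astype(int)
        return df


# ---------------------------------------------------------------------------
# Loading

def load_orthologs(
    path: str | Path, scaffold_lengths: Mapping[str, int] | None = None
) -> OrthologTable:
    """Read and validate a five-column ortholog TSV.

    Expected header: ``focal_gene focal_scaffold focal_start ref_gene
    ref_chromosome``. Malformed rows are reported with their line number;
    duplicate gene ids (either side) and, when ``scaffold_lengths`` is
    given, out-of-bounds positions or unknown scaffolds are rejected.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty ortholog table") from None
        if header != _COLUMNS:
            raise ValueError(
                f"{path}: expected columns {_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            try:
                start = int(row[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: focal_start {row[2]!r} is not an integer"
                ) from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative focal_start {start}")
            rows.append((row[0], row[1], start, row[3], row[4]))
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    if scaffold_lengths is not None:
        for r in frame.itertuples():
            if r.focal_scaffold not in scaffold_lengths:
                raise ValueError(
                    f"{path}: ortholog {r.focal_gene!r} on unknown scaffold "
                    f"{r.focal_scaffold!r}"
                )
            if r.focal_start >= scaffold_lengths[r.focal_scaffold]:
                raise ValueError(
                    f"{path}: ortholog {r.focal_gene!r} position {r.focal_start} "
                    f"beyond scaffold {r.focal_scaffold!r} length "
                    f"{scaffold_lengths[r.focal_scaffold]}"
                )
    return OrthologTable.from_frame(frame)


# ---------------------------------------------------------------------------
# Painting

def paint(table: OrthologTable, grid: WindowGrid) -> PaintingMatrix:
    """Tally orthologs per window per reference chromosome.

    Each pair is assigned to the window containing its focal gene start;
    per-window fractions are counts over the window's ortholog total.
    Windows with zero orthologs are flagged ``no_synteny`` (rendered red
    in the classic painting figure). The result is invariant to input
    row order.
    """
    labels = table.reference_chromosomes
    label_idx = {l: j for j, l in enumerate(labels)}
    counts = np.zeros((grid.n_windows, len(labels)), dtype=np.int64)
    for r in table.pairs.itertuples():
        if r.focal_scaffold not in grid:
            raise ValueError(f"ortholog on scaffold {r.focal_scaffold!r} not in grid")
        w = grid.window_index(r.focal_scaffold, int(r.focal_start))
        counts[w, label_idx[r.ref_chromosome]] += 1
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals[:, None] > 0, counts / totals[:, None], np.nan)
    return PaintingMatrix(
        grid=grid,
        labels=labels,
        counts=counts,
        totals=totals,
        fractions=fractions,
        no_synteny=totals == 0,
    )


# ---------------------------------------------------------------------------
# Homology summary / fusion detection

def window_dominant_labels(
    matrix: PaintingMatrix, min_window_fraction: float = 0.5
) -> np.ndarray:
    """Per-window dominant reference chromosome.

    The dominant label is the argmax fraction among labels reaching
    ``min_window_fraction``; ties break by the declared label order
    (:data:`REFERENCE_ORDER` first). No-synteny windows and windows where
    no label qualifies report ``"none"``.
    """
    out = np.full(matrix.grid.n_windows, NO_LABEL, dtype=object)
    if not matrix.labels:
        return out
    ok = ~matrix.no_synteny
    if not ok.any():
        return out
    frac = matrix.fractions[ok]
    best = np.argmax(frac, axis=1)  # first max wins: declared-order tie-break
    best_frac = frac[np.arange(len(frac)), best]
    labels = np.asarray(matrix.labels, dtype=object)
    chosen = np.where(best_frac >= min_window_fraction, labels[best], NO_LABEL)
    out[ok] = chosen
    return out


def summarize_homology(
    matrix: PaintingMatrix,
    min_span_bp: int = 1_000_000,
    min_window_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-scaffold homology spans and fusion flags.

    For each scaffold, the bp span of each reference chromosome is the
    total length of windows where it is the dominant label; the
    scaffold's dominant chromosome is the one with the maximal span
    (``"none"`` when every window lacks synteny). ``fusion_flag`` is set
    when at least two reference chromosomes each span
    ``min_span_bp`` or more — the signature of a chromosome fusion or
    translocation relative to the reference karyotype.

    Returns one row per scaffold with columns ``scaffold``,
    ``dominant_ref``, ``fusion_flag``, ``refs_over_threshold``
    (comma-joined) and ``span_<label>`` for every label.
    """
    if min_span_bp < 0:
        raise ValueError("min_span_bp must be >= 0")
    dominant = window_dominant_labels(matrix, min_window_fraction)
    wlens = matrix.grid.window_lengths()
    labels = matrix.labels
    rows = []
    for scaffold in matrix.grid.scaffolds:
        sl = matrix.grid.scaffold_slice(scaffold)
        spans = {
            label: int(wlens[sl][dominant[sl] == label].sum()) for label in labels
        }
        over = [l for l in labels if spans[l] >= min_span_bp]
        if spans and max(spans.values()) > 0:
            dom = max(labels, key=lambda l: spans[l])  # declared-order tie-break
        else:
            dom = NO_LABEL
        row = {
            "scaffold": scaffold,
            "dominant_ref": dom,
            "fusion_flag": len(over) >= 2,
            "refs_over_threshold": ",".join(over),
        }
        row.update({f"span_{l}": spans[l] for l in labels})
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_breakpoints(
    matrix: PaintingMatrix, min_window_fraction: float = 0.5
) -> list[tuple[str, int, str, str]]:
    """Boundaries where the dominant label changes along a scaffold.

    Windows with dominant ``"none"`` are skipped, so a breakpoint between
    two informative windows separated by empty ones is placed at the
    start of the later informative window. Returns
    ``(scaffold, position, left_label, right_label)`` tuples.
    """
    dominant = window_dominant_labels(matrix, min_window_fraction)
    starts = matrix.grid.window_starts()
    out = []
    for scaffold in matrix.grid.scaffolds:
        sl = matrix.grid.scaffold_slice(scaffold)
        labs = dominant[sl]
        pos = starts[sl]
        informative = [(p, l) for p, l in zip(pos, labs) if l != NO_LABEL]
        for (_, l1), (p2, l2) in zip(informative, informative[1:]):
            if l1 != l2:
                out.append((scaffold, int(p2), l1, l2))
    return out
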