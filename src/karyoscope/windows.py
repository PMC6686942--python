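"""Fixed-width window grids over genome scaffolds.

All internal coordinates are 0-based half-open ``[start, end)``. A
:class:`WindowGrid` tiles each scaffold with contiguous, non-overlapping
windows of a fixed size; the final window of a scaffold is truncated at
the scaffold end, so the concatenation of windows tiles each scaffold
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["WindowGrid", "make_windows"]


@dataclass(frozen=True)
class WindowGrid:
    """Tiling of a set of scaffolds into fixed windows.

    Parameters
    ----------
    scaffold_lengths
        Ordered mapping of scaffold name to length in bp. The iteration
        order defines the global window order.
    window_size
        Window width in bp (default 100 kb, the width used for coverage,
        gene-density and repeat-density tracks).
    """

    scaffold_lengths: Mapping[str, int]
    window_size: int = 100_000
    _offsets: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError(f"window_size must be >= 1, got {self.window_size}")
        offsets: dict[str, int] = {}
        total = 0
        for name, length in self.scaffold_lengths.items():
            if length < 1:
                raise ValueError(f"scaffold {name!r} has non-positive length {length}")
            offsets[name] = total
            total += self.n_windows_of(name)
        object.__setattr__(self, "_offsets", offsets)

    # -- structure ---------------------------------------------------------

    @property
    def scaffolds(self) -> list[str]:
        return list(self.scaffold_lengths)

    def n_windows_of(self, scaffold: str) -> int:
        length = self.scaffold_lengths[scaffold]
        return -(-length // self.window_size)  # ceil division

    @property
    def n_windows(self) -> int:
        return sum(self.n_windows_of(s) for s in self.scaffold_lengths)

    def offset(self, scaffold: str) -> int:
        """Global index of the scaffold's first window."""
        return self._offsets[scaffold]

    def scaffold_slice(self, scaffold: str) -> slice:
        """Slice selecting the scaffold's windows in any per-window array."""
        start = self.offset(scaffold)
        return slice(start, start + self.n_windows_of(scaffold))

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.scaffold_lengths

    # -- coordinates -------------------------------------------------------

    def window_index(self, scaffold: str, pos: int) -> int:
        """Global index of the window containing position ``pos`` (0-based)."""
        length = self.scaffold_lengths[scaffold]
        if not 0 <= pos < length:
            raise ValueError(
                f"position {pos} outside scaffold {scaffold!r} [0, {length})"
            )
        return self.offset(scaffold) + pos // self.window_size

    def windows(self) -> Iterator[tuple[str, int, int]]:
        """Yield ``(scaffold, start, end)`` for every window, in order."""
        for name, length in self.scaffold_lengths.items():
            for start in range(0, length, self.window_size):
                yield name, start, min(start + self.window_size, length)

    def window_lengths(self) -> np.ndarray:
        """Per-window lengths in bp (last window per scaffold may be short)."""
        out = np.full(self.n_windows, self.window_size, dtype=np.int64)
        for name, length in self.scaffold_lengths.items():
            rem = length % self.window_size
            if rem:
                out[self.offset(name) + self.n_windows_of(name) - 1] = rem
        return out

    def window_scaffold_names(self) -> np.ndarray:
        """Per-window scaffold name array, aligned with track values."""
        return np.array(
            [s for s in self.scaffold_lengths for _ in range(self.n_windows_of(s))]
        )

    def window_starts(self) -> np.ndarray:
        return np.array([w[1] for w in self.windows()], dtype=np.int64)

    def window_ends(self) -> np.ndarray:
        return np.array([w[2] for w in self.windows()], dtype=np.int64)


def make_windows(scaffold_lengths: Mapping[str, int], window_size: int = 100_000) -> WindowGrid:
    """Tile scaffolds into fixed windows.

    Per scaffold, ``ceil(length / window_size)`` windows are produced and
    their concatenation exactly tiles the scaffold; the last window may be
    shorter than ``window_size``.

    Raises
    ------
    ValueError
        If ``window_size`` or any scaffold length is not positive.
    """
    if not scaffold_lengths:
        raise ValueError("scaffold_lengths is empty")
    return WindowGrid(dict(scaffold_lengths), window_size)
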