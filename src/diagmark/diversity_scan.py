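"""Sliding-window nucleotide diversity and divergence-hotspot calling.

Nucleotide diversity (pi) is the mean proportion of pairwise differences per
usable site. A usable column carries an unambiguous base (A/C/G/T) in every
sequence; gapped or ambiguous columns count toward window span but not toward
pi, so reported coordinates stay in alignment space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import BASES, Alignment

logger = logging.getLogger(__name__)

#: Returned by :func:`nucleotide_diversity` when no usable column exists.
UNDEFINED_PI = float("nan")


@dataclass(frozen=True)
class WindowDiversity:
    """Diversity of one sliding window (1-based inclusive columns)."""

    start: int
    end: int
    usable_sites: int
    pi: float


@dataclass(frozen=True)
class HotspotRegion:
    """Merged run of above-threshold windows."""

    start: int
    end: int
    max_pi: float
    window_count: int


def _encode(alignment: Alignment) -> np.ndarray:
    """Byte matrix (n_sequences x length) of the alignment."""
    return np.frombuffer(
        "".join(alignment.sequences).encode("ascii"), dtype="S1"
    ).reshape(alignment.n_sequences, alignment.length)


def _usable_mask(mat: np.ndarray) -> np.ndarray:
    ok = np.zeros(mat.shape, dtype=bool)
    for b in BASES:
        ok |= mat == b.encode()
    return ok.all(axis=0)


def nucleotide_diversity(alignment: Alignment, columns: Iterable[int] | None = None) -> float:
    """Per-site nucleotide diversity over the given 1-based columns.

    pi = mean over usable columns of (pairwise mismatches / C(n, 2)).
    Returns NaN when no column is usable.
    """
    n = alignment.n_sequences
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    mat = _encode(alignment)
    if columns is not None:
        idx = np.asarray(sorted(set(columns)), dtype=int) - 1
        if idx.size and (idx.min() < 0 or idx.max() >= alignment.length):
            raise IndexError("column selection outside alignment bounds")
        mat = mat[:, idx]
    mat = mat[:, _usable_mask(mat)]
    if mat.shape[1] == 0:
        return UNDEFINED_PI

    pairs = comb(n, 2)
    mismatches = 0
    for i in range(n - 1):
        mismatches += (mat[i + 1:] != mat[i]).sum()
    return float(mismatches) / (pairs * mat.shape[1])


def sliding_window_pi(alignment: Alignment, window: int = 600, step: int = 200) -> list[WindowDiversity]:
    """Diversity in full-length windows starting at columns 1, 1+step, ...

    Trailing partial windows are dropped so every pi value averages over the
    same span.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if window > alignment.length:
        raise ValueError(f"window {window} exceeds alignment length {alignment.length}")

    mat = _encode(alignment)
    usable = _usable_mask(mat)
    n = alignment.n_sequences
    pairs = comb(n, 2)

    # per-column pairwise mismatch counts, computed once
    col_mismatch = np.zeros(alignment.length, dtype=np.int64)
    for i in range(n - 1):
        col_mismatch += (mat[i + 1:] != mat[i]).sum(axis=0)
    col_pi = np.where(usable, col_mismatch / pairs, 0.0)

    out: list[WindowDiversity] = []
    start = 1
    while start + window - 1 <= alignment.length:
        sl = slice(start - 1, start - 1 + window)
        n_usable = int(usable[sl].sum())
        pi = float(col_pi[sl].sum() / n_usable) if n_usable else UNDEFINED_PI
        out.append(WindowDiversity(start=start, end=start + window - 1,
                                   usable_sites=n_usable, pi=pi))
        start += step
    return out


def call_hotspots(windows: Sequence[WindowDiversity], threshold: float = 0.05) -> list[HotspotRegion]:
    """Merge overlapping/book-ended windows with pi strictly above threshold.

    Windows with undefined pi are skipped with a warning.
    """
    selected = []
    for w in windows:
        if np.isnan(w.pi):
            logger.warning("window %d-%d has no usable site; excluded from hotspot calling",
                           w.start, w.end)
            continue
        if w.pi > threshold:
            selected.append(w)
    selected.sort(key=lambda w: w.start)

    regions: list[HotspotRegion] = []
    for w in selected:
        if regions and w.start <= regions[-1].end + 1:
            last = regions[-1]
            regions[-1] = HotspotRegion(
                start=last.start,
                end=max(last.end, w.end),
                max_pi=max(last.max_pi, w.pi),
                window_count=last.window_count + 1,
            )
        else:
            regions.append(HotspotRegion(start=w.start, end=w.end,
                                         max_pi=w.pi, window_count=1))
    return regions


def write_windows(windows: Sequence[WindowDiversity], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tusable_sites\tpi\n")
        for w in windows:
            pi = "NA" if np.isnan(w.pi) else f"{w.pi:.6f}"
            fh.write(f"{w.start}\t{w.end}\t{w.usable_sites}\t{pi}\n")


def write_hotspots(regions: Sequence[HotspotRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tmax_pi\twindow_count\n")
        for r in regions:
            fh.write(f"{r.start}\t{r.end}\t{r.max_pi:.6f}\t{r.window_count}\n")
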