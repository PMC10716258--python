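"""Observed/expected pileups and average signal enrichment around loops.

The expected model is the classic cis distance-decay track: for each
chromosome, the mean contact count over all bin pairs at a given diagonal
offset.  A candidate loop's 5 kb bin is extended by 10 bins (50 kb) in all
directions, giving a 21 x 21 observed/expected matrix; the enrichment
statistic compares the 3 x 3 centre block with five 3 x 3 background blocks
(upper-left, upper-middle, upper-right, middle-right, lower-right).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .calling import DEFAULT_BIN_SIZE, LoopBin

WINDOW_RADIUS = 10          # bins on each side of the loop bin
WINDOW = 2 * WINDOW_RADIUS + 1  # 21 rows and columns

#: Distinguished value for a pileup whose background block mean is zero
#: ("infinite" enrichment); excluded from aggregates.
EXCLUDED = math.inf

# 1-based inclusive block coordinates of the enrichment statistic, exactly
# as conventionally printed; pinned by unit tests.
_CENTER_BLOCK = (slice(9, 12), slice(9, 12))        # rows/cols 10-12
_BACKGROUND_BLOCKS = (
    (slice(0, 3), slice(0, 3)),      # upper left    1-3  x 1-3
    (slice(0, 3), slice(9, 12)),     # upper middle  1-3  x 10-12
    (slice(0, 3), slice(18, 21)),    # upper right   1-3  x 19-21
    (slice(9, 12), slice(18, 21)),   # middle right  10-12 x 19-21
    (slice(18, 21), slice(18, 21)),  # lower right   19-21 x 19-21
)


@dataclass
class ContactGrid:
    """Upper-triangle binned contact counts for one chromosome."""

    chrom: str
    n_bins: int
    bin_size: int
    counts: Counter  # (bin_x, bin_y) with bin_x <= bin_y -> count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, bx: int, by: int) -> int:
        if by < bx:
            bx, by = by, bx
        return self.counts.get((bx, by), 0)


def bin_contacts(records, chromsizes: dict,
                 bin_size: int = DEFAULT_BIN_SIZE) -> dict:
    """Bin intrachromosomal pairs into per-chromosome upper-triangle grids."""
    grids = {}
    per_chrom = defaultdict(Counter)
    for rec in records:
        if not rec.is_intra:
            continue
        bx = (rec.pos1 - 1) // bin_size
        by = (rec.pos2 - 1) // bin_size
        if by < bx:
            bx, by = by, bx
        per_chrom[rec.chrom1][(bx, by)] += 1
    for chrom, counts in per_chrom.items():
        if chrom not in chromsizes:
            raise ValueError(f"no chromosome size for {chrom!r}")
        n_bins = -(-int(chromsizes[chrom]) // bin_size)
        grids[chrom] = ContactGrid(chrom, n_bins, bin_size, counts)
    return grids


@dataclass
class ExpectedModel:
    """Mean contact count per bin pair as a function of diagonal offset."""

    chrom: str
    bin_size: int
    values: np.ndarray  # values[d] = mean count at diagonal offset d

    def at(self, offset: int) -> float:
        if 0 <= offset < len(self.values):
            return float(self.values[offset])
        return 0.0


def expected_by_distance(grid: ContactGrid) -> ExpectedModel:
    """Diagonal-mean expected track for one chromosome.

    expected(d) = (sum of counts at offset d) / (number of bin pairs at
    offset d), so summing expected(d) times the bin-pair count recovers the
    total contact count exactly.
    """
    if not grid.counts:
        raise ValueError(f"{grid.chrom}: no contacts to build an expected model")
    sums = np.zeros(grid.n_bins, dtype=float)
    for (bx, by), c in grid.counts.items():
        sums[by - bx] += c
    n_at_offset = grid.n_bins - np.arange(grid.n_bins, dtype=float)
    return ExpectedModel(grid.chrom, grid.bin_size, sums / n_at_offset)


def expected_from_records(records, chromsizes: dict,
                          bin_size: int = DEFAULT_BIN_SIZE) -> dict:
    """Per-chromosome expected models straight from a pairs stream."""
    grids = bin_contacts(records, chromsizes, bin_size)
    return {chrom: expected_by_distance(grid) for chrom, grid in grids.items()}


@dataclass
class PileupMatrix:
    """21 x 21 observed/expected ratios centred on a candidate loop."""

    loop: LoopBin
    grid: np.ndarray  # (21, 21); NaN where expected is zero

    @property
    def enrichment(self) -> float:
        return signal_enrichment(self.grid)


def pileup_at(loop: LoopBin, grid: ContactGrid,
              expected: ExpectedModel) -> PileupMatrix:
    """Observed/expected window around one loop bin.

    The window must fit inside the contact matrix and stay strictly above
    the diagonal (the loop must sit at least ``WINDOW_RADIUS`` bins from
    every matrix edge and far enough off-diagonal that no window pixel
    touches the lower triangle); otherwise the loop is excluded with a
    warning and ``None`` is returned.  Pixels whose expected value is zero
    are recorded as missing (NaN).
    """
    r = WINDOW_RADIUS
    if (loop.bin_x < r or loop.bin_y < r
            or loop.bin_x + r >= grid.n_bins or loop.bin_y + r >= grid.n_bins
            or loop.bin_y - loop.bin_x < WINDOW):
        warnings.warn(f"loop bin ({loop.bin_x}, {loop.bin_y}) too close to the "
                      "matrix edge or the diagonal; excluded from pileup")
        return None
    out = np.full((WINDOW, WINDOW), np.nan)
    for i in range(WINDOW):
        bx = loop.bin_x - r + i
        for j in range(WINDOW):
            by = loop.bin_y - r + j
            exp = expected.at(by - bx)
            if exp > 0:
                out[i, j] = grid.get(bx, by) / exp
    return PileupMatrix(loop, out)


def signal_enrichment(matrix: np.ndarray) -> float:
    """Centre-over-background enrichment of a 21 x 21 pileup.

    numerator: mean of the centre 3 x 3 block (rows/cols 10-12, 1-based);
    denominator: mean over the union of the five 3 x 3 background blocks.
    Missing pixels are dropped from the means.  A zero background mean
    yields the distinguished ``EXCLUDED`` (infinite) value.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (WINDOW, WINDOW):
        raise ValueError(f"expected a {WINDOW}x{WINDOW} matrix, got {matrix.shape}")
    center = matrix[_CENTER_BLOCK]
    background = np.concatenate([matrix[b].ravel() for b in _BACKGROUND_BLOCKS])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        num = np.nanmean(center)
        den = np.nanmean(background)
    if not np.isfinite(num) or not np.isfinite(den) or den == 0:
        return EXCLUDED
    return float(num / den)


def aggregate_enrichment(loops, grid: ContactGrid, expected: ExpectedModel):
    """Mean finite enrichment over loops and the count of finite values.

    Loops with infinite ("excluded") enrichment, and loops whose window
    does not fit, do not contribute.  Raises if nothing finite remains.
    """
    if not loops:
        raise ValueError("need at least one loop")
    finite = []
    for loop in loops:
        pile = pileup_at(loop, grid, expected)
        if pile is None:
            continue
        e = pile.enrichment
        if np.isfinite(e):
            finite.append(e)
    if not finite:
        raise ValueError("no loop had a finite signal enrichment")
    return float(np.mean(finite)), len(finite)


def mean_pileup(loops, grid: ContactGrid, expected: ExpectedModel) -> np.ndarray:
    """Pixel-wise mean of the observed/expected windows over loops."""
    stacks = [p.grid for p in (pileup_at(l, grid, expected) for l in loops)
              if p is not None]
    if not stacks:
        raise ValueError("no loop had a usable pileup window")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(stacks), axis=0)
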