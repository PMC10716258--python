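"""Synthetic read-pair generator with controlled statistical structure.

Emulates the gross statistics of a micro-C cis contact map: a distance-
dependent background whose per-locus-pair contact intensity decays as a
power law s^-alpha, optional TAD blocks with elevated within-block contact
frequency, and planted focal loops (anchor pairs with Gaussian positional
jitter).  Every planted loop's bin is recorded in a truth table so caller
recall/precision can be evaluated without external data.

Background sampling: separation s is drawn from the truncated power law on
[min_distance, L], the left read position uniformly on the chromosome, and
the pair is rejected if its right end leaves the chromosome.  Acceptance is
proportional to (L - s), so the 2D contact intensity at separation s is
proportional to s^-alpha — the field's standard meaning of a power-law
distance decay (what a P(s) curve measures) — while the realized marginal
separation distribution carries the finite-chromosome factor s^-alpha(L-s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import DEFAULT_BIN_SIZE, LoopBin
from .pairs import ContactRecord, write_pairs


@dataclass(frozen=True)
class TadSpec:
    """Interval with a within-TAD contact multiplier (>= 1 boosts)."""

    start: int  # 0-based half-open bp
    end: int
    multiplier: float = 2.0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("TAD interval must satisfy end > start")
        if self.multiplier <= 0:
            raise ValueError("TAD multiplier must be positive")


@dataclass(frozen=True)
class LoopSpec:
    """A planted focal loop: two anchors, extra pairs, positional jitter."""

    anchor1: int  # 1-based bp, anchor1 < anchor2
    anchor2: int
    n_pairs: int = 15
    jitter_sd: float = 500.0

    def __post_init__(self):
        if self.anchor1 >= self.anchor2:
            raise ValueError("loop anchors must satisfy anchor1 < anchor2")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if self.n_pairs < 0:
            raise ValueError("loop pair count must be >= 0")


@dataclass(frozen=True)
class SimSpec:
    chrom: str = "chrS"
    length: int = 50_000_000
    n_pairs: int = 50_000
    alpha: float = 1.0
    tads: tuple = ()
    loops: tuple = ()
    seed: int = 0
    min_distance: int = 1_000  # sampling floor, mirrors the caller default

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("decay exponent alpha must be > 0")
        if self.length <= self.min_distance:
            raise ValueError("chromosome shorter than the distance floor")
        for loop in self.loops:
            if loop.anchor2 > self.length or loop.anchor1 < 1:
                raise ValueError(f"loop anchors {loop.anchor1}-{loop.anchor2} "
                                 "outside the chromosome")
        for tad in self.tads:
            if tad.end > self.length:
                raise ValueError("TAD outside the chromosome")


@dataclass
class SimResult:
    spec: SimSpec
    records: list
    truth: list  # planted loops as LoopBin entries
    pairs_path: str = None
    truth_path: str = None


def _power_law_distances(rng, n, dmin, dmax, alpha):
    """Inverse-CDF sample of the truncated power law s^-alpha on [dmin, dmax]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        s = dmin * (dmax / dmin) ** u
    else:
        a = 1.0 - alpha
        s = (dmin ** a + u * (dmax ** a - dmin ** a)) ** (1.0 / a)
    return np.minimum(np.floor(s).astype(np.int64), dmax - 1)


def _tad_weights(pos1, pos2, tads):
    w = np.ones(len(pos1))
    for tad in tads:
        inside = ((pos1 - 1 >= tad.start) & (pos1 - 1 < tad.end)
                  & (pos2 - 1 >= tad.start) & (pos2 - 1 < tad.end))
        w = np.where(inside, np.maximum(w, tad.multiplier), w)
    return w


def sample_background(spec: SimSpec, n: int, rng) -> tuple:
    """Draw n background pairs; returns (pos1, pos2) 1-based int arrays."""
    L = spec.length
    w_max = max([1.0] + [t.multiplier for t in spec.tads])
    out1 = np.empty(0, dtype=np.int64)
    out2 = np.empty(0, dtype=np.int64)
    while len(out1) < n:
        m = int(1.5 * (n - len(out1))) + 64
        s = _power_law_distances(rng, m, spec.min_distance, L, spec.alpha)
        p1 = rng.integers(1, L + 1, size=m)
        p2 = p1 + s
        keep = p2 <= L  # both read ends on the chromosome
        if spec.tads:
            w = _tad_weights(p1, p2, spec.tads)
            keep &= rng.random(m) < w / w_max
        else:
            keep &= np.ones(m, dtype=bool)
        out1 = np.concatenate([out1, p1[keep]])
        out2 = np.concatenate([out2, p2[keep]])
    return out1[:n], out2[:n]


def _loop_pairs(spec: SimSpec, rng):
    pos1, pos2 = [], []
    for loop in spec.loops:
        j1 = np.rint(rng.normal(0.0, loop.jitter_sd, loop.n_pairs)).astype(np.int64)
        j2 = np.rint(rng.normal(0.0, loop.jitter_sd, loop.n_pairs)).astype(np.int64)
        p1 = np.clip(loop.anchor1 + j1, 1, spec.length)
        p2 = np.clip(loop.anchor2 + j2, 1, spec.length)
        lo = np.minimum(p1, p2)
        hi = np.maximum(p1, p2)
        pos1.append(lo)
        pos2.append(hi)
    if not pos1:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(pos1), np.concatenate(pos2)


def truth_bins(spec: SimSpec, bin_size: int = DEFAULT_BIN_SIZE):
    """Planted loops on the 0-anchored bin grid shared with the caller."""
    out = []
    for loop in spec.loops:
        bx = (loop.anchor1 - 1) // bin_size
        by = (loop.anchor2 - 1) // bin_size
        if by < bx:
            bx, by = by, bx
        out.append(LoopBin(spec.chrom, spec.chrom, int(bx), int(by),
                           loop.n_pairs, float("nan"), bin_size))
    return out


def simulate_pairs(spec: SimSpec, pairs_path=None, truth_path=None,
                   bgzf: bool = False, bin_size: int = DEFAULT_BIN_SIZE) -> SimResult:
    """Generate a sorted, upper-triangle-normalized synthetic pairs dataset.

    Identical spec and seed give byte-identical output files.  The record
    count is exactly n_pairs plus the planted loops' extra pair counts.
    """
    rng = np.random.default_rng(spec.seed)
    b1, b2 = sample_background(spec, spec.n_pairs, rng)
    l1, l2 = _loop_pairs(spec, rng)
    pos1 = np.concatenate([b1, l1])
    pos2 = np.concatenate([b2, l2])
    strand1 = np.where(rng.random(len(pos1)) < 0.5, "+", "-")
    strand2 = np.where(rng.random(len(pos1)) < 0.5, "+", "-")
    order = np.lexsort((pos2, pos1))
    records = [ContactRecord(f"sim{i}", spec.chrom, int(pos1[k]), spec.chrom,
                             int(pos2[k]), str(strand1[k]), str(strand2[k]))
               for i, k in enumerate(order)]
    truth = truth_bins(spec, bin_size)
    result = SimResult(spec, records, truth)
    if pairs_path is not None:
        write_pairs(records, pairs_path, {spec.chrom: spec.length}, bgzf=bgzf)
        result.pairs_path = str(pairs_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("chrom\tbin_x\tbin_y\tbin_size\tn_pairs\n")
            for t in truth:
                fh.write(f"{t.chrom1}\t{t.bin_x}\t{t.bin_y}\t{t.bin_size}\t{t.support}\n")
        result.truth_path = str(truth_path)
    return result


@dataclass
class TruthEval:
    recall: float
    precision: float  # fraction of called bins within 1 bin of a truth bin
    n_called: int

    @property
    def zero_support(self) -> bool:
        """True when nothing was called, making precision vacuous."""
        return self.n_called == 0


def truth_eval(called, truth) -> TruthEval:
    """Recall and a proximity-based precision proxy for called loop bins.

    Recall counts exact bin identity; the precision proxy accepts a called
    bin within Chebyshev distance 1 of any truth bin (loop pairs jittered
    across a bin boundary legitimately shift the called bin by one).  With
    no called bins precision is reported as 1.0 with the zero-support flag.
    """
    truth_keys = {t.key for t in truth}
    called_keys = [c.key for c in called]
    called_key_set = set(called_keys)
    recall = (sum(1 for t in truth_keys if t in called_key_set) / len(truth_keys)
              if truth_keys else 1.0)
    if not called_keys:
        return TruthEval(recall, 1.0, 0)
    near = 0
    truth_by_chrom = {}
    for t in truth:
        truth_by_chrom.setdefault((t.chrom1, t.chrom2), []).append((t.bin_x, t.bin_y))
    for c in called:
        candidates = truth_by_chrom.get((c.chrom1, c.chrom2), [])
        if any(max(abs(c.bin_x - tx), abs(c.bin_y - ty)) <= 1
               for tx, ty in candidates):
            near += 1
    return TruthEval(recall, near / len(called_keys), len(called_keys))
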