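"""Self-evaluation experiments on synthetic data.

Canned simulation studies of the calling and pileup pipelines: the null
false-discovery behaviour of the pair-level test, planted-loop recovery,
and aggregate pileup enrichment.  These power the acceptance checks and
give users a reproducible way to gauge the caller on data with known truth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .calling import (DEFAULT_BIN_SIZE, DEFAULT_FDR, DEFAULT_MIN_SUPPORT,
                      bh_select, call_loops, fit_background,
                      observations_from_records, score_pairs)
from .pileup import aggregate_enrichment, bin_contacts, expected_by_distance
from .simulate import LoopSpec, SimSpec, simulate_pairs, truth_eval


@dataclass
class NullReplicate:
    """Outcome of the pair-level test on one background-only simulation."""

    seed: int
    n_pairs: int
    n_retained: int          # BH-retained pairs; all are false discoveries
    n_spurious_bins: int     # bins passing the support filter

    @property
    def fdp(self) -> float:
        """Realized false-discovery proportion V / max(R, 1)."""
        return 1.0 if self.n_retained else 0.0


def null_fdp_replicate(seed: int, n_pairs: int = 50_000,
                       length: int = 50_000_000, alpha: float = 1.0,
                       fdr: float = DEFAULT_FDR,
                       bin_size: int = DEFAULT_BIN_SIZE,
                       min_support: int = DEFAULT_MIN_SUPPORT) -> NullReplicate:
    """Run the calling pipeline on pure distance-decay background.

    Every retained pair is a false discovery by construction; the replicate
    records how many pairs BH retains and how many 5 kb bins nonetheless
    collect enough retained pairs to be called.
    """
    spec = SimSpec(chrom="chrN", length=length, n_pairs=n_pairs, alpha=alpha,
                   seed=seed)
    result = simulate_pairs(spec)
    obs = observations_from_records(result.records, length)
    fit = fit_background(obs)
    z, p = score_pairs(obs, fit)
    retained = bh_select(p, fdr)
    bins = defaultdict(int)
    for i in retained:
        rec = obs[i].record
        bins[((rec.pos1 - 1) // bin_size, (rec.pos2 - 1) // bin_size)] += 1
    spurious = sum(1 for c in bins.values() if c >= min_support)
    return NullReplicate(seed, n_pairs, len(retained), spurious)


def _random_loops(rng, length, n_loops, pairs_per_loop, jitter_sd,
                  distance_range):
    margin = 120_000  # keep pileup windows inside the matrix
    loops = []
    for _ in range(n_loops):
        d = int(rng.integers(*distance_range))
        a1 = int(rng.integers(margin, length - d - margin))
        loops.append(LoopSpec(a1, a1 + d, pairs_per_loop, jitter_sd))
    return tuple(loops)


def planted_recovery_replicate(seed: int, n_background: int = 50_000,
                               length: int = 50_000_000, n_loops: int = 20,
                               pairs_per_loop: int = 15,
                               jitter_sd: float = 500.0,
                               distance_range=(100_000, 1_000_000),
                               fdr: float = DEFAULT_FDR,
                               min_support: int = DEFAULT_MIN_SUPPORT):
    """Recall/precision of the caller on background plus planted loops."""
    rng = np.random.default_rng(seed)
    loops = _random_loops(rng, length, n_loops, pairs_per_loop, jitter_sd,
                          distance_range)
    spec = SimSpec(chrom="chrP", length=length, n_pairs=n_background,
                   loops=loops, seed=seed)
    result = simulate_pairs(spec)
    called, _ = call_loops(result.records, {spec.chrom: length}, fdr=fdr,
                           min_support=min_support)
    return truth_eval(called, result.truth)


def enrichment_experiment(seed: int, n_background: int = 100_000,
                          length: int = 25_000_000, n_loops: int = 50,
                          pairs_per_loop: int = 15, jitter_sd: float = 500.0,
                          distance_range=(150_000, 1_000_000)):
    """Aggregate pileup enrichment over planted loops.

    Returns (mean enrichment over finite loops, number of finite loops).
    The background is dense enough that most loops have nonzero background
    blocks; loops whose background is all zero stay excluded.
    """
    rng = np.random.default_rng(seed)
    loops = _random_loops(rng, length, n_loops, pairs_per_loop, jitter_sd,
                          distance_range)
    spec = SimSpec(chrom="chrE", length=length, n_pairs=n_background,
                   loops=loops, seed=seed)
    result = simulate_pairs(spec)
    grids = bin_contacts(result.records, {spec.chrom: length})
    expected = expected_by_distance(grids[spec.chrom])
    return aggregate_enrichment(result.truth, grids[spec.chrom], expected)
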