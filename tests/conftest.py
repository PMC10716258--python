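import numpy as np
import pytest

import voronoi3c as v3c

TOY_PAIRS = (
    "## pairs format v1.0\n"
    "#chromsize: chr1 1000\n"
    "#chromsize: chr2 800\n"
    "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n"
    "r1\tchr1\t100\tchr1\t900\t+\t-\n"
    "r2\tchr1\t200\tchr2\t50\t-\t+\n"
)


@pytest.fixture
def toy_pairs_path(tmp_path):
    path = tmp_path / "toy.pairs"
    path.write_text(TOY_PAIRS)
    return path


@pytest.fixture
def unit_viewport():
    return v3c.Viewport.square("chr1", 0, 1)


def make_sorted_pairs(tmp_path, n=1000, seed=0, name="synthetic.pairs",
                      chroms=(("chr1", 2_000_000), ("chr2", 1_500_000)),
                      bgzf=False):
    """Synthetic multi-chromosome pairs file sorted by (chrom1, pos1)."""
    rng = np.random.default_rng(seed)
    records = []
    for ci, (chrom, length) in enumerate(chroms):
        m = n // len(chroms)
        p1 = np.sort(rng.integers(1, length + 1, size=m))
        for k, pos1 in enumerate(p1):
            if rng.random() < 0.8:  # intra, upper triangle
                pos2 = int(rng.integers(pos1, length + 1))
                c2 = chrom
            else:
                c2 = chroms[min(ci + 1, len(chroms) - 1)][0]
                if c2 == chrom:  # keep (chrom1, pos1) sort order intact
                    pos2 = int(rng.integers(pos1, length + 1))
                else:
                    pos2 = int(rng.integers(1, dict(chroms)[c2] + 1))
            records.append(v3c.ContactRecord(f"{chrom}.{k}", chrom, int(pos1),
                                             c2, int(pos2)))
    path = tmp_path / name
    v3c.write_pairs(records, path, dict(chroms), bgzf=bgzf)
    return path, records


@pytest.fixture(scope="session")
def looped_sim():
    """Small simulated chromosome with planted loops, shared across tests."""
    rng = np.random.default_rng(42)
    length = 20_000_000
    loops = []
    for _ in range(12):
        a1 = int(rng.integers(1_000_000, length - 2_100_000))
        d = int(rng.integers(150_000, 1_000_000))
        loops.append(v3c.LoopSpec(a1, a1 + d, 15, 500.0))
    spec = v3c.SimSpec(chrom="chrT", length=length, n_pairs=20_000,
                       loops=tuple(loops), seed=7)
    return v3c.simulate_pairs(spec)
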