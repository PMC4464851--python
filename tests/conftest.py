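import numpy as np
import pytest

from phylosites import _seq
from phylosites.pipeline import RunConfig, run_benchmark
from phylosites.reads import ReadBatch


def make_tiled_batch(genome: np.ndarray, species: str, read_length: int = 50,
                     step: int = 20, fragment_length: int | None = None,
                     exclude=None) -> ReadBatch:
    """Error-free, plus-strand read pairs tiled along a genome.

    ``exclude`` is an optional (lo, hi) interval: fragments overlapping it
    are dropped, which starves the excluded region of coverage.
    """
    L = len(genome)
    flen = fragment_length or 2 * read_length
    starts = [s for s in range(0, L - flen + 1, step)]
    if exclude is not None:
        lo, hi = exclude
        starts = [s for s in starts if s + flen <= lo or s >= hi]
    starts = np.array(starts, dtype=np.int64)
    n = len(starts)
    offs = np.arange(read_length)
    r1 = genome[starts[:, None] + offs].astype(np.uint8)
    ends = starts + flen
    r2 = _seq.COMP_CODE[genome[(ends - read_length)[:, None] + offs]][:, ::-1]
    return ReadBatch(species=species, read_length=read_length, coverage=0.0,
                     seed=0, error_rate=0.0, r1=r1, r2=np.ascontiguousarray(r2),
                     starts=starts,
                     lengths=np.full(n, flen, dtype=np.int64),
                     strands=np.ones(n, dtype=np.int8))


@pytest.fixture(scope="session")
def small_benchmark():
    """One 20 kb balanced equal-tree run at 10x, shared across test modules."""
    config = RunConfig(genome_length=20_000, genome_size=20_000,
                       coverage=10.0, seed=1, max_unknown=[3])
    return run_benchmark(config)
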