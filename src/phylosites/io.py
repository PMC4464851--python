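"""Loading user sequencing data into in-memory batches."""

from __future__ import annotations

import numpy as np

from . import _seq
from .errors import ConfigurationError
from .reads import ReadBatch
from .subsample import iter_fastq, iter_fastq_pairs


def batch_from_fastq(species: str, paths) -> ReadBatch:
    """Load paired (2 paths) or single-end (1 path) FASTQ into a ReadBatch.

    Reads must share one length (the mapper extends end-to-end); single-end
    input is represented as pairs with an empty mate-2 side by duplicating
    mate 1, which downstream stages treat identically because mates are
    processed independently. True origins are unknown for real data, so the
    origin fields are zeroed; evaluation against truth only applies to
    simulated batches.
    """
    if len(paths) == 2:
        recs = list(iter_fastq_pairs(paths[0], paths[1]))
        seqs1 = [r[0][1].upper() for r in recs]
        seqs2 = [r[1][1].upper() for r in recs]
    elif len(paths) == 1:
        singles = list(iter_fastq(paths[0]))
        seqs1 = [r[1].upper() for r in singles]
        seqs2 = seqs1
    else:
        raise ConfigurationError(
            f"{species}: expected 1 or 2 FASTQ paths, got {len(paths)}")
    if not seqs1:
        raise ConfigurationError(f"{species}: no reads in {paths}")
    lengths = {len(s) for s in seqs1} | {len(s) for s in seqs2}
    if len(lengths) != 1:
        raise ConfigurationError(
            f"{species}: reads must share one length, found {sorted(lengths)}")
    read_length = lengths.pop()
    n = len(seqs1)

    def stack(seqs):
        mat = np.empty((n, read_length), dtype=np.uint8)
        for i, s in enumerate(seqs):
            mat[i] = _seq.encode(s)
        return mat

    return ReadBatch(
        species=species, read_length=read_length, coverage=0.0, seed=0,
        error_rate=0.0, r1=stack(seqs1), r2=stack(seqs2),
        starts=np.zeros(n, dtype=np.int64),
        lengths=np.full(n, 2 * read_length, dtype=np.int64),
        strands=np.ones(n, dtype=np.int8))
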