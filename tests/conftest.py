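import numpy as np
import pytest

from regrank import accessibility as acc
from regrank import synthetic as syn
from regrank.model import GenomicInterval, PeakSet, Summit, TagTrack

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """The default synthetic study used by every planted-truth test."""
    return syn.generate_study(STUDY_SEED)


@pytest.fixture(scope="session")
def ranked_table(study):
    union = acc.build_summit_union(study.summits["acc_A"], study.summits["acc_B"])
    table = acc.rank_sites(union, study.tracks["acc_A"], study.tracks["acc_B"])
    return acc.classify_sites(table, log2_threshold=1.0)


@pytest.fixture(scope="session")
def chip_peak_sets(study):
    def build(track_key, label):
        summits = study.summits[track_key]
        intervals = [
            GenomicInterval(s.chrom, max(0, s.pos - 150), s.pos + 150) for s in summits
        ]
        return PeakSet(label, intervals, summits)

    return [
        build("chip_LMO2_A", "LMO2"),
        build("chip_TAL1_A", "TAL1"),
        build("chip_LDB1_A", "LDB1"),
    ]


def random_track(rng, chrom_sizes, n_tags=50):
    """Sparse random track laid down tag by tag."""
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    chroms = list(chrom_sizes)
    for _ in range(n_tags):
        c = chroms[rng.integers(0, len(chroms))]
        counts[c][rng.integers(0, chrom_sizes[c])] += 1
    return TagTrack(counts)


def random_peak_set(rng, label, n_peaks, chrom_sizes, width=200):
    intervals, summits = [], []
    chroms = list(chrom_sizes)
    for _ in range(n_peaks):
        c = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, chrom_sizes[c] - width))
        intervals.append(GenomicInterval(c, start, start + width))
        summits.append(Summit(c, start + width // 2))
    return PeakSet(label, intervals, summits)
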