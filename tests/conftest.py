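import numpy as np
import pandas as pd
import pytest

from loopscape.intervals import FeatureTrack
from loopscape.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_ds():
    """A small but fully annotated synthetic study shared across tests."""
    cfg = SynthConfig(seed=11, n_anchors=200, n_true_loops=600,
                      library_depth=150_000, n_genes=150, n_gwas_clusters=1050)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_norm(small_ds):
    """Filtered + normalized interaction matrix for the shared study."""
    from loopscape import loopstats as ls

    M = small_ds.true_counts
    M = M.loc[ls.filter_testable(M).index]
    M = M.loc[~ls.zero_variance_rows(M)]
    return M, ls.normalize_matrix(M)


def track_from_tuples(rows, name=""):
    """Build a FeatureTrack from (chrom, start, end[, strand[, label]]) tuples."""
    full = []
    for r in rows:
        chrom, start, end = r[:3]
        strand = r[3] if len(r) > 3 else "."
        label = r[4] if len(r) > 4 else ""
        full.append((chrom, start, end, strand, label, 0.0))
    df = pd.DataFrame(full, columns=["chrom", "start", "end", "strand", "label", "score"])
    return FeatureTrack(df, name=name)


def brute_force_overlaps(query, subject, min_overlap=1):
    """Quadratic all-pairs overlap scan used as the oracle."""
    hits = []
    for qi in range(len(query)):
        q = query[qi]
        for si in range(len(subject)):
            s = subject[si]
            if q.chrom != s.chrom:
                continue
            ov = min(q.end, s.end) - max(q.start, s.start)
            if ov >= min_overlap:
                hits.append((qi, si))
    return sorted(hits)
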