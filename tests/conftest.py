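import numpy as np
import pytest

import loopspread as ls


@pytest.fixture(scope="session")
def default_spec():
    return ls.GenomeSpec()


@pytest.fixture(scope="session")
def default_manifest(default_spec):
    return ls.build_genome(default_spec, ls.SimulationParams(seed=0))


@pytest.fixture(scope="session")
def default_chip(default_manifest):
    return ls.simulate_chip_tracks(default_manifest)


@pytest.fixture(scope="session")
def default_hic(default_manifest):
    return ls.simulate_hic(default_manifest)


@pytest.fixture(scope="session")
def default_oe(default_hic):
    from loopspread import hic

    oe, masks = {}, {}
    for cond, per_chrom in default_hic.items():
        oe[cond], masks[cond] = {}, {}
        for chrom, mat in per_chrom.items():
            oe[cond][chrom], masks[cond][chrom] = hic.balance_and_oe(mat)
    return oe, masks


def reciprocal_hits(query_df, target_df, min_frac=0.5):
    """Number of query intervals with >= min_frac reciprocal overlap in target."""
    hits = 0
    for r in query_df.itertuples(index=False):
        sub = target_df[target_df["chrom"] == r.chrom]
        if len(sub) == 0:
            continue
        ov = np.minimum(sub["end"], r.end) - np.maximum(sub["start"], r.start)
        frac = ov / np.maximum(r.end - r.start, sub["end"] - sub["start"])
        if (frac >= min_frac).any():
            hits += 1
    return hits
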