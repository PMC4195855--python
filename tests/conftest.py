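import numpy as np
import pandas as pd
import pytest

from cnascan import CNAEvent, ClonalArchitecture, Clone, make_genome


@pytest.fixture
def flat_bins():
    """Small ideal genome: flat GC, perfect mappability, no blacklist."""
    bins = make_genome(2, 3_000_000, 15_000, gc_profile="flat", seed=0)
    bins["mappability"] = 1.0
    bins["blacklisted"] = False
    return bins


@pytest.fixture
def biased_bins():
    """Genome with realistic GC/mappability variation."""
    return make_genome(4, 15_000_000, 15_000, seed=7)


def pure_clonal(events, purity=1.0):
    """Architecture with a single fully clonal tumor population."""
    return ClonalArchitecture(
        clones=(Clone("truncal", tuple(events), 1.0),), purity=purity
    )


def whole_chrom_loss(bins: pd.DataFrame, chrom: str, copies: int = 1) -> CNAEvent:
    sub = bins[bins["chrom"] == chrom]
    return CNAEvent(chrom, int(sub["start"].min()), int(sub["end"].max()), copies)
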