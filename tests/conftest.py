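import numpy as np
import pandas as pd
import pytest

from apakit.io import PolyASite, SiteCountMatrix


@pytest.fixture
def two_site_atlas():
    """One plus-strand and one minus-strand two-site gene on a toy contig."""
    return [
        # plus strand: proximal = genomically left
        PolyASite("gA_s1", "gA", "chr1", "+", 95, 115, 100, "TE",
                  hexamers=(("AAUAAA", 12.3),)),
        PolyASite("gA_s2", "gA", "chr1", "+", 395, 415, 400, "TE"),
        # minus strand: proximal = genomically right
        PolyASite("gB_s1", "gB", "chr1", "-", 890, 910, 900, "IN"),
        PolyASite("gB_s2", "gB", "chr1", "-", 590, 610, 600, "TE"),
    ]


@pytest.fixture
def sample_sheet():
    return pd.DataFrame(
        {
            "condition": ["P", "P", "Q", "Q"],
            "replicate": [1, 2, 1, 2],
            "timepoint_h": [np.nan] * 4,
        },
        index=pd.Index(["P_r1", "P_r2", "Q_r1", "Q_r2"], name="sample_id"),
    )


@pytest.fixture
def two_site_matrix(two_site_atlas, sample_sheet):
    counts = pd.DataFrame(
        {
            "P_r1": [30, 70, 50, 50],
            "P_r2": [30, 70, 50, 50],
            "Q_r1": [10, 90, 50, 50],
            "Q_r2": [10, 90, 50, 50],
        },
        index=pd.Index([s.site_id for s in two_site_atlas], name="site_id"),
    )
    return SiteCountMatrix(counts, sample_sheet)


@pytest.fixture
def toy_contig():
    """Deterministic 1.2 kb contig for window-extraction tests."""
    rng = np.random.default_rng(42)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=1200))}
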