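import numpy as np
import pandas as pd
import pytest

from lohscape.markers import HET, HOM_P1, HOM_P2, MISSING  # noqa: F401
from lohscape.simulate import Genome, SimConfig

STATE_OF_CHAR = {"H": HET, "1": HOM_P1, "2": HOM_P2, "M": MISSING}


def calls_from_string(pattern: str, chrom: str = "chr1", spacing: int = 1000,
                      start: int = 1000, gq: int = 99) -> pd.DataFrame:
    """Build a one-chromosome call table from a compact state string.

    ``pattern`` uses H (heterozygous), 1/2 (homozygous parent 1/2) and
    M (missing); markers are evenly spaced.
    """
    states = np.array([STATE_OF_CHAR[c] for c in pattern], dtype=np.int8)
    n = len(states)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(n, dtype=np.int64),
            "p1": "A",
            "p2": "G",
            "state": states,
            "gq": np.int16(gq),
            "dp": np.int16(50),
        }
    )


@pytest.fixture
def small_genome() -> Genome:
    return Genome((("chr1", 200_000), ("chr2", 150_000)))


@pytest.fixture
def quiet_config() -> SimConfig:
    """Noise-free configuration with no planted events."""
    return SimConfig(
        seed=11,
        n_lines=3,
        n_bottlenecks=10,
        divisions_per_bottleneck=10.0,
        marker_density=2.0,
        i_loh_rate=0.0,
        t_loh_rate=0.0,
        snm_rate=0.0,
        missing_rate=0.0,
        gq_range=(99, 99),
    )
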