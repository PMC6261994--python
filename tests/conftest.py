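import numpy as np
import pandas as pd
import pytest

from crosspop.io import PopulationStats, ReferencePanel


def make_stats(rows, population="EAS", trait="SBP"):
    """Build a PopulationStats from a list of dicts with canonical columns."""
    defaults = {
        "CHR": "1", "EA": "G", "NEA": "A", "EAF": 0.3, "BETA": 0.1,
        "SE": 0.05, "P": 0.5, "N": 10_000, "INFO": 1.0, "CALL_RATE": 1.0,
    }
    table = pd.DataFrame([{**defaults, **r} for r in rows])
    return PopulationStats(population=population, trait=trait, table=table)


@pytest.fixture
def stats_factory():
    return make_stats


@pytest.fixture
def small_panel():
    """Deterministic 8-haplotype, 4-SNP panel for LD lookups."""
    haps = np.array(
        [
            [1, 1, 0, 1],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 0, 0],
            [1, 0, 1, 1],
            [0, 1, 1, 0],
        ],
        dtype=np.int8,
    )
    meta = pd.DataFrame(
        {
            "CHR": "1",
            "POS": [100, 200, 300, 400],
            "SNP": ["rs1", "rs2", "rs3", "rs4"],
            "REF": "A",
            "ALT": "G",
            "BLOCK": 0,
        }
    )
    return ReferencePanel("EAS", haps, meta)
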