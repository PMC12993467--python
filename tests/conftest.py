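import numpy as np
import pandas as pd
import pytest

from rumengrad import AbundanceTable, default_config
from rumengrad.reference import BACTEROIDETES_LINE, FIRMICUTES_LINE


@pytest.fixture
def core_phyla_table() -> AbundanceTable:
    """Group-mean proportions table built from the two core-phylum trend lines.

    Bacteroidetes and Firmicutes follow their fitted gradient lines
    exactly at the five concentrate fractions; a residual pool closes each
    column to 1 so the table is a valid composition.
    """
    x = np.array([0.20, 0.35, 0.50, 0.65, 0.80])
    bact = BACTEROIDETES_LINE[0] * x + BACTEROIDETES_LINE[1]
    firm = FIRMICUTES_LINE[0] * x + FIRMICUTES_LINE[1]
    rest = 1.0 - bact - firm
    labels = ["20:80", "35:65", "50:50", "65:35", "80:20"]
    values = pd.DataFrame(
        [bact, firm, rest],
        index=["p_Bacteroidetes", "p_Firmicutes", "p_Other"],
        columns=labels,
    )
    meta = pd.DataFrame(
        {"group_label": labels, "concentrate_fraction": x},
        index=pd.Index(labels, name="sample_id"),
    )
    return AbundanceTable(values=values, metadata=meta, mode="proportions")


@pytest.fixture
def counts_table() -> AbundanceTable:
    """Small integer counts table with uneven depths for rarefaction tests."""
    rng = np.random.default_rng(42)
    taxa = ["p_Bacteroidetes|g_Prevotella 1", "p_Bacteroidetes|g_Rikenellaceae RC9",
            "p_Firmicutes|g_Ruminococcus 2", "p_Firmicutes|g_Christensenellaceae R-7",
            "p_Spirochaetes|g_Treponema 2", "unranked_taxon"]
    samples = [f"S{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.integers(0, 500, size=(len(taxa), len(samples))),
        index=taxa, columns=samples,
    )
    meta = pd.DataFrame(
        {
            "group_label": ["20:80", "20:80", "50:50", "50:50", "80:20", "80:20"],
            "concentrate_fraction": [0.2, 0.2, 0.5, 0.5, 0.8, 0.8],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return AbundanceTable(values=values, metadata=meta, mode="counts")


@pytest.fixture
def cfg():
    return default_config(seed=7)
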