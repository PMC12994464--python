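import numpy as np
import pandas as pd
import pytest

from mirconcord.de_io import DETable

MIR21 = "UAGCUUAUCAGACUGAUGUUGA"  # mature miR-21-5p


@pytest.fixture
def mir21() -> str:
    return MIR21


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_called_table(contrast_id: str, calls: dict[str, str]) -> DETable:
    """DETable with explicit significance calls.

    ``calls`` maps gene id to 'up', 'down' or 'none'; fold-changes and
    p-values are filled in consistently with the call.
    """
    rows = []
    for gene, call in calls.items():
        sig = call in ("up", "down")
        rows.append(
            {
                "feature_id": gene,
                "log2FoldChange": {"up": 2.0, "down": -2.0, "none": 0.1}[call],
                "pvalue": 1e-8 if sig else 0.8,
                "padj": 1e-6 if sig else 0.9,
                "tested": True,
                "significant": sig,
                "direction": call,
            }
        )
    return DETable(contrast_id, pd.DataFrame(rows))


@pytest.fixture
def called_table_factory():
    return make_called_table
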