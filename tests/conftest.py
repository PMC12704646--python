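import numpy as np
import pandas as pd
import pytest

from proteomr.types import CANONICAL_COLUMNS


def make_variants(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical variant table from partial row dicts."""
    defaults = {"chr": "1", "pos": 0, "ea": "A", "oa": "G", "beta": 0.1,
                "se": 0.01, "p": np.nan, "eaf": 0.3, "n": 10_000}
    full = []
    for i, row in enumerate(rows):
        rec = {**defaults, "variant_id": f"v{i + 1}", **row}
        if np.isnan(rec["p"]):
            from scipy.stats import norm

            rec["p"] = 2 * norm.sf(abs(rec["beta"] / rec["se"]))
        full.append(rec)
    return pd.DataFrame(full, columns=CANONICAL_COLUMNS)


@pytest.fixture
def variants_factory():
    return make_variants


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
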