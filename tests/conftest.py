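import numpy as np
import pandas as pd
import pytest

from causalmr import HarmonisedInstruments, SummaryDataset
from causalmr.summary_data import SUMMARY_COLUMNS


def make_harmonised(
    beta_exposure,
    se_exposure,
    beta_outcome,
    se_outcome,
    snp_ids=None,
    n_exposure=50_000,
    n_outcome=50_000,
) -> HarmonisedInstruments:
    """Build a HarmonisedInstruments directly from association arrays."""
    be = np.asarray(beta_exposure, dtype=float)
    j = len(be)
    if snp_ids is None:
        snp_ids = [f"rs{i+1:03d}" for i in range(j)]
    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "beta_exposure": be,
            "se_exposure": np.broadcast_to(np.asarray(se_exposure, float), (j,)).copy(),
            "beta_outcome": np.asarray(beta_outcome, dtype=float),
            "se_outcome": np.broadcast_to(np.asarray(se_outcome, float), (j,)).copy(),
            "eaf": 0.3,
            "flag": "kept",
        }
    )
    return HarmonisedInstruments("exposure", "outcome", table, n_exposure, n_outcome)


def make_dataset(trait_name, rows) -> SummaryDataset:
    """rows: list of dicts with any subset of the canonical columns."""
    defaults = {
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-9,
        "n": 10_000,
    }
    full = []
    for i, row in enumerate(rows):
        r = {"snp_id": f"rs{i+1:03d}", **defaults, **row}
        full.append(r)
    return SummaryDataset(trait_name, pd.DataFrame(full, columns=SUMMARY_COLUMNS))


@pytest.fixture
def harmonised_basic():
    """Five valid instruments consistent with a causal effect of 0.5."""
    rng = np.random.default_rng(42)
    be = np.array([0.08, 0.10, 0.12, 0.09, 0.11])
    bo = 0.5 * be + rng.normal(0, 0.002, 5)
    return make_harmonised(be, 0.01, bo, 0.005)
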