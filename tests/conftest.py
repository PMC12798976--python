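"""Shared fixture builders: tiny in-memory cohorts assembled programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methclock.io import BetaMatrix, SampleSheet


def make_sheet(sample_ids, **overrides) -> SampleSheet:
    """A valid sample sheet with sensible defaults, column overrides allowed.

    Scalar overrides broadcast; sequence overrides must match the length.
    """
    n = len(sample_ids)
    cols = {
        "sample_id": list(sample_ids),
        "individual_id": list(sample_ids),
        "tissue": "liver",
        "species": "cheetah",
        "sex": "female",
        "age_years": 5.0,
        "disease_status": "none",
        "source": "test",
    }
    cols.update(overrides)
    return SampleSheet(pd.DataFrame(cols))


def make_beta(values, sample_prefix="S", probe_prefix="cg") -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return BetaMatrix(
        [f"{sample_prefix}{i:03d}" for i in range(n)],
        [f"{probe_prefix}{j:05d}" for j in range(p)],
        values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
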