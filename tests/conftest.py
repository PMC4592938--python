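"""Shared fixtures: toy interaction matrices and group metadata."""

import numpy as np
import pandas as pd
import pytest

from callnet import CALL_TYPES, DyadResult, InteractionMatrix


def make_matrix(birds, significant_cells=(), invalid_cells=(), recording_id="rec0", stage=None):
    """Build a fully-valid matrix over `birds` x five call types, with the
    given cells flagged significant-positive (or invalid)."""
    axes = [(b, t) for b in birds for t in CALL_TYPES]
    sig = set(significant_cells)
    inv = set(invalid_cells)
    cells = {}
    for a in axes:
        for b in axes:
            if a[0] == b[0]:
                continue
            if (a, b) in inv:
                cells[(a, b)] = DyadResult(valid=False, significant=0, total_events=10)
            else:
                s = 1 if (a, b) in sig else 0
                cells[(a, b)] = DyadResult(
                    n_base=100,
                    n_response=150 if s else 100,
                    r_index=0.2 if s else 0.0,
                    valid=True,
                    significant=s,
                    total_events=500,
                )
    return InteractionMatrix(axes, cells, recording_id=recording_id, stage=stage)


@pytest.fixture
def four_birds_meta():
    """Two female/male pairs: (F0, M0) and (F1, M1)."""
    return pd.DataFrame(
        [
            {"bird_id": "F0", "sex": "female", "pair_id": "p0", "success": "successful"},
            {"bird_id": "M0", "sex": "male", "pair_id": "p0", "success": "successful"},
            {"bird_id": "F1", "sex": "female", "pair_id": "p1", "success": "unsuccessful"},
            {"bird_id": "M1", "sex": "male", "pair_id": "p1", "success": "unsuccessful"},
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
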