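"""Shared fixtures.

The statistical suites reuse a handful of session-scoped datasets.  Sizes are
the package's desk-scale defaults (see docs/methods.md): large enough for the
qualitative statistical claims to have decent power, small enough that the
whole suite runs on one CPU in well under half an hour.
"""

import numpy as np
import pytest

import knotph as kp
from knotph import stats

#: root seed for every stochastic suite (fixed for reproducibility)
SUITE_SEED = 20260920

#: desk-scale sizes
DS1_LENGTHS = (20, 50, 100)
DS1_PER_LENGTH = 60
DS2_UNKNOT_LENGTHS = (50, 100, 150, 200)
DS2_UNKNOT_PER_CELL = 10
DS2_TREFOIL_LENGTHS = (50, 100)
DS2_TREFOIL_PER_CELL = 15


@pytest.fixture(scope="session")
def dataset1():
    """Random-polygon feature table with Betti curves, desk scale."""
    df, curves = stats.build_dataset1(
        DS1_LENGTHS, DS1_PER_LENGTH, seed=SUITE_SEED, return_curves=True)
    return df, curves


@pytest.fixture(scope="session")
def dataset2(dataset2_unknots, dataset2_trefoils):
    import pandas as pd

    df = pd.concat([dataset2_unknots[0], dataset2_trefoils[0]],
                   ignore_index=True)
    curves = {**dataset2_unknots[1], **dataset2_trefoils[1]}
    return df, curves


@pytest.fixture(scope="session")
def dataset2_unknots():
    df, curves, incomplete = stats.build_dataset2(
        ["0_1"], DS2_UNKNOT_LENGTHS, DS2_UNKNOT_PER_CELL,
        seed=SUITE_SEED + 1, return_curves=True)
    assert not incomplete
    return df, curves


@pytest.fixture(scope="session")
def dataset2_trefoils():
    df, curves, incomplete = stats.build_dataset2(
        ["3_1"], DS2_TREFOIL_LENGTHS, DS2_TREFOIL_PER_CELL,
        seed=SUITE_SEED + 2, return_curves=True)
    assert not incomplete
    return df, curves


@pytest.fixture(scope="session")
def trefoil_suite():
    """100 independently sampled and classified trefoils at length 50."""
    rng = np.random.default_rng(SUITE_SEED + 3)
    out = []
    while len(out) < 100:
        out.append(kp.sample_fixed_type(50, "3_1", max_attempts=500, rng=rng))
    return out


@pytest.fixture(scope="session")
def trefoil_family_curves():
    """Betti curves of the three n=120 trefoil-family embeddings."""
    out = {}
    for kind in ("balanced", "elongated", "flattened"):
        P = kp.trefoil_family(kind, 120)
        out[kind] = kp.betti_curve(kp.rips_h1_barcode(kp.interpolate(P, 10)))
    return out
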