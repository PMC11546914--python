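import numpy as np
import pytest

from metamarker.io_prep import CASE, CONTROL, MetabolomicMatrix


@pytest.fixture
def tiny_matrix():
    """6 samples x 3 metabolites with one missing cell, raw positive scale."""
    values = np.array(
        [
            [10.0, 5.0, 2.0],
            [12.0, np.nan, 2.5],
            [11.0, 6.0, 3.0],
            [9.0, 5.5, 2.2],
            [20.0, 9.0, 4.0],
            [22.0, 8.5, 4.4],
        ]
    )
    return MetabolomicMatrix(
        sample_ids=[f"s{i}" for i in range(6)],
        group=np.array([CONTROL] * 4 + [CASE] * 2, dtype=object),
        metabolite_ids=["lactate", "inositol", "serine"],
        values=values,
    )


def two_group_matrix(values_control, values_case, metabolite_ids=None):
    """Assemble a MetabolomicMatrix from per-group value arrays (already log scale)."""
    values_control = np.asarray(values_control, dtype=float)
    values_case = np.asarray(values_case, dtype=float)
    n_c, p = values_control.shape
    n_a = values_case.shape[0]
    if metabolite_ids is None:
        metabolite_ids = [f"m{j:02d}" for j in range(p)]
    return MetabolomicMatrix(
        sample_ids=[f"c{i}" for i in range(n_c)] + [f"a{i}" for i in range(n_a)],
        group=np.array([CONTROL] * n_c + [CASE] * n_a, dtype=object),
        metabolite_ids=metabolite_ids,
        values=np.vstack([values_control, values_case]),
    )


@pytest.fixture
def complementary_pair_matrix():
    """27 controls, 12 cases; metabolites 0 and 1 each separate half the cases.

    Cases 0-5 sit far above the control range on metabolite 0, cases 6-11 on
    metabolite 1; the remaining 50 metabolites are pure noise.  Either marker
    alone leaves half the cases indistinguishable from controls, so only the
    pair (plus anything) reaches perfect fold accuracies.
    """
    rng = np.random.default_rng(1234)
    ctrl = rng.normal(0.0, 1.0, size=(27, 52))
    case = rng.normal(0.0, 1.0, size=(12, 52))
    case[:6, 0] += 8.0
    case[6:, 1] += 8.0
    return two_group_matrix(ctrl, case, [f"m{j:02d}" for j in range(52)])
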