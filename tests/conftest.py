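import numpy as np
import pytest

from lfpca import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(20151020)


def make_stack(data, times, subjects_per_visit=None, mask=None):
    """Assemble a small ImageStack from a (p, J) matrix and per-column times.

    ``times`` is a list of per-subject time tuples; columns are laid out
    subject-major in that order.
    """
    data = np.asarray(data, dtype=float)
    sids, visits, tcol = [], [], []
    for i, ts in enumerate(times):
        for j, t in enumerate(ts):
            sids.append(f"S{i + 1:02d}")
            visits.append(j + 1)
            tcol.append(t)
    p = data.shape[0]
    if mask is None:
        mask = np.ones((p, 1, 1), dtype=bool)
    return ImageStack(
        data=data,
        subject_id=np.array(sids),
        visit_index=np.array(visits),
        time=np.array(tcol, dtype=float),
        mask=mask,
    )


@pytest.fixture
def make_model_components():
    """Random orthonormal component sets for the truncated model."""

    def _make(p, n_x, n_w, seed=0):
        rng = np.random.default_rng(seed)
        stacked, _ = np.linalg.qr(rng.normal(size=(2 * p, n_x)))
        phi_w, _ = np.linalg.qr(rng.normal(size=(p, n_w)))
        return stacked[:p], stacked[p:], phi_w

    return _make
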