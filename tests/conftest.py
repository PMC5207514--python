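import pytest

import pts1pred as pp
from pts1pred.seq_io import windows_from_records


@pytest.fixture(scope="session")
def synth():
    """Default-condition synthetic dataset (90 positives, 176 negatives)."""
    return pp.generate_synthetic(pp.SyntheticSpec(seed=101))


@pytest.fixture(scope="session")
def synth_windows(synth):
    return (
        windows_from_records(synth.positives, 30),
        windows_from_records(synth.negatives, 30),
    )


@pytest.fixture(scope="session")
def synth_model(synth_windows):
    """One RBF model trained on the session dataset with fixed hyperparameters."""
    pos, neg = synth_windows
    return pp.train(pos, neg, C=8.0, gamma=0.125, seed=7)


@pytest.fixture(scope="session")
def synth_cv(synth_windows):
    """Pooled 5-fold CV of the session dataset (held-out scores reused widely)."""
    pos, neg = synth_windows
    return pp.cross_validate(pos, neg, k=5, cutoff=1.0, C=8.0, gamma=0.125, seed=7)
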