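import numpy as np
import pytest

from postgdm.nested_cv import AggregatedPredictions
from postgdm.synthetic import GeneratorSpec, generate_cohort


@pytest.fixture(scope="session")
def default_table():
    """One default-condition synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorSpec(n=394, seed=7))


@pytest.fixture
def make_preds():
    """Build an AggregatedPredictions from raw (probs, labels) arrays."""

    def _make(probs, labels, **kw):
        return AggregatedPredictions.from_arrays(np.asarray(probs, float),
                                                 np.asarray(labels, int), **kw)

    return _make


def pairwise_auc(probs, labels) -> float:
    """O(n^2) Mann-Whitney concordance oracle with ties counted 1/2."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
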