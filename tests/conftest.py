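import numpy as np
import pandas as pd
import pytest

from mhcbind import _autodiff
from mhcbind.network import ModelConfig
from mhcbind.simulate import make_world


@pytest.fixture
def float64_graph():
    """Run the autodiff graph in float64 (for finite-difference checks)."""
    _autodiff.set_dtype(np.float64)
    yield
    _autodiff.set_dtype(np.float32)


@pytest.fixture
def tiny_world():
    """2-allele world with a short pseudo-sequence for fast unit tests."""
    return make_world(n_alleles=2, peptide_length=9, seed=7, pseudo_len=10)


def tiny_config(**overrides) -> ModelConfig:
    base = dict(
        task="classification", max_pep_len=10, n_filters_1d=4,
        n_filters_2d=3, lstm_hidden=4, blosum_dense=12, mlp_hidden=(16,),
        cbam_reduction=2, spatial_kernel=3, epochs=2, t_max=2,
        batch_size=64, learning_rate=1e-3, seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


class StubModel:
    """Deterministic stand-in scorer for curation/panel tests.

    ``fn(peptide, allele) -> score``; optionally carries a config with a
    task attribute so ensemble task checks can be exercised.
    """

    def __init__(self, fn, task=None):
        self.fn = fn
        if task is not None:
            class _Cfg:
                pass

            self.config = _Cfg()
            self.config.task = task

    def predict(self, X):
        if hasattr(X, "columns"):
            pairs = zip(X["peptide"], X["allele"])
        else:
            pairs = X
        return np.array([self.fn(p, a) for p, a in pairs], dtype=float)


@pytest.fixture
def stub_model_factory():
    return StubModel


def el_frame(rows):
    """Build an eluted-ligand frame from (peptide, alleles, label) rows."""
    return pd.DataFrame(rows, columns=["peptide", "alleles", "label"])
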