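import numpy as np
import pandas as pd
import pytest

import metabomark as mm
from metabomark.feature_table import FeatureTable
from metabomark.svm_rfe import SVMConfig


def make_table(matrix, concentrations=None, bin_ids=None, species="sp") -> FeatureTable:
    """Hand-built FeatureTable around a raw matrix, for unit tests."""
    matrix = np.asarray(matrix, dtype=float)
    n, f = matrix.shape
    if concentrations is None:
        concentrations = [0.0] * (n // 2) + [1250.0] * (n - n // 2)
    if bin_ids is None:
        bin_ids = [f"RT{100 + i}.0_MZ{50 + i}" for i in range(f)]
    sample_ids = [f"{species}_s{i}" for i in range(n)]
    abund = pd.DataFrame(matrix, index=pd.Index(sample_ids, name="sample_id"),
                         columns=bin_ids)
    meta = pd.DataFrame({"species": species,
                         "concentration_ug_per_L": [float(c) for c in concentrations],
                         "tube_id": [f"t{i // 2}" for i in range(n)]},
                        index=abund.index)
    return FeatureTable(abund, meta)


def fast_svm(seed=0, repeats=10, **kw) -> SVMConfig:
    """Small grids and few repeats: fast but structurally faithful."""
    kw.setdefault("cost_grid", (1.0, 100.0))
    kw.setdefault("gamma_grid", (0.01, 0.1))
    kw.setdefault("tune_repeats", 2)
    return SVMConfig(repeats=repeats, seed=seed, **kw)


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic dataset with planted signal, reused across tests."""
    cfg = mm.SyntheticConfig(n_bins=120, n_planted=6, effect_size=2.5,
                             noise_sigma=0.4, concentrations=(0.0, 1250.0),
                             tubes_per_group=3, individuals_per_tube=4, seed=7)
    table, truth = mm.generate_feature_table(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_contrast(small_bundle):
    """Preprocessed control-vs-exposed contrast of the small bundle."""
    _, table, truth = small_bundle
    scaled = mm.univariate_scale(mm.constant_sum_normalize(table))
    labels = (scaled.sample_meta["concentration_ug_per_L"].astype(float) > 0).astype(int)
    return scaled, labels, truth
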