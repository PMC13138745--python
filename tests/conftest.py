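import numpy as np
import pytest

from caser.synthdata import SimConfig, generate_classification_data
from caser.tables import FeatureTable, impute_missing, zscore_normalize


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by pipeline-level tests."""
    cfg = SimConfig(n_genes=300, n_features=12, n_labeled_pos=12,
                    n_labeled_neg=12, n_unlabeled=150, effect_size=2.0, seed=42)
    return generate_classification_data(cfg)


@pytest.fixture(scope="session")
def small_training(small_dataset):
    """Preprocessed (imputed + z-scored) training view of small_dataset."""
    full = zscore_normalize(impute_missing(small_dataset.table))
    tv, labels = small_dataset.training_view()
    table = FeatureTable(full.df.loc[tv.gene_ids], dict(full.categories),
                         dict(full.value_kind))
    return table, labels


@pytest.fixture(scope="session")
def fitted_results(small_training):
    from caser.model import CaserModel
    from caser.tritrain import TrainConfig

    table, labels = small_training
    return CaserModel(table, labels, TrainConfig(seed=5), preprocess=False).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
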