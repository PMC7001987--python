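import numpy as np
import pytest

from covrec import classify, synthetic


@pytest.fixture(scope="session")
def anatomy():
    return synthetic.toy_anatomy_ontology()


@pytest.fixture(scope="session")
def histone():
    return synthetic.histone_mark_ontology()


@pytest.fixture(scope="session")
def go_like():
    return synthetic.go_like_ontology()


@pytest.fixture(scope="session")
def ontology_set():
    return synthetic.default_ontology_set()


@pytest.fixture(scope="session")
def small_cohort():
    """120-dataset, 2-class separable cohort (stem-like vs heart-like)."""
    spec = synthetic.CohortSpec(
        n_features=400,
        classes=(
            synthetic.ClassSpec("embryonic stem cell", 60, tuple(range(0, 25)), 3.0),
            synthetic.ClassSpec("heart", 60, tuple(range(25, 50)), 3.0),
        ),
        seed=42,
    )
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def trained_model(small_cohort, ontology_set):
    """One cell-type model trained on the small cohort (session-scoped)."""
    matrix, records = small_cohort
    labels = classify.derive_labels(records, ontology_set)
    label_sets = [labels[r.dataset_id] for r in records]
    config = classify.ClassifierConfig(top_k_features=150, random_seed=7)
    model = classify.train_classifier(
        matrix,
        label_sets,
        config,
        assembly="toy1",
        experiment_type="RNA-seq",
        metadata_field="cell_type",
        feature_class="transcript",
    )
    assert model is not None
    return model
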