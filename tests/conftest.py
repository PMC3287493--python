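import pytest

from adrnet import pipeline
from adrnet.modeling import ModelSpec
from adrnet.simulate import SynthConfig, generate


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(c) for c in r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def tsv_writer(tmp_path):
    def _write(name, header, rows):
        return write_tsv(tmp_path / name, header, rows)
    return _write


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the generator at its default study conditions."""
    return generate(SynthConfig())


@pytest.fixture(scope="session")
def default_facts(default_dataset):
    ds = default_dataset
    dt, labels = pipeline.target_facts_and_labels(ds.targets, ds.adrs, ds.icd)
    return dt, labels


@pytest.fixture(scope="session")
def no_net_summary(default_facts):
    """Median CV metrics for the raw-target ("No Net") SVM condition."""
    dt, labels = default_facts
    _, med = pipeline.evaluate_condition(dt, labels, ModelSpec("svm_rbf"),
                                         folds=10, repeats=3, seed=7)
    return med


@pytest.fixture(scope="session")
def stars2_summary(default_dataset, default_facts):
    """Median CV metrics for the "2 Stars UP" one-level-expansion condition."""
    ds = default_dataset
    dt, labels = default_facts
    X = pipeline.stars_up_features(dt, ds.ppi, 2)
    _, med = pipeline.evaluate_condition(X, labels, ModelSpec("svm_rbf"),
                                         folds=10, repeats=3, seed=7)
    return med
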