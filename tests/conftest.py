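import numpy as np
import pytest

import pvcausal as pv
from pvcausal.classifier import ClassifierConfig


@pytest.fixture(scope="session")
def toy_schema():
    return pv.FeatureSchema(
        features=("gender", "drug", "outcomes"),
        vocab={
            "gender": {"male", "female"},
            "drug": {"APAP", "tramadol"},
            "outcomes": {"death", "recovered"},
        },
        endpoint_feature="outcomes",
        endpoint_term="death",
    )


@pytest.fixture(scope="session")
def planted_study():
    """One reference synthetic study: reports, sentences, split, fitted
    token-logistic model and its probability table (n = 2,000, seed 1)."""
    gen = pv.default_config(n_reports=2000, seed=1)
    reports = pv.generate_cases(gen)
    sentences = pv.generate_sentences(reports, gen.schema)
    split = pv.stratified_split(sentences, seed=1)
    cfg = ClassifierConfig(
        kind="token-logistic", total_steps=200, checkpoint_every=50,
        learning_rate=1.0, seed=1,
    )
    model, trace = pv.train_classifier(split.train, split.dev, cfg)
    probs = pv.predict_proba(model, split.all_records)
    return {
        "generator": gen,
        "schema": gen.schema,
        "reports": reports,
        "sentences": sentences,
        "split": split,
        "model": model,
        "trace": trace,
        "probs": probs,
    }


@pytest.fixture(scope="session")
def separable_corpus():
    """400 sentences where one token perfectly determines the label."""
    rng = np.random.default_rng(7)
    records = []
    filler = list("abcdefgh")
    for i in range(400):
        y = int(rng.random() < 0.5)
        words = " ".join(rng.choice(filler, size=6))
        text = ("signal " if y else "noise ") + words
        records.append(pv.SentenceRecord(f"s{i:03d}", text, y))
    return records[:300], records[300:]
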