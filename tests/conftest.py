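import numpy as np
import pytest

from forumrx.crf import TrainConfig
from forumrx.evaluation import split_posts
from forumrx.features import reference_gazetteer
from forumrx.pipeline import build_examples, predict_spans, train_crf
from forumrx.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def gazetteer():
    return reference_gazetteer()


@pytest.fixture(scope="session")
def small_synth():
    """A small generated corpus for unit-level checks."""
    cfg = GeneratorConfig(n_authors=20, posts_per_author=6, cue_ambiguity=0.2, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def attribution_lr(separable_run):
    """Logistic attribution classifier trained on the separable run's gold
    train spans (shared by baseline and ordering tests)."""
    from forumrx.baselines import train_attribution_lr

    return train_attribution_lr(
        separable_run["examples_train"], separable_run["gold_train"],
        l1_lambda=0.1, seed=0,
    )


@pytest.fixture(scope="session")
def separable_run(gazetteer):
    """One full train/predict cycle on a separable 2,000-post corpus.

    Shared by every test that needs a trained model: 70/30 split by post,
    all three feature families, CRF trained to convergence tolerance.
    Returns a dict with the corpus, gold/predicted spans and the model.
    """
    cfg = GeneratorConfig(
        n_authors=100, posts_per_author=20, cue_ambiguity=0.0, seed=42
    )
    corpus, gold = generate(cfg)
    train_corpus, test_corpus = split_posts(corpus, 0.3, seed=7)
    train_ids = {p.post_id for p in train_corpus}
    gold_train = [s for s in gold if s.post_id in train_ids]
    gold_test = [s for s in gold if s.post_id not in train_ids]
    fams = ("lexical", "semantic", "syntactic")
    ex_train = build_examples(train_corpus, gold_train, fams, (gazetteer,))
    ex_test = build_examples(test_corpus, None, fams, (gazetteer,))
    model = train_crf(ex_train, TrainConfig(max_iterations=60))
    pred, repairs = predict_spans(model, ex_test)
    return {
        "config": cfg,
        "corpus": corpus,
        "gold": gold,
        "train_corpus": train_corpus,
        "test_corpus": test_corpus,
        "gold_train": gold_train,
        "gold_test": gold_test,
        "examples_train": ex_train,
        "examples_test": ex_test,
        "families": fams,
        "model": model,
        "pred": pred,
        "repairs": repairs,
    }
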