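"""Span matching, P/R/F regimes, Cohen's kappa, and the ablation grid."""

from datetime import datetime, timezone

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from forumrx.corpus import Corpus, MentionSpan, Post
from forumrx.evaluation import (
    REGIMES,
    ablation_run,
    binary_merge,
    cohen_kappa,
    match_spans,
    prf_report,
    split_posts,
    token_kappa,
)


def sp(post_id, cs, ce, label, surface="x"):
    return MentionSpan(post_id, cs, ce, surface, label)


class TestMatchSpans:
    def test_identical_lists(self):
        gold = [sp("p1", 0, 5, "pt"), sp("p1", 10, 15, "gen")]
        tp, fp, fn, pairs = match_spans(gold, list(gold), typed=True)
        assert (tp, fp, fn) == (2, 0, 0)

    def test_wrong_label_typed_vs_untyped(self):
        gold = [sp("p1", 0, 5, "pt")]
        pred = [sp("p1", 0, 5, "gen")]
        assert match_spans(gold, pred, typed=True)[:3] == (0, 1, 1)
        assert match_spans(gold, pred, typed=False)[:3] == (1, 0, 0)

    def test_off_by_one_character_is_error_even_untyped(self):
        gold = [sp("p1", 0, 5, "pt")]
        pred = [sp("p1", 1, 5, "pt")]
        assert match_spans(gold, pred, typed=False)[:3] == (0, 1, 1)

    def test_overlapping_spans_rejected(self):
        bad = [sp("p1", 0, 5, "pt"), sp("p1", 3, 8, "gen")]
        with pytest.raises(ValueError, match="overlap"):
            match_spans(bad, [])


class TestPrfReport:
    def test_perfect_predictions(self):
        gold = [sp("p1", 0, 5, "pt"), sp("p2", 3, 9, "gen")]
        for regime in REGIMES:
            rep = prf_report(gold, list(gold), regime)
            assert rep.micro.f1 == 1.0

    def test_hand_counted_confusion(self):
        """2 gold pt; predictions: 1 exact pt, 1 boundary-correct but gen."""
        gold = [sp("p1", 0, 5, "pt"), sp("p1", 10, 15, "pt")]
        pred = [sp("p1", 0, 5, "pt"), sp("p1", 10, 15, "gen")]
        rep = prf_report(gold, pred, "five_class")
        assert (rep.per_class["pt"].tp, rep.per_class["pt"].fn) == (1, 1)
        assert rep.per_class["gen"].fp == 1
        m = rep.micro
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        assert m.precision == 0.5 and m.recall == 0.5 and m.f1 == 0.5

    def test_empty_predictions_zero_convention(self):
        gold = [sp("p1", 0, 5, "pt")]
        rep = prf_report(gold, [], "five_class")
        assert rep.micro.precision == 0.0
        assert rep.micro.recall == 0.0
        assert rep.micro.f1 == 0.0

    def test_micro_equals_pooled_recount(self):
        gold = [sp("p1", 0, 5, "pt"), sp("p1", 10, 15, "gen"), sp("p2", 0, 4, "cg")]
        pred = [sp("p1", 0, 5, "gen"), sp("p1", 10, 15, "gen"), sp("p2", 1, 4, "cg")]
        rep = prf_report(gold, pred, "five_class")
        # oracle: pool raw tp/fp/fn by direct counting over (boundary,label) keys
        gk = {(s.post_id, s.char_start, s.char_end, s.label) for s in gold}
        pk = {(s.post_id, s.char_start, s.char_end, s.label) for s in pred}
        tp = len(gk & pk)
        assert (rep.micro.tp, rep.micro.fp, rep.micro.fn) == (
            tp, len(pk) - tp, len(gk) - tp
        )

    def test_binary_regime_merges_both_sides(self):
        gold = [sp("p1", 0, 5, "pt-gen")]
        pred = [sp("p1", 0, 5, "cg")]  # both merge to non-pt -> not a pt error
        rep = prf_report(gold, pred, "binary_pt")
        assert rep.micro.tp == 0 and rep.micro.fp == 0 and rep.micro.fn == 0
        pred_pt = [sp("p1", 0, 5, "pt")]
        rep2 = prf_report(gold, pred_pt, "binary_pt")
        assert rep2.per_class["pt"].fp == 1

    def test_unknown_regime(self):
        with pytest.raises(ValueError, match="unknown regime"):
            prf_report([], [], "macro")


class TestBinaryMerge:
    @pytest.mark.parametrize(
        "label,expected",
        [("pt", "pt"), ("pt-gen", "non-pt"), ("cg", "non-pt"),
         ("others", "non-pt"), ("gen", "non-pt")],
    )
    def test_merge_rule(self, label, expected):
        assert binary_merge(label) == expected

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            binary_merge("patient")


KAPPA_A = ["pt", "pt", "pt", "O", "O", "O", "O", "O", "gen", "gen"]
KAPPA_B = ["pt", "pt", "gen", "O", "O", "O", "O", "O", "gen", "pt"]
# hand computation: p_o = 0.8; marginals A {pt:.3, O:.5, gen:.2},
# B {pt:.3, O:.5, gen:.2}; p_e = .09+.25+.04 = .38; kappa = .42/.62
KAPPA_EXPECTED = (0.8 - 0.38) / (1 - 0.38)


class TestCohenKappa:
    def test_identical_annotations(self):
        r = cohen_kappa(KAPPA_A, KAPPA_A)
        assert r.value == 1.0 and not r.degenerate

    def test_degenerate_all_o(self):
        r = cohen_kappa(["O"] * 5, ["O"] * 5)
        assert r.value == 1.0 and r.degenerate

    def test_hand_fixture_closed_form(self):
        r = cohen_kappa(KAPPA_A, KAPPA_B)
        assert r.value == pytest.approx(KAPPA_EXPECTED, abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        assert cohen_kappa(KAPPA_A, KAPPA_B).value == pytest.approx(
            cohen_kappa_score(KAPPA_A, KAPPA_B), abs=1e-12
        )

    def test_symmetry_and_label_permutation_invariance(self):
        assert cohen_kappa(KAPPA_B, KAPPA_A).value == pytest.approx(
            cohen_kappa(KAPPA_A, KAPPA_B).value, abs=1e-12
        )
        perm = {"pt": "gen", "gen": "cg", "O": "pt-gen"}
        a2 = [perm[x] for x in KAPPA_A]
        b2 = [perm[x] for x in KAPPA_B]
        assert cohen_kappa(a2, b2).value == pytest.approx(KAPPA_EXPECTED, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="token universes"):
            cohen_kappa(["O"], ["O", "O"])

    def test_token_kappa_on_corpus(self):
        post = Post("p1", "a1", "t1", datetime(2012, 1, 1, tzinfo=timezone.utc),
                    "My son tried risperdal")
        corpus = Corpus([post])
        span = MentionSpan("p1", 13, 22, "risperdal", "pt")
        r = token_kappa(corpus, [span], [span])
        assert r.value == 1.0
        r2 = token_kappa(corpus, [span], [])
        assert r2.value == 0.0  # one side all-O: no agreement beyond chance


@pytest.fixture(scope="module")
def tiny_grid(gazetteer):
    from forumrx.crf import TrainConfig
    from forumrx.synth import GeneratorConfig, generate

    cfg = GeneratorConfig(n_authors=12, posts_per_author=5, cue_ambiguity=0.0, seed=5)
    corpus, gold = generate(cfg)
    kwargs = dict(
        family_sets=[["lexical"]],
        systems=("crf", "baseline", "baseline_plus"),
        regimes=REGIMES,
        gazetteers=(gazetteer,),
        test_fraction=0.3,
        seed=3,
        train_config=TrainConfig(max_iterations=40),
    )
    return corpus, gold, kwargs


class TestAblationRun:
    def test_grid_shape_and_shared_span_property(self, tiny_grid):
        corpus, gold, kwargs = tiny_grid
        df = ablation_run(corpus, gold, **kwargs)
        assert set(df["system"]) == {"crf", "baseline", "baseline_plus"}
        assert set(df["regime"]) == set(REGIMES)
        crf_m = df[(df.system == "crf") & (df.regime == "mention_only") & (df["class"] == "micro")]
        plus_m = df[(df.system == "baseline_plus") & (df.regime == "mention_only") & (df["class"] == "micro")]
        assert crf_m["f1"].iloc[0] == plus_m["f1"].iloc[0]

    def test_mention_f_bounds_five_class_micro(self, tiny_grid):
        corpus, gold, kwargs = tiny_grid
        df = ablation_run(corpus, gold, **kwargs)
        for system in ("crf", "baseline", "baseline_plus"):
            m = df[(df.system == system) & (df.regime == "mention_only") & (df["class"] == "micro")]["f1"].iloc[0]
            five = df[(df.system == system) & (df.regime == "five_class") & (df["class"] == "micro")]["f1"].iloc[0]
            assert m >= five - 1e-12

    def test_rerun_identical(self, tiny_grid):
        corpus, gold, kwargs = tiny_grid
        df1 = ablation_run(corpus, gold, **kwargs)
        df2 = ablation_run(corpus, gold, **kwargs)
        assert df1.equals(df2)


class TestSplitPosts:
    def test_partition_and_determinism(self, small_synth):
        corpus, _ = small_synth
        tr1, te1 = split_posts(corpus, 0.3, seed=1)
        tr2, te2 = split_posts(corpus, 0.3, seed=1)
        assert [p.post_id for p in tr1] == [p.post_id for p in tr2]
        ids = sorted([p.post_id for p in tr1] + [p.post_id for p in te1])
        assert ids == sorted(p.post_id for p in corpus)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_posts(Corpus([]), 0.3, seed=0)
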