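"""Synthetic generators: determinism, invariants, planted structure."""

import io

import numpy as np
import pytest
from scipy import stats

from stslens import (
    BiasConfig,
    CorpusConfig,
    ModelSpec,
    Planting,
    ValidationError,
    generate_activations,
    generate_corpus,
    generate_predictions,
    jaccard_distance,
)
from stslens.data import count_tokens, write_pairs_tsv
from stslens.features import pair_loss
from stslens.probing import fit_probe_cv
from stslens.representations import build_all


class TestCorpus:
    def test_sizes_and_default_scale(self):
        cfg = CorpusConfig()
        assert (cfg.n_train, cfg.n_test) == (1642, 412)
        c = generate_corpus(CorpusConfig(n_train=25, n_test=9), seed=0)
        assert len(c.train) == 25 and len(c.test) == 9

    def test_same_seed_same_corpus_bytes(self):
        cfg = CorpusConfig(n_train=30, n_test=15)
        bufs = []
        for _ in range(2):
            c = generate_corpus(cfg, seed=7)
            buf = io.StringIO()
            write_pairs_tsv(c.train + c.test, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seed_differs(self):
        cfg = CorpusConfig(n_train=10, n_test=5)
        a = generate_corpus(cfg, seed=1)
        b = generate_corpus(cfg, seed=2)
        assert any(
            x.tokens_a != y.tokens_a for x, y in zip(a.train, b.train)
        )

    def test_vocab_recount_and_scores_on_levels(self, small_corpus):
        small_corpus.validate()
        assert small_corpus.vocab == count_tokens(small_corpus.train)
        levels = set(CorpusConfig().score_levels)
        assert {p.score for p in small_corpus.test} <= levels

    def test_pair_token_budget(self, small_corpus):
        assert all(p.n_tokens <= 125 for p in small_corpus.train + small_corpus.test)

    def test_overlap_coupling_plants_jaccard_score_relation(self):
        c = generate_corpus(
            CorpusConfig(
                n_train=10, n_test=412, overlap_coupling=1.0, overlap_jitter=0.0
            ),
            seed=11,
        )
        j = [jaccard_distance(p.tokens_a, p.tokens_b) for p in c.test]
        s = [p.score for p in c.test]
        assert stats.spearmanr(j, s).statistic <= -0.9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            CorpusConfig(n_train=0)
        with pytest.raises(ValidationError):
            CorpusConfig(score_levels=())
        with pytest.raises(ValidationError):
            CorpusConfig(overlap_coupling=1.5)


class TestPredictions:
    def test_zero_bias_zero_noise_equals_gold(self, small_corpus):
        ps = generate_predictions(
            small_corpus, BiasConfig(0.0, 0.0, 0.0), seed=0
        )
        total = sum(
            pair_loss(ps.predictions[p.pair_id], p.score)
            for p in small_corpus.test
        )
        assert total == pytest.approx(0.0, abs=1e-24)

    def test_additive_bias_gives_squared_loss_for_interior_scores(self, small_corpus):
        c = 0.25
        ps = generate_predictions(small_corpus, BiasConfig(0.0, c, 0.0), seed=0)
        for p in small_corpus.test:
            if c <= p.score <= 5 - c:  # away from clipping
                assert pair_loss(ps.predictions[p.pair_id], p.score) == pytest.approx(c * c)

    def test_overlap_bias_raises_loss_of_high_overlap_low_score_pairs(self):
        # at the score floor only upward (over-prediction) errors survive
        # clipping, so the overlap bias shows directly in the group means
        corpus = generate_corpus(CorpusConfig(n_train=40, n_test=412), seed=5)
        ps = generate_predictions(
            corpus, BiasConfig(overlap_bias_strength=1.5, additive_bias=0.0, noise_sd=0.25),
            seed=5,
        )
        low = [p for p in corpus.test if p.score == 0.0]
        j = np.array([jaccard_distance(p.tokens_a, p.tokens_b) for p in low])
        loss = np.array(
            [pair_loss(ps.predictions[p.pair_id], p.score) for p in low]
        )
        med = np.median(j)
        assert loss[j < med].mean() > loss[j > med].mean()

    def test_every_test_pair_predicted_once_in_range(self, small_corpus):
        ps = generate_predictions(small_corpus, BiasConfig(), seed=3)
        assert set(ps.predictions) == {p.pair_id for p in small_corpus.test}
        vals = np.array(list(ps.predictions.values()))
        assert ((vals >= 0) & (vals <= 5)).all()


class TestActivations:
    def test_layouts_place_special_tokens(self, small_corpus):
        pair = small_corpus.test[0]
        for layout, cls_pos in (("cls_first", 0), ("cls_last", -1)):
            spec = ModelSpec("m", 2, 8, layout)
            acts = generate_activations([pair], spec, seed=0)
            segs = acts.pairs[pair.pair_id].segments
            assert segs[cls_pos] == "CLS"
            assert segs.count("CLS") == 1 and segs.count("SEP") == 2
            assert len(segs) == pair.n_tokens + 3

    def test_token_count_constant_across_layers(self, small_corpus, tiny_model_spec):
        acts = generate_activations(small_corpus.test[:5], tiny_model_spec, seed=1)
        for pa in acts.pairs.values():
            assert pa.tensor.shape == (12, len(pa.segments), 16)

    def test_deterministic_per_seed(self, small_corpus, tiny_model_spec):
        a = generate_activations(small_corpus.test[:4], tiny_model_spec, seed=9)
        b = generate_activations(small_corpus.test[:4], tiny_model_spec, seed=9)
        for pid in a.pairs:
            np.testing.assert_array_equal(a.pairs[pid].tensor, b.pairs[pid].tensor)

    def test_planting_validation(self, small_corpus, tiny_model_spec):
        with pytest.raises(ValidationError):
            Planting(3, "not_a_rep", 1.0)
        with pytest.raises(ValidationError):
            generate_activations(
                small_corpus.test[:2], tiny_model_spec,
                [Planting(13, "cls", 1.0)], seed=0,
            )

    def test_noise_free_cls_plant_is_perfectly_decodable(self, small_corpus):
        spec = ModelSpec("m", 4, 16, "cls_first")
        acts = generate_activations(
            small_corpus.test, spec, [Planting(2, "cls", 200.0)], seed=4
        )
        table = build_all(acts, [2], ["cls"])
        gold = {p.pair_id: p.score for p in small_corpus.test}
        y = np.array([gold[pid] for pid in table.pair_ids])
        _, r = fit_probe_cv(table.matrix("cls", 2), y, folds=10, seed=0)
        assert r >= 0.999

    def test_probe_monotone_in_signal_strength(self, small_corpus):
        spec = ModelSpec("m", 3, 16, "cls_first")
        gold = {p.pair_id: p.score for p in small_corpus.test}
        rs = []
        for s in [0.0, 0.5, 1.0, 2.0, 4.0]:
            acts = generate_activations(
                small_corpus.test, spec, [Planting(2, "cls", s)], seed=9
            )
            table = build_all(acts, [2], ["cls"])
            y = np.array([gold[pid] for pid in table.pair_ids])
            _, r = fit_probe_cv(table.matrix("cls", 2), y, folds=10, seed=0)
            rs.append(r)
        assert all(b >= a for a, b in zip(rs, rs[1:]))

    def test_unplanted_probe_correlations_match_permutation_null(self, small_corpus):
        spec = ModelSpec("m", 6, 8, "cls_first")
        acts = generate_activations(small_corpus.test, spec, seed=13)
        table = build_all(acts, range(1, 7))
        gold = {p.pair_id: p.score for p in small_corpus.test}
        y = np.array([gold[pid] for pid in table.pair_ids])
        observed = []
        for key, mat in table.values.items():
            _, r = fit_probe_cv(mat, y, folds=5, seed=0)
            observed.append(abs(r))
        # permutation null on one representative feature matrix
        null_rng = np.random.default_rng(0)
        null = []
        base = table.matrix("cls", 3)
        for _ in range(100):
            yp = null_rng.permutation(y)
            _, r = fit_probe_cv(base, yp, folds=5, seed=0)
            null.append(abs(r))
        cutoff = np.quantile(null, 0.975)
        frac_below = np.mean(np.array(observed) < cutoff)
        assert frac_below >= 0.9
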