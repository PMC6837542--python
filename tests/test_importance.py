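"""Shuffle-based feature importance: normalisation, degenerate cases,
exchangeability, and the ignored-feature contract."""

import numpy as np
import pytest

from crisprattn.errors import ValidationError
from crisprattn.importance import perturbation_importance, plot_importance
from crisprattn.models import ModelConfig, build_model
from crisprattn.training import TrainConfig, train_model


@pytest.fixture(scope="module")
def trained_regressor():
    rng = np.random.default_rng(42)
    toks = rng.integers(0, 16, size=(150, 19))
    extra = rng.normal(size=(150, 1))
    y = 0.5 * toks[:, 4] + 2.0 * extra[:, 0] + rng.normal(0, 0.2, 150)
    cfg = ModelConfig.compact(max_len=19, task="regress", n_extra_features=1, seed=7)
    model = build_model("attn_crispr", cfg)
    tcfg = TrainConfig(epochs=12, batch_size=32, val_fraction=0.1, seed=7)
    train_model(model, toks, y, extra=extra, cfg=tcfg)
    return model, toks, extra, y


class TestNormalisation:
    def test_scores_sum_to_one(self, trained_regressor):
        model, toks, extra, y = trained_regressor
        rep = perturbation_importance(
            model, toks[:60], y[:60], extra=extra[:60], extra_names=["NetExpress"],
            n_repeats=5, seed=0,
        )
        assert rep.normalized_scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert (rep.raw_scores >= 0).all()
        assert rep.feature_names[-1] == "NetExpress"
        assert len(rep.feature_names) == 20

    def test_single_sample_scores_uniform(self, trained_regressor):
        model, toks, extra, y = trained_regressor
        rep = perturbation_importance(
            model, toks[:1], y[:1], extra=extra[:1], extra_names=["NetExpress"],
            n_repeats=3, seed=0,
        )
        # permutation of one sample is the identity: every raw score is the
        # baseline loss, so normalised scores are uniform
        assert np.allclose(rep.raw_scores, rep.baseline_loss)
        assert np.allclose(rep.normalized_scores, 1.0 / len(rep.feature_names))


class TestInformativeFeatures:
    def test_planted_features_rank_high(self, trained_regressor):
        model, toks, extra, y = trained_regressor
        rep = perturbation_importance(
            model, toks, y, extra=extra, extra_names=["NetExpress"],
            n_repeats=10, seed=1,
        )
        assert "NetExpress" in rep.top(2)
        assert "dimer_4" in rep.top(3)

    def test_ignored_feature_scores_baseline_loss(self, trained_regressor):
        model, toks, extra, y = trained_regressor
        # sever the covariate input: zero every first-layer weight row that
        # reads the extra feature column (last input column of the FC head)
        saved = model.head.hidden[0].weight.data.copy()
        model.head.hidden[0].weight.data[-1, :] = 0.0
        try:
            rep = perturbation_importance(
                model, toks[:80], y[:80], extra=extra[:80], extra_names=["NetExpress"],
                n_repeats=5, seed=2,
            )
            i = rep.feature_names.index("NetExpress")
            assert rep.raw_scores[i] == pytest.approx(rep.baseline_loss, rel=1e-12)
            assert rep.normalized_scores[i] == rep.normalized_scores.min()
        finally:
            model.head.hidden[0].weight.data = saved

    def test_exchangeable_features_converge_to_common_value(self):
        # untrained model, pure-noise labels: every token column is
        # exchangeable, so importances converge to a common value
        rng = np.random.default_rng(0)
        toks = rng.integers(0, 16, size=(40, 10))
        y = rng.normal(size=40)
        cfg = ModelConfig.compact(max_len=10, task="regress", seed=0)
        model = build_model("attn_crispr", cfg).eval()
        rep = perturbation_importance(model, toks, y, n_repeats=200, seed=3)
        spread = rep.normalized_scores.max() - rep.normalized_scores.min()
        assert spread < 0.02  # ~3 s.e. at 200 repeats for this model


class TestPlotting:
    def test_bar_chart_written(self, trained_regressor, tmp_path):
        model, toks, extra, y = trained_regressor
        rep = perturbation_importance(
            model, toks[:30], y[:30], extra=extra[:30], extra_names=["NetExpress"],
            n_repeats=2, seed=0,
        )
        out = plot_importance(rep, tmp_path / "imp.png")
        assert out.exists() and out.stat().st_size > 0

    def test_empty_report_rejected(self):
        from crisprattn.importance import ImportanceReport

        with pytest.raises(ValidationError):
            ImportanceReport(
                feature_names=[],
                raw_scores=np.array([]),
                normalized_scores=np.array([]),
                n_repeats=1,
                seed=0,
                baseline_loss=0.0,
            )
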