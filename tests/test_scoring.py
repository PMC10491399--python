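"""Quantile log-odds guide scores, gene means, and matched empirical nulls."""

import numpy as np
import pandas as pd
import pytest

from chemoscreen import (
    ConfigurationError,
    ScoreParams,
    SimConfig,
    ValidationError,
    essentiality_from_control,
    gene_score,
    guide_log_ratios,
    guide_scores,
    matched_null_pvalue,
    score_screen,
    simulate_screen,
)
from chemoscreen.guide_stats import essentiality_index
from conftest import make_library


def _gst(log_ratios, genes=None):
    n = len(log_ratios)
    genes = genes or [f"G{i}" for i in range(n)]
    return pd.DataFrame({"gene": genes, "log_ratio": log_ratios},
                        index=[f"sg{i}" for i in range(n)])


class TestGuideScores:
    def test_median_guide_scores_zero(self):
        s = guide_scores(_gst(list(range(11))))
        assert s.iloc[5] == pytest.approx(0.0)

    def test_most_depleted_of_999(self):
        s = guide_scores(_gst(list(range(999))))
        assert s.iloc[0] == pytest.approx(-np.log(999))
        assert s.iloc[-1] == pytest.approx(np.log(999))

    def test_negating_ratios_negates_scores(self):
        rng = np.random.default_rng(0)
        lr = rng.normal(size=51)
        np.testing.assert_allclose(guide_scores(_gst(lr)),
                                   -guide_scores(_gst(-lr)), atol=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        lr = rng.normal(size=40)
        np.testing.assert_allclose(guide_scores(_gst(lr)),
                                   guide_scores(_gst(np.exp(lr))))

    def test_ties_get_midrank_scores(self):
        s = guide_scores(_gst([0.0] * 5 + [1.0] * 6))
        assert s.iloc[:5].nunique() == 1
        assert s.iloc[0] < 0 < s.iloc[-1]

    def test_small_library_rejected(self):
        with pytest.raises(ValidationError):
            guide_scores(_gst([1.0] * 9))


class TestGeneScore:
    def test_mean_of_guides(self):
        lib = make_library({"A": 2, "B": 1})
        scores = pd.Series([-2.0, -4.0, 5.0],
                           index=["A_sg1", "A_sg2", "B_sg1"])
        gs = gene_score(scores, lib)
        assert gs["A"] == -3.0
        assert gs["B"] == 5.0  # single-guide gene keeps its guide's score

    def test_symmetric_quantiles_cancel(self):
        lib = make_library({"A": 2, "F": 9})
        lr = _gst(list(range(11)), genes=["A"] + ["F"] * 9 + ["A"])
        s = guide_scores(lr)
        s.index = ["A_sg1"] + [f"F_sg{i}" for i in range(1, 10)] + ["A_sg2"]
        assert gene_score(s, lib)["A"] == pytest.approx(0.0)

    def test_control_genes_excluded(self):
        lib = make_library({"A": 2, "CTRL": 1}, control_genes=("CTRL",))
        scores = pd.Series([1.0, 2.0, 9.0],
                           index=["A_sg1", "A_sg2", "CTRL_sg1"])
        assert list(gene_score(scores, lib).index) == ["A"]


class TestMatchedNull:
    def _library_scores(self, n_genes=50, k=4, seed=0):
        rng = np.random.default_rng(seed)
        lib = make_library({f"G{i}": k for i in range(n_genes)})
        scores = pd.Series(rng.normal(size=n_genes * k), index=lib.guide_ids)
        ess = essentiality_index(
            pd.Series(rng.normal(size=n_genes),
                      index=[f"G{i}" for i in range(n_genes)]), n_bins=5)
        return lib, scores, ess

    def test_add_one_floor(self):
        lib, scores, ess = self._library_scores()
        scores.iloc[lib.guide_indices["G0"]] = 100.0  # beyond every null draw
        p = matched_null_pvalue("G0", scores, lib, ess, n_resamples=9999, seed=1)
        assert p == pytest.approx(1e-4)

    def test_p_never_zero_and_bounded(self):
        lib, scores, ess = self._library_scores()
        for g in ("G1", "G2", "G3"):
            p = matched_null_pvalue(g, scores, lib, ess, n_resamples=199, seed=2)
            assert 1 / 200 <= p <= 1.0

    def test_unmatched_uses_library_wide_pool(self):
        lib, scores, ess = self._library_scores()
        p = matched_null_pvalue("G1", scores, lib, None, n_resamples=199, seed=3)
        assert 0 < p <= 1

    def test_exchangeable_gene_p_is_moderate(self):
        # a gene whose guides are a random draw from its own pool should not
        # look extreme under any seed
        lib, scores, ess = self._library_scores(seed=4)
        ps = [matched_null_pvalue("G5", scores, lib, ess, n_resamples=499, seed=s)
              for s in range(5)]
        assert min(ps) > 0.001

    def test_too_few_resamples_rejected(self):
        lib, scores, ess = self._library_scores()
        with pytest.raises(ConfigurationError):
            matched_null_pvalue("G0", scores, lib, ess, n_resamples=10)

    def test_sparse_bin_falls_back_to_adjacent(self, caplog):
        # 5 bins over 10 genes of 8 guides: a bin holds ~16 eligible guides,
        # below 5*k = 40, so the pool must widen to adjacent bins
        rng = np.random.default_rng(5)
        lib = make_library({f"G{i}": 8 for i in range(10)})
        scores = pd.Series(rng.normal(size=80), index=lib.guide_ids)
        ess = essentiality_index(
            pd.Series(rng.normal(size=10), index=[f"G{i}" for i in range(10)]),
            n_bins=5)
        with caplog.at_level("INFO"):
            p = matched_null_pvalue("G0", scores, lib, ess,
                                    n_resamples=199, seed=6)
        assert 0 < p <= 1
        assert any("widened" in r.message for r in caplog.records)


@pytest.fixture(scope="module")
def small_screen():
    cfg = SimConfig(n_genes=60, n_control_guides=20, frac_essential=0.2,
                    n_enhancers=4, interaction_effect=0.5, seed=21)
    cm, lib, truth = simulate_screen(cfg)
    ess = essentiality_from_control(cm, lib, screen_id="S1", n_bins=5)
    return cm, lib, truth, ess


class TestScoreScreen:
    def test_deterministic_given_seed(self, small_screen):
        cm, lib, _, ess = small_screen
        params = ScoreParams(seed=42, n_resamples=199)
        r1 = score_screen(cm, lib, ess, params, screen_id="S1")
        r2 = score_screen(cm, lib, ess, params, screen_id="S1")
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_enhancers_rank_most_negative(self, small_screen):
        cm, lib, truth, ess = small_screen
        params = ScoreParams(seed=42, n_resamples=199)
        res = score_screen(cm, lib, ess, params, screen_id="S1")
        top4 = set(res.nsmallest(4, "score")["gene"])
        assert top4 == set(truth.genes_in_class("enhancer"))

    def test_result_schema(self, small_screen):
        cm, lib, _, ess = small_screen
        res = score_screen(cm, lib, ess, ScoreParams(seed=1, n_resamples=199),
                           screen_id="S1")
        assert list(res.columns) == ["gene", "score", "p_value", "n_guides",
                                     "screen_id"]
        assert (res["n_guides"] == 10).all()
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()
        assert len(res) == 60  # control pseudo-gene excluded
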