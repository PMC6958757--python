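"""Curation: quality filter, ICC, matching, distributions, export."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fexpr import (MatchingError, export_model_table, icc, label_distribution,
                   matched_subgroup, quality_filter, read_corpus, write_corpus)
from fexpr.landmarks import EMOTIONS

from conftest import toy_corpus


def icc2_oracle(table: np.ndarray) -> float:
    """Closed-form two-way random, absolute-agreement, single-rater ICC.

    Mean-squares formulation: ICC(2,1) = (MSR - MSE) /
    (MSR + (k-1) MSE + k (MSC - MSE) / n) for n targets and k raters.
    """
    t = np.asarray(table, dtype=float)
    n, k = t.shape
    grand = t.mean()
    row_means = t.mean(axis=1)
    col_means = t.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((t - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def ratings_from_table(table: np.ndarray, emotion: str = "happiness"):
    rows = []
    for v, scores in enumerate(table):
        for j, s in enumerate(scores):
            rows.append({"video_id": f"v{v}", "judge_id": f"judge{j}",
                         "emotion": emotion, "score": s})
    return pd.DataFrame(rows)


class TestQualityFilter:
    def test_unanimous_eights_retained_at_threshold_seven(self):
        corpus = toy_corpus({"v0": [8, 8, 8]})
        assert quality_filter(corpus, 7).video_ids == ["v0"]

    def test_mean_exactly_seven_is_excluded(self):
        # strictly-greater-than rule
        corpus = toy_corpus({"v0": [7, 7, 7], "v1": [6, 7, 8]})
        assert len(quality_filter(corpus, 7)) == 0

    def test_counts_on_graded_means(self):
        # means 3..10 including 7 and 7.5: exactly the five means > 7 survive
        scores = {"v0": [3, 3, 3], "v1": [4, 4, 4], "v2": [5, 5, 5],
                  "v3": [6, 6, 6], "v4": [7, 7, 7], "v5": [7, 8, 8],
                  "v6": [8, 8, 8], "v7": [9, 9, 9], "v8": [9, 9, 9],
                  "v9": [10, 10, 10]}
        corpus = toy_corpus(scores)
        assert len(quality_filter(corpus, 7)) == 5

    def test_idempotent(self):
        corpus = toy_corpus({f"v{i}": [i, i, i] for i in range(11)})
        once = quality_filter(corpus, 7)
        twice = quality_filter(once, 7)
        assert once.video_ids == twice.video_ids

    @given(st.lists(st.integers(0, 10), min_size=2, max_size=8))
    def test_monotone_in_threshold(self, thresholds):
        corpus = toy_corpus({f"v{i}": [i, i + 1 if i < 10 else i, i]
                             for i in range(11)})
        kept = [len(quality_filter(corpus, t)) for t in sorted(thresholds)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_subjects_without_videos_are_dropped(self):
        corpus = toy_corpus({"v0": [9, 9, 9], "v1": [2, 2, 2]})
        kept = quality_filter(corpus, 7)
        assert list(kept.subjects["subject_id"]) == ["s-v0"]

    def test_empty_ratings_rejected(self):
        corpus = toy_corpus({"v0": [8, 8, 8]})
        corpus.ratings = corpus.ratings.iloc[0:0]
        with pytest.raises(ValueError):
            quality_filter(corpus, 7)


class TestICC:
    def test_perfect_agreement_gives_one(self):
        table = np.array([[1, 1, 1], [4, 4, 4], [7, 7, 7], [10, 10, 10]])
        assert icc(ratings_from_table(table), "happiness") == pytest.approx(1.0)

    def test_independent_ratings_give_near_zero(self):
        rng = np.random.default_rng(0)
        table = rng.integers(0, 11, size=(200, 3))
        assert abs(icc(ratings_from_table(table), "happiness")) < 0.1

    def test_worked_table_matches_mean_squares_oracle(self):
        table = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2]])
        expected = icc2_oracle(table)
        got = icc(ratings_from_table(table), "happiness")
        assert got == pytest.approx(expected, abs=1e-10)

    def test_relabelling_judges_leaves_icc_unchanged(self):
        rng = np.random.default_rng(1)
        table = rng.integers(0, 11, size=(30, 3))
        a = icc(ratings_from_table(table), "happiness")
        b = icc(ratings_from_table(table[:, ::-1]), "happiness")
        assert b == pytest.approx(a, abs=1e-12)

    def test_duplicating_judges_barely_moves_high_agreement_icc(self):
        # the single-rater ICC is a per-judge quantity: cloning every judge
        # shifts only the degrees of freedom, so high-agreement tables move
        # very little
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 10, 40)
        table = np.clip(np.round(v[:, None] + rng.normal(0, 1, (40, 3))),
                        0, 10)
        a = icc(ratings_from_table(table), "happiness")
        b = icc(ratings_from_table(np.hstack([table, table])), "happiness")
        assert a > 0.8
        assert b == pytest.approx(a, abs=0.05)

    def test_zero_variance_defined_as_zero_with_warning(self):
        table = np.full((5, 3), 6)
        with pytest.warns(RuntimeWarning):
            assert icc(ratings_from_table(table), "happiness") == 0.0

    def test_too_few_judges_rejected(self):
        table = np.array([[1], [2], [3]])
        with pytest.raises(ValueError):
            icc(ratings_from_table(table), "happiness")


@pytest.fixture(scope="module")
def match_corpus():
    from fexpr import (AMBIGUOUS_GROUP, CLEAR_GROUP, CorpusConfig,
                       Demographics, GroupSpec, generate_corpus)

    demo = Demographics(age_range=(6, 12), p_male=0.6, p_site_a=0.5)
    cfg = CorpusConfig(
        groups=(GroupSpec("clear", CLEAR_GROUP, 60, demo,
                          videos_per_subject=(8, 14)),
                GroupSpec("ambiguous", AMBIGUOUS_GROUP, 8, demo,
                          videos_per_subject=(2, 5))),
        render=False, seed=17)
    return generate_corpus(cfg)


class TestMatchedSubgroup:
    def test_self_matching_returns_reference(self, small_corpus):
        sub = matched_subgroup(small_corpus, "ambiguous",
                               source_group="ambiguous", seed=0)
        ref = small_corpus.group("ambiguous")
        assert sorted(sub.video_ids) == sorted(ref.video_ids)

    def test_margins_and_label_profile_match_reference(self, match_corpus):
        ref = match_corpus.group("ambiguous")
        sub = matched_subgroup(match_corpus, "ambiguous", seed=1)
        assert set(sub.subjects["group"]) == {"clear"}
        assert len(sub.subjects) == len(ref.subjects)
        ref_m = ref.subjects.groupby(["gender", "site"]).size()
        sub_m = sub.subjects.groupby(["gender", "site"]).size()
        pd.testing.assert_series_equal(ref_m, sub_m)
        ref_e = ref.metadata()["target_emotion"].value_counts()
        sub_e = sub.metadata()["target_emotion"].value_counts()
        pd.testing.assert_series_equal(ref_e.sort_index(), sub_e.sort_index())
        # matched ages within the 1-year caliper on average
        assert abs(ref.subjects["age"].mean() - sub.subjects["age"].mean()) <= 1.0

    def test_infeasible_matching_names_the_subject(self, small_corpus):
        bad = small_corpus.subset(small_corpus.video_ids)
        bad.subjects.loc[bad.subjects["group"] == "ambiguous", "age"] = 99
        with pytest.raises(MatchingError, match="ambiguous-s"):
            matched_subgroup(bad, "ambiguous", seed=0)


class TestLabelDistribution:
    def test_reference_group_profile(self):
        counts = {"neutral": 677, "happiness": 525, "anger": 397,
                  "sadness": 246}
        scores = {}
        i = 0
        for e, n in counts.items():
            for _ in range(n):
                scores[f"{e}{i}"] = e
                i += 1
        corpus = toy_corpus({v: [8, 8, 8] for v in scores})
        for f in corpus.frames:
            f.target_emotion = scores[f.video_id]
        table = label_distribution(corpus).set_index("emotion")
        assert table.loc["neutral", "count"] == 677
        assert table.loc["happiness", "count"] == 525
        assert table.loc["anger", "count"] == 397
        assert table.loc["sadness", "count"] == 246
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_counts_conserve_group_sizes(self, small_corpus):
        table = label_distribution(small_corpus)
        meta = small_corpus.metadata()
        for g, sub in table.groupby("group"):
            assert sub["count"].sum() == (meta["group"] == g).sum()

    def test_emotion_absent_from_a_group_gets_explicit_zero(self):
        corpus = toy_corpus({"v0": [8, 8, 8]}, emotion="anger")
        table = label_distribution(corpus).set_index("emotion")
        assert table.loc["sadness", "count"] == 0


class TestExportModelTable:
    def test_score_is_mean_judge_rating(self):
        corpus = toy_corpus({"v0": [6, 7, 8]})
        table = export_model_table(corpus)
        assert table.loc["v0", "score"] == pytest.approx(7.0)

    def test_one_row_per_video_and_roundtrip(self, small_corpus, tmp_path):
        path = tmp_path / "model_table.csv"
        table = export_model_table(small_corpus, path)
        assert len(table) == len(small_corpus)
        back = pd.read_csv(path, index_col="video_id")
        pd.testing.assert_frame_equal(back, table, check_dtype=False)
        assert list(table.columns) == ["score", "age", "gender", "order",
                                       "task", "modality", "emotion", "site",
                                       "group", "subject_id"]


class TestCorpusIO:
    def test_directory_roundtrip_preserves_data(self, small_corpus, tmp_path):
        sub = small_corpus.subset(small_corpus.video_ids[:8])
        out = write_corpus(sub, tmp_path / "corpus")
        back = read_corpus(out)
        assert back.video_ids == sub.video_ids
        for fa, fb in zip(sub.frames, back.frames):
            np.testing.assert_allclose(fb.landmarks, fa.landmarks)
            np.testing.assert_array_equal(fb.image, fa.image)
        a = sub.ratings.sort_values(["video_id", "judge_id", "emotion"])
        b = back.ratings.sort_values(["video_id", "judge_id", "emotion"])
        np.testing.assert_array_equal(a["score"].to_numpy(),
                                      b["score"].to_numpy())
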