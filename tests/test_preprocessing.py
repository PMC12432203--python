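import numpy as np
import pandas as pd
import pytest

from flustim.preprocessing import (
    TrialTableError,
    code_figural_accuracy,
    code_fluency_accuracy,
    compute_rts,
    executive_composite,
    outlier_filter,
    parse_bars,
    read_trials,
)


def _trials(rows):
    base = {
        "participant": "P01", "session": 1, "condition": "sham",
        "task": "semantic_fluency", "item": "animals", "trial_index": 1,
        "response": "dog", "onset": 0.0, "offset": 0.0, "correct": None,
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d["trial_index"] = i + 1
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


class TestComputeRts:
    def test_semantic_rt_is_onset_minus_previous_offset(self):
        df = _trials([
            {"onset": 9.0, "offset": 10.0},
            {"onset": 11.5, "offset": 12.0},
        ])
        rts, flagged = compute_rts(df, "semantic_fluency")
        assert rts["rt"].tolist() == [1.5]
        assert flagged["reason"].tolist() == ["first-item (no preceding offset)"]

    def test_single_item_category_yields_no_rt(self):
        rts, _ = compute_rts(_trials([{"onset": 1.0, "offset": 2.0}]),
                             "semantic_fluency")
        assert rts.empty

    def test_categories_do_not_chain_across(self):
        df = _trials([
            {"item": "a", "onset": 1.0, "offset": 2.0},
            {"item": "b", "onset": 5.0, "offset": 6.0},
        ])
        rts, _ = compute_rts(df, "semantic_fluency")
        assert rts.empty  # each category has a single (first) item

    def test_picture_naming_interval(self):
        df = _trials([{"task": "picture_naming", "onset": 3.0, "offset": 3.8}])
        rts, _ = compute_rts(df, "picture_naming")
        assert rts["rt"].tolist() == [pytest.approx(0.8)]

    def test_negative_rt_flagged(self):
        df = _trials([
            {"onset": 1.0, "offset": 5.0},
            {"onset": 4.0, "offset": 6.0},  # onset before previous offset
        ])
        rts, flagged = compute_rts(df, "semantic_fluency")
        assert rts.empty
        assert "negative RT" in flagged["reason"].tolist()


class TestOutlierFilter:
    @staticmethod
    def _group(rts):
        return pd.DataFrame({
            "rt": rts, "participant": "P01", "session": 1,
            "task": "semantic_fluency", "item": "animals",
        })

    def test_worked_twenty_trial_group(self):
        rts = [1.0] * 19 + [10.0]
        kept, report = outlier_filter(self._group(rts))
        # oracle: direct mean/SD computation
        mean, sd = np.mean(rts), np.std(rts, ddof=1)
        assert 10.0 >= mean + 3 * sd > 1.0
        assert report.n_removed == 1
        assert kept["rt"].tolist() == [1.0] * 19

    def test_identical_values_untouched(self):
        kept, report = outlier_filter(self._group([2.0] * 10))
        assert report.n_removed == 0 and len(kept) == 10

    def test_tiny_group_passes_through(self):
        kept, report = outlier_filter(self._group([1.0, 100.0]))
        assert report.n_removed == 0 and len(kept) == 2

    def test_never_removes_below_group_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "rt": rng.exponential(1.0, 500),
            "participant": rng.integers(0, 5, 500),
            "session": 1, "task": "t", "item": rng.integers(0, 3, 500),
        })
        kept, _ = outlier_filter(df)
        removed = df.loc[df.index.difference(kept.index)]
        means = df.groupby(["participant", "item"])["rt"].mean()
        for r in removed.itertuples():
            assert r.rt > means.loc[(r.participant, r.item)]

    def test_missing_group_column_error(self):
        with pytest.raises(TrialTableError):
            outlier_filter(pd.DataFrame({"rt": [1.0]}))


class TestFluencyAccuracy:
    def test_repetitions_marked_incorrect(self):
        df = _trials([{"response": r} for r in ["dog", "cat", "dog"]])
        out = code_fluency_accuracy(df)
        assert out["correct"].tolist() == [True, True, False]

    def test_case_folded_repetition(self):
        df = _trials([{"response": "dog"}, {"response": " Dog "}])
        assert code_fluency_accuracy(df)["correct"].tolist() == [True, False]

    def test_all_distinct_all_correct(self):
        df = _trials([{"response": r} for r in ["dog", "cat", "owl"]])
        assert code_fluency_accuracy(df)["correct"].all()

    def test_membership_list_marks_intrusions(self):
        df = _trials([{"response": "dog"}, {"response": "table"}])
        out = code_fluency_accuracy(df, category_members={"animals": ["dog", "cat"]})
        assert out["correct"].tolist() == [True, False]

    def test_proper_names_marked_incorrect(self):
        df = _trials([{"response": "dog"}, {"response": "Rex"}])
        out = code_fluency_accuracy(df, proper_names=["rex"])
        assert out["correct"].tolist() == [True, False]


class TestFiguralAccuracy:
    @staticmethod
    def _designs(bar_strings):
        return pd.DataFrame({
            "participant": "P01", "session": 1, "item": "arrA",
            "trial_index": range(1, len(bar_strings) + 1),
            "response": bar_strings,
        })

    def test_repeated_bar_set_incorrect(self):
        flags = code_figural_accuracy(self._designs(["1-2", "2-3", "1-2"]))
        assert flags.tolist() == [True, True, False]

    def test_bar_order_insensitive(self):
        flags = code_figural_accuracy(self._designs(["1-2;2-3", "2-3;1-2"]))
        assert flags.tolist() == [True, False]

    def test_bar_endpoint_order_insensitive(self):
        flags = code_figural_accuracy(self._designs(["1-2", "2-1"]))
        assert flags.tolist() == [True, False]

    def test_distinct_designs_all_correct(self):
        bars = [f"1-{d}" for d in range(2, 6)] + ["2-3;4-5"]
        assert code_figural_accuracy(self._designs(bars)).all()

    def test_unknown_dot_rejected(self):
        with pytest.raises(TrialTableError, match="outside arrangement"):
            code_figural_accuracy(
                self._designs(["1-9"]), arrangement_dots={"arrA": "12345"})

    def test_degenerate_bar_rejected(self):
        with pytest.raises(TrialTableError, match="malformed bar"):
            parse_bars("1-1")


class TestExecutiveComposite:
    def test_two_participant_oracle(self):
        df = pd.DataFrame({
            "participant": ["a", "b"],
            "tmt_seconds": [30.0, 50.0],
            "dsst_count": [60, 40],
            "stw_raw": [20, 30],
        })
        out = executive_composite(df)
        # hand z-scores with sample SD: inverted TMT [-30, -50] -> z = +/- 1/sqrt(2)
        assert out["executive_z"].tolist() == pytest.approx(
            [np.sqrt(0.5), -np.sqrt(0.5)])
        assert out["stw_z"].tolist() == pytest.approx(
            [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_cohort_mean_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "participant": [f"p{i}" for i in range(24)],
            "tmt_seconds": rng.uniform(20, 60, 24),
            "dsst_count": rng.integers(30, 80, 24),
            "stw_raw": rng.uniform(10, 40, 24),
        })
        out = executive_composite(df)
        assert abs(out["executive_z"].mean()) < 1e-10
        assert abs(out["stw_z"].mean()) < 1e-10
        assert out["stw_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_participant_at_cohort_mean_scores_zero(self):
        df = pd.DataFrame({
            "participant": ["a", "b", "c"],
            "tmt_seconds": [30.0, 40.0, 50.0],
            "dsst_count": [50, 60, 70],
            "stw_raw": [1, 2, 3],
        })
        out = executive_composite(df)
        assert out.loc[1, "executive_z"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_error_names_it(self):
        df = pd.DataFrame({
            "participant": ["a", "b"], "tmt_seconds": [30.0, 40.0],
            "dsst_count": [50, 50], "stw_raw": [1, 2],
        })
        with pytest.raises(ValueError, match="dsst"):
            executive_composite(df)


class TestReadTrials:
    def test_round_trip_and_validation(self, tmp_path, full_small_dataset):
        path = tmp_path / "trials.tsv"
        full_small_dataset.trials.to_csv(path, sep="\t", index=False)
        df = read_trials(path)
        assert len(df) == len(full_small_dataset.trials)

    def test_offset_before_onset_rejected(self, tmp_path):
        df = _trials([{"onset": 5.0, "offset": 4.0}])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(TrialTableError, match="offset precedes onset"):
            read_trials(path)

    def test_inconsistent_condition_mapping_rejected(self, tmp_path):
        df = _trials([{}, {"condition": "IFG"}])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(TrialTableError, match="multiple conditions"):
            read_trials(path)
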