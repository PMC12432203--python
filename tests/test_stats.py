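import warnings

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from flustim._glmm import SeparationError
from flustim.stats import (
    ModelError,
    ModelSpec,
    condition_contrasts,
    fdr_bh,
    fit_accuracy_model,
    fit_rt_model,
    fit_switch_count_model,
    simple_coding,
)

CONDITIONS = ("sham", "IFG", "preSMA", "dual")


def _spec(outcome, family, terms, levels=CONDITIONS):
    return ModelSpec(
        outcome=outcome, family=family, fixed_terms=terms,
        contrasts={"condition": (levels, "sham"),
                   "session": ((1, 2, 3, 4), 1),
                   "difficulty": (("easy", "difficult"), "easy")},
    )


class TestSimpleCoding:
    def test_two_levels(self):
        m = simple_coding(["sham", "IFG"], "sham")
        assert m.to_numpy().ravel().tolist() == [-0.5, 0.5]

    def test_four_levels_structure(self):
        m = simple_coding(CONDITIONS, "sham")
        arr = m.to_numpy()
        assert arr.shape == (4, 3)
        for j in range(3):
            col = sorted(arr[:, j])
            assert col[:3] == pytest.approx([-0.25] * 3)
            assert col[3] == pytest.approx(0.75)

    def test_intercept_is_grand_mean_in_balanced_fit(self):
        # balanced one-factor data, direct least squares
        m = simple_coding(["sham", "IFG", "preSMA"], "sham")
        levels = ["sham", "IFG", "preSMA"]
        y = np.array([1.0, 1.0, 3.0, 3.0, 8.0, 8.0])
        lv = ["sham", "sham", "IFG", "IFG", "preSMA", "preSMA"]
        X = np.column_stack([np.ones(6)] + [
            [m.loc[l, c] for l in lv] for c in m.columns])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert beta[0] == pytest.approx(4.0)  # mean of level means
        assert beta[1] == pytest.approx(3.0 - 1.0)  # IFG - sham

    def test_unknown_reference_rejected(self):
        with pytest.raises(ModelError):
            simple_coding(["a", "b"], "z")


class TestFdrBh:
    def test_worked_examples(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)
        assert fdr_bh([0.5]).tolist() == [0.5]
        assert fdr_bh([0.0, 0.0, 0.0]).tolist() == [0.0, 0.0, 0.0]
        assert fdr_bh([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 30)))
        expected = multipletests(p, method="fdr_bh")[1]
        assert fdr_bh(p) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_above_raw_over_m(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        adj = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p).all()


class TestRtModel:
    def test_noise_free_shift_recovered_exactly(self):
        df = pd.DataFrame({
            "rt": np.exp([1.0, 1.1] * 6),
            "condition": ["sham", "IFG"] * 6,
            "participant": np.repeat([f"p{i}" for i in range(6)], 2),
            "correct": True,
        })
        spec = _spec("log_rt", "gaussian_on_log", ["condition"], ("sham", "IFG"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_rt_model(df, spec)
        assert fit.coefficients["condition[IFG-sham]"] == pytest.approx(0.10, abs=1e-8)

    def test_only_correct_trials_enter(self):
        df = pd.DataFrame({
            "rt": np.exp([1.0, 1.1, 9.9, 9.9] * 6),
            "condition": ["sham", "IFG"] * 12,
            "participant": np.repeat([f"p{i}" for i in range(6)], 4),
            "correct": [True, True, False, False] * 6,
        })
        spec = _spec("log_rt", "gaussian_on_log", ["condition"], ("sham", "IFG"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_rt_model(df, spec)
        assert fit.n_obs == 12
        assert fit.coefficients["condition[IFG-sham]"] == pytest.approx(0.10, abs=1e-8)

    def test_null_coverage(self):
        rng = np.random.default_rng(0)
        inside = 0
        for _ in range(100):
            df = pd.DataFrame({
                "rt": np.exp(0.3 * rng.standard_normal(96)),
                "condition": list(CONDITIONS) * 24,
                "participant": np.repeat([f"p{i}" for i in range(24)], 4),
                "correct": True,
            })
            spec = _spec("log_rt", "gaussian_on_log", ["condition"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_rt_model(df, spec)
            est = fit.coefficients["condition[IFG-sham]"]
            se = fit.std_errors["condition[IFG-sham]"]
            inside += abs(est) <= 2 * se
        assert inside >= 93

    def test_rank_deficiency_reported(self):
        df = pd.DataFrame({
            "rt": np.exp(np.linspace(0.5, 1.5, 8)),
            "condition": ["sham", "IFG"] * 4,
            "participant": list("aabbccdd"),
            "clone": [0.0, 1.0] * 4,  # aliased with the condition contrast
            "correct": True,
        })
        spec = _spec("log_rt", "gaussian_on_log", ["condition", "clone"],
                     ("sham", "IFG"))
        with pytest.raises(ModelError, match="aliased"):
            fit_rt_model(df, spec)


class TestAccuracyModel:
    def test_null_condition_or_near_one(self):
        rng = np.random.default_rng(1)
        covered = 0
        for _ in range(100):
            rows = []
            for pi in range(24):
                b = 0.3 * rng.standard_normal()
                p = 1 / (1 + np.exp(-(1.5 + b)))
                for cond in CONDITIONS:
                    y = rng.random(15) < p
                    rows += [{"participant": f"p{pi}", "condition": cond,
                              "correct": bool(v)} for v in y]
            df = pd.DataFrame(rows)
            spec = _spec("binary_correct", "binomial_logit", ["condition"])
            fit = fit_accuracy_model(df, spec)
            lo, hi = fit.conf_intervals["condition[IFG-sham]"]
            covered += lo <= 0.0 <= hi
        assert covered >= 93

    def test_or_recovery_with_planted_effect(self):
        rng = np.random.default_rng(2)
        ors = []
        for _ in range(200):
            rows = []
            for pi in range(24):
                b = 0.4 * rng.standard_normal()
                for cond, shift in zip(CONDITIONS, (0.0, 0.0, 0.0, np.log(0.79))):
                    p = 1 / (1 + np.exp(-(2.2 + shift + b)))
                    y = rng.random(60) < p
                    rows += [{"participant": f"p{pi}", "condition": cond,
                              "correct": bool(v)} for v in y]
            df = pd.DataFrame(rows)
            spec = _spec("binary_correct", "binomial_logit", ["condition"])
            fit = fit_accuracy_model(df, spec)
            ors.append(fit.exp_effects["condition[dual-sham]"])
        assert 0.70 <= np.mean(ors) <= 0.89

    def test_all_correct_is_separation_error(self):
        df = pd.DataFrame({
            "participant": list("abcd") * 2, "condition": ["sham", "IFG"] * 4,
            "correct": True,
        })
        spec = _spec("binary_correct", "binomial_logit", ["condition"],
                     ("sham", "IFG"))
        with pytest.raises(SeparationError):
            fit_accuracy_model(df, spec)

    def test_exp_effects_match_link_scale(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "participant": np.repeat([f"p{i}" for i in range(12)], 8),
            "condition": list(CONDITIONS) * 24,
            "correct": rng.random(96) < 0.8,
        })
        spec = _spec("binary_correct", "binomial_logit", ["condition"])
        fit = fit_accuracy_model(df, spec)
        for term, est in fit.coefficients.items():
            assert fit.exp_effects[term] == pytest.approx(np.exp(est), abs=1e-10)
            lo, hi = fit.conf_intervals[term]
            assert lo <= est <= hi


class TestSwitchCountModel:
    def test_single_factor_irr_is_ratio_of_means(self):
        df = pd.DataFrame({
            "n_switches": [10, 12, 14, 6, 9, 9],
            "condition": ["sham"] * 3 + ["dual"] * 3,
            "participant": list("abcdef"),
        })
        spec = _spec("count", "negative_binomial_log", ["condition"],
                     ("sham", "dual"))
        fit = fit_switch_count_model(df, spec)
        assert fit.exp_effects["condition[dual-sham]"] == pytest.approx(
            8 / 12, abs=1e-3)

    def test_identical_distributions_irr_near_one(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(10, 24)
        df = pd.DataFrame({
            "n_switches": np.tile(counts, 4),
            "condition": np.repeat(CONDITIONS, 24),
            "participant": list(np.tile([f"p{i}" for i in range(24)], 4)),
        })
        spec = _spec("count", "negative_binomial_log", ["condition"])
        fit = fit_switch_count_model(df, spec)
        for c in ("IFG", "preSMA", "dual"):
            assert fit.exp_effects[f"condition[{c}-sham]"] == pytest.approx(1.0, abs=1e-2)

    def test_all_zero_counts_error(self):
        df = pd.DataFrame({
            "n_switches": 0, "condition": ["sham", "IFG"] * 3,
            "participant": list("aabbcc"),
        })
        spec = _spec("count", "negative_binomial_log", ["condition"],
                     ("sham", "IFG"))
        with pytest.raises(ModelError, match="all-zero|zero"):
            fit_switch_count_model(df, spec)

    def test_glmmtmb_cross_check(self, tmp_path):
        """Independent oracle: R glmmTMB NB2 random-intercept fit."""
        import subprocess

        rng = np.random.default_rng(5)
        rows = []
        for pi in range(20):
            b = 0.3 * rng.standard_normal()
            for cond, mult in zip(("sham", "dual"), (1.0, 0.8)):
                for _ in range(6):
                    lam = rng.gamma(1 / 0.2, 0.2 * 10 * mult * np.exp(b))
                    rows.append({"participant": f"p{pi}", "condition": cond,
                                 "n_switches": int(rng.poisson(lam))})
        df = pd.DataFrame(rows)
        spec = _spec("count", "negative_binomial_log", ["condition"],
                     ("sham", "dual"))
        fit = fit_switch_count_model(df, spec)
        csv = tmp_path / "counts.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv("{csv}")
        d$cond <- ifelse(d$condition == "dual", 0.5, -0.5)
        m <- glmmTMB(n_switches ~ cond + (1 | participant), data = d,
                     family = nbinom2)
        cat(fixef(m)$cond["cond"], sigma(m), "\n")
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_beta = float(out.stdout.split()[0])
        assert fit.coefficients["condition[dual-sham]"] == pytest.approx(
            r_beta, abs=0.01)


class TestConditionContrasts:
    @pytest.fixture()
    def nb_fit(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "n_switches": rng.poisson(10, 96),
            "condition": list(CONDITIONS) * 24,
            "participant": list(np.repeat([f"p{i}" for i in range(24)], 4)),
        })
        spec = _spec("count", "negative_binomial_log", ["condition"])
        return fit_switch_count_model(df, spec)

    def test_default_family_is_active_vs_sham(self, nb_fit):
        table = condition_contrasts(nb_fit)
        assert set(table["contrast"]) == {
            "IFG - sham", "preSMA - sham", "dual - sham"}
        expected = fdr_bh(table["p_raw"].to_numpy())
        assert table["p_adj"].to_numpy() == pytest.approx(expected)

    def test_single_comparison_family_unadjusted(self, nb_fit):
        table = condition_contrasts(nb_fit, comparisons=[("IFG", "sham")])
        assert table["p_adj"].iloc[0] == pytest.approx(table["p_raw"].iloc[0])

    def test_self_contrast_is_zero(self, nb_fit):
        table = condition_contrasts(nb_fit, comparisons=[("IFG", "IFG")])
        assert table["estimate"].iloc[0] == 0.0

    def test_posthoc_pair_is_coefficient_difference(self, nb_fit):
        table = condition_contrasts(nb_fit, comparisons=[("IFG", "preSMA")])
        expect = (nb_fit.coefficients["condition[IFG-sham]"]
                  - nb_fit.coefficients["condition[preSMA-sham]"])
        assert table["estimate"].iloc[0] == pytest.approx(expect)

    def test_inestimable_contrast_rejected(self, nb_fit):
        with pytest.raises(ModelError, match="not estimable"):
            condition_contrasts(nb_fit, comparisons=[("bogus", "sham")])
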