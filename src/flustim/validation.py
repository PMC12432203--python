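"""Simulation studies that audit the pipeline against its own generator.

Each function runs a self-contained parameter-recovery or calibration study:
synthetic data are generated with known truth, pushed through the same code
paths an analysis would use, and the recovered quantity is returned.  They
back the package's test suite and the reproduction script, and double as
templates for power analyses at other design sizes.

All studies take an explicit seed and are deterministic given it.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .efield import dual_site_regression
from .pipeline import infer_difficulty
from .stats import ModelSpec, condition_contrasts, fit_rt_model, fit_switch_count_model
from .switching import annotate_sequence
from .synthetic_data import (
    SimulationConfig,
    simulate_dataset,
    simulate_efields,
    simulate_switch_counts,
)

__all__ = [
    "planted_cluster_recovery",
    "switch_multiplier_recovery",
    "logrt_shift_recovery",
    "null_rejection_rate",
    "null_outlier_removal",
    "efield_slope_recovery",
    "dual_site_null_coverage",
]

ACTIVE = ("IFG", "preSMA", "dual")


def _semantic_config(seed: int, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(tasks=("semantic_fluency",), seed=seed)
    return dataclasses.replace(cfg, **overrides)


def planted_cluster_recovery(
    n_sequences: int = 1000, seed: int = 0, threshold: float = 0.5
) -> float:
    """Fraction of simulated sequences whose detected switches equal the
    planted subcluster transitions.

    Lexicons use the well-separated default geometry (within-subcluster
    similarity 0.9, between 0.1) and the threshold is calibrated between the
    two similarity bands, so detection should be essentially exact.
    """
    n_participants = int(np.ceil(n_sequences / 24))
    cfg = _semantic_config(seed, n_participants=n_participants)
    ds = simulate_dataset(cfg)
    trials = prep.code_fluency_accuracy(ds.trials, category_members=ds.lexicon.all_words())
    sem = trials[trials["correct"].astype("boolean").fillna(False).astype(bool)]
    groups = dict(tuple(sem.groupby(["participant", "session", "item"], sort=True)))
    hits = 0
    rows = ds.truth["switch_counts"].head(n_sequences)
    for r in rows.itertuples():
        grp = groups[(r.participant, r.session, r.category)].sort_values("trial_index")
        ann = annotate_sequence(grp["response"].tolist(), ds.embeddings, threshold)
        detected = [i for i, f in enumerate(ann.boundary_flags) if f]
        hits += detected == ds.truth["boundaries"][r.sequence_id]
    return hits / len(rows)


def switch_multiplier_recovery(
    n_replicates: int = 200, multiplier: float = 0.85, seed: int = 0,
    participant_sd: float = 0.3,
) -> dict[str, float]:
    """Mean recovered IRR per active condition when every active condition's
    switch rate is multiplied by ``multiplier`` (24 participants x 4
    conditions x 6 categories, participant intercept SD as given)."""
    cfg = _semantic_config(
        seed,
        switch_multiplier={c: multiplier for c in ACTIVE},
        participant_switch_sd=participant_sd,
        category_switch_sd=0.0,
    )
    rng = np.random.default_rng(seed)
    spec = ModelSpec(outcome="count", family="negative_binomial_log",
                     fixed_terms=["condition", "session", "difficulty"])
    irrs = {c: [] for c in ACTIVE}
    for _ in range(n_replicates):
        table = simulate_switch_counts(cfg, rng)
        fit = fit_switch_count_model(table, spec)
        for c in ACTIVE:
            irrs[c].append(fit.exp_effects[f"condition[{c}-sham]"])
    return {c: float(np.mean(v)) for c, v in irrs.items()}


def _fit_semantic_rt(ds):
    trials = prep.code_fluency_accuracy(ds.trials, category_members=ds.lexicon.all_words())
    rts, _ = prep.compute_rts(trials, "semantic_fluency")
    kept, _ = prep.outlier_filter(rts)
    kept = kept.copy()
    kept["difficulty"] = infer_difficulty(kept["item"])
    spec = ModelSpec(outcome="log_rt", family="gaussian_on_log",
                     fixed_terms=["condition", "session", "difficulty"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_rt_model(kept, spec)
    return fit


def logrt_shift_recovery(
    n_replicates: int = 100, shift: float = 0.10, seed: int = 0
) -> float:
    """Mean recovered log-RT condition coefficient (averaged over the three
    active-vs-sham contrasts) when every active condition is slowed by
    ``shift`` log-units, at the full design size, through the complete
    preprocessing + outlier + mixed-model path."""
    ests = []
    for rep in range(n_replicates):
        cfg = _semantic_config(
            (seed * 100003 + rep) % 2**31,
            logrt_shift_semantic={c: shift for c in ACTIVE},
        )
        fit = _fit_semantic_rt(simulate_dataset(cfg))
        ests.append(np.mean([fit.coefficients[f"condition[{c}-sham]"] for c in ACTIVE]))
    return float(np.mean(ests))


def null_rejection_rate(
    n_replicates: int = 1000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Empirical probability that the BH-corrected active-vs-sham family of
    the log-RT model rejects anything when all condition effects are null.

    Uses a reduced design (8 participants, 2 categories per session, 45-s
    windows) so that many replicates are affordable; calibration of the
    Wald + BH machinery does not depend on the design size.
    """
    rejections = 0
    for rep in range(n_replicates):
        cfg = _semantic_config(
            (seed * 100003 + rep) % 2**31,
            n_participants=8,
            categories_per_session=2,
            fluency_duration_s=45.0,
            logrt_shift_semantic={c: 0.0 for c in ACTIVE},
            switch_multiplier={c: 1.0 for c in ACTIVE},
            efield_rt_slope=0.0,
        )
        fit = _fit_semantic_rt(simulate_dataset(cfg))
        contrasts = condition_contrasts(fit)
        rejections += bool((contrasts["p_adj"] < alpha).any())
    return rejections / n_replicates


def null_outlier_removal(
    n_groups: int = 10000, group_size: int = 90, seed: int = 0
) -> float:
    """Mean removed fraction of the 3-SD trim on standard-normal RT groups,
    run through :func:`flustim.preprocessing.outlier_filter`."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_groups, group_size))
    df = pd.DataFrame({
        "rt": x.ravel(),
        "participant": np.repeat(np.arange(n_groups), group_size),
        "session": 1, "task": "t", "item": 1,
    })
    _, report = prep.outlier_filter(df)
    return report.removed_fraction


def efield_slope_recovery(
    n_replicates: int = 500, slope: float = 0.01, seed: int = 0,
    n_participants: int = 24, behavior_sd: float = 0.3,
) -> float:
    """Mean OLS-recovered e-field/behavior coupling slope across replicates.

    Baseline behavior is participant-level noise with SD ``behavior_sd``
    (matching the between-participant spread of mean log RTs); the generator
    adds ``slope * (e95 - mean)`` and the recovery regresses the perturbed
    behavior on e95.
    """
    cfg = SimulationConfig(n_participants=n_participants)
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_replicates):
        baseline = behavior_sd * rng.standard_normal(n_participants)
        efields, behavior = simulate_efields(cfg, baseline, slope=slope, rng=rng)
        x = efields["e95_Vpm"].to_numpy()
        b = np.polyfit(x, behavior, 1)[0]
        slopes.append(b)
    return float(np.mean(slopes))


def dual_site_null_coverage(
    n_replicates: int = 500, slope: float = 0.01, seed: int = 0,
    n_participants: int = 24, behavior_sd: float = 0.3,
) -> float:
    """Fraction of replicates in which the dual-site regression assigns the
    *uncoupled* target a standardized beta within 2 SE of zero, when the
    outcome is coupled only to the pre-SMA field."""
    cfg = SimulationConfig(n_participants=n_participants)
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        baseline = behavior_sd * rng.standard_normal(n_participants)
        e_ifg, _ = simulate_efields(cfg, baseline, target="IFG", slope=0.0, rng=rng)
        e_sma, behavior = simulate_efields(cfg, baseline, target="preSMA",
                                           slope=slope, rng=rng)
        res = dual_site_regression(e_ifg["e95_Vpm"], e_sma["e95_Vpm"], behavior)
        covered += abs(res.coefficients["e_IFG"]) <= 2.0 * res.std_errors["e_IFG"]
    return covered / n_replicates
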