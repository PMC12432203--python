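"""Synthetic fluency studies with fully known ground truth.

The generator emulates a four-session within-subject neurostimulation study:
24 participants each complete one session per stimulation condition (sham,
IFG, preSMA, dual), with six 90-s semantic-fluency categories per session
(three easy, three difficult), three figural-fluency dot arrangements
(up to 40 designs each), and a 99-picture naming run.

Semantic sequences are produced by a subcluster-run process over a planted
lexicon: a subcluster of the category is chosen, a run of distinct words is
emitted from it, then the process transitions to a different subcluster.
The number of transitions per sequence is drawn from a negative-binomial
rate (base rate x condition multiplier x difficulty multiplier x
exp(participant + category intercepts)), so the planted switch count is a
countable truth the detection pipeline can be audited against.
Inter-response intervals are lognormal with additive log-scale condition
shifts; accuracy structure comes from injected repetitions and
out-of-category intrusions; e-field intensities are linearly coupled to
behavior in the sessions where the target is stimulated.

Everything is reproducible bit-for-bit from ``(config, seed)`` via per
component substreams.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingStore, write_embeddings

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "Lexicon",
    "make_lexicon",
    "simulate_dataset",
    "simulate_switch_counts",
    "simulate_efields",
    "write_dataset",
]

CONDITIONS = ("sham", "IFG", "preSMA", "dual")


def _cond_dict(ifg, presma, dual):
    return {"IFG": ifg, "preSMA": presma, "dual": dual}


@dataclass
class SimulationConfig:
    """Study-design parameters and planted effect sizes.

    Effect-size defaults are the point estimates reported for this design:
    log-RT shifts of 0.09/0.12/0.11 (semantic) and 0.04 (figural) for
    IFG/preSMA/dual vs sham, switch-rate multipliers 0.93/0.90/0.87, and a
    figural-accuracy odds shift of 1.17/0.96/0.79.
    """

    # design
    n_participants: int = 24
    conditions: tuple = CONDITIONS
    categories_per_session: int = 6  # half easy, half difficult
    fluency_duration_s: float = 90.0
    n_pictures: int = 99
    picture_interval_s: float = 2.5
    figural_arrangements_per_session: int = 3
    figural_max_designs: int = 40
    figural_duration_s: float = 210.0
    tasks: tuple = ("semantic_fluency", "figural_fluency", "picture_naming")

    # lexicon geometry
    embedding_dim: int = 32
    n_subclusters: int = 4
    words_per_subcluster: int = 8
    within_similarity: float = 0.9
    between_similarity: float = 0.1

    # condition effects (additive on log scale / multiplicative on rates)
    logrt_shift_semantic: dict = field(default_factory=lambda: _cond_dict(0.09, 0.12, 0.11))
    logrt_shift_figural: dict = field(default_factory=lambda: _cond_dict(0.04, 0.04, 0.04))
    logrt_shift_naming: dict = field(default_factory=lambda: _cond_dict(0.01, -0.01, -0.01))
    switch_multiplier: dict = field(default_factory=lambda: _cond_dict(0.93, 0.90, 0.87))
    figural_acc_logodds: dict = field(
        default_factory=lambda: {c: float(np.log(v)) for c, v in
                                 _cond_dict(1.17, 0.96, 0.79).items()}
    )
    naming_acc_logodds: dict = field(
        default_factory=lambda: {c: float(np.log(v)) for c, v in
                                 _cond_dict(1.00, 0.95, 0.81).items()}
    )

    # rates and noise
    base_switch_rate: float = 12.0  # expected switches, easy category, sham
    difficulty_switch_multiplier: float = 0.60
    nb_dispersion: float = 0.15  # NB2 alpha
    semantic_logrt_mu: float = float(np.log(3.0))  # log seconds, easy/sham
    semantic_logrt_sigma: float = 0.45
    difficulty_logrt_shift: float = 0.48
    figural_logrt_mu: float = float(np.log(4.5))
    figural_logrt_sigma: float = 0.40
    figural_session_logrt: tuple = (0.0, -0.08, -0.14, -0.15)
    figural_bars_logrt_slope: float = 0.10  # per bar, centered at 2.5
    naming_logrt_mu: float = float(np.log(0.9))
    naming_logrt_sigma: float = 0.25
    figural_base_accuracy: float = 0.90
    naming_base_accuracy: float = 0.97
    word_duration_range: tuple = (0.4, 0.9)
    initial_latency_mu: float = float(np.log(1.5))
    initial_latency_sigma: float = 0.30
    repetition_rate: float = 0.03
    intrusion_rate: float = 0.02

    # random intercept SDs
    participant_logrt_sd: float = 0.15
    participant_switch_sd: float = 0.30
    participant_acc_sd: float = 0.40
    category_logrt_sd: float = 0.10
    category_switch_sd: float = 0.20

    # covariates and their coupling
    tmt_mean_s: float = 35.0
    tmt_sd_s: float = 8.0
    dsst_mean: float = 60.0
    dsst_sd: float = 10.0
    stw_mean: float = 25.0
    stw_sd: float = 5.0
    executive_logrt_slope: float = -0.20  # per executive-z unit, semantic RT

    # e-fields (95th-percentile ROI summaries, V/m)
    efield_mean: dict = field(default_factory=lambda: {"IFG": 90.0, "preSMA": 85.0})
    efield_sd: float = 15.0
    efield_rt_slope: float = 0.01     # log-RT units per V/m, IFG session
    efield_figacc_slope: float = -0.02  # log-odds per V/m, dual session

    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def n_sessions(self) -> int:
        return len(self.conditions)

    @property
    def n_categories(self) -> int:
        return self.categories_per_session * self.n_sessions

    @property
    def category_capacity(self) -> int:
        return self.n_subclusters * self.words_per_subcluster

    def validate_geometry(self) -> None:
        if not 0 <= self.between_similarity < self.within_similarity < 1:
            raise ValueError(
                "similarity targets must satisfy 0 <= between < within < 1, got "
                f"between={self.between_similarity}, within={self.within_similarity}"
            )
        if self.embedding_dim < 3:
            raise ValueError("embedding dimension must be >= 3")
        for name in ("switch_multiplier",):
            if any(v <= 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} entries must be > 0")
        for name in ("nb_dispersion", "participant_logrt_sd", "participant_switch_sd",
                     "participant_acc_sd", "category_logrt_sd", "category_switch_sd",
                     "efield_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.categories_per_session % 2:
            raise ValueError("categories_per_session must be even (easy/difficult halves)")
        if any(m <= 0 for m in self.efield_mean.values()):
            raise ValueError("e-field means must be positive")

    def validate(self) -> None:
        self.validate_geometry()
        # feasibility: the fastest plausible cell must fit in the lexicon
        shifts = [0.0] + list(self.logrt_shift_semantic.values())
        fastest = (
            self.semantic_logrt_mu
            + min(shifts)
            - 2.0 * self.participant_logrt_sd
            + self.semantic_logrt_sigma**2 / 2.0
        )
        per_item = float(np.exp(fastest)) + self.word_duration_range[0]
        max_expected = self.fluency_duration_s / per_item
        if self.category_capacity < max_expected:
            raise ValueError(
                f"infeasible rates: up to ~{max_expected:.0f} items fit in "
                f"{self.fluency_duration_s:.0f} s but the category lexicon holds "
                f"only {self.category_capacity}"
            )


@dataclass
class Lexicon:
    """Planted category lexicon: per category, a list of subcluster word
    lists, plus difficulty labels."""

    words: dict[str, list[list[str]]]
    difficulty: dict[str, str]

    def category_words(self, category: str) -> list[str]:
        return [w for sub in self.words[category] for w in sub]

    def all_words(self) -> dict[str, list[str]]:
        return {cat: self.category_words(cat) for cat in self.words}


@dataclass
class SimulatedDataset:
    trials: pd.DataFrame
    embeddings: EmbeddingStore
    efields: pd.DataFrame
    covariates: pd.DataFrame
    lexicon: Lexicon
    truth: dict
    config: SimulationConfig


# ----------------------------------------------------------------------
# lexicon geometry


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _category_vectors(
    dim: int, n_sub: int, n_words: int, within: float, between: float,
    rng: np.random.Generator, tol: float = 0.05, max_iter: int = 25,
) -> np.ndarray:
    """Unit vectors (n_sub * n_words, dim) whose mean within-subcluster
    cosine is within ``tol`` of ``within`` and mean between-subcluster
    cosine within ``tol`` of ``between``, via shared-component construction
    with internal re-tuning of the mixing weights."""
    if dim <= n_sub:
        raise ValueError(f"embedding dimension {dim} too small for {n_sub} subclusters")
    a = within                       # word/centroid shared fraction
    b = between / within if within > 0 else 0.0  # centroid/centroid cosine
    for _ in range(max_iter):
        a_c = float(np.clip(a, 1e-4, 1 - 1e-4))
        b_c = float(np.clip(b, -1.0 / max(n_sub - 1, 1) + 1e-4, 1 - 1e-4))
        # centroids with exact pairwise cosine b_c: Cholesky of the target
        # Gram matrix mapped onto a random orthonormal frame
        gram = np.full((n_sub, n_sub), b_c)
        np.fill_diagonal(gram, 1.0)
        chol = np.linalg.cholesky(gram)
        frame, _ = np.linalg.qr(rng.standard_normal((dim, n_sub)))
        cents = chol @ frame.T  # (n_sub, dim), unit rows
        # word noise orthogonal to the whole centroid span, so between-pair
        # similarity concentrates at a_c * b_c
        proj = cents.T @ np.linalg.solve(cents @ cents.T, cents)
        vecs = np.empty((n_sub * n_words, dim))
        labels = np.repeat(np.arange(n_sub), n_words)
        for i, k in enumerate(labels):
            u = rng.standard_normal(dim)
            u = _unit(u - proj @ u)
            vecs[i] = _unit(np.sqrt(a_c) * cents[k] + np.sqrt(1 - a_c) * u)
        sims = vecs @ vecs.T
        iu, ju = np.triu_indices(len(vecs), k=1)
        same = labels[iu] == labels[ju]
        mean_within = float(sims[iu[same], ju[same]].mean())
        if n_sub > 1:
            mean_between = float(sims[iu[~same], ju[~same]].mean())
        else:
            mean_between = between  # vacuous constraint
        if abs(mean_within - within) <= tol and abs(mean_between - between) <= tol:
            return vecs
        a += within - mean_within
        if n_sub > 1 and a > 1e-3:
            b += (between - mean_between) / a
    raise RuntimeError(
        f"could not realize similarity targets within={within}, between={between} "
        f"in dimension {dim}"
    )


def make_lexicon(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Lexicon, EmbeddingStore]:
    """Planted lexicon plus its embedding store (deterministic given seed)."""
    config.validate_geometry()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    words: dict[str, list[list[str]]] = {}
    difficulty: dict[str, str] = {}
    vectors: dict[str, np.ndarray] = {}
    n_easy = config.n_categories // 2
    for ci in range(config.n_categories):
        diff = "easy" if ci < n_easy else "difficult"
        cat = f"cat{ci:02d}_{diff}"
        vecs = _category_vectors(
            config.embedding_dim, config.n_subclusters, config.words_per_subcluster,
            config.within_similarity, config.between_similarity, rng,
        )
        subs: list[list[str]] = []
        i = 0
        for k in range(config.n_subclusters):
            sub = []
            for j in range(config.words_per_subcluster):
                w = f"{cat}_s{k}w{j:02d}"
                vectors[w] = vecs[i]
                sub.append(w)
                i += 1
            subs.append(sub)
        words[cat] = subs
        difficulty[cat] = diff
    return Lexicon(words=words, difficulty=difficulty), EmbeddingStore(vectors)


# ----------------------------------------------------------------------
# switch-count process


def _draw_nb(rate: float, alpha: float, rng: np.random.Generator) -> int:
    """NB2 draw with mean ``rate`` and variance rate + alpha*rate^2."""
    if alpha <= 1e-12:
        return int(rng.poisson(rate))
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * rate)
    return int(rng.poisson(lam))


def _compose_runs(
    n_items: int, n_switches: int, run_cap: int, rng: np.random.Generator,
    max_tries: int = 200,
) -> list[int]:
    """Run lengths (n_switches + 1 of them, each in [1, run_cap]) summing to
    n_items, boundaries placed uniformly at random among valid placements."""
    n_runs = n_switches + 1
    if not (n_runs <= n_items <= run_cap * n_runs):
        raise ValueError("infeasible run composition")
    for _ in range(max_tries):
        cuts = rng.choice(n_items - 1, size=n_switches, replace=False)
        cuts.sort()
        edges = np.concatenate([[0], cuts + 1, [n_items]])
        lengths = np.diff(edges)
        if lengths.max() <= run_cap:
            return lengths.tolist()
    # deterministic fallback: near-equal split
    base = n_items // n_runs
    lengths = [base] * n_runs
    for i in range(n_items - base * n_runs):
        lengths[i] += 1
    return lengths


def _assign_subclusters(
    lengths: Sequence[int], pools: list[list[str]], rng: np.random.Generator
) -> tuple[list[str], list[int]]:
    """Emit words run by run: each run draws from one subcluster (never the
    previous run's), without replacement within the sequence."""
    remaining = [list(p) for p in pools]
    for p in remaining:
        rng.shuffle(p)
    tokens: list[str] = []
    assignment: list[int] = []
    prev = -1
    for L in lengths:
        eligible = [k for k in range(len(remaining)) if k != prev and len(remaining[k]) >= L]
        if not eligible:
            # take the fullest non-previous pool and shorten the run
            order = sorted(
                (k for k in range(len(remaining)) if k != prev),
                key=lambda k: -len(remaining[k]),
            )
            k = order[0]
            L = min(L, len(remaining[k]))
            if L == 0:
                break
        else:
            k = int(rng.choice(eligible))
        for _ in range(L):
            tokens.append(remaining[k].pop())
            assignment.append(k)
        prev = k
    return tokens, assignment


def _sequence_boundaries(assignment: Sequence[int]) -> list[int]:
    return [i for i in range(len(assignment) - 1) if assignment[i] != assignment[i + 1]]


# ----------------------------------------------------------------------
# full dataset


def _session_plan(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Per-participant condition order (counterbalanced by random permutation)."""
    return {
        f"P{p + 1:02d}": [config.conditions[i] for i in rng.permutation(config.n_sessions)]
        for p in range(config.n_participants)
    }


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic study (trials for the configured tasks,
    embeddings, e-fields, covariates) with full generating truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(6)
    rng_lex, rng_design, rng_trials, rng_ef, rng_cov, rng_acc = (
        np.random.default_rng(s) for s in ss
    )
    lexicon, store = make_lexicon(config, rng_lex)
    participants = [f"P{p + 1:02d}" for p in range(config.n_participants)]
    plan = _session_plan(config, rng_design)

    # covariates + executive z within the generator (for coupling)
    tmt = config.tmt_mean_s + config.tmt_sd_s * rng_cov.standard_normal(len(participants))
    tmt = np.clip(tmt, 10.0, None)
    dsst = np.clip(config.dsst_mean + config.dsst_sd * rng_cov.standard_normal(len(participants)), 5.0, None)
    stw = config.stw_mean + config.stw_sd * rng_cov.standard_normal(len(participants))
    covariates = pd.DataFrame(
        {"participant": participants, "tmt_seconds": np.round(tmt, 1),
         "dsst_count": np.round(dsst).astype(int), "stw_raw": np.round(stw, 1)}
    )

    def _z(x):
        return (x - x.mean()) / x.std(ddof=1)

    exec_z = ((_z(-covariates["tmt_seconds"]) + _z(covariates["dsst_count"])) / 2).to_numpy()

    # random intercepts
    p_rt = config.participant_logrt_sd * rng_design.standard_normal(len(participants))
    p_sw = config.participant_switch_sd * rng_design.standard_normal(len(participants))
    p_acc = config.participant_acc_sd * rng_design.standard_normal(len(participants))
    cats = list(lexicon.words)
    c_rt = config.category_logrt_sd * rng_design.standard_normal(len(cats))
    c_sw = config.category_switch_sd * rng_design.standard_normal(len(cats))
    cat_rt = dict(zip(cats, c_rt))
    cat_sw = dict(zip(cats, c_sw))

    # e-fields: one value per participant x target, reused in the single-site
    # and dual sessions of that target
    efield_rows = []
    e95 = {}
    for target, mean in config.efield_mean.items():
        vals = mean + config.efield_sd * rng_ef.standard_normal(len(participants))
        for _ in range(100):
            bad = vals <= 0
            if not bad.any():
                break
            vals[bad] = mean + config.efield_sd * rng_ef.standard_normal(int(bad.sum()))
        e95[target] = vals
        for pi, pid in enumerate(participants):
            for cond in (target, "dual"):
                efield_rows.append(
                    {"participant": pid, "target": target, "condition": cond,
                     "e95_Vpm": float(np.round(vals[pi], 2))}
                )
    efields = pd.DataFrame(efield_rows)

    easy_cats = [c for c in cats if lexicon.difficulty[c] == "easy"]
    diff_cats = [c for c in cats if lexicon.difficulty[c] == "difficult"]
    per_half = config.categories_per_session // 2
    session_cats = {
        s: easy_cats[(s - 1) * per_half: s * per_half]
        + diff_cats[(s - 1) * per_half: s * per_half]
        for s in range(1, config.n_sessions + 1)
    }
    arrangement_ids = [
        f"arr{chr(ord('A') + i)}"
        for i in range(config.figural_arrangements_per_session * config.n_sessions)
    ]
    session_arr = {
        s: arrangement_ids[(s - 1) * config.figural_arrangements_per_session:
                           s * config.figural_arrangements_per_session]
        for s in range(1, config.n_sessions + 1)
    }
    dots = [str(d) for d in range(1, 6)]
    all_bars = [f"{a}-{b}" for i, a in enumerate(dots) for b in dots[i + 1:]]

    rows = []
    truth_switches = []
    truth_boundaries: dict[str, list[int]] = {}
    dur_lo, dur_hi = config.word_duration_range

    for pi, pid in enumerate(participants):
        for s in range(1, config.n_sessions + 1):
            cond = plan[pid][s - 1]
            cshift_sem = config.logrt_shift_semantic.get(cond, 0.0)
            cshift_fig = config.logrt_shift_figural.get(cond, 0.0)
            cshift_nam = config.logrt_shift_naming.get(cond, 0.0)
            cmult_sw = config.switch_multiplier.get(cond, 1.0)
            ef_rt = config.efield_rt_slope * (e95["IFG"][pi] - config.efield_mean["IFG"]) \
                if cond == "IFG" else 0.0
            ef_acc = config.efield_figacc_slope * (e95["preSMA"][pi] - config.efield_mean["preSMA"]) \
                if cond == "dual" else 0.0

            if "semantic_fluency" in config.tasks:
                for cat in session_cats[s]:
                    diff = lexicon.difficulty[cat]
                    mu = (
                        config.semantic_logrt_mu + cshift_sem
                        + (config.difficulty_logrt_shift if diff == "difficult" else 0.0)
                        + p_rt[pi] + cat_rt[cat]
                        + config.executive_logrt_slope * exec_z[pi] + ef_rt
                    )
                    rows_cat, tr = _simulate_fluency_cell(
                        config, lexicon, pid, s, cond, cat, diff, mu,
                        cmult_sw, p_sw[pi], cat_sw[cat], rng_trials,
                        dur_lo, dur_hi,
                    )
                    rows.extend(rows_cat)
                    truth_switches.append(tr)
                    truth_boundaries[tr["sequence_id"]] = tr.pop("boundaries")

            if "figural_fluency" in config.tasks:
                logit0 = float(np.log(config.figural_base_accuracy /
                                      (1 - config.figural_base_accuracy)))
                p_correct = 1.0 / (1.0 + np.exp(-(
                    logit0 + config.figural_acc_logodds.get(cond, 0.0)
                    + p_acc[pi] + ef_acc
                )))
                for arr in session_arr[s]:
                    rows.extend(_simulate_figural_block(
                        config, pid, s, cond, arr, all_bars, p_correct,
                        config.figural_logrt_mu + cshift_fig
                        + config.figural_session_logrt[s - 1] + p_rt[pi],
                        rng_trials, rng_acc,
                    ))

            if "picture_naming" in config.tasks:
                logit0 = float(np.log(config.naming_base_accuracy /
                                      (1 - config.naming_base_accuracy)))
                p_name = 1.0 / (1.0 + np.exp(-(
                    logit0 + config.naming_acc_logodds.get(cond, 0.0) + p_acc[pi]
                )))
                rts = np.exp(
                    config.naming_logrt_mu + cshift_nam + p_rt[pi]
                    + config.naming_logrt_sigma * rng_trials.standard_normal(config.n_pictures)
                )
                correct = rng_acc.random(config.n_pictures) < p_name
                for i in range(config.n_pictures):
                    onset = i * config.picture_interval_s
                    rows.append({
                        "participant": pid, "session": s, "condition": cond,
                        "task": "picture_naming", "item": f"pic{i + 1:03d}",
                        "trial_index": i + 1, "response": f"name_pic{i + 1:03d}",
                        "onset": round(onset, 3), "offset": round(onset + rts[i], 3),
                        "correct": bool(correct[i]),
                    })

    trials = pd.DataFrame(rows)
    truth = {
        "condition_effects": {
            "logrt_shift_semantic": dict(config.logrt_shift_semantic),
            "logrt_shift_figural": dict(config.logrt_shift_figural),
            "switch_multiplier": dict(config.switch_multiplier),
            "figural_acc_logodds": dict(config.figural_acc_logodds),
        },
        "participant_intercepts": {
            "logrt": dict(zip(participants, p_rt.tolist())),
            "switch": dict(zip(participants, p_sw.tolist())),
            "accuracy": dict(zip(participants, p_acc.tolist())),
        },
        "category_intercepts": {
            "logrt": {c: float(v) for c, v in cat_rt.items()},
            "switch": {c: float(v) for c, v in cat_sw.items()},
        },
        "session_plan": plan,
        "switch_counts": pd.DataFrame(truth_switches),
        "boundaries": truth_boundaries,
        "executive_z": dict(zip(participants, exec_z.tolist())),
        "efield_coupling": {
            "rt_slope_logrt_per_Vpm": config.efield_rt_slope,
            "figacc_slope_logodds_per_Vpm": config.efield_figacc_slope,
        },
    }
    return SimulatedDataset(
        trials=trials, embeddings=store, efields=efields, covariates=covariates,
        lexicon=lexicon, truth=truth, config=config,
    )


def _simulate_fluency_cell(
    config, lexicon, pid, session, cond, cat, diff, mu, cmult, p_sw, c_sw,
    rng, dur_lo, dur_hi,
):
    """One participant x session x category sequence with planted switches."""
    capacity = config.category_capacity
    # timing first: number of tokens that fit in the task window
    irts = [float(np.exp(mu + config.initial_latency_sigma * rng.standard_normal()
                         + (config.initial_latency_mu - mu)))]  # initial latency
    durs = [float(rng.uniform(dur_lo, dur_hi))]
    t = irts[0] + durs[0]
    while len(irts) < capacity:
        irt = float(np.exp(mu + config.semantic_logrt_sigma * rng.standard_normal()))
        dur = float(rng.uniform(dur_lo, dur_hi))
        if t + irt + dur > config.fluency_duration_s:
            break
        irts.append(irt)
        durs.append(dur)
        t += irt + dur
    n_total = len(irts)

    # split into correct tokens vs injected repetitions/intrusions
    kinds = []
    for i in range(n_total):
        u = rng.random()
        if i >= 2 and u < config.repetition_rate:
            kinds.append("repetition")
        elif i >= 1 and u < config.repetition_rate + config.intrusion_rate:
            kinds.append("intrusion")
        else:
            kinds.append("correct")
    n_correct = kinds.count("correct")
    if n_correct < 1:
        kinds[0] = "correct"
        n_correct = 1

    rate = (
        config.base_switch_rate * cmult
        * (config.difficulty_switch_multiplier if diff == "difficult" else 1.0)
        * float(np.exp(p_sw + c_sw))
    )
    k = _draw_nb(rate, config.nb_dispersion, rng)
    k_min = max(0, int(np.ceil(n_correct / config.words_per_subcluster)) - 1)
    k = int(np.clip(k, k_min, n_correct - 1))
    lengths = _compose_runs(n_correct, k, config.words_per_subcluster, rng)
    tokens, assignment = _assign_subclusters(lengths, lexicon.words[cat], rng)
    boundaries = _sequence_boundaries(assignment)

    other_cats = [c for c in lexicon.words if c != cat]
    seq = []
    ci = 0
    for kind in kinds:
        if kind == "correct" and ci < len(tokens):
            seq.append(tokens[ci])
            ci += 1
        elif kind == "repetition" and seq:
            seq.append(str(rng.choice(seq)))
        else:  # intrusion (or fallback when correct tokens exhausted)
            oc = str(rng.choice(other_cats))
            seq.append(str(rng.choice(lexicon.category_words(oc))))

    out = []
    t = 0.0
    for i, (tok, irt, dur) in enumerate(zip(seq, irts, durs)):
        onset = t + irt
        offset = onset + dur
        out.append({
            "participant": pid, "session": session, "condition": cond,
            "task": "semantic_fluency", "item": cat, "trial_index": i + 1,
            "response": tok, "onset": round(onset, 3), "offset": round(offset, 3),
            "correct": None,
        })
        t = offset
    seq_id = f"{pid}/s{session}/{cat}"
    tr = {
        "sequence_id": seq_id, "participant": pid, "session": session,
        "condition": cond, "category": cat, "difficulty": diff,
        "n_switches": len(boundaries), "n_items_correct": len(tokens),
        "n_items_total": len(seq), "boundaries": boundaries,
    }
    return out, tr


def _simulate_figural_block(config, pid, session, cond, arr, all_bars,
                            p_correct, mu, rng, rng_acc):
    rows = []
    seen: list[str] = []
    t = 0.0
    for i in range(config.figural_max_designs):
        n_bars = int(rng.integers(1, 5))
        rt = float(np.exp(
            mu + config.figural_bars_logrt_slope * (n_bars - 2.5)
            + config.figural_logrt_sigma * rng.standard_normal()
        ))
        if t + rt > config.figural_duration_s:
            break
        make_repeat = seen and (rng_acc.random() >= p_correct)
        if make_repeat:
            bars = str(rng.choice(seen))
        else:
            for _ in range(50):
                chosen = rng.choice(len(all_bars), size=n_bars, replace=False)
                bars = ";".join(sorted(all_bars[j] for j in chosen))
                if bars not in seen:
                    break
            seen.append(bars)
        rows.append({
            "participant": pid, "session": session, "condition": cond,
            "task": "figural_fluency", "item": arr, "trial_index": i + 1,
            "response": bars, "onset": round(t, 3), "offset": round(t + rt, 3),
            "correct": None,
        })
        t += rt
    return rows


# ----------------------------------------------------------------------
# fast paths for simulation studies


def simulate_switch_counts(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Switch-count table straight from the NB generating process (no
    sequence construction): one row per participant x session x category
    with columns matching the output of ``switching.switch_table``."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    participants = [f"P{p + 1:02d}" for p in range(config.n_participants)]
    plan = _session_plan(config, rng)
    p_sw = config.participant_switch_sd * rng.standard_normal(len(participants))
    per_half = config.categories_per_session // 2
    rows = []
    for pi, pid in enumerate(participants):
        for s in range(1, config.n_sessions + 1):
            cond = plan[pid][s - 1]
            cmult = config.switch_multiplier.get(cond, 1.0)
            for j in range(config.categories_per_session):
                diff = "easy" if j < per_half else "difficult"
                cat = f"s{s}_{diff}{j % per_half}"
                c_sw = config.category_switch_sd * rng.standard_normal()
                rate = (
                    config.base_switch_rate * cmult
                    * (config.difficulty_switch_multiplier if diff == "difficult" else 1.0)
                    * float(np.exp(p_sw[pi] + c_sw))
                )
                rows.append({
                    "participant": pid, "session": s, "condition": cond,
                    "category": cat, "difficulty": diff,
                    "n_switches": _draw_nb(rate, config.nb_dispersion, rng),
                })
    return pd.DataFrame(rows)


def simulate_efields(
    config: SimulationConfig,
    behavior_truth: Sequence[float],
    target: str = "IFG",
    slope: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-participant e-field values plus the coupled behavior.

    ``behavior_truth`` is the baseline per-participant behavior measure; the
    returned perturbed copy adds ``slope * (e95 - mean)``.  E-fields are
    Normal(mean, sd) truncated at zero.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean = config.efield_mean[target]
    if mean <= 0:
        raise ValueError("e-field mean must be positive (truncation would reject > 50%)")
    if slope is None:
        slope = config.efield_rt_slope
    behavior = np.asarray(behavior_truth, dtype=float)
    n = behavior.shape[0]
    vals = mean + config.efield_sd * rng.standard_normal(n)
    for _ in range(100):
        bad = vals <= 0
        if not bad.any():
            break
        vals[bad] = mean + config.efield_sd * rng.standard_normal(int(bad.sum()))
    efields = pd.DataFrame({
        "participant": [f"P{p + 1:02d}" for p in range(n)],
        "target": target, "condition": target, "e95_Vpm": vals,
    })
    perturbed = behavior + slope * (vals - mean)
    return efields, perturbed


# ----------------------------------------------------------------------
# disk round-trip


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write the dataset in the delimited-text schemas the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.tsv",
        "embeddings": outdir / "embeddings.vec",
        "efields": outdir / "efields.tsv",
        "covariates": outdir / "covariates.tsv",
        "category_members": outdir / "category_members.tsv",
        "truth": outdir / "truth.json",
    }
    ds.trials.to_csv(paths["trials"], sep="\t", index=False)
    write_embeddings(ds.embeddings, paths["embeddings"])
    ds.efields.to_csv(paths["efields"], sep="\t", index=False)
    ds.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    members = pd.DataFrame(
        [(cat, w) for cat, words in ds.lexicon.all_words().items() for w in words],
        columns=["category", "word"],
    )
    members.to_csv(paths["category_members"], sep="\t", index=False)
    truth = dict(ds.truth)
    truth["switch_counts"] = truth["switch_counts"].to_dict(orient="records")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return paths
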