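"""Condition-effect models with simple contrast coding and BH-FDR contrasts.

Three model families mirror the behavioral outcomes:

* Gaussian linear mixed model on natural-log RTs of correct trials
  (participant random intercept, via statsmodels MixedLM);
* logistic regression for binary accuracy (participant random intercept via
  Gauss-Hermite quadrature);
* negative-binomial (NB2, log link) regression for switch / correct-item
  counts (participant random intercept via Gauss-Hermite quadrature),
  reporting incidence-rate ratios.

Categorical factors are simple-coded: each non-reference level is compared
with the reference (sham stimulation, session 1) while the intercept stays
at the grand mean over levels.  Condition contrasts are BH-FDR adjusted over
the declared family (by default the three active-vs-sham comparisons).

Crossed item/category random intercepts from the full study models are not
fitted; their omission is declared in ``FitResult.metadata`` and the
variance they would absorb is taken up by the residual/dispersion term.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from ._glmm import SeparationError, fit_glmm

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelError",
    "simple_coding",
    "build_design",
    "fit_rt_model",
    "fit_accuracy_model",
    "fit_switch_count_model",
    "condition_contrasts",
    "fdr_bh",
]

DEFAULT_CONTRASTS: dict[str, tuple[tuple, object]] = {
    "condition": (("sham", "IFG", "preSMA", "dual"), "sham"),
    "session": ((1, 2, 3, 4), 1),
    "difficulty": (("easy", "difficult"), "easy"),
}


class ModelError(ValueError):
    """Raised for inestimable or degenerate model requests."""


@dataclass
class ModelSpec:
    """Which outcome/family to fit and with which terms.

    ``fixed_terms`` names columns of the data; names present in
    ``contrasts`` are expanded with simple coding, everything else enters as
    a numeric regressor.  ``group`` is the random-intercept factor.
    """

    outcome: str  # log_rt | binary_correct | count
    family: str  # gaussian_on_log | binomial_logit | negative_binomial_log
    fixed_terms: list[str]
    group: str = "participant"
    contrasts: dict[str, tuple[tuple, object]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRASTS)
    )

    def __post_init__(self):
        if "condition" not in self.fixed_terms:
            raise ModelError("'condition' must be among the fixed terms")


@dataclass
class FitResult:
    """Tidy view of one fitted condition-effect model."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    conf_intervals: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    exp_effects: dict[str, float]  # IRR / OR; empty for the gaussian family
    dispersion: Optional[float]
    converged: bool
    n_obs: int
    family: str
    cov: pd.DataFrame  # fixed-effect covariance (term x term)
    metadata: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for term, est in self.coefficients.items():
            lo, hi = self.conf_intervals[term]
            rows.append(
                {
                    "term": term,
                    "estimate": est,
                    "se": self.std_errors[term],
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": self.p_values[term],
                    "exp_estimate": self.exp_effects.get(term, np.nan),
                }
            )
        return pd.DataFrame(rows)


def simple_coding(levels: Sequence, reference) -> pd.DataFrame:
    """Simple-coding contrast matrix (k x (k-1)).

    Column *j* compares level *j* with the reference: its entries are
    (k-1)/k on level j's row and -1/k elsewhere, so each coefficient is
    ``mean(level_j) - mean(reference)`` and the intercept is the grand mean
    over the k level means.
    """
    levels = list(levels)
    if reference not in levels:
        raise ModelError(f"reference {reference!r} not among levels {levels}")
    k = len(levels)
    if k < 2:
        raise ModelError("simple coding needs >= 2 levels")
    others = [lv for lv in levels if lv != reference]
    mat = np.full((k, k - 1), -1.0 / k)
    for j, lv in enumerate(others):
        mat[levels.index(lv), j] = (k - 1.0) / k
    cols = [f"{lv}-{reference}" for lv in others]
    return pd.DataFrame(mat, index=levels, columns=cols)


def build_design(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand fixed terms into a design matrix with intercept.

    Returns the design and a map term -> its column names (one per contrast
    column for simple-coded factors).
    """
    cols: dict[str, pd.Series] = {"Intercept": pd.Series(1.0, index=df.index)}
    term_cols: dict[str, list[str]] = {}
    for term in spec.fixed_terms:
        if term not in df.columns:
            raise ModelError(f"term {term!r} not in data")
        if term in spec.contrasts:
            levels, ref = spec.contrasts[term]
            observed = set(df[term].unique())
            unknown = observed - set(levels)
            if unknown:
                raise ModelError(f"unknown levels {sorted(map(str, unknown))} for {term!r}")
            observed_levels = [lv for lv in levels if lv in observed]
            if ref not in observed_levels:
                raise ModelError(f"reference level {ref!r} absent from data for {term!r}")
            if len(observed_levels) < 2:
                raise ModelError(f"factor {term!r} has a single observed level")
            cmat = simple_coding(observed_levels, ref)
            names = []
            for contrast_name in cmat.columns:
                col = f"{term}[{contrast_name}]"
                cols[col] = df[term].map(cmat[contrast_name]).astype(float)
                names.append(col)
            term_cols[term] = names
        else:
            cols[term] = pd.to_numeric(df[term])
            term_cols[term] = [term]
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X)
        raise ModelError(f"rank-deficient fixed design; aliased columns: {aliased}")
    return X, term_cols


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    qr_r = np.linalg.qr(X.to_numpy(), mode="r")
    diag = np.abs(np.diag(qr_r))
    tol = diag.max() * 1e-10
    return [c for c, d in zip(X.columns, diag) if d < tol]


def _wald(est, se):
    z = np.divide(est, se, out=np.full_like(np.asarray(est, float), np.nan), where=se != 0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    lo = est - 1.959963984540054 * se
    hi = est + 1.959963984540054 * se
    return p, lo, hi


def _pack_result(names, est, se, cov, family, n_obs, converged,
                 dispersion=None, exponentiate=False, metadata=None) -> FitResult:
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    p, lo, hi = _wald(est, se)
    return FitResult(
        coefficients=dict(zip(names, est)),
        std_errors=dict(zip(names, se)),
        conf_intervals={n: (l, h) for n, l, h in zip(names, lo, hi)},
        p_values=dict(zip(names, p)),
        exp_effects=dict(zip(names, np.exp(est))) if exponentiate else {},
        dispersion=dispersion,
        converged=converged,
        n_obs=int(n_obs),
        family=family,
        cov=pd.DataFrame(cov, index=names, columns=names),
        metadata=metadata or {},
    )


_OMITTED_NOTE = "crossed item/category random intercepts omitted; absorbed by dispersion"


def fit_rt_model(rt_table: pd.DataFrame, spec: ModelSpec,
                 rt_col: str = "rt") -> FitResult:
    """Linear mixed model on natural-log RTs of correct trials with a
    participant random intercept."""
    df = rt_table
    if "correct" in df.columns:
        df = df[df["correct"].astype("boolean").fillna(False).astype(bool)]
    df = df[df[rt_col] > 0]
    if df.empty:
        raise ModelError("no positive-RT correct trials to fit")
    X, _ = build_design(df, spec)
    y = np.log(df[rt_col].to_numpy(dtype=float))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X.to_numpy(), groups=df[spec.group].to_numpy())
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True)) and not any(
        "Convergence" in str(w.message) for w in caught
    )
    k = X.shape[1]
    cov = np.asarray(fit.cov_params())[:k, :k]
    return _pack_result(
        list(X.columns), np.asarray(fit.fe_params), np.asarray(fit.bse_fe),
        cov, spec.family, len(df), converged,
        dispersion=float(fit.scale),
        metadata={"random": f"(1 | {spec.group})", "approximation": _OMITTED_NOTE,
                  "random_intercept_sd": float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))},
    )


def fit_accuracy_model(trials: pd.DataFrame, spec: ModelSpec,
                       outcome_col: str = "correct") -> FitResult:
    """Logistic random-intercept model for binary accuracy; reports ORs."""
    df = trials.dropna(subset=[outcome_col])
    y = df[outcome_col].astype(float).to_numpy()
    if y.size == 0:
        raise ModelError("no outcome rows")
    if y.min() == y.max():
        raise SeparationError("all trials share one accuracy value; logit undefined")
    X, _ = build_design(df, spec)
    res = fit_glmm(y, X.to_numpy(), df[spec.group].to_numpy(), family="binomial")
    return _pack_result(
        list(X.columns), res.beta, res.se, res.cov, spec.family, res.n_obs,
        res.converged, dispersion=None, exponentiate=True,
        metadata={"random": f"(1 | {spec.group})", "approximation": _OMITTED_NOTE,
                  "random_intercept_sd": res.sigma, "loglik": res.loglik},
    )


def fit_switch_count_model(switch_table: pd.DataFrame, spec: ModelSpec,
                           count_col: str = "n_switches") -> FitResult:
    """NB2 random-intercept model for counts; reports IRRs and dispersion."""
    df = switch_table.dropna(subset=[count_col])
    y = df[count_col].to_numpy(dtype=float)
    if y.size == 0:
        raise ModelError("no count rows")
    if (y < 0).any():
        raise ModelError("negative counts")
    if y.max() == 0:
        raise ModelError("all counts are zero; rate model undefined")
    X, _ = build_design(df, spec)
    res = fit_glmm(y, X.to_numpy(), df[spec.group].to_numpy(), family="negbin")
    return _pack_result(
        list(X.columns), res.beta, res.se, res.cov, spec.family, res.n_obs,
        res.converged, dispersion=res.alpha, exponentiate=True,
        metadata={"random": f"(1 | {spec.group})", "approximation": _OMITTED_NOTE,
                  "random_intercept_sd": res.sigma, "loglik": res.loglik},
    )


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved,
    capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def condition_contrasts(
    fit: FitResult,
    comparisons: Optional[list[tuple[str, str]]] = None,
    term: str = "condition",
    reference: str = "sham",
) -> pd.DataFrame:
    """Estimates, SEs, raw and BH-adjusted p for a family of condition
    comparisons.

    The default family is every active condition vs the reference (sham).
    Pairs among non-reference conditions (the post-hoc family) are formed
    from coefficient differences using the fitted covariance.
    """
    cond_terms = {
        name.split("[", 1)[1].rstrip("]").rsplit("-", 1)[0]: name
        for name in fit.coefficients
        if name.startswith(f"{term}[")
    }
    if comparisons is None:
        comparisons = [(lv, reference) for lv in cond_terms]
    rows = []
    for a, b in comparisons:
        if a == b:
            est, se = 0.0, 0.0
        elif b == reference:
            name = cond_terms.get(a)
            if name is None:
                raise ModelError(f"contrast {a!r} vs {b!r} not estimable from fit")
            est = fit.coefficients[name]
            se = fit.std_errors[name]
        elif a == reference:
            name = cond_terms.get(b)
            if name is None:
                raise ModelError(f"contrast {a!r} vs {b!r} not estimable from fit")
            est = -fit.coefficients[name]
            se = fit.std_errors[name]
        else:
            na, nb = cond_terms.get(a), cond_terms.get(b)
            if na is None or nb is None:
                raise ModelError(f"contrast {a!r} vs {b!r} not estimable from fit")
            est = fit.coefficients[na] - fit.coefficients[nb]
            var = (
                fit.cov.loc[na, na] + fit.cov.loc[nb, nb] - 2.0 * fit.cov.loc[na, nb]
            )
            se = float(np.sqrt(max(var, 0.0)))
        if np.isfinite(se) and se > 0:
            p = 2.0 * sps.norm.sf(abs(est) / se)
        elif a == b:
            p = 1.0  # self-contrast: identically zero
        else:
            p = np.nan  # SE not estimable (degenerate fit)
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "p_raw": p,
                "exp_estimate": float(np.exp(est)) if fit.exp_effects else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    finite = np.isfinite(out["p_raw"].to_numpy())
    if finite.any():
        out.loc[finite, "p_adj"] = fdr_bh(out.loc[finite, "p_raw"].to_numpy())
    return out
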