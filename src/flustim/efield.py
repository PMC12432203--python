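"""Dose-response association between induced e-field strength and behavior.

The module consumes per-participant e-field summaries (the 95th-percentile
field strength in V/m within a small ROI around each stimulation target) as
data — it never computes fields from anatomy.  Associations are Pearson
correlations of a target's e-field with per-participant mean RT or accuracy
of the matching task and session, BH-FDR adjusted over the full declared
family; the dual-site session is handled with a two-predictor ordinary
least-squares regression whose coefficients are standardized post hoc
(beta_j * SD(x_j) / SD(y)), placing them on the correlation scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .stats import fdr_bh

logger = logging.getLogger(__name__)

__all__ = [
    "EFieldError",
    "read_efields",
    "correlate_efield_behavior",
    "dual_site_regression",
    "standardize_coefficients",
    "DualSiteResult",
]

TARGETS = ("IFG", "preSMA")

EFIELD_COLUMNS = ["participant", "target", "condition", "e95_Vpm"]


class EFieldError(ValueError):
    pass


def read_efields(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"participant": str})
    missing = [c for c in EFIELD_COLUMNS if c not in df.columns]
    if missing:
        raise EFieldError(f"{path}: missing columns {missing}")
    if (df["e95_Vpm"] <= 0).any():
        row = df.index[df["e95_Vpm"] <= 0][0]
        raise EFieldError(f"{path}: nonpositive e95 at line {row + 2}")
    dup = df.duplicated(subset=["participant", "target", "condition"])
    if dup.any():
        raise EFieldError(f"{path}: duplicate participant/target/condition at line {df.index[dup][0] + 2}")
    return df


def correlate_efield_behavior(
    efields: pd.DataFrame,
    behavior: pd.DataFrame,
    alternative: str = "two-sided",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation screen of e-field strength against behavior.

    ``behavior`` needs columns ``participant, condition, task, measure,
    value`` (one row per participant-level summary, e.g. mean RT in the IFG
    session).  Each target's e-field in its own stimulation session is
    paired with every task x measure summary from that same session; the BH
    family is all associations computed in the run.  Constant inputs are
    flagged ``undefined`` and excluded from the family with a logged reason.
    """
    if method not in ("pearson", "spearman"):
        raise EFieldError(f"unknown correlation method {method!r}")
    rows = []
    for target in TARGETS:
        ef = efields[(efields["target"] == target) & (efields["condition"] == target)]
        ef = ef.set_index("participant")["e95_Vpm"]
        beh = behavior[behavior["condition"] == target]
        for (task, measure), grp in beh.groupby(["task", "measure"], sort=True):
            merged = grp.set_index("participant")["value"].to_frame("value").join(
                ef, how="inner"
            ).dropna()
            n = len(merged)
            if n < 3:
                logger.warning("association (%s, %s, %s): only %d pairs, skipped",
                               target, task, measure, n)
                continue
            x = merged["e95_Vpm"].to_numpy(float)
            y = merged["value"].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("association (%s, %s, %s): constant input, undefined",
                               target, task, measure)
                rows.append({"target": target, "task": task, "measure": measure,
                             "n": n, "r": np.nan, "p_raw": np.nan,
                             "status": "undefined"})
                continue
            if method == "pearson":
                res = sps.pearsonr(x, y, alternative=alternative)
            else:
                res = sps.spearmanr(x, y, alternative=alternative)
            rows.append({"target": target, "task": task, "measure": measure,
                         "n": n, "r": float(res.statistic),
                         "p_raw": float(res.pvalue), "status": "ok"})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = np.nan
    ok = out["status"] == "ok"
    if ok.any():
        out.loc[ok, "p_adj"] = fdr_bh(out.loc[ok, "p_raw"].to_numpy())
    return out


@dataclass
class DualSiteResult:
    """OLS of behavior on both targets' e-fields (dual-site session)."""

    n: int
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    standardized_betas: dict[str, float]
    r_squared: float
    metadata: dict = field(default_factory=dict)


def dual_site_regression(
    e_ifg: Sequence[float],
    e_presma: Sequence[float],
    y: Sequence[float],
) -> DualSiteResult:
    """behavior ~ e_IFG + e_preSMA with intercept, plus standardized betas."""
    e_ifg = np.asarray(e_ifg, float)
    e_presma = np.asarray(e_presma, float)
    y = np.asarray(y, float)
    if not (len(e_ifg) == len(e_presma) == len(y)):
        raise EFieldError("predictor/outcome length mismatch")
    if len(y) < 4:
        raise EFieldError("dual-site regression needs >= 4 complete triples")
    if np.ptp(e_ifg) == 0 or np.ptp(e_presma) == 0 or np.ptp(y) == 0:
        raise EFieldError("constant predictor or outcome")
    r_pred = np.corrcoef(e_ifg, e_presma)[0, 1]
    if abs(r_pred) > 0.999:
        raise EFieldError(f"collinear predictors (|r| = {abs(r_pred):.4f} > 0.999)")
    X = sm.add_constant(np.column_stack([e_ifg, e_presma]))
    fit = sm.OLS(y, X).fit()
    names = ["Intercept", "e_IFG", "e_preSMA"]
    betas = dict(zip(names, fit.params))
    std = standardize_coefficients(
        {k: v for k, v in betas.items() if k != "Intercept"},
        x_sds={"e_IFG": np.std(e_ifg, ddof=1), "e_preSMA": np.std(e_presma, ddof=1)},
        y_sd=np.std(y, ddof=1),
    )
    return DualSiteResult(
        n=len(y),
        coefficients=betas,
        std_errors=dict(zip(names, fit.bse)),
        p_values=dict(zip(names, fit.pvalues)),
        standardized_betas=std,
        r_squared=float(fit.rsquared),
        metadata={"predictor_correlation": float(r_pred)},
    )


def standardize_coefficients(
    betas: dict[str, float],
    x_sds: dict[str, float],
    y_sd: float,
) -> dict[str, float]:
    """Post-hoc standardization: beta_j * SD(x_j) / SD(y).

    Places coefficients on a dimensionless common scale; for a
    single-predictor regression the result equals Pearson's r.  The
    intercept is excluded by construction (pass slope terms only).
    """
    if y_sd <= 0 or not np.isfinite(y_sd):
        raise EFieldError("outcome SD must be positive")
    out = {}
    for term, b in betas.items():
        sd = x_sds.get(term)
        if sd is None:
            raise EFieldError(f"no SD supplied for term {term!r}")
        if sd <= 0 or not np.isfinite(sd):
            raise EFieldError(f"zero or invalid SD for term {term!r}")
        out[term] = float(b) * float(sd) / float(y_sd)
    return out
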