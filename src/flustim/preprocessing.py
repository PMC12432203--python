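"""Task-specific reaction-time extraction, outlier removal, accuracy coding,
and participant-level covariates.

Trial tables are tab-separated text with one row per response and columns
``participant, session, condition, task, item, trial_index, response, onset,
offset, correct``.  Timestamp semantics differ by task:

* ``semantic_fluency`` — onset/offset of the spoken word; the RT of item *i*
  is ``onset_i - offset_{i-1}`` within a category (the first item has none).
* ``figural_fluency`` — onset = presentation of the blank dot arrangement,
  offset = the button press recording the design; RT = offset - onset.
* ``picture_naming`` — onset = picture presentation, offset = naming onset;
  RT = offset - onset.

The outlier rule removes, within each participant x session x task x item
group, RTs at least three sample SDs above the group mean, in a single pass.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "TrialTableError",
    "read_trials",
    "write_trials",
    "compute_rts",
    "outlier_filter",
    "OutlierReport",
    "code_fluency_accuracy",
    "code_figural_accuracy",
    "parse_bars",
    "executive_composite",
]

TRIAL_COLUMNS = [
    "participant",
    "session",
    "condition",
    "task",
    "item",
    "trial_index",
    "response",
    "onset",
    "offset",
    "correct",
]

TASKS = ("semantic_fluency", "figural_fluency", "picture_naming")
CONDITIONS = ("sham", "IFG", "preSMA", "dual")


class TrialTableError(ValueError):
    """Raised for schema violations in delimited-text inputs."""


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"participant": str, "response": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    bad_task = df.loc[~df["task"].isin(TASKS)]
    if not bad_task.empty:
        raise TrialTableError(
            f"{path}: unknown task {bad_task['task'].iloc[0]!r} "
            f"at line {bad_task.index[0] + 2}"
        )
    bad_cond = df.loc[~df["condition"].isin(CONDITIONS)]
    if not bad_cond.empty:
        raise TrialTableError(
            f"{path}: unknown condition {bad_cond['condition'].iloc[0]!r} "
            f"at line {bad_cond.index[0] + 2}"
        )
    both = df["onset"].notna() & df["offset"].notna()
    bad_time = df.loc[both & (df["offset"] < df["onset"])]
    if not bad_time.empty:
        raise TrialTableError(
            f"{path}: offset precedes onset at line {bad_time.index[0] + 2}"
        )
    # (participant, session) must map to exactly one condition
    n_cond = df.groupby(["participant", "session"])["condition"].nunique()
    if (n_cond > 1).any():
        key = n_cond[n_cond > 1].index[0]
        raise TrialTableError(f"{path}: multiple conditions for participant/session {key}")
    return df


def write_trials(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, columns=[c for c in TRIAL_COLUMNS if c in df.columns])


def compute_rts(records: pd.DataFrame, task: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract per-trial reaction times for one task.

    Returns ``(rts, flagged)``: the RT table (one row per eligible trial,
    column ``rt`` in seconds) and the table of rows excluded for negative RT
    or missing timestamps, with a ``reason`` column.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    df = records[records["task"] == task].copy()
    df = df.sort_values(["participant", "session", "item", "trial_index"])
    if task == "semantic_fluency":
        grp = df.groupby(["participant", "session", "item"], sort=False)
        df["rt"] = df["onset"] - grp["offset"].shift(1)
        df["reason"] = ""
        df.loc[grp.cumcount() == 0, "reason"] = "first-item (no preceding offset)"
    else:
        df["rt"] = df["offset"] - df["onset"]
        df["reason"] = ""
    df.loc[df["reason"].eq("") & df["rt"].isna(), "reason"] = "missing timestamp"
    df.loc[df["reason"].eq("") & (df["rt"] < 0), "reason"] = "negative RT"
    flagged = df[df["reason"] != ""].copy()
    rts = df[df["reason"] == ""].drop(columns=["reason"])
    return rts, flagged


@dataclass
class OutlierReport:
    n_total: int
    n_removed: int
    per_group: pd.DataFrame  # group keys + n, n_removed, mean, sd, cutoff

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


def outlier_filter(
    rts: pd.DataFrame,
    group_cols: Sequence[str] = ("participant", "session", "task", "item"),
    n_sd: float = 3.0,
    min_group_size: int = 3,
    rt_col: str = "rt",
) -> tuple[pd.DataFrame, OutlierReport]:
    """Single-pass upper 3-SD trim within each grouping cell.

    A row is removed when ``rt >= mean + n_sd * sd`` of its group, with the
    sample SD (n-1 denominator).  Groups smaller than ``min_group_size`` are
    passed through untouched (SD on so few points is unstable).
    """
    missing = [c for c in group_cols if c not in rts.columns]
    if missing:
        raise TrialTableError(f"outlier_filter: missing grouping columns {missing}")
    df = rts.copy()
    grp = df.groupby(list(group_cols), sort=False)[rt_col]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    size = grp.transform("size")
    cutoff = mean + n_sd * sd
    remove = (size >= min_group_size) & sd.gt(0) & (df[rt_col] >= cutoff)
    kept = df[~remove]
    per_group = (
        df.assign(_removed=remove)
        .groupby(list(group_cols), sort=False)
        .agg(n=(rt_col, "size"), n_removed=("_removed", "sum"),
             mean=(rt_col, "mean"), sd=(rt_col, "std"))
        .reset_index()
    )
    per_group["cutoff"] = per_group["mean"] + n_sd * per_group["sd"]
    report = OutlierReport(n_total=len(df), n_removed=int(remove.sum()), per_group=per_group)
    return kept, report


def _normalize_response(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold().str.replace(r"\s+", " ", regex=True)


def code_fluency_accuracy(
    records: pd.DataFrame,
    category_members: Optional[dict[str, Iterable[str]]] = None,
    proper_names: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Set ``correct`` for semantic-fluency rows.

    Within a participant x session x category, the second and later
    occurrences of a normalized response are incorrect (repetitions).  When
    a category membership list is supplied, responses outside it are
    incorrect (wrong answers), as are responses on the proper-name list.
    Other tasks' rows are returned unchanged.
    """
    df = records.copy()
    mask = df["task"] == "semantic_fluency"
    sem = df[mask].sort_values(["participant", "session", "item", "trial_index"])
    norm = _normalize_response(sem["response"])
    dup = norm.groupby(
        [sem["participant"], sem["session"], sem["item"]]
    ).transform(lambda s: s.duplicated())
    correct = ~dup
    if category_members is not None:
        members = {
            str(cat): {w.strip().casefold() for w in words}
            for cat, words in category_members.items()
        }
        in_cat = pd.Series(
            [tok in members.get(str(cat), set()) for tok, cat in zip(norm, sem["item"])],
            index=sem.index,
        )
        correct &= in_cat
    if proper_names is not None:
        banned = {w.strip().casefold() for w in proper_names}
        correct &= ~norm.isin(banned)
    df.loc[sem.index, "correct"] = correct
    return df


def parse_bars(bars: str) -> frozenset[frozenset[str]]:
    """Parse a design descriptor like ``"1-2;2-3"`` into a set of bars
    (unordered dot pairs)."""
    out = set()
    for part in str(bars).split(";"):
        part = part.strip()
        if not part:
            continue
        dots = part.split("-")
        if len(dots) != 2 or dots[0] == dots[1]:
            raise TrialTableError(f"malformed bar {part!r} in design {bars!r}")
        out.add(frozenset(dots))
    if not out:
        raise TrialTableError(f"design {bars!r} has no bars")
    return frozenset(out)


def code_figural_accuracy(
    designs: pd.DataFrame,
    arrangement_dots: Optional[dict[str, Iterable[str]]] = None,
    bars_col: str = "response",
) -> pd.Series:
    """Correct flags for figural designs: the first occurrence of each
    distinct bar-set within a participant x session x arrangement is correct,
    later identical bar-sets (order-insensitive) are repetitions.

    ``arrangement_dots`` optionally validates that every bar joins dots that
    exist in its arrangement.
    """
    df = designs.sort_values(["participant", "session", "item", "trial_index"])
    parsed = df[bars_col].map(parse_bars)
    if arrangement_dots is not None:
        dots = {str(k): set(v) for k, v in arrangement_dots.items()}
        for idx, (arr, bar_set) in zip(df.index, zip(df["item"], parsed)):
            known = dots.get(str(arr))
            if known is None:
                raise TrialTableError(f"unknown arrangement {arr!r}")
            used = set().union(*bar_set)
            if not used <= known:
                raise TrialTableError(
                    f"design at row {idx} references dots {sorted(used - known)} "
                    f"outside arrangement {arr!r}"
                )
    dup = parsed.groupby(
        [df["participant"], df["session"], df["item"]]
    ).transform(lambda s: s.duplicated())
    return (~dup).reindex(designs.index)


def _zscore(x: pd.Series, name: str) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot z-standardize constant column {name!r}")
    return (x - x.mean()) / sd


def executive_composite(scores: pd.DataFrame) -> pd.DataFrame:
    """Executive composite and verbal-knowledge covariates.

    ``executive_z`` = per-participant mean of z(-TMT seconds) and
    z(DSST count); ``stw_z`` = z(Spot-the-Word raw).  All z-scores use the
    analysis cohort's sample mean/SD (TMT is inverted first so that larger
    values mean better performance for both tests).
    """
    required = ["participant", "tmt_seconds", "dsst_count", "stw_raw"]
    missing = [c for c in required if c not in scores.columns]
    if missing:
        raise TrialTableError(f"executive_composite: missing columns {missing}")
    if len(scores) < 2:
        raise ValueError("executive composite needs a cohort of >= 2 participants")
    df = scores.copy()
    tmt_z = _zscore(-df["tmt_seconds"].astype(float), "tmt_seconds")
    dsst_z = _zscore(df["dsst_count"].astype(float), "dsst_count")
    df["executive_z"] = (tmt_z + dsst_z) / 2.0
    df["stw_z"] = _zscore(df["stw_raw"].astype(float), "stw_raw")
    return df
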