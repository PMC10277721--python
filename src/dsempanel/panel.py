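"""Weekly symptom panel container, CSV I/O and eligibility filtering.

A :class:`Panel` holds one score per participant, outcome and week on a
common 1..T weekly grid.  Weeks a participant did not answer are explicit
``NaN`` cells, never absent rows, so the missingness mask is always
well-defined.  Baseline covariates (bipolar subtype, gender, the age >= 55
indicator and history of rapid cycling) are binary and fixed per
participant.

Two CSV dialects are read: ``scores`` (columns ``dep``, ``ins``, ``hypo``,
empty cell = missing week) and ``items`` (raw questionnaire columns
``qids_01``..``qids_16`` and ``asrm_01``..``asrm_05``, scored on read via
:mod:`dsempanel.scales`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import scales

__all__ = [
    "OUTCOMES",
    "SCALE_BOUNDS",
    "COVARIATES",
    "Panel",
    "read_panel",
    "write_panel",
    "apply_eligibility",
    "missingness_summary",
]

OUTCOMES = ("dep", "ins", "hypo")
#: inclusive upper bound of each outcome scale (lower bound is 0)
SCALE_BOUNDS = {"dep": 27, "ins": 9, "hypo": 16}
COVARIATES = ("bd2", "female", "age55", "rapid")

_QIDS_COLS = [f"qids_{i:02d}" for i in range(1, 17)]
_ASRM_COLS = [f"asrm_{i:02d}" for i in range(1, 6)]


@dataclasses.dataclass
class Panel:
    """Long-format weekly panel on a common 1..T grid.

    Attributes
    ----------
    data
        DataFrame with columns ``id``, ``week`` and one column per outcome
        in :data:`OUTCOMES` (float, ``NaN`` = missing), sorted by
        (id, week), exactly T rows per participant.
    covariates
        DataFrame indexed by participant id with the binary columns of
        :data:`COVARIATES`.
    """

    data: pd.DataFrame
    covariates: pd.DataFrame

    @property
    def ids(self) -> list:
        return list(self.covariates.index)

    @property
    def n_participants(self) -> int:
        return len(self.covariates)

    @property
    def n_weeks(self) -> int:
        return int(self.data["week"].max()) if len(self.data) else 0

    def validate(self) -> "Panel":
        dup = self.data.duplicated(subset=["id", "week"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValueError(f"duplicate (id, week) pair: ({row['id']}, {row['week']})")
        weeks = self.data["week"]
        if not np.array_equal(weeks, weeks.astype(int)):
            raise ValueError("week indices must be integers")
        if len(self.data) and weeks.min() < 1:
            raise ValueError("week indices are 1-based; found week < 1")
        T = self.n_weeks
        counts = self.data.groupby("id")["week"].agg(["count", "nunique"])
        if (counts["count"] != T).any() or (counts["nunique"] != T).any():
            bad = counts.index[counts["count"] != T].tolist()
            raise ValueError(f"participants not on the common 1..{T} grid: {bad[:5]}")
        missing_cov = set(self.data["id"]) - set(self.covariates.index)
        if missing_cov:
            raise ValueError(f"participants without covariate records: {sorted(missing_cov)[:5]}")
        for c in COVARIATES:
            vals = self.covariates[c]
            if not vals.isin([0, 1]).all():
                raise ValueError(f"covariate {c!r} outside {{0,1}}")
        return self

    def to_arrays(self, outcomes) -> np.ndarray:
        """Return a (n_participants, T, len(outcomes)) float array, NaN = missing."""
        T = self.n_weeks
        wide = {
            y: self.data.pivot(index="id", columns="week", values=y).reindex(
                index=self.ids, columns=range(1, T + 1)
            )
            for y in outcomes
        }
        return np.stack([wide[y].to_numpy(dtype=float) for y in outcomes], axis=-1)

    def covariate_matrix(self) -> np.ndarray:
        return self.covariates[list(COVARIATES)].to_numpy(dtype=float)

    def subset(self, ids) -> "Panel":
        ids = list(ids)
        data = self.data[self.data["id"].isin(ids)].copy()
        return Panel(data.reset_index(drop=True), self.covariates.loc[ids].copy())

    def split(self, covariate: str) -> dict:
        """Split into strata {0: Panel, 1: Panel} on a binary covariate."""
        if covariate not in COVARIATES:
            raise ValueError(f"unknown stratification covariate {covariate!r}")
        out = {}
        for level in (0, 1):
            ids = self.covariates.index[self.covariates[covariate] == level]
            if len(ids) == 0:
                raise ValueError(f"degenerate stratum: no participants with {covariate}={level}")
            out[level] = self.subset(ids)
        return out

    def plot_series(self, participant_id, outcomes=OUTCOMES, ax=None):
        """Plot one participant's weekly series (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.data[self.data["id"] == participant_id].sort_values("week")
        for y in outcomes:
            if y in sub and not sub[y].isna().all():
                ax.plot(sub["week"], sub[y], marker=".", label=y)
        ax.set_xlabel("week")
        ax.set_ylabel("score")
        ax.legend()
        return ax


def _score_item_rows(df: pd.DataFrame) -> pd.DataFrame:
    dep, ins, hypo = [], [], []
    for idx, row in df.iterrows():
        qids = row[_QIDS_COLS]
        asrm = row[_ASRM_COLS]
        q_missing, a_missing = qids.isna().all(), asrm.isna().all()
        if qids.isna().any() and not q_missing:
            raise ValueError(
                f"partial QIDS item missingness at id={row['id']} week={row['week']}; "
                "weeks must be answered in full or missing in full"
            )
        if asrm.isna().any() and not a_missing:
            raise ValueError(
                f"partial ASRM item missingness at id={row['id']} week={row['week']}"
            )
        if q_missing:
            dep.append(np.nan)
            ins.append(np.nan)
        else:
            items = [int(v) for v in qids]
            dep.append(scales.score_qids_depression(items))
            ins.append(scales.score_qids_insomnia(items))
        hypo.append(np.nan if a_missing else scales.score_asrm([int(v) for v in asrm]))
    out = df[["id", "week"]].copy()
    out["dep"], out["ins"], out["hypo"] = dep, ins, hypo
    return out


def read_panel(path, dialect: str = "scores", n_weeks: int | None = None) -> Panel:
    """Read a long-format panel CSV onto an explicit 1..T grid.

    Parameters
    ----------
    path
        CSV with header ``id, week, bd2, female, age55, rapid`` followed by
        the dialect's outcome columns.
    dialect
        ``"scores"`` for pre-computed ``dep, ins, hypo`` columns or
        ``"items"`` for raw questionnaire items (scored on read).
    n_weeks
        Grid length T; defaults to the maximum week index in the file.
    """
    if dialect not in ("scores", "items"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    required = ["id", "week", *COVARIATES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns: {missing}")
    week_float = pd.to_numeric(df["week"], errors="raise")
    if not np.array_equal(week_float, week_float.astype(int)):
        raise ValueError("non-integer week index in panel CSV")
    df["week"] = week_float.astype(int)
    if df.duplicated(subset=["id", "week"]).any():
        row = df[df.duplicated(subset=["id", "week"])].iloc[0]
        raise ValueError(f"duplicate (id, week) pair: ({row['id']}, {row['week']})")

    cov = df.groupby("id")[list(COVARIATES)].agg(["first", "nunique"])
    for c in COVARIATES:
        if (cov[(c, "nunique")] > 1).any():
            raise ValueError(f"covariate {c!r} varies within a participant")
    covariates = cov.xs("first", axis=1, level=1)
    for c in COVARIATES:
        if not covariates[c].isin([0, 1]).all():
            raise ValueError(f"covariate {c!r} outside {{0,1}}")
    covariates = covariates.astype(int)

    if dialect == "items":
        for c in _QIDS_COLS + _ASRM_COLS:
            if c not in df.columns:
                raise ValueError(f"items dialect requires column {c!r}")
        long = _score_item_rows(df)
    else:
        for c in OUTCOMES:
            if c not in df.columns:
                df[c] = np.nan
        long = df[["id", "week", *OUTCOMES]].copy()
        for y in OUTCOMES:
            long[y] = pd.to_numeric(long[y], errors="raise")

    T = int(n_weeks if n_weeks is not None else long["week"].max())
    grid = pd.MultiIndex.from_product([covariates.index, range(1, T + 1)], names=["id", "week"])
    long = (
        long.set_index(["id", "week"])
        .reindex(grid)
        .reset_index()
        .sort_values(["id", "week"])
        .reset_index(drop=True)
    )
    return Panel(long, covariates).validate()


def write_panel(panel: Panel, path) -> None:
    """Write the scores dialect CSV (explicit grid, empty cell = missing)."""
    out = panel.data.merge(
        panel.covariates.reset_index().rename(columns={"index": "id"}), on="id"
    )
    out = out[["id", "week", *COVARIATES, *OUTCOMES]].sort_values(["id", "week"])
    out.to_csv(path, index=False)


def _modelled_outcomes(panel: Panel, outcomes=None):
    if outcomes is not None:
        return list(outcomes)
    return [y for y in OUTCOMES if not panel.data[y].isna().all()]


def apply_eligibility(
    panel: Panel,
    min_weeks: int = 20,
    require_variation: bool = True,
    outcomes=None,
):
    """Apply the eligibility filters for intensive longitudinal analysis.

    Removes participants with fewer than ``min_weeks`` non-missing weeks on
    any modelled outcome, and (when ``require_variation``) participants
    whose observed values on any modelled outcome never vary — such flat
    series carry no within-person dynamic information.

    Returns ``(panel, exclusion_log)`` where the log is a DataFrame with
    columns ``id`` and ``reason``.
    """
    outcomes = _modelled_outcomes(panel, outcomes)
    records = []
    keep = []
    grouped = panel.data.groupby("id")
    for pid in panel.ids:
        sub = grouped.get_group(pid)
        reason = None
        for y in outcomes:
            vals = sub[y].dropna()
            if len(vals) < min_weeks:
                reason = f"fewer than {min_weeks} non-missing weeks ({y}: {len(vals)})"
                break
        if reason is None and require_variation:
            for y in outcomes:
                vals = sub[y].dropna()
                if len(vals) > 0 and vals.nunique() == 1:
                    reason = f"no variation ({y})"
                    break
        if reason is None:
            keep.append(pid)
        else:
            records.append({"id": pid, "reason": reason})
    if not keep:
        raise ValueError(
            "eligibility filters removed every participant; review min_weeks "
            f"(={min_weeks}) and require_variation (={require_variation})"
        )
    log = pd.DataFrame.from_records(records, columns=["id", "reason"])
    return panel.subset(keep), log


def missingness_summary(panel: Panel, outcomes=None) -> dict:
    """Per-participant, per-week and overall missing fractions."""
    outcomes = _modelled_outcomes(panel, outcomes)
    if not outcomes:
        outcomes = list(OUTCOMES)
    mask = panel.data[outcomes].isna()
    by_id = mask.groupby(panel.data["id"]).mean().mean(axis=1)
    by_week = mask.groupby(panel.data["week"]).mean().mean(axis=1)
    return {
        "per_participant": by_id,
        "per_week": by_week,
        "overall": float(mask.to_numpy().mean()),
    }
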