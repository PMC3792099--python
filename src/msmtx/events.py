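"""Domain model for the three-state transplant process and dataset assembly.

The process has states Diagnosis (1) -> Transplant (2) -> Death (3), with a
direct Diagnosis -> Death transition; Death is absorbing.  Two registries
observe it partially:

* a transplant registry containing only patients who reached transplant
  (so the Diagnosis -> Transplant waiting time is right-truncated and
  post-transplant follow-up is left-truncated at the transplant date), and
* a non-transplant registry containing only patients never transplanted
  during follow-up, from which the pre-transplant death rate is estimated.

This module validates per-patient registry records and deterministically
assembles them into transition-specific counting-process rows (the long
format every estimator downstream consumes), following the estimability
rules that the design implies: Diagnosis->Death rows come only from the
non-transplant registry, Transplant->Death rows only from the transplant
registry (with delayed entry at the transplant date on the diagnosis clock),
and the Diagnosis->Transplant transition is represented not as rows but as a
right-truncated waiting-time sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "REGISTRY_COLUMNS",
    "COVARIATE_COLUMNS",
    "MultiStateData",
    "ValidationIssue",
    "validate_records",
    "assemble_multistate_dataset",
    "assemble_complete_dataset",
    "read_registry_csv",
    "write_registry_csv",
]

# Registry CSV schema; times are day offsets from diagnosis, never dates.
COVARIATE_COLUMNS = ["age_gt60", "raebt", "cyto_abnormal", "year_dx"]
REGISTRY_COLUMNS = [
    "id", "cohort", "t_tx_days", "t_end_days", "dead", "r_trunc_days",
] + COVARIATE_COLUMNS

COHORTS = ("tx_registry", "non_tx_registry", "complete")

#: transition codes used throughout: 1 = Dx->Tx, 2 = Dx->Death, 3 = Tx->Death
TRANS_DX_TX, TRANS_DX_DEATH, TRANS_TX_DEATH = 1, 2, 3


@dataclass(frozen=True)
class StateSpace:
    """The illness-death state space: Diagnosis -> Transplant -> Death."""

    states: dict = field(
        default_factory=lambda: {1: "Diagnosis", 2: "Transplant", 3: "Death"}
    )
    transitions: tuple = ((1, 2), (1, 3), (2, 3))

    def __post_init__(self):
        if len(self.states) != 3:
            raise ValueError("illness-death model has exactly 3 states")
        if set(self.transitions) != {(1, 2), (1, 3), (2, 3)}:
            raise ValueError("transitions must be (1,2), (1,3), (2,3)")

    @property
    def absorbing(self) -> int:
        return 3


@dataclass(frozen=True)
class ValidationIssue:
    id: object
    code: str
    action: str  # "adjusted" or "rejected"
    detail: str = ""


def _as_binary(col: pd.Series) -> pd.Series:
    return pd.to_numeric(col, errors="coerce")


def validate_records(
    records: pd.DataFrame,
    *,
    tie_offset_days: float = 0.5,
    year_range: tuple[int, int] = (1950, 2035),
) -> tuple[pd.DataFrame, list[ValidationIssue]]:
    """Validate and clean a registry table.

    Hard violations (duplicate ids, negative times, a transplant-registry
    record lacking a transplant time, unknown cohort labels) raise
    ``ValueError``.  Recoverable problems are resolved or dropped and
    reported: a same-day transplant-and-death tie gets ``tie_offset_days``
    added to the end time (counting processes need strictly positive at-risk
    intervals); records violating registry membership rules are rejected.

    Returns the cleaned table and a list of :class:`ValidationIssue`.
    """
    df = records.copy().reset_index(drop=True)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing registry columns: {missing}")

    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise ValueError(
            f"unknown cohort labels: {sorted(df.loc[bad_cohort, 'cohort'].unique())}"
        )

    for col in ("t_tx_days", "t_end_days", "r_trunc_days"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["t_end_days"] < 0).any() or (df["t_tx_days"] < 0).any():
        raise ValueError("negative time offsets are not allowed")
    if ((df["cohort"] == "tx_registry") & df["t_tx_days"].isna()).any():
        raise ValueError("tx_registry record lacking t_tx_days")

    df["dead"] = pd.to_numeric(df["dead"], errors="coerce").astype(int)
    for col in ("age_gt60", "raebt", "cyto_abnormal"):
        df[col] = _as_binary(df[col])
    df["year_dx"] = pd.to_numeric(df["year_dx"], errors="coerce")

    issues: list[ValidationIssue] = []
    keep = np.ones(len(df), dtype=bool)

    for i, row in df.iterrows():
        rid = row["id"]
        if row["cohort"] == "non_tx_registry" and not pd.isna(row["t_tx_days"]):
            issues.append(ValidationIssue(
                rid, "transplant in non-transplant registry", "rejected"))
            keep[i] = False
            continue
        if not row["t_end_days"] > 0:
            issues.append(ValidationIssue(
                rid, "non-positive follow-up time", "rejected"))
            keep[i] = False
            continue
        t_tx = row["t_tx_days"]
        if not pd.isna(t_tx):
            if t_tx <= 0 or t_tx > row["t_end_days"]:
                issues.append(ValidationIssue(
                    rid, "transplant time outside (0, t_end]", "rejected"))
                keep[i] = False
                continue
            if t_tx == row["t_end_days"]:
                df.loc[i, "t_end_days"] = t_tx + tie_offset_days
                issues.append(ValidationIssue(
                    rid, "same-day transplant/death", "adjusted",
                    f"t_end_days set to {t_tx + tie_offset_days}"))
            rtr = row["r_trunc_days"]
            if row["cohort"] == "tx_registry" and not pd.isna(rtr) and t_tx > rtr:
                issues.append(ValidationIssue(
                    rid, "transplant after right-truncation limit", "rejected"))
                keep[i] = False
                continue
        for col in ("age_gt60", "raebt", "cyto_abnormal"):
            v = row[col]
            if not pd.isna(v) and v not in (0, 1):
                issues.append(ValidationIssue(
                    rid, f"non-binary {col}", "rejected"))
                keep[i] = False
                break
        if not keep[i]:
            continue
        y = row["year_dx"]
        if not pd.isna(y) and not (year_range[0] <= y <= year_range[1]):
            issues.append(ValidationIssue(rid, "year_dx out of range", "rejected"))
            keep[i] = False

    return df.loc[keep].reset_index(drop=True), issues


@dataclass
class MultiStateData:
    """Assembled counting-process data for the illness-death registries.

    Attributes
    ----------
    transition_rows : DataFrame
        Long format, one row per at-risk interval, columns
        ``id, trans, entry, exit, status`` plus covariates (transition-3 rows
        additionally carry ``wait_days``, the diagnosis-to-transplant
        interval).  Transition codes: 2 = Diagnosis->Death (non-transplant
        registry), 3 = Transplant->Death (transplant registry).
    waiting_times : DataFrame
        One row per transplant-registry subject: observed waiting time
        ``time`` and right-truncation limit ``rtrunc`` (``time <= rtrunc``).
    clock : str
        'forward' (times since diagnosis, delayed entry at transplant) or
        'reset' (transition-3 times since transplant).
    """

    transition_rows: pd.DataFrame
    waiting_times: pd.DataFrame
    clock: str
    _comparison_rows: pd.DataFrame | None = None

    @property
    def comparison_rows(self) -> pd.DataFrame:
        """Pooled treatment-comparison rows on the diagnosis time scale.

        Non-transplant subjects are at risk over ``(0, t_end]`` with
        ``tx_state=0``; transplant subjects enter the risk set at transplant
        (``(t_tx, t_end]``) with ``tx_state=1``.  Only defined on the
        forward clock.
        """
        if self._comparison_rows is None:
            raise ValueError(
                "comparison rows are defined on the diagnosis time scale only "
                "(clock='forward')"
            )
        return self._comparison_rows

    def rows_for(self, trans: int) -> pd.DataFrame:
        return self.transition_rows[self.transition_rows["trans"] == trans]


def assemble_multistate_dataset(
    non_tx: pd.DataFrame,
    tx: pd.DataFrame,
    clock: str = "forward",
    *,
    validate: bool = True,
) -> MultiStateData:
    """Map the two registry tables onto counting-process form.

    The mapping is exact: non-transplant records produce one
    Diagnosis->Death row each (entry 0, exit ``t_end_days``); transplant
    records produce one Transplant->Death row each (delayed entry at
    ``t_tx_days`` on the forward clock, or entry 0 / exit
    ``t_end - t_tx`` on the reset clock) and one right-truncated
    waiting-time pair.  No Diagnosis->Transplant rows are emitted: that
    transition is not directly estimable because the transplant registry
    never observes deaths while waiting.  On the forward clock, pooled
    per-subject comparison rows are also produced for the treatment Cox
    model.
    """
    if clock not in ("forward", "reset"):
        raise ValueError("clock must be 'forward' or 'reset'")
    if len(non_tx) == 0:
        raise ValueError("empty non-transplant cohort")
    if len(tx) == 0:
        raise ValueError("empty transplant cohort")
    if validate:
        non_tx, _ = validate_records(non_tx)
        tx, _ = validate_records(tx)
        if len(non_tx) == 0 or len(tx) == 0:
            raise ValueError("a cohort became empty after validation")
    overlap = set(non_tx["id"]) & set(tx["id"])
    if overlap:
        raise ValueError(f"subjects present in both registries: {sorted(overlap)}")

    cov_n = non_tx[COVARIATE_COLUMNS].reset_index(drop=True)
    cov_t = tx[COVARIATE_COLUMNS].reset_index(drop=True)

    rows_2 = pd.DataFrame({
        "id": non_tx["id"].values,
        "trans": TRANS_DX_DEATH,
        "entry": 0.0,
        "exit": non_tx["t_end_days"].values.astype(float),
        "status": non_tx["dead"].values.astype(int),
        "tx_state": 0,
    }).join(cov_n)

    t_tx = tx["t_tx_days"].values.astype(float)
    t_end = tx["t_end_days"].values.astype(float)
    if clock == "forward":
        entry3, exit3 = t_tx, t_end
    else:
        entry3, exit3 = np.zeros_like(t_tx), t_end - t_tx
    rows_3 = pd.DataFrame({
        "id": tx["id"].values,
        "trans": TRANS_TX_DEATH,
        "entry": entry3,
        "exit": exit3,
        "status": tx["dead"].values.astype(int),
        "tx_state": 1,
    }).join(cov_t)
    rows_3["wait_days"] = t_tx

    transition_rows = pd.concat([rows_2, rows_3], ignore_index=True)

    # Right-truncated waiting-time sample; when no data-collection limit is
    # recorded the maximum observed waiting time is used, which makes the
    # estimated CDF conditional on T <= that maximum.
    rtrunc = tx["r_trunc_days"].values.astype(float)
    rtrunc = np.where(np.isnan(rtrunc), np.max(t_tx), rtrunc)
    waiting = pd.DataFrame({"id": tx["id"].values, "time": t_tx, "rtrunc": rtrunc})

    comparison = None
    if clock == "forward":
        comp_n = rows_2.copy()
        comp_t = pd.DataFrame({
            "id": tx["id"].values,
            "trans": 0,
            "entry": t_tx,
            "exit": t_end,
            "status": tx["dead"].values.astype(int),
            "tx_state": 1,
        }).join(cov_t)
        comp_n = comp_n.assign(trans=0)
        comparison = pd.concat([comp_n, comp_t], ignore_index=True)
        comparison = comparison.drop(columns=["wait_days"], errors="ignore")

    return MultiStateData(
        transition_rows=transition_rows,
        waiting_times=waiting,
        clock=clock,
        _comparison_rows=comparison,
    )


def assemble_complete_dataset(
    records: pd.DataFrame, clock: str = "forward", *, validate: bool = True
) -> MultiStateData:
    """Counting-process rows for a fully observed (simulated) cohort.

    Unlike the registry situation, a complete cohort observes every subject
    from diagnosis, so all three transitions are directly estimable:
    each subject contributes a Diagnosis->Transplant and a Diagnosis->Death
    row over ``(0, min(t_tx, t_end)]`` (competing risks out of Diagnosis)
    and, if transplanted, a Transplant->Death row with delayed entry.
    """
    if clock not in ("forward", "reset"):
        raise ValueError("clock must be 'forward' or 'reset'")
    if len(records) == 0:
        raise ValueError("empty cohort")
    if validate:
        records, _ = validate_records(records)

    cov = records[COVARIATE_COLUMNS].reset_index(drop=True)
    t_tx = records["t_tx_days"].values.astype(float)
    t_end = records["t_end_days"].values.astype(float)
    dead = records["dead"].values.astype(int)
    has_tx = ~np.isnan(t_tx)
    exit1 = np.where(has_tx, t_tx, t_end)

    rows_1 = pd.DataFrame({
        "id": records["id"].values, "trans": TRANS_DX_TX,
        "entry": 0.0, "exit": exit1,
        "status": has_tx.astype(int), "tx_state": 0,
    }).join(cov)
    rows_2 = pd.DataFrame({
        "id": records["id"].values, "trans": TRANS_DX_DEATH,
        "entry": 0.0, "exit": exit1,
        "status": (~has_tx & (dead == 1)).astype(int), "tx_state": 0,
    }).join(cov)
    sub = records.loc[has_tx]
    if clock == "forward":
        entry3, exit3 = t_tx[has_tx], t_end[has_tx]
    else:
        entry3, exit3 = np.zeros(int(has_tx.sum())), t_end[has_tx] - t_tx[has_tx]
    rows_3 = pd.DataFrame({
        "id": sub["id"].values, "trans": TRANS_TX_DEATH,
        "entry": entry3, "exit": exit3,
        "status": sub["dead"].values.astype(int), "tx_state": 1,
    }).join(cov.loc[has_tx].reset_index(drop=True))
    rows_3["wait_days"] = t_tx[has_tx]

    transition_rows = pd.concat([rows_1, rows_2, rows_3], ignore_index=True)
    waiting = pd.DataFrame({
        "id": sub["id"].values, "time": t_tx[has_tx],
        "rtrunc": np.full(int(has_tx.sum()), np.inf),
    })
    return MultiStateData(transition_rows=transition_rows,
                          waiting_times=waiting, clock=clock)


def read_registry_csv(path) -> pd.DataFrame:
    """Read a registry table; empty fields are missing values."""
    df = pd.read_csv(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing registry columns {missing}")
    return df[REGISTRY_COLUMNS]


def write_registry_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=REGISTRY_COLUMNS, float_format="%.10g")


#: long-format exchange schema consumed by every estimator downstream
COUNTING_PROCESS_COLUMNS = ["id", "trans", "entry", "exit", "status",
                            "tx_state"] + COVARIATE_COLUMNS


def write_counting_process_csv(rows: pd.DataFrame, path) -> None:
    cols = [c for c in COUNTING_PROCESS_COLUMNS if c in rows.columns]
    extra = [c for c in rows.columns if c not in cols]
    rows.to_csv(path, index=False, columns=cols + extra, float_format="%.10g")


def read_counting_process_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"entry", "exit", "status"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing counting-process columns "
                         f"{sorted(need - set(df.columns))}")
    return df
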