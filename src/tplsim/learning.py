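"""Learning index, learner classification and group summaries.

The learning index (LI) is the fractional change in threshold from the
pre-test to the post-test, LI = (pre − post) / pre, computed per condition
on the Weber-fraction scale; positive LI means improvement. A *learner* is
a participant whose trained-condition threshold strictly decreased from pre
to post (a tie classifies as non-learner). The test design crosses stimulus
format (empty, filled) with standard duration (200, 400 ms), so each
participant contributes four LI values.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .observer import TRAINED_CONDITION, Condition

__all__ = [
    "ExcludedParticipantError",
    "learning_index",
    "summarize_learning",
    "learner_ratio",
    "learning_curve",
    "group_summary",
]


class ExcludedParticipantError(ValueError):
    """The requested participant was excluded upstream."""


def learning_index(pre_wf: float, post_wf: float) -> float:
    """LI = (pre − post) / pre; positive iff performance improved."""
    if pre_wf <= 0:
        raise ValueError("pre_wf must be strictly positive")
    return (pre_wf - post_wf) / pre_wf


def summarize_learning(
    sessions: pd.DataFrame,
    *,
    trained_condition: dict[str, Condition] | None = None,
) -> pd.DataFrame:
    """Per participant × condition: pre/post WF, LI, learner flag.

    ``sessions`` is the session-level table (one pre and one post row per
    participant × condition). ``learner`` is a participant-level flag —
    strict pre→post decrease on the group's trained condition — repeated on
    each of the participant's rows; ``improved`` is the row-wise flag.
    """
    trained = trained_condition or TRAINED_CONDITION
    tests = sessions[sessions["phase"].isin(["pre", "post"])]
    wide = tests.pivot_table(
        index=["participant", "group", "condition_format", "condition_duration"],
        columns="phase",
        values="wf",
        aggfunc="first",
    ).reset_index()
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise ValueError("sessions table lacks pre and/or post phases")
    wide = wide.dropna(subset=["pre", "post"])
    wide["learning_index"] = (wide["pre"] - wide["post"]) / wide["pre"]
    wide["improved"] = wide["post"] < wide["pre"]
    wide["trained"] = [
        (f, d) == trained[g]
        for f, d, g in zip(
            wide["condition_format"], wide["condition_duration"], wide["group"]
        )
    ]
    learner_by_pid = (
        wide[wide["trained"]].set_index("participant")["improved"].to_dict()
    )
    wide["learner"] = wide["participant"].map(learner_by_pid)
    wide = wide.rename(columns={"pre": "pre_wf", "post": "post_wf"})
    cols = [
        "participant",
        "group",
        "condition_format",
        "condition_duration",
        "pre_wf",
        "post_wf",
        "learning_index",
        "improved",
        "trained",
        "learner",
    ]
    return wide[cols].sort_values(
        ["group", "participant", "condition_format", "condition_duration"]
    ).reset_index(drop=True)


def learner_ratio(summaries: pd.DataFrame, group: str | None = None) -> float:
    """Fraction of a group's participants classified as learners.

    Computed over the trained-condition rows; ``group=None`` pools all rows.
    """
    rows = summaries[summaries["trained"]]
    if group is not None:
        rows = rows[rows["group"] == group]
    if len(rows) == 0:
        raise ValueError("no participants in the requested group")
    return float(rows["improved"].mean())


def learning_curve(
    sessions: pd.DataFrame,
    participant: str,
    *,
    excluded: Sequence[str] = (),
    trained_condition: dict[str, Condition] | None = None,
    n_training_sessions: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Trained-condition WFs over the schedule: pre, training 1..n, post.

    Returns ``(values, present)``: a ``(n_training_sessions + 2)``-element
    array ordered pre → training → post, with missing training sessions left
    as NaN and flagged False in ``present`` — never imputed. Raises if the
    participant was excluded, or if the pre- or post-test is missing (no
    curve exists without both endpoints).
    """
    if participant in set(excluded):
        raise ExcludedParticipantError(f"participant {participant!r} was excluded")
    trained = trained_condition or TRAINED_CONDITION
    rows = sessions[sessions["participant"] == participant]
    if len(rows) == 0:
        raise ValueError(f"no sessions for participant {participant!r}")
    group = rows["group"].iloc[0]
    fmt, dur = trained[group]
    rows = rows[
        (rows["condition_format"] == fmt) & (rows["condition_duration"] == dur)
    ]
    n_points = n_training_sessions + 2
    values = np.full(n_points, np.nan)
    for _, rec in rows.iterrows():
        if rec["phase"] == "pre":
            values[0] = rec["wf"]
        elif rec["phase"] == "post":
            values[-1] = rec["wf"]
        elif rec["phase"] == "train" and 1 <= rec["session"] <= n_training_sessions:
            values[int(rec["session"])] = rec["wf"]
    if math.isnan(values[0]) or math.isnan(values[-1]):
        raise ValueError(
            f"participant {participant!r} lacks a pre- and/or post-test WF "
            "on the trained condition"
        )
    return values, ~np.isnan(values)


def group_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Condition × group cell means of LI with between-subject SEM and n.

    SEM = SD/√n with sample SD; cells with n < 2 have undefined SEM and are
    flagged. The table is tidy and ready for external ANOVA/t-test software.
    """
    rows = []
    for (grp, fmt, dur), sub in summaries.groupby(
        ["group", "condition_format", "condition_duration"], sort=True
    ):
        li = sub["learning_index"].astype(float)
        n = len(li)
        sem = float(li.std(ddof=1) / math.sqrt(n)) if n >= 2 else np.nan
        rows.append(
            dict(
                group=grp,
                condition_format=fmt,
                condition_duration=dur,
                n=n,
                mean_li=float(li.mean()),
                sem_li=sem,
                trained=bool(sub["trained"].iloc[0]),
                flagged=n < 2,
            )
        )
    return pd.DataFrame(rows)
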