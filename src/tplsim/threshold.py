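"""Reversal-based threshold estimation and exclusion rules.

A block's threshold is the mean of its reversal Δt values excluding the
first three; blocks with fewer than five reversals are excluded outright.
The Weber fraction (WF) is the threshold divided by the standard interval.
Within each training session, a block is dropped as an outlier when its WF
lies more than three scaled median absolute deviations (scaled MAD, normal
consistency constant 1.4826) from the session's center. Participants whose
training-session WFs exceed their group's mean by more than three standard
deviations in more than one session are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAD_SCALE",
    "EXCLUDED_TOO_FEW_REVERSALS",
    "EXCLUDED_SESSION_OUTLIER",
    "EmptySessionError",
    "BlockResult",
    "SessionEstimate",
    "ParticipantExclusion",
    "block_threshold",
    "weber_fraction",
    "mad_keep_mask",
    "session_threshold",
    "exclude_participants",
    "block_table",
    "session_table",
]

#: Normal-consistency constant: scaled MAD = 1.4826 * median(|x - center|).
MAD_SCALE = 1.4826

EXCLUDED_TOO_FEW_REVERSALS = "too-few-reversals"
EXCLUDED_SESSION_OUTLIER = "session-outlier"


class EmptySessionError(ValueError):
    """Every block of a participant-session was excluded; no WF can be formed."""


@dataclass(frozen=True)
class BlockResult:
    condition: tuple[str, int]
    reversal_values: tuple[float, ...]
    threshold: float | None
    weber_fraction: float | None
    n_reversals: int
    exclusion_reason: str  # "none" | "too-few-reversals" | "session-outlier"


@dataclass(frozen=True)
class SessionEstimate:
    """Session-level WF plus the per-block keep mask the MAD rule produced."""

    wf: float
    keep: tuple[bool, ...]


@dataclass(frozen=True)
class ParticipantExclusion:
    kept: tuple[str, ...]
    excluded: tuple[str, ...]
    flags: pd.DataFrame  # participant x session booleans


def block_threshold(
    reversal_values: Sequence[float],
    *,
    discard_first: int = 3,
    min_reversals: int = 5,
) -> float | None:
    """Mean reversal Δt after discarding the first ``discard_first`` reversals.

    Returns ``None`` (exclusion, not an error) when fewer than
    ``min_reversals`` reversals occurred.
    """
    values = list(reversal_values)
    if any(v < 0 for v in values):
        raise ValueError("reversal values must be non-negative")
    if len(values) < min_reversals:
        return None
    return float(np.mean(values[discard_first:]))


def weber_fraction(threshold: float, standard_T: float) -> float:
    """WF = Δt threshold / standard interval T."""
    if standard_T <= 0:
        raise ValueError("standard_T must be strictly positive")
    return threshold / standard_T


def mad_keep_mask(
    values: Sequence[float], *, center: float | None = None, n_mads: float = 3.0
) -> np.ndarray:
    """Boolean mask of values within ``n_mads`` scaled MADs of ``center``.

    ``center`` defaults to the median of ``values``. The comparison is
    ``|x - center| <= n_mads * scaledMAD`` with no special casing: a fully
    constant sample keeps everything, while a constant majority (MAD = 0)
    keeps exactly the values at the center — the convention MATLAB's
    ``isoutlier`` uses.
    """
    x = np.asarray(values, dtype=float)
    if center is None:
        center = float(np.median(x))
    mad = MAD_SCALE * float(np.median(np.abs(x - center)))
    return np.abs(x - center) <= n_mads * mad


def session_threshold(
    block_wfs: Sequence[float],
    *,
    center: float | None = None,
    n_mads: float = 3.0,
) -> SessionEstimate:
    """Session WF: mean of block WFs surviving the scaled-MAD outlier screen.

    ``center`` is the participant-session median by default; pass an external
    value (e.g. a group-session mean) to change the screening center.
    Exclusion never alters surviving values — only membership.
    """
    values = list(block_wfs)
    if len(values) == 0:
        raise EmptySessionError("no non-excluded blocks in session")
    keep = mad_keep_mask(values, center=center, n_mads=n_mads)
    if not keep.any():
        raise EmptySessionError("all blocks flagged as session outliers")
    return SessionEstimate(
        wf=float(np.mean(np.asarray(values, dtype=float)[keep])),
        keep=tuple(bool(k) for k in keep),
    )


def exclude_participants(
    session_wfs: pd.DataFrame,
    groups: pd.Series | dict,
    *,
    n_sd: float = 3.0,
    max_flagged: int = 1,
) -> ParticipantExclusion:
    """Flag participant-sessions beyond mean + ``n_sd``·SD of their group.

    ``session_wfs`` is participants (rows) × sessions (columns); ``groups``
    maps participant → group label. The mean and SD are computed per group
    and session across participants (sample SD); a degenerate session
    (SD = 0 or undefined) produces no flags. A participant is excluded when
    flagged in more than ``max_flagged`` sessions. Deterministic.
    """
    groups = pd.Series(groups).reindex(session_wfs.index)
    if groups.isna().any():
        missing = list(session_wfs.index[groups.isna()])
        raise ValueError(f"missing group labels for {missing}")
    flags = pd.DataFrame(
        False, index=session_wfs.index, columns=session_wfs.columns
    )
    for _, members in session_wfs.groupby(groups, sort=False):
        for col in members.columns:
            vals = members[col].astype(float)
            mean, sd = vals.mean(), vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0.0:
                continue
            flags.loc[members.index, col] = vals > mean + n_sd * sd
    n_flagged = flags.sum(axis=1)
    excluded = tuple(session_wfs.index[n_flagged > max_flagged])
    kept = tuple(p for p in session_wfs.index if p not in excluded)
    return ParticipantExclusion(kept=kept, excluded=excluded, flags=flags)


# ---------------------------------------------------------------------------
# Table pipeline over trial-level logs
# ---------------------------------------------------------------------------

_BLOCK_KEYS = [
    "participant",
    "group",
    "phase",
    "session",
    "block",
    "condition_format",
    "condition_duration",
]


def block_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-block thresholds and WFs from a trial-level log.

    Practice trials are dropped. Reversal values are taken from the logged
    per-trial flags in trial order; the WF divides the threshold by the
    block's standard interval (``condition_duration``).
    """
    data = trials[trials["phase"] != "practice"]
    rows = []
    for keys, grp in data.groupby(_BLOCK_KEYS, sort=True):
        grp = grp.sort_values("trial")
        revs = grp.loc[grp["reversal"].astype(bool), "delta_ms"].tolist()
        thr = block_threshold(revs)
        rec = dict(zip(_BLOCK_KEYS, keys))
        rec.update(
            n_reversals=len(revs),
            threshold_ms=thr if thr is not None else np.nan,
            wf=(
                weber_fraction(thr, rec["condition_duration"])
                if thr is not None
                else np.nan
            ),
            exclusion_reason="none" if thr is not None else EXCLUDED_TOO_FEW_REVERSALS,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def session_table(
    blocks: pd.DataFrame, *, mad_center: str = "participant-median", n_mads: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate block WFs to session WFs; mark training-session outlier blocks.

    Pre/post-test sessions have one block per condition, so their session WF
    is the block WF. Training sessions pool the participant's blocks through
    the scaled-MAD screen; ``mad_center`` selects the screening center:
    ``"participant-median"`` (median of the participant's own session blocks)
    or ``"group-mean"`` (mean over all the group's blocks in that session).

    Returns ``(blocks, sessions)`` where ``blocks`` is a copy with
    ``exclusion_reason`` updated for outlier blocks.
    """
    if mad_center not in ("participant-median", "group-mean"):
        raise ValueError(f"unknown mad_center {mad_center!r}")
    blocks = blocks.copy()
    rows = []

    train = blocks[(blocks["phase"] == "train") & (blocks["exclusion_reason"] == "none")]
    group_centers = (
        train.groupby(["group", "session"])["wf"].mean() if len(train) else None
    )
    for (pid, grp_label, session), sub in train.groupby(
        ["participant", "group", "session"], sort=True
    ):
        center = None
        if mad_center == "group-mean":
            center = float(group_centers.loc[(grp_label, session)])
        est = session_threshold(sub["wf"].tolist(), center=center, n_mads=n_mads)
        dropped = sub.index[[not k for k in est.keep]]
        blocks.loc[dropped, "exclusion_reason"] = EXCLUDED_SESSION_OUTLIER
        fmt = sub["condition_format"].iloc[0]
        dur = sub["condition_duration"].iloc[0]
        rows.append(
            dict(
                participant=pid,
                group=grp_label,
                phase="train",
                session=session,
                condition_format=fmt,
                condition_duration=dur,
                wf=est.wf,
                n_blocks=int(sum(est.keep)),
            )
        )

    tests = blocks[blocks["phase"].isin(["pre", "post"]) & (blocks["exclusion_reason"] == "none")]
    for _, rec in tests.iterrows():
        rows.append(
            dict(
                participant=rec["participant"],
                group=rec["group"],
                phase=rec["phase"],
                session=rec["session"],
                condition_format=rec["condition_format"],
                condition_duration=rec["condition_duration"],
                wf=rec["wf"],
                n_blocks=1,
            )
        )
    sessions = pd.DataFrame(rows).sort_values(
        ["participant", "session", "condition_format", "condition_duration"]
    )
    return blocks, sessions.reset_index(drop=True)
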