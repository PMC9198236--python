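"""Full-study orchestration: schedule, cohort simulation, log I/O, pipeline.

The schedule follows the five-day design: a pre-test on day 1 (10 practice
trials, then one 60-trial block per condition E200/E400/F200/F400), four
daily training sessions of 12 blocks on the group's trained condition
(720 trials/day, 2,880 in total), and a post-test on day 5 mirroring the
pre-test. Session indices are 0 (pre), 1–4 (training) and 5 (post).

Simulation is reproducible from (config, seed): the root seed is split with
``numpy.random.SeedSequence`` into per-participant streams, each split again
into per-block substreams, so any block can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import learning as learning_mod
from . import threshold as threshold_mod
from .observer import (
    CONDITIONS,
    GROUPS,
    IMPROVING_CONDITIONS,
    TRAINED_CONDITION,
    Condition,
    ConfigurationError,
    ObserverParams,
    make_cohort,
)
from .staircase import StaircaseConfig, run_block

__all__ = [
    "SchemaError",
    "ObserverDefaults",
    "AnalysisOptions",
    "ExperimentConfig",
    "BlockSpec",
    "Schedule",
    "POST_TEST_SESSION",
    "build_schedule",
    "simulate_participant",
    "simulate_experiment",
    "write_trials",
    "read_trials",
    "run_pipeline",
    "load_config",
    "config_hash",
    "write_manifest",
]

#: Session index at which the post-test is run (day 5, after 4 training days).
POST_TEST_SESSION = 5

PRE_SESSION = 0

LOG_COLUMNS = [
    "participant",
    "group",
    "phase",
    "session",
    "block",
    "condition_format",
    "condition_duration",
    "trial",
    "delta_ms",
    "order",
    "choice",
    "correct",
    "reversal",
    "step_ms",
    "seed",
]


class SchemaError(ValueError):
    """A trial log does not match the expected schema."""


@dataclass(frozen=True)
class ObserverDefaults:
    wf_start: float = 0.20
    wf_asymptote: float = 0.13
    tau_sessions: float = 1.5
    lapse_rate: float = 0.02
    jitter_cv: float = 0.10


@dataclass(frozen=True)
class AnalysisOptions:
    mad_center: str = "participant-median"  # or "group-mean"
    n_mads: float = 3.0
    participant_n_sd: float = 3.0
    participant_max_flagged: int = 1


@dataclass(frozen=True)
class ExperimentConfig:
    n_ei: int = 11
    n_fi: int = 12
    trials_per_block: int = 60
    training_blocks_per_session: int = 12
    n_training_sessions: int = 4
    practice_trials: int = 10
    initial_delta_fraction: float = 0.20
    coarse_step_fraction: float = 0.10
    fine_step_fraction: float = 0.05
    step_change_after_reversal: int = 3
    frame_grid_ms: float | None = None
    shuffle_test_blocks: bool = True
    observer: ObserverDefaults = field(default_factory=ObserverDefaults)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def staircase_config(self, standard_T: float, n_trials: int | None = None) -> StaircaseConfig:
        return StaircaseConfig(
            standard_T=standard_T,
            initial_delta_fraction=self.initial_delta_fraction,
            coarse_step_fraction=self.coarse_step_fraction,
            fine_step_fraction=self.fine_step_fraction,
            step_change_after_reversal=self.step_change_after_reversal,
            trials_per_block=n_trials or self.trials_per_block,
            frame_grid_ms=self.frame_grid_ms,
        )


@dataclass(frozen=True)
class BlockSpec:
    phase: str  # practice | pre | train | post
    session: int
    block: int  # index within the session
    condition: Condition
    n_trials: int


@dataclass(frozen=True)
class Schedule:
    group: str
    blocks: tuple[BlockSpec, ...]

    @property
    def total_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def training_trials(self, session: int | None = None) -> int:
        return sum(
            b.n_trials
            for b in self.blocks
            if b.phase == "train" and (session is None or b.session == session)
        )


def build_schedule(
    group: str,
    config: ExperimentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Schedule:
    """Deterministic schedule skeleton for one participant.

    Pre/post test block order is shuffled with ``rng`` when provided and
    ``config.shuffle_test_blocks`` is set; otherwise the fixed E200, E400,
    F200, F400 order is used (handy for regression tests).
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    cfg = config or ExperimentConfig()
    trained = TRAINED_CONDITION[group]

    def test_order() -> list[Condition]:
        order = list(CONDITIONS)
        if cfg.shuffle_test_blocks and rng is not None:
            order = [order[i] for i in rng.permutation(len(order))]
        return order

    blocks: list[BlockSpec] = []
    if cfg.practice_trials > 0:
        blocks.append(BlockSpec("practice", PRE_SESSION, 0, trained, cfg.practice_trials))
    for i, cond in enumerate(test_order()):
        blocks.append(BlockSpec("pre", PRE_SESSION, i, cond, cfg.trials_per_block))
    for session in range(1, cfg.n_training_sessions + 1):
        for b in range(cfg.training_blocks_per_session):
            blocks.append(BlockSpec("train", session, b, trained, cfg.trials_per_block))
    for i, cond in enumerate(test_order()):
        blocks.append(BlockSpec("post", POST_TEST_SESSION, i, cond, cfg.trials_per_block))
    return Schedule(group=group, blocks=tuple(blocks))


def _learning_session_index(spec: BlockSpec) -> int:
    """Map a schedule block to the observer's learning-trajectory session.

    Practice and pre-test run at the naive state (0); training session k runs
    at k; the post-test at POST_TEST_SESSION.
    """
    if spec.phase in ("practice", "pre"):
        return 0
    return spec.session


def simulate_participant(
    observer: ObserverParams,
    config: ExperimentConfig,
    seed_seq: np.random.SeedSequence,
) -> pd.DataFrame:
    """Simulate one participant through the full schedule; returns log rows."""
    schedule_seq, *_ = seed_seq.spawn(1)
    schedule = build_schedule(
        observer.group, config, np.random.default_rng(schedule_seq)
    )
    block_seqs = seed_seq.spawn(len(schedule.blocks))
    frames = []
    for spec, sub_seq in zip(schedule.blocks, block_seqs):
        block_seed = int(sub_seq.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seq)
        sc = config.staircase_config(spec.condition[1], spec.n_trials)
        records, _ = run_block(
            sc,
            observer,
            spec.condition,
            _learning_session_index(spec),
            rng,
            n_trials=spec.n_trials,
        )
        frames.append(
            pd.DataFrame(
                dict(
                    participant=observer.participant,
                    group=observer.group,
                    phase=spec.phase,
                    session=spec.session,
                    block=spec.block,
                    condition_format=spec.condition[0],
                    condition_duration=spec.condition[1],
                    trial=[r.trial_index for r in records],
                    delta_ms=[r.delta for r in records],
                    order=[r.order for r in records],
                    choice=[r.choice for r in records],
                    correct=[r.correct for r in records],
                    reversal=[r.reversal for r in records],
                    step_ms=[r.step_ms for r in records],
                    seed=block_seed,
                )
            )
        )
    return pd.concat(frames, ignore_index=True)[LOG_COLUMNS]


def simulate_experiment(
    config: ExperimentConfig | None = None,
    seed: int = 0,
    cohorts: dict[str, Sequence[ObserverParams]] | None = None,
) -> pd.DataFrame:
    """Simulate both cohorts end-to-end; fully reproducible from (config, seed).

    When ``cohorts`` is omitted, default EI/FI cohorts of sizes
    ``config.n_ei`` / ``config.n_fi`` are generated from the same seed.
    """
    cfg = config or ExperimentConfig()
    root = np.random.SeedSequence(seed)
    cohort_seq, participants_seq = root.spawn(2)
    if cohorts is None:
        ei_seq, fi_seq = cohort_seq.spawn(2)
        od = cfg.observer
        cohorts = {
            "EI": make_cohort(
                "EI", cfg.n_ei, ei_seq,
                wf_start=od.wf_start, wf_asymptote=od.wf_asymptote,
                tau_sessions=od.tau_sessions, lapse_rate=od.lapse_rate,
                jitter_cv=od.jitter_cv,
            ),
            "FI": make_cohort(
                "FI", cfg.n_fi, fi_seq,
                wf_start=od.wf_start, wf_asymptote=od.wf_asymptote,
                tau_sessions=od.tau_sessions, lapse_rate=od.lapse_rate,
                jitter_cv=od.jitter_cv,
            ),
        }
    all_observers = [obs for grp in sorted(cohorts) for obs in cohorts[grp]]
    pid_seqs = participants_seq.spawn(len(all_observers))
    frames = [
        simulate_participant(obs, cfg, sq) for obs, sq in zip(all_observers, pid_seqs)
    ]
    return pd.concat(frames, ignore_index=True)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write the trial log as CSV with the canonical column order."""
    trials[LOG_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and schema-check a trial log CSV.

    Raises :class:`SchemaError` with a row reference for missing columns,
    unreadable files, or rows violating basic value constraints.
    """
    try:
        trials = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse trial log {path}: {exc}") from exc
    missing = [c for c in LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial log {path} lacks columns {missing}")
    for col, check, what in [
        ("delta_ms", lambda s: s > 0, "non-positive delta_ms"),
        ("condition_duration", lambda s: s > 0, "non-positive condition_duration"),
        ("phase", lambda s: s.isin(["practice", "pre", "train", "post"]), "unknown phase"),
        ("order", lambda s: s.isin(["standard_first", "comparison_first"]), "unknown order"),
        ("choice", lambda s: s.isin(["first", "second"]), "unknown choice"),
    ]:
        ok = check(trials[col])
        if not ok.all():
            row = int(trials.index[~ok][0]) + 2  # 1-based, after header
            raise SchemaError(f"{what} in {path} at line {row}")
    trials["correct"] = trials["correct"].astype(bool)
    trials["reversal"] = trials["reversal"].astype(bool)
    return trials


def run_pipeline(
    trials: pd.DataFrame | str | Path,
    config: ExperimentConfig | None = None,
) -> dict:
    """Trial log → block, session, learning and group tables with exclusions.

    A pure function of the log: re-running on the same CSV reproduces
    identical tables. Returns a dict with keys ``blocks``, ``sessions``,
    ``summary``, ``group_summary``, ``learner_ratio``, ``excluded`` and
    ``exclusion_flags``.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = read_trials(trials)
    cfg = config or ExperimentConfig()
    opts = cfg.analysis
    blocks = threshold_mod.block_table(trials)
    blocks, sessions = threshold_mod.session_table(
        blocks, mad_center=opts.mad_center, n_mads=opts.n_mads
    )
    train = sessions[sessions["phase"] == "train"]
    if len(train):
        wf_matrix = train.pivot_table(
            index="participant", columns="session", values="wf", aggfunc="first"
        )
        groups = train.groupby("participant")["group"].first()
        excl = threshold_mod.exclude_participants(
            wf_matrix,
            groups,
            n_sd=opts.participant_n_sd,
            max_flagged=opts.participant_max_flagged,
        )
        excluded = list(excl.excluded)
        flags = excl.flags
    else:
        excluded, flags = [], pd.DataFrame()
    kept_sessions = sessions[~sessions["participant"].isin(excluded)]
    summary = learning_mod.summarize_learning(kept_sessions)
    group_tbl = learning_mod.group_summary(summary)
    ratios = {
        grp: learning_mod.learner_ratio(summary, grp)
        for grp in sorted(summary["group"].unique())
    }
    return dict(
        blocks=blocks,
        sessions=sessions,
        summary=summary,
        group_summary=group_tbl,
        learner_ratio=ratios,
        excluded=excluded,
        exclusion_flags=flags,
    )


# ---------------------------------------------------------------------------
# Config files and manifests
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Recognized sections: ``observer``, ``staircase``, ``schedule``,
    ``analysis``; keys within each map onto the corresponding dataclass
    fields, with unspecified keys keeping their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    known = {"observer", "staircase", "schedule", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config sections {sorted(unknown)}")

    def _take(section: str, cls):
        data = raw.get(section) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ConfigurationError(f"unknown {section} keys {sorted(bad)}")
        return data

    stair = raw.get("staircase") or {}
    sched = raw.get("schedule") or {}
    stair_fields = {
        "initial_delta_fraction",
        "coarse_step_fraction",
        "fine_step_fraction",
        "step_change_after_reversal",
        "trials_per_block",
        "frame_grid_ms",
    }
    sched_fields = {
        "n_ei",
        "n_fi",
        "training_blocks_per_session",
        "n_training_sessions",
        "practice_trials",
        "shuffle_test_blocks",
    }
    bad = (set(stair) - stair_fields) | (set(sched) - sched_fields)
    if bad:
        raise ConfigurationError(f"unknown config keys {sorted(bad)}")
    kwargs: dict = {**stair, **sched}
    try:
        return ExperimentConfig(
            observer=ObserverDefaults(**_take("observer", ObserverDefaults)),
            analysis=AnalysisOptions(**_take("analysis", AnalysisOptions)),
            **kwargs,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def config_hash(config: ExperimentConfig) -> str:
    """Stable SHA-256 of the configuration (for output manifests)."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(
    out_dir: str | Path, config: ExperimentConfig, seed: int, n_trials: int
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(
        json.dumps(
            dict(seed=seed, config_sha256=config_hash(config), n_trials=n_trials),
            indent=2,
        )
        + "\n"
    )
    return path
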