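"""Simulate the full five-day study for the default cohorts.

11 empty-interval (EI) and 12 filled-interval (FI) observers each complete
10 practice trials, a four-condition pre-test, four 720-trial training
sessions on their group's trained condition, and a post-test. Writes the
trial-level log and a manifest under results/.
"""

from pathlib import Path

import tplsim as t

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = t.ExperimentConfig()
    trials = t.simulate_experiment(cfg, seed=SEED)
    OUT.mkdir(exist_ok=True)
    t.write_trials(trials, OUT / "trials.csv")
    t.experiment.write_manifest(OUT, cfg, SEED, len(trials))
    n_pp = trials.groupby("participant").size()
    print(f"simulated {trials['participant'].nunique()} participants, "
          f"{len(trials)} trials total ({n_pp.iloc[0]} per participant)")
    print(f"wrote {OUT / 'trials.csv'}")


if __name__ == "__main__":
    main()
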