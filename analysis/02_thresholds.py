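"""Estimate block and session thresholds from the simulated trial log.

Block thresholds average the reversal Δt values excluding the first three
(blocks with <5 reversals are excluded); Weber fractions divide by the
standard interval. Training-session WFs pool 12 blocks through the
3-scaled-MAD outlier screen, and participants beyond their group mean by
3 SD in more than one training session are dropped. Writes blocks.csv and
sessions.csv under results/.
"""

from pathlib import Path

import tplsim as t

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    res = t.run_pipeline(OUT / "trials.csv")
    res["blocks"].to_csv(OUT / "blocks.csv", index=False)
    res["sessions"].to_csv(OUT / "sessions.csv", index=False)
    blocks = res["blocks"]
    n_excl = (blocks["exclusion_reason"] != "none").sum()
    print(f"{len(blocks)} blocks analysed; {n_excl} excluded "
          f"({dict(blocks['exclusion_reason'].value_counts())})")
    if res["excluded"]:
        print(f"participants excluded by the 3-SD rule: {res['excluded']}")
    else:
        print("no participants excluded by the 3-SD rule")
    pre = res["sessions"].query("phase == 'pre'").groupby("group")["wf"].mean()
    print("mean pre-test WF by group:")
    print(pre.to_string())
    print(f"wrote {OUT / 'blocks.csv'} and {OUT / 'sessions.csv'}")


if __name__ == "__main__":
    main()
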