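#!/usr/bin/env python
"""Sex-stratified Z tables and ATC-class adverse-event summary.

Prints the per-sex drug counts, checks female + male + sex-excluded records
conserve the overall total, and tabulates events per first-letter ATC class.
The tables themselves were written by 02_clean_and_map.py under
``results/pipeline/``.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
PIPE = ROOT / "results" / "pipeline"


def main() -> None:
    summary = json.loads((PIPE / "run_summary.json").read_text())["reports"]
    total = summary["n_records"]
    parts = (
        summary["n_records_female"],
        summary["n_records_male"],
        summary["n_records_sex_excluded"],
    )
    assert sum(parts) == total
    print(
        f"{total} records = {parts[0]} female + {parts[1]} male + "
        f"{parts[2]} without usable sex information"
    )
    for stratum in ("female", "male"):
        z = pd.read_csv(PIPE / f"z_{stratum}.csv", index_col=0)
        print(f"  {stratum}: {len(z)} drugs with a defined stratified profile")

    atc = pd.read_csv(PIPE / "atc_summary.csv")
    print("\nadverse events per ATC anatomical class:")
    for _, row in atc.iterrows():
        print(
            f"  class {row['atc_class']}: {row['n_drugs']} drugs, "
            f"{row['total_events']} events "
            f"({row['mean_events_per_drug']:.1f}/drug), "
            f"{row['total_significant_socs']} significant SOCs"
        )

    trials = pd.read_csv(PIPE / "trial_assignments.csv")
    hist = summary_hist(trials)
    print(
        f"\ntrial registry: {len(trials)} drugs assigned; tested in "
        f"1 / 2 / 3 / >3 trials: {hist[0]} / {hist[1]} / {hist[2]} / {hist[3]}"
    )


def summary_hist(trials: pd.DataFrame) -> tuple[int, int, int, int]:
    bins = [0, 0, 0, 0]
    for n in trials["n_trials"]:
        if n == 1:
            bins[0] += 1
        elif n == 2:
            bins[1] += 1
        elif n == 3:
            bins[2] += 1
        elif n > 3:
            bins[3] += 1
    return tuple(bins)  # type: ignore[return-value]


if __name__ == "__main__":
    main()
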