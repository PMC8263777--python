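#!/usr/bin/env python
"""Compute the Z-score safety profiles and check planted-signal recovery.

Reads the mapped records from 02_clean_and_map.py, standardizes each drug's
27-SOC count profile, and prints every significantly frequent (Z > 2) SOC.
The planted enrichments from 01_simulate.py should sit at the top.
"""

import pandas as pd
from pathlib import Path

from socsafety.faers import DrugEventRecord
from socsafety.vocab import load_soc_vocabulary
from socsafety.zscore import aggregate_profiles, compute_zscores, significant_socs

ROOT = Path(__file__).resolve().parent.parent
RECORDS = ROOT / "results" / "pipeline" / "records.csv"
PLANTED = {"D003": "CARD", "D007": "MUSC", "D012": "HEPAT"}


def main() -> None:
    vocab = load_soc_vocabulary()
    frame = pd.read_csv(RECORDS, dtype=str, keep_default_na=False)
    records = [
        DrugEventRecord(r.drug_id, r.soc_code, r.sex_stratum, r.case_id or None)
        for r in frame.itertuples(index=False)
    ]
    profiles = aggregate_profiles(records, vocab)
    print(f"{len(profiles)} drugs with >= 1 mapped adverse event")
    recovered = 0
    for profile in profiles:
        zrecs = compute_zscores(profile, vocab)
        sig = significant_socs(zrecs)
        if sig:
            detail = ", ".join(
                f"{r.soc_code} (Z = {r.z:.1f})"
                for r in sorted(zrecs, key=lambda r: -(r.z or -99))
                if r.soc_code in sig
            )
            print(f"  {profile.drug_id}: significantly frequent in {detail}")
        if profile.drug_id in PLANTED and PLANTED[profile.drug_id] in sig:
            recovered += 1
    print(f"planted signals recovered with Z > 2: {recovered}/{len(PLANTED)}")


if __name__ == "__main__":
    main()
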