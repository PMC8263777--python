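#!/usr/bin/env python
"""Generate the study corpus: 20 drugs, 200 reports each, three planted signals.

Writes the synthetic trial registry, FAERS-dialect report tables, term
dictionary, drug lexicon, and the ground-truth manifest under
``results/corpus/``. The planted (drug, SOC) enrichments are what the
downstream Z-score stage should rediscover.
"""

from pathlib import Path

from socsafety.simulate import Enrichment, SimulationConfig, simulate_corpus

OUT = Path(__file__).resolve().parent.parent / "results" / "corpus"

PLANTED = [
    Enrichment(drug_id="D003", soc_code="CARD", factor=5.0),
    Enrichment(drug_id="D007", soc_code="MUSC", factor=5.0),
    Enrichment(drug_id="D012", soc_code="HEPAT", factor=8.0),
]


def main() -> None:
    config = SimulationConfig(
        n_drugs=20,
        n_reports_per_drug=200,
        duplicate_rate=0.05,
        incomplete_rate=0.05,
        enrichments=PLANTED,
        seed=17,
    )
    corpus = simulate_corpus(config, OUT)
    totals = corpus.manifest["totals"]
    print(f"wrote corpus under {OUT}")
    print(
        f"  {totals['n_base_reports']} base reports, "
        f"{totals['n_duplicates']} injected duplicates, "
        f"{totals['n_incomplete']} injected incomplete reports"
    )
    for e in PLANTED:
        print(f"  planted signal: {e.drug_id} enriched {e.factor}x in {e.soc_code}")


if __name__ == "__main__":
    main()
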