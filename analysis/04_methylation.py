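#!/usr/bin/env python
"""Bisulfite methylation summary on a synthetic near-unmethylated genome.

Simulates bisulfite reads at depth 5 from a 20 kb genome with low per-context
methylation (CG 1%, CHG/CHH 0.2%) and 99.5% conversion — the regime of a
genome that has essentially lost DNA methylation — maps them with the
built-in three-letter mapper, and summarizes per-context rates and site
classes. Writes results/methylation/.
"""

import json
from pathlib import Path

from compbias import simulate as sim
from compbias.methylation import classify_contexts, count_calls, naive_bisulfite_map, summarize, site_table

OUT = Path(__file__).resolve().parents[1] / "results" / "methylation"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sim.SimulationSpec(seed=seed)
    spec.genome.length = 20_000
    genome = sim.sim_genome(spec)
    reads, truth = sim.sim_bisulfite(spec, genome)
    sam = OUT / "alignments.sam"
    tally = naive_bisulfite_map(reads, genome, sam)

    sites = classify_contexts(genome)
    calls = count_calls(sam, genome)
    summ = summarize(sites, calls)
    site_table(sites, calls).to_csv(OUT / "sites.tsv", sep="\t", index=False)
    summ.per_context.to_csv(OUT / "context_summary.tsv", sep="\t")
    (OUT / "summary.json").write_text(
        json.dumps(
            {
                "mapped": tally["mapped"],
                "covered": summ.n_covered,
                "two_plus": summ.n_two_plus,
                "site_classes": summ.site_classes,
                "rates_percent": {
                    c: round(100 * float(v), 3)
                    for c, v in summ.per_context["meth_rate"].items()
                },
            },
            indent=2,
        )
    )

    print(f"Bisulfite summary: {tally['mapped']} reads mapped "
          f"({tally['ambiguous']} ambiguous)")
    print(summ.per_context.round(5).to_string())
    print(f"  covered cytosines: {summ.n_covered}; with >=2 reads: {summ.n_two_plus}")
    print(f"  site classes: {summ.site_classes}")
    print(
        "  Finding: the vast majority of covered cytosines are never "
        "methylated and per-context rates sit near the simulated "
        "probabilities plus the conversion-failure floor — the pattern of a "
        "genome with near-absent methylation."
    )


if __name__ == "__main__":
    main()
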