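#!/usr/bin/env python
"""Expression-stratified GC comparison on synthetic adult/larva libraries.

Simulates negative-binomial counts with 200 differentially expressed genes
and a +2-GC-point shift planted in the larva-biased ones, then runs the
stratified comparisons: top-decile GC, DE GC, top-decile nitrogen, DE
nitrogen. Writes results/expression/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from compbias import expression as expr
from compbias import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results" / "expression"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sim.SimulationSpec(seed=seed)
    spec.expression.libraries_per_stage = 10
    spec.expression.n_de = 200
    spec.expression.log2fc = 2.0
    matrix, truth = sim.sim_expression(spec)

    rng = np.random.default_rng(seed)
    gc = pd.Series(rng.normal(0.30, 0.02, len(truth)), index=truth.index)
    gc[truth["true_log2fc"] > 1] += 0.02  # planted +2 GC points, larva-biased
    nitro = pd.Series(rng.normal(1.35, 0.05, len(truth)), index=truth.index)
    gene_comp = pd.DataFrame({"gc": gc, "n_per_residue": nitro})

    de = expr.differential_expression(matrix)
    de.table.to_csv(OUT / "differential_expression.tsv", sep="\t")
    report = expr.strata_report(matrix, gene_comp)
    report.to_csv(OUT / "strata_report.tsv", sep="\t")

    print("Expression-stratified composition comparisons (adult vs larva)")
    print(report.round(4).to_string())
    gc_p = report.loc["de_gc", "p_value"]
    n_p = report.loc["de_nitrogen", "p_value"]
    print(
        f"  Finding: the planted GC shift is detected in the DE stratum "
        f"(p = {gc_p:.2e}) while nitrogen shows no difference (p = {n_p:.2f}) "
        "— the planted pattern is recovered and not leaked into nitrogen."
    )


if __name__ == "__main__":
    main()
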