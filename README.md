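# compbias

Composition bias, haploid linkage mapping and methylation summaries for
extremely AT-rich insect genomes.

Parasitoid wasps of the subfamily Aphidiinae (e.g. *Aphidius ervi*,
*Lysiphlebus fabarum*) have the most AT-rich arthropod genomes reported
(~24–26% GC), with strongly skewed codon usage, life-stage-dependent GC
differences in expressed genes, and a near-total absence of DNA
methylation. `compbias` implements the computations such an analysis
rests on, for genomicists working on these or similarly biased genomes:

* **Composition** — genome and per-gene GC, third-position GC (GC3),
  codon counts and relative synonymous codon usage
  (RSCU_c = k·n_c / Σ_family n, so 1 = unbiased), nitrogen cost per base,
  per duplex pair and per amino-acid residue, RSCU profile distances and
  PCA.
* **Expression strata** — median-of-ratios normalization, top-decile
  strata per life stage, a calibrated Welch + Benjamini–Hochberg
  differential-expression stand-in, and the four stratified
  GC/nitrogen comparisons (Welch two-sided t-tests).
* **Linkage mapping** — a genetic map from haploid sons of a single
  female with unknown maternal phase: marker filtering (> 20% missing or
  MAF < 15% removed), the phase-mirror device, Fisher-exact grouping
  (p < 1e-6 in coupling), MST + local-search ordering, Kosambi
  centimorgans (d = 25·ln((1+2r)/(1−2r))), > 70 cM gap splitting,
  scaffold anchoring with orientation and chimera advisories.
* **Methylation** — CG/CHG/CHH cytosine-context classification on both
  strands, per-site methylated/unmethylated call tallies from bisulfite
  SAM, per-context rates and never/always/variable site classes.
* **Synthetic data** — seeded generators for genomes, codon-biased genes,
  NB expression counts, meioses of one phased mother, and bisulfite
  reads, each with a truth table, so the whole pipeline runs and is
  tested with no downloads.

## Worked example

Build a linkage map from a simulated cross (6 chromosomes × 30 markers,
90 haploid sons, 5% missing data):

```python
from compbias import simulate as sim
from compbias import linkage as lnk

spec = sim.SimulationSpec(seed=1)
matrix, truth = sim.sim_cross(spec)
gmap = lnk.build_map(matrix)          # filter, mirror, group, order, split
for g in gmap.groups:
    print(g.name, len(g.marker_ids), round(g.positions_cm[-1], 1))
```

prints

```
LG1 30 192.3
LG2 30 168.6
LG3 30 161.6
LG4 30 176.5
LG5 30 171.6
LG6 30 178.1
```

— six linkage groups of 30 markers each (the six simulated chromosomes,
recovered despite the unknown maternal phase), with total Kosambi map
lengths of ~160–190 cM per group. `lnk.anchor_scaffolds(gmap,
matrix.markers)` then assigns each marker scaffold to a group with an
orientation and flags scaffolds whose marker blocks disagree (putative
assembly chimeras, with a suggested split position).

The same story for the other stages lives in `analysis/`:

```bash
python analysis/01_composition.py       # GC / GC3 / RSCU / nitrogen tables
python analysis/02_expression_strata.py # top-decile + DE composition comparisons
python analysis/03_linkage_map.py       # the map above + scaffold anchors
python analysis/04_methylation.py       # bisulfite context summary
```

Each driver prints what it found and writes its tables under `results/`.
There is also a CLI (`compbias extract-cds | composition | rscu | strata |
linkage | methylation | simulate`) over the same functions for file-based
use.

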