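"""Synthetic data with the statistical structure the analyses assume.

Every generator is a pure function of a :class:`SimulationSpec` (the seed
fully determines the output) and emits a machine-readable truth table, so
every pipeline stage is testable without downloading anything.

What is emulated, and with what defaults:

* genome — iid bases at a target GC of 0.25, the extreme AT-richness of
  aphidiine parasitoid genomes;
* coding genes — ATG + codons drawn from an AT-skewed codon frequency
  table + stop, embedded on both strands, optionally multi-exon;
* expression — negative-binomial counts for two life stages (adult, larva)
  with planted log2 fold changes and an optional GC-coupled shift that
  reproduces the "larva-biased genes are GC-richer" pattern;
* mapping cross — one phased diploid mother, haploid sons by a Markov
  recombination walk along each chromosome (90 sons over 6 chromosomes by
  default, the post-filtering panel size of the real cross), with phase
  labels randomized per marker so the unknown maternal phase is genuine;
* bisulfite reads — uniform read sampling from both strands, per-site
  methylation states drawn with per-context probabilities, unmethylated
  cytosines converted C→T at the conversion rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from compbias.genome_io import GenomeSequence, GeneModel, reverse_complement
from compbias.composition import SENSE_CODONS
from compbias.expression import ExpressionMatrix
from compbias.linkage import GenotypeMatrix

_BASES = np.array(list("ACGT"))


def at_rich_codon_table(gc_weight: float = 0.15) -> dict[str, float]:
    """A codon frequency table skewed towards AT-rich codons.

    Each sense codon's weight is ``gc_weight ** (codon GC count)``,
    normalized; at the default this yields strong usage bias of the kind
    seen in extremely AT-rich genomes.
    """
    weights = {c: gc_weight ** (c.count("G") + c.count("C")) for c in SENSE_CODONS}
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


@dataclass
class GenomeSpec:
    length: int = 250_000
    gc: float = 0.25


@dataclass
class CdsSpec:
    n_genes: int = 200
    codon_freqs: dict[str, float] = field(default_factory=at_rich_codon_table)
    mean_codons: int = 150
    min_codons: int = 30
    minus_fraction: float = 0.5
    exons_per_gene: int = 2
    intron_length: int = 60


@dataclass
class ExpressionSpec:
    stages: tuple[str, str] = ("adult", "larva")
    libraries_per_stage: int = 10
    mean_expression: float = 200.0
    dispersion: float = 0.1
    n_de: int = 0
    log2fc: float = 2.0
    gc_slope: float = 0.0  # log2-expression shift per GC fraction unit, larva


@dataclass
class CrossSpec:
    n_chromosomes: int = 6
    markers_per_chromosome: int = 30
    r_adjacent: float = 0.05
    n_sons: int = 90
    missing_rate: float = 0.05
    error_rate: float = 0.005
    marker_spacing_bp: int = 50_000


@dataclass
class BisulfiteSpec:
    p_meth: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.01, "CHG": 0.002, "CHH": 0.002}
    )
    conversion: float = 0.995
    read_length: int = 80
    depth: float = 5.0


@dataclass
class SimulationSpec:
    """Seed plus the per-component parameter blocks."""

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    cds: CdsSpec = field(default_factory=CdsSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    cross: CrossSpec = field(default_factory=CrossSpec)
    bisulfite: BisulfiteSpec = field(default_factory=BisulfiteSpec)


# ---------------------------------------------------------------------------


def sim_genome(spec: SimulationSpec, name: str = "scaf1") -> GenomeSequence:
    """An iid genome at the target GC: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    g = spec.genome
    if g.length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= g.gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    if g.gc in (0.0, 1.0):
        import logging

        logging.getLogger(__name__).warning("degenerate GC target %s", g.gc)
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - g.gc) / 2, g.gc / 2, g.gc / 2, (1 - g.gc) / 2])
    seq = "".join(rng.choice(_BASES, size=g.length, p=p))
    return GenomeSequence(id=name, residues=seq)


def sim_cds_set(
    spec: SimulationSpec, genome: GenomeSequence
) -> tuple[GenomeSequence, list[GeneModel], pd.DataFrame]:
    """Embed codon-biased genes in a genome; return models and truth.

    Genes are ATG + sampled sense codons + stop (never an internal stop by
    construction), placed non-overlapping, a stated fraction on the minus
    strand, split into exons by fixed-length introns. The truth table holds
    each gene's strand, exon count and generated CDS.
    """
    c = spec.cds
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    codons = list(c.codon_freqs)
    probs = np.array([c.codon_freqs[x] for x in codons])
    probs = probs / probs.sum()
    stops = ["TAA", "TAG", "TGA"]

    residues = list(genome.residues)
    n = len(residues)
    n_exons = max(1, c.exons_per_gene)

    # gene footprints: CDS + introns between exons
    cursor = 10
    genes = []
    for k in range(c.n_genes):
        n_codons = max(c.min_codons, int(rng.poisson(c.mean_codons)))
        cds_len = 3 * (n_codons + 2)  # ATG + codons + stop
        footprint = cds_len + (n_exons - 1) * c.intron_length
        gap = int(rng.integers(20, 200))
        start = cursor + gap
        if start + footprint + 10 > n:
            raise ValueError(
                f"genome too short: placed {k} of {c.n_genes} genes in {n} bp"
            )
        body = "ATG" + "".join(rng.choice(codons, size=n_codons, p=probs)) + str(rng.choice(stops))
        strand = "-" if rng.random() < c.minus_fraction else "+"

        # split CDS into n_exons pieces (codon-boundary-free split is fine:
        # phase is carried by the intervals)
        piece_lens = _split_lengths(len(body), n_exons, rng)
        exons = []
        pos = start
        for plen in piece_lens:
            exons.append((pos + 1, pos + plen))  # 1-based inclusive
            pos += plen + c.intron_length
        genomic = body if strand == "+" else reverse_complement(body)
        # lay the genomic-order sequence across the exon intervals
        goff = 0
        for (s1, e1) in exons:
            plen = e1 - s1 + 1
            residues[s1 - 1 : e1] = list(genomic[goff : goff + plen])
            goff += plen
        cursor = exons[-1][1]
        gid = f"gene{k:04d}"
        # (spans of successive genes never overlap: start > previous cursor)
        genes.append(
            {
                "gene_id": gid,
                "strand": strand,
                "n_exons": n_exons,
                "cds": body,
                "exons": exons,
            }
        )

    embedded = GenomeSequence(id=genome.id, residues="".join(residues))
    models = [
        GeneModel(
            gene_id=g["gene_id"],
            scaffold_id=genome.id,
            strand=g["strand"],
            exons=g["exons"],
            phase=[0] * len(g["exons"]),
        )
        for g in genes
    ]
    truth = pd.DataFrame(
        [{k: v for k, v in g.items() if k != "exons"} for g in genes]
    ).set_index("gene_id")
    return embedded, models, truth


def _split_lengths(total: int, pieces: int, rng: np.random.Generator) -> list[int]:
    if pieces == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(3, total - 3), size=pieces - 1, replace=False))
    bounds = [0, *cuts.tolist(), total]
    return [bounds[i + 1] - bounds[i] for i in range(pieces)]


def write_gff(models: list[GeneModel], path) -> None:
    """Write gene models as GFF3 CDS features grouped by Parent."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            for (s, e), ph in zip(m.exons, m.phase or [0] * len(m.exons)):
                fh.write(
                    f"{m.scaffold_id}\tsim\tCDS\t{s}\t{e}\t.\t{m.strand}\t{ph or 0}\t"
                    f"Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------


def sim_expression(
    spec: SimulationSpec, gene_gc: pd.Series | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial two-stage count matrix with planted structure.

    ``n_de`` genes get the stated log2 fold change (half up in larva, half
    up in adult). If ``gene_gc`` is given and ``gc_slope`` is nonzero, each
    gene's larval log2 mean is shifted by slope x (GC - mean GC) — the
    device that reproduces the larva-biased-genes-are-GC-richer pattern.
    Truth columns: true_log2fc, de (bool).
    """
    e = spec.expression
    if e.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    if gene_gc is not None:
        genes = list(gene_gc.index)
    else:
        genes = [f"gene{k:04d}" for k in range(2000)]
    G = len(genes)
    libs = [f"{stage}_{i + 1}" for stage in e.stages for i in range(e.libraries_per_stage)]
    stages = [stage for stage in e.stages for _ in range(e.libraries_per_stage)]

    base_log2 = np.log2(e.mean_expression) + rng.normal(0.0, 1.0, size=G)
    lfc = np.zeros(G)
    de = np.zeros(G, dtype=bool)
    if e.n_de:
        de_idx = rng.choice(G, size=min(e.n_de, G), replace=False)
        half = len(de_idx) // 2
        lfc[de_idx[:half]] = e.log2fc
        lfc[de_idx[half:]] = -e.log2fc
        de[de_idx] = True
    if gene_gc is not None and e.gc_slope:
        gc = gene_gc.to_numpy(dtype=float)
        lfc = lfc + e.gc_slope * (gc - np.nanmean(gc))

    counts = np.empty((G, len(libs)), dtype=np.int64)
    nb_n = 1.0 / e.dispersion
    for j, stage in enumerate(stages):
        log2_mean = base_log2 + (lfc if stage == e.stages[1] else 0.0)
        mean = np.power(2.0, log2_mean)
        p = nb_n / (nb_n + mean)
        counts[:, j] = rng.negative_binomial(nb_n, p)
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=libs),
        library_meta=pd.DataFrame(
            {"stage": stages, "replicate": [lib.split("_")[-1] for lib in libs]},
            index=libs,
        ),
    )
    truth = pd.DataFrame({"true_log2fc": lfc, "de": de}, index=genes)
    return matrix, truth


# ---------------------------------------------------------------------------


def sim_cross(spec: SimulationSpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Haploid sons of one phased diploid female over several chromosomes.

    The mother's two haplotypes differ at every marker; each son is a
    recombinant haplotype generated by a Markov walk with the adjacent
    recombination probability; phase labels are then randomized per marker
    (a fresh 0/1 relabeling) so the maternal phase is unknowable; missing
    data and symmetric genotype errors are applied last. The truth table
    carries chromosome, order index and bp for every marker.
    """
    c = spec.cross
    if not 0.0 <= c.r_adjacent < 0.5:
        raise ValueError("adjacent recombination fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    rows = []
    meta = []
    for chrom in range(1, c.n_chromosomes + 1):
        m = c.markers_per_chromosome
        # maternal haplotype A is all 0, haplotype B all 1 (differ everywhere)
        first = rng.integers(0, 2, size=c.n_sons)
        states = [first]
        for _ in range(m - 1):
            flip = rng.random(c.n_sons) < c.r_adjacent
            states.append(np.where(flip, 1 - states[-1], states[-1]))
        block = np.array(states, dtype=float)  # markers x sons
        for i in range(m):
            mid = f"c{chrom}_m{i:03d}"
            meta.append(
                {
                    "marker": mid,
                    "scaffold": f"chr{chrom}",
                    "pos": (i + 1) * c.marker_spacing_bp,
                    "chromosome": chrom,
                    "order": i,
                }
            )
        rows.append(block)
    calls = np.vstack(rows)

    # randomize phase per marker: relabel alleles with a coin flip
    flip = rng.random(calls.shape[0]) < 0.5
    calls[flip] = 1.0 - calls[flip]

    # symmetric genotype error, then missingness
    err = rng.random(calls.shape) < c.error_rate
    calls = np.where(err, 1.0 - calls, calls)
    miss = rng.random(calls.shape) < c.missing_rate
    calls[miss] = np.nan

    meta_df = pd.DataFrame(meta).set_index("marker")
    truth = meta_df[["chromosome", "order", "scaffold", "pos"]].copy()
    matrix = GenotypeMatrix(markers=meta_df[["scaffold", "pos"]], calls=calls)
    return matrix, truth


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    df = matrix.markers.copy()
    calls = pd.DataFrame(
        matrix.calls,
        index=matrix.markers.index,
        columns=[f"son{j + 1:03d}" for j in range(matrix.n_individuals)],
    )
    pd.concat([df, calls], axis=1).to_csv(path, sep="\t", na_rep="NA", index_label="marker")


# ---------------------------------------------------------------------------


def sim_bisulfite(
    spec: SimulationSpec, genome: GenomeSequence
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Bisulfite reads plus per-site methylation truth.

    Each cytosine (either strand) draws a methylation state once, with its
    context probability (context-undefined sites use the CHH probability).
    Reads are sampled uniformly from both strands at the requested mean
    depth; on a read, a methylated C is always retained as C, an
    unmethylated C is converted to T with the conversion rate.

    Returns ``(reads, truth)`` where reads are ``(name, sequence)`` in the
    read's own orientation, and truth is indexed by ``(pos, strand)`` with
    columns ``context`` and ``methylated``.
    """
    b = spec.bisulfite
    if b.depth <= 0:
        raise ValueError("depth must be positive")
    seq = genome.residues
    n = len(seq)
    if b.read_length > n:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))

    from compbias.methylation import classify_contexts

    sites = classify_contexts(genome)
    state: dict[tuple[int, str], bool] = {}
    truth_rows = []
    for site in sites:
        p = b.p_meth.get(site.context, b.p_meth.get("CHH", 0.0))
        methylated = bool(rng.random() < p)
        state[(site.position, site.strand)] = methylated
        truth_rows.append(
            {
                "pos": site.position,
                "strand": site.strand,
                "context": site.context,
                "methylated": methylated,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index(["pos", "strand"])

    n_reads = int(round(b.depth * n / b.read_length))
    reads: list[tuple[str, str]] = []
    starts = rng.integers(0, n - b.read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    for k in range(n_reads):
        start = int(starts[k])
        minus = bool(strands[k])
        frag = seq[start : start + b.read_length]
        if minus:
            frag = reverse_complement(frag)
        out = []
        for off, base in enumerate(frag):
            if base != "C":
                out.append(base)
                continue
            if minus:
                pos1 = start + b.read_length - off  # 1-based + coordinate
                key = (pos1, "-")
            else:
                key = (start + off + 1, "+")
            if state.get(key, False):
                out.append("C")
            elif rng.random() < b.conversion:
                out.append("T")
            else:
                out.append("C")
        reads.append((f"read{k:06d}", "".join(out)))
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
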