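"""Cytosine-context classification and bisulfite methylation summaries.

Every cytosine in the genome (on either strand) is classified by its two
downstream bases into CG, CHG or CHH (H = A, C or T); sites within two
bases of the 3' end of their strand, or with an ambiguity code in the
context window, are context-undefined and excluded from rate tables.
Bisulfite read alignments are tallied per site: on the forward strand C
means methylated and T unmethylated; on the reverse strand the reference-
orientation read shows G (methylated) or A (unmethylated). Covered sites
are classed never / always / variably methylated.

A deliberately naive three-letter exact mapper is included so the module is
fully exercisable on synthetic reads without an external bisulfite aligner;
real data would normally arrive as an aligner's SAM.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from compbias.genome_io import GenomeSequence, reverse_complement

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
_H = set("ACT")


@dataclass
class CytosineSite:
    scaffold: str
    position: int  # 1-based
    strand: str
    context: str  # CG | CHG | CHH | undefined


@dataclass
class SiteCalls:
    methylated: int = 0
    unmethylated: int = 0
    mismatches: int = 0

    @property
    def coverage(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def site_class(self) -> str:
        if self.methylated == 0:
            return "never"
        if self.unmethylated == 0:
            return "always"
        return "variable"


@dataclass
class MethylationSummary:
    """Per-context availability/coverage/rate plus global site classes."""

    per_context: pd.DataFrame
    site_classes: dict[str, int] = field(default_factory=dict)
    n_covered: int = 0
    n_two_plus: int = 0


def classify_contexts(genome: GenomeSequence) -> list[CytosineSite]:
    """Classify every cytosine on both strands of one scaffold.

    Forward-strand cytosines are Cs of the sequence; reverse-strand
    cytosines appear as Gs and are read on the reverse complement.
    """
    seq = genome.residues
    n = len(seq)
    sites: list[CytosineSite] = []
    for i, base in enumerate(seq):
        if base == "C":
            ctx = _context(seq[i + 1 : i + 3]) if i + 2 < n else "undefined"
            sites.append(CytosineSite(genome.id, i + 1, "+", ctx))
        elif base == "G":
            if i - 2 < 0:
                ctx = "undefined"
            else:
                down = reverse_complement(seq[i - 2 : i])
                ctx = _context(down)
            sites.append(CytosineSite(genome.id, i + 1, "-", ctx))
    return sites


def _context(down: str) -> str:
    """Context from the two downstream bases on the cytosine's strand."""
    if len(down) < 2:
        return "undefined"
    b1, b2 = down[0], down[1]
    if b1 == "G":
        return "CG"
    if b1 in _H and b2 == "G":
        return "CHG"
    if b1 in _H and b2 in _H:
        return "CHH"
    return "undefined"  # ambiguity code in the window


def count_calls(
    sam_path: str | Path,
    genome: GenomeSequence,
) -> dict[tuple[int, str], SiteCalls]:
    """Tally methylated/unmethylated calls per cytosine site from a SAM.

    Keys are ``(position_1based, strand)``. Forward-strand alignments call
    forward cytosines (C methylated / T unmethylated); reverse-strand
    alignments call reverse cytosines (G / A in reference orientation).
    Other observations at a cytosine are counted as mismatches.
    """
    seq = genome.residues
    calls: dict[tuple[int, str], SiteCalls] = defaultdict(SiteCalls)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.reference_name != genome.id:
                raise ValueError(f"alignment to unknown scaffold {aln.reference_name!r}")
            read = aln.query_sequence
            rev = aln.is_reverse
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                ref_base = seq[rpos]
                obs = read[qpos]
                if not rev and ref_base == "C":
                    key = (rpos + 1, "+")
                    if obs == "C":
                        calls[key].methylated += 1
                    elif obs == "T":
                        calls[key].unmethylated += 1
                    else:
                        calls[key].mismatches += 1
                elif rev and ref_base == "G":
                    key = (rpos + 1, "-")
                    if obs == "G":
                        calls[key].methylated += 1
                    elif obs == "A":
                        calls[key].unmethylated += 1
                    else:
                        calls[key].mismatches += 1
    return dict(calls)


def summarize(
    sites: list[CytosineSite],
    calls: dict[tuple[int, str], SiteCalls],
    min_reads_for_class: int = 1,
) -> MethylationSummary:
    """Per-context availability, coverage and methylation rate; site classes.

    The methylation rate is raw: methylated calls / total calls, with no
    correction for incomplete bisulfite conversion. Site classes
    (never/always/variable) are counted over covered sites with at least
    ``min_reads_for_class`` calls; context-undefined sites are excluded
    from the per-context table but counted for coverage.
    """
    rows = {c: {"context": c, "available": 0, "covered": 0, "two_plus": 0,
                "meth_calls": 0, "total_calls": 0} for c in CONTEXTS}
    classes = {"never": 0, "always": 0, "variable": 0}
    n_covered = 0
    n_two_plus = 0
    for site in sites:
        sc = calls.get((site.position, site.strand))
        cov = sc.coverage if sc else 0
        if cov >= 1:
            n_covered += 1
            if cov >= 2:
                n_two_plus += 1
            if cov >= min_reads_for_class:
                classes[sc.site_class] += 1
        if site.context == "undefined":
            continue
        row = rows[site.context]
        row["available"] += 1
        if cov >= 1:
            row["covered"] += 1
            row["meth_calls"] += sc.methylated
            row["total_calls"] += cov
            if cov >= 2:
                row["two_plus"] += 1
    table = pd.DataFrame(rows.values()).set_index("context")
    with np.errstate(invalid="ignore"):
        table["meth_rate"] = table["meth_calls"] / table["total_calls"].replace(0, np.nan)
    return MethylationSummary(
        per_context=table,
        site_classes=classes,
        n_covered=n_covered,
        n_two_plus=n_two_plus,
    )


def site_table(sites: list[CytosineSite], calls: dict[tuple[int, str], SiteCalls]) -> pd.DataFrame:
    """Per-site TSV-ready table (scaffold, pos, strand, context, calls, class)."""
    rows = []
    for site in sites:
        sc = calls.get((site.position, site.strand), SiteCalls())
        rows.append(
            {
                "scaffold": site.scaffold,
                "pos": site.position,
                "strand": site.strand,
                "context": site.context,
                "meth": sc.methylated,
                "unmeth": sc.unmethylated,
                "class": sc.site_class if sc.coverage else "uncovered",
            }
        )
    return pd.DataFrame(rows)


def naive_bisulfite_map(
    reads: list[tuple[str, str]],
    genome: GenomeSequence,
    sam_path: str | Path,
) -> dict[str, int]:
    """Three-letter exact bisulfite mapper (synthetic use only).

    Reads are ``(name, sequence)``. The genome and each read are collapsed
    C→T (forward) and G→A (reverse, after reverse-complementing the read)
    and matched exactly; reads hitting more than one locus across both
    strands are discarded as ambiguous. Alignments go to ``sam_path`` as
    headered SAM. Returns tallies: mapped / ambiguous / unmapped.
    """
    seq = genome.residues
    fwd_ref = seq.replace("C", "T")
    rev_ref = seq.replace("G", "A")
    tally = {"mapped": 0, "ambiguous": 0, "unmapped": 0}

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.id, "LN": len(seq)}],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for name, read in reads:
            if len(read) > len(seq):
                raise ValueError(f"read {name} longer than scaffold")
            fwd_pat = read.replace("C", "T")
            rc = reverse_complement(read)
            rev_pat = rc.replace("G", "A")
            hits = [(pos, False) for pos in _find_all(fwd_ref, fwd_pat)]
            hits += [(pos, True) for pos in _find_all(rev_ref, rev_pat)]
            if len(hits) == 0:
                tally["unmapped"] += 1
                continue
            if len(hits) > 1:
                tally["ambiguous"] += 1
                continue
            pos, is_rev = hits[0]
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = rc if is_rev else read
            a.flag = 16 if is_rev else 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(read)}M"
            out.write(a)
            tally["mapped"] += 1
    return tally


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return out
        out.append(pos)
        start = pos + 1
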