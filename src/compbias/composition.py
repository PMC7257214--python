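"""Nucleotide and codon composition statistics.

GC content, third-position GC (GC3), codon counts and relative synonymous
codon usage (RSCU), nitrogen cost per base / duplex pair / amino-acid
residue, cross-profile comparison (distances + PCA), and the Welch t-test
used to compare composition between gene sets.

RSCU for codon c in a synonymous family of size k is

    RSCU_c = k * n_c / sum over the family of n_c'

so a value of 1 means unbiased usage. Stop codons are excluded from RSCU and
from GC3; single-codon families (Met, Trp) are reported as 1 when observed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

from compbias.genome_io import CdsSequence

logger = logging.getLogger(__name__)

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_TO_AA = dict(standard_dna_table.forward_table)

#: synonymous families: amino acid -> sorted list of its sense codons
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)
for _aa in SYNONYMOUS_FAMILIES:
    SYNONYMOUS_FAMILIES[_aa].sort()

# nitrogen atoms per nucleobase (purines 5, cytosine 3, thymine 2)
NITROGEN_PER_BASE = {"A": 5, "G": 5, "C": 3, "T": 2}

# total nitrogen atoms per amino-acid residue (backbone amide + side chain)
NITROGEN_PER_RESIDUE = {aa: 1 for aa in "ACDEFGILMPSTVY"}
NITROGEN_PER_RESIDUE.update({"K": 2, "N": 2, "Q": 2, "W": 2, "H": 3, "R": 4})

# side-chain-only nitrogen (backbone N excluded)
NITROGEN_SIDECHAIN = {aa: n - 1 for aa, n in NITROGEN_PER_RESIDUE.items()}


@dataclass
class CompositionSummary:
    gc_fraction: float
    gc3_fraction: float | None
    length_bases: int
    ambiguous_bases: int
    nitrogen_per_base: float | None = None
    nitrogen_per_residue: float | None = None


@dataclass
class CodonUsageProfile:
    """Codon counts plus RSCU per synonymous family."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    rscu: dict[str, float] = field(default_factory=dict)
    total_codons: int = 0
    skipped_ambiguous: int = 0

    def rscu_vector(self, codons: list[str] | None = None) -> np.ndarray:
        """RSCU values as a vector over ``codons`` (default: all sense codons
        in families of size > 1, plus Met/Trp), NaN where undefined."""
        codons = codons if codons is not None else SENSE_CODONS
        return np.array([self.rscu.get(c, np.nan) for c in codons])


@dataclass
class GeneSetComparison:
    """Welch two-sample comparison of a composition measure between gene sets."""

    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    df: float


def gc_fraction(seq: str, policy: str = "exclude_ambiguous") -> float:
    """GC fraction of a nucleotide sequence.

    ``exclude_ambiguous`` (default) computes (G+C)/(A+C+G+T), dropping IUPAC
    ambiguity codes from the denominator; ``count_as_non_gc`` keeps them in
    the denominator. An empty sequence, or one with no unambiguous base under
    the default policy, raises ValueError.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if policy == "exclude_ambiguous":
        denom = gc + at
        if denom == 0:
            raise ValueError("sequence contains only ambiguous bases; GC undefined")
    elif policy == "count_as_non_gc":
        denom = len(seq)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return gc / denom


def gc3(cds: CdsSequence | str, policy: str = "exclude_ambiguous") -> float:
    """GC fraction over third codon positions of sense codons.

    The terminal stop codon is excluded; a trailing partial codon is
    truncated with a warning. Requires at least one sense codon.
    """
    seq = cds.seq if isinstance(cds, CdsSequence) else cds
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than two codons; GC3 undefined")
    if len(seq) % 3:
        logger.warning("length %d not a multiple of 3; trailing partial codon dropped", len(seq))
        seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    thirds = "".join(c[2] for c in codons)
    if not thirds:
        raise ValueError("no sense codon left after truncation")
    return gc_fraction(thirds, policy=policy)


def pooled_gc3(cds_set: list[CdsSequence | str], policy: str = "exclude_ambiguous") -> float:
    """GC3 pooled over a CDS set: third positions of all sense codons,
    excluding each gene's terminal stop, concatenated before the GC call."""
    thirds = []
    for cds in cds_set:
        seq = (cds.seq if isinstance(cds, CdsSequence) else cds).upper()
        seq = seq[: len(seq) - len(seq) % 3]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        thirds.append("".join(c[2] for c in codons))
    pooled = "".join(thirds)
    if not pooled:
        raise ValueError("no sense codon in the CDS set")
    return gc_fraction(pooled, policy=policy)


def codon_counts(cds_set: list[CdsSequence | str]) -> CodonUsageProfile:
    """Pooled codon counts over a whole CDS set (concatenated pooling).

    Sequences are truncated to a codon boundary; codons containing ambiguity
    codes are skipped and tallied in ``skipped_ambiguous``.
    """
    profile = CodonUsageProfile()
    for cds in cds_set:
        seq = (cds.seq if isinstance(cds, CdsSequence) else cds).upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in profile.counts:
                profile.counts[codon] += 1
                profile.total_codons += 1
            else:
                profile.skipped_ambiguous += 1
    return profile


def rscu(profile: CodonUsageProfile) -> CodonUsageProfile:
    """Fill the RSCU table of a codon-count profile (in place, returned).

    Families with zero total are left undefined (absent from the table).
    """
    if profile.total_codons == 0:
        raise ValueError("empty codon profile")
    profile.rscu = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(profile.counts[c] for c in family)
        if total == 0:
            continue
        k = len(family)
        for c in family:
            profile.rscu[c] = k * profile.counts[c] / total
    return profile


def nitrogen_per_base(seq: str, duplex: bool = False) -> float:
    """Mean nitrogen atoms per base (A=5, G=5, C=3, T=2; ambiguity skipped).

    With ``duplex=True`` the cost of the paired base is included (G:C pair
    8 N, A:T pair 7 N), i.e. the per-pair nitrogen load of double-stranded
    DNA at this composition.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n_bases = sum(counts.values())
    if n_bases == 0:
        raise ValueError("sequence contains only ambiguous bases")
    if duplex:
        total = 8 * (counts["G"] + counts["C"]) + 7 * (counts["A"] + counts["T"])
    else:
        total = sum(NITROGEN_PER_BASE[b] * n for b, n in counts.items())
    return total / n_bases


def nitrogen_per_residue(protein: str, sidechain_only: bool = False) -> float:
    """Mean nitrogen atoms per amino-acid residue.

    Uses total N per residue (Arg 4, His 3, Lys/Asn/Gln/Trp 2, others 1);
    ``sidechain_only=True`` subtracts the backbone amide. X and ``*`` are
    skipped and tallied via a warning.
    """
    if not protein:
        raise ValueError("empty protein")
    table = NITROGEN_SIDECHAIN if sidechain_only else NITROGEN_PER_RESIDUE
    total = 0
    n = 0
    skipped = 0
    for aa in protein.upper():
        if aa in table:
            total += table[aa]
            n += 1
        else:
            skipped += 1
    if n == 0:
        raise ValueError("no standard residue in protein")
    if skipped:
        logger.warning("skipped %d non-standard residues", skipped)
    return total / n


def translate(cds: CdsSequence | str) -> str:
    """Standard-code translation; terminal stop dropped, ambiguous codon -> X."""
    seq = (cds.seq if isinstance(cds, CdsSequence) else cds).upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq[: len(seq) - len(seq) % 3]
    prot = str(Seq(seq).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def compare_codon_profiles(
    profiles: dict[str, CodonUsageProfile],
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Pairwise RSCU distances and a principal-component projection.

    Returns ``(distances, projection, explained_variance)``: a symmetric
    Euclidean distance matrix on RSCU vectors (undefined entries dropped
    pairwise), the profiles projected on principal components of the
    centered RSCU matrix (SVD), and the per-component explained variance.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    names = list(profiles)
    vectors = np.vstack([profiles[n].rscu_vector() for n in names])
    m = len(names)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mask = ~np.isnan(vectors[i]) & ~np.isnan(vectors[j])
            d = float(np.linalg.norm(vectors[i, mask] - vectors[j, mask]))
            dist[i, j] = dist[j, i] = d
    distances = pd.DataFrame(dist, index=names, columns=names)

    col_has_data = ~np.isnan(vectors).all(axis=0)
    col_means = np.zeros(vectors.shape[1])
    col_means[col_has_data] = np.nanmean(vectors[:, col_has_data], axis=0)
    filled = np.where(np.isnan(vectors), col_means, vectors)
    centered = filled - filled.mean(axis=0)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    var = s**2 / max(m - 1, 1)
    ncomp = min(m - 1, proj.shape[1]) or 1
    projection = pd.DataFrame(
        proj[:, :ncomp], index=names, columns=[f"PC{i + 1}" for i in range(ncomp)]
    )
    return distances, projection, var[:ncomp]


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample two-sided t-test, from first principles.

    Returns ``(t, p, df)`` with the Welch–Satterthwaite degrees of freedom.
    Both groups having zero variance and equal means gives t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(na + nb - 2)
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0, float(na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0)), float(df)


def compare_gene_sets_gc(values_a, values_b) -> GeneSetComparison:
    """Welch two-sided t-test between two sets of per-gene composition values.

    Values are typically GC percentages or nitrogen costs; means are reported
    on the input scale.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    t, p, df = welch_ttest(a, b)
    return GeneSetComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=t,
        p_value=p,
        n_a=len(a),
        n_b=len(b),
        df=df,
    )


def gene_composition_table(cds_set: list[CdsSequence]) -> pd.DataFrame:
    """Per-gene composition table: GC, GC3, nitrogen per base and per residue.

    GC3 and protein nitrogen are NaN where a gene is too short or entirely
    ambiguous. Percentages are fractions here; multiply by 100 for display.
    """
    rows = []
    for cds in cds_set:
        row = {"gene_id": cds.gene_id, "length": len(cds.seq), "complete": cds.complete}
        try:
            row["gc"] = gc_fraction(cds.seq)
        except ValueError:
            row["gc"] = np.nan
        try:
            row["gc3"] = gc3(cds)
        except ValueError:
            row["gc3"] = np.nan
        try:
            row["n_per_base"] = nitrogen_per_base(cds.seq)
        except ValueError:
            row["n_per_base"] = np.nan
        try:
            row["n_per_residue"] = nitrogen_per_residue(translate(cds))
        except ValueError:
            row["n_per_residue"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def codon_usage_table(profile: CodonUsageProfile) -> pd.DataFrame:
    """Tidy codon table (codon, amino acid, count, RSCU) for output."""
    rows = []
    for codon in ALL_CODONS:
        aa = CODON_TO_AA.get(codon, "*")
        rows.append(
            {
                "codon": codon,
                "aa": aa,
                "count": profile.counts[codon],
                "rscu": profile.rscu.get(codon, np.nan),
            }
        )
    return pd.DataFrame(rows)
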