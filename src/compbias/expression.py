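"""Expression stratification: normalization, top-decile strata, and a
differential-expression stand-in.

Libraries are normalized with median-of-ratios size factors. Genes are
stratified two ways: the most highly expressed 10% per life stage, and genes
differentially expressed between stages (Welch t on log2 normalized counts,
Benjamini–Hochberg FDR < 0.05). The strata feed Welch comparisons of
per-gene GC and nitrogen content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from compbias.composition import GeneSetComparison, compare_gene_sets_gc, welch_ttest


@dataclass
class ExpressionMatrix:
    """Gene x library count matrix with per-library stage labels.

    ``counts``: DataFrame, genes as index, libraries as columns, counts >= 0.
    ``library_meta``: DataFrame indexed by library id with at least a
    ``stage`` column (e.g. ``adult`` / ``larva``).
    """

    counts: pd.DataFrame
    library_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.library_meta.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")

    def libraries_for(self, stage: str) -> list[str]:
        libs = [
            lib
            for lib in self.counts.columns
            if self.library_meta.loc[lib, "stage"] == stage
        ]
        if not libs:
            raise ValueError(f"no library with stage {stage!r}")
        return libs

    @property
    def stages(self) -> list[str]:
        return sorted(self.library_meta.loc[self.counts.columns, "stage"].unique())


@dataclass
class DeResult:
    """Per-gene differential-expression table (larva vs adult)."""

    table: pd.DataFrame  # columns: log2fc, t, p_value, fdr_q

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["fdr_q"] < alpha]

    def biased(self, direction: str, alpha: float = 0.05) -> pd.Index:
        """Genes significant at ``alpha`` and up in ``direction``
        (``larva``: log2fc > 0; ``adult``: log2fc < 0)."""
        sig = self.table["fdr_q"] < alpha
        if direction == "larva":
            return self.table.index[sig & (self.table["log2fc"] > 0)]
        if direction == "adult":
            return self.table.index[sig & (self.table["log2fc"] < 0)]
        raise ValueError(f"unknown direction {direction!r}")


def size_factors(matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes of count_gj / geometric-mean_g, where the
    geometric mean runs over libraries and genes with a zero anywhere (zero
    geometric mean) are excluded from the reference.
    """
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene with nonzero counts in every library; "
            "consider a pseudo-reference (add a pseudocount)"
        )
    log_geomean = logs[usable].mean(axis=1)
    ratios = logs[usable] - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(matrix: ExpressionMatrix) -> pd.DataFrame:
    return matrix.counts / size_factors(matrix)


def top_decile(matrix: ExpressionMatrix, stage: str, fraction: float = 0.10) -> pd.Index:
    """The most highly expressed ``fraction`` of genes in one life stage.

    Ranking is on mean normalized expression over the stage's libraries;
    ceil(fraction * G) genes are returned; ties break by gene id so the
    stratum is deterministic.
    """
    if len(matrix.counts) < 10:
        raise ValueError("need at least 10 genes for a decile stratum")
    libs = matrix.libraries_for(stage)
    norm = normalized_counts(matrix)[libs].mean(axis=1)
    k = math.ceil(fraction * len(norm))
    order = sorted(norm.index, key=lambda g: (-norm[g], g))
    cut = norm[order[k - 1]]
    if k < len(order) and norm[order[k]] == cut:
        import logging

        logging.getLogger(__name__).warning(
            "tie at the decile boundary (%g); broken by gene id", cut
        )
    return pd.Index(order[:k])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(
    matrix: ExpressionMatrix,
    stage_a: str = "adult",
    stage_b: str = "larva",
    pseudocount: float = 1.0,
) -> DeResult:
    """Stand-in DE test: Welch t on log2(normalized count + pseudocount).

    Log2 fold change is stage_b minus stage_a (larva vs adult by default).
    q-values are Benjamini–Hochberg. This is deliberately a simple,
    well-calibrated stand-in for a negative-binomial GLM; see the methods
    note for what that choice does and does not preserve.
    """
    from scipy import stats as _stats

    libs_a = matrix.libraries_for(stage_a)
    libs_b = matrix.libraries_for(stage_b)
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ValueError("each stage needs at least two libraries")
    norm = normalized_counts(matrix)
    log_a = np.log2(norm[libs_a].to_numpy() + pseudocount)
    log_b = np.log2(norm[libs_b].to_numpy() + pseudocount)
    na, nb = log_a.shape[1], log_b.shape[1]
    ma, mb = log_a.mean(axis=1), log_b.mean(axis=1)
    va, vb = log_a.var(axis=1, ddof=1), log_b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0.0
    equal = degenerate & (ma == mb)
    t = np.where(equal, 0.0, t)
    p = np.where(
        degenerate,
        np.where(equal, 1.0, 0.0),
        2.0 * _stats.t.sf(np.abs(t), np.where(degenerate, 1.0, df)),
    )
    table = pd.DataFrame(
        {"log2fc": mb - ma, "t": t, "p_value": np.minimum(p, 1.0)},
        index=matrix.counts.index.rename("gene_id"),
    )
    table["fdr_q"] = bh_fdr(table["p_value"].to_numpy())
    return DeResult(table=table)


def strata_report(
    matrix: ExpressionMatrix,
    gene_compositions: pd.DataFrame,
    stage_a: str = "adult",
    stage_b: str = "larva",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The four stratified composition comparisons.

    Rows: top-decile GC, DE GC, top-decile nitrogen, DE nitrogen —
    each a Welch two-sided t-test of per-gene values between the stage_a and
    stage_b stratum. ``gene_compositions`` must carry ``gc`` (fraction) and
    ``n_per_residue`` columns indexed by gene id. GC means are reported in
    percent.
    """
    missing = set(matrix.counts.index) - set(gene_compositions.index)
    if missing:
        raise ValueError(f"composition missing for {len(missing)} genes")

    deciles = {s: top_decile(matrix, s) for s in (stage_a, stage_b)}
    de = differential_expression(matrix, stage_a=stage_a, stage_b=stage_b)
    sig = de.table["fdr_q"] < alpha
    de_strata = {
        stage_a: de.table.index[sig & (de.table["log2fc"] < 0)],
        stage_b: de.table.index[sig & (de.table["log2fc"] > 0)],
    }

    def compare(genes_a, genes_b, column, scale) -> GeneSetComparison:
        if len(genes_a) < 2 or len(genes_b) < 2:
            raise ValueError("stratum with fewer than two genes")
        va = gene_compositions.loc[genes_a, column].dropna() * scale
        vb = gene_compositions.loc[genes_b, column].dropna() * scale
        return compare_gene_sets_gc(va, vb)

    specs = [
        ("top_decile_gc", deciles, "gc", 100.0),
        ("de_gc", de_strata, "gc", 100.0),
        ("top_decile_nitrogen", deciles, "n_per_residue", 1.0),
        ("de_nitrogen", de_strata, "n_per_residue", 1.0),
    ]
    rows = []
    for name, strata, column, scale in specs:
        c = compare(strata[stage_a], strata[stage_b], column, scale)
        rows.append(
            {
                "comparison": name,
                f"mean_{stage_a}": c.mean_a,
                f"mean_{stage_b}": c.mean_b,
                "t": c.t_statistic,
                "p_value": c.p_value,
                f"n_{stage_a}": c.n_a,
                f"n_{stage_b}": c.n_b,
            }
        )
    return pd.DataFrame(rows).set_index("comparison")


def read_counts_tsv(counts_path, meta_path) -> ExpressionMatrix:
    """Read a genes x libraries count TSV and a library metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "stage" not in meta.columns:
        raise ValueError("metadata must have a 'stage' column")
    return ExpressionMatrix(counts=counts, library_meta=meta)
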