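"""Linkage-map construction from haploid sons of one female.

In haplodiploid Hymenoptera each male carries a single maternal recombinant
haplotype, so a panel of sons from one female is formally a doubled-haploid
mapping population — except that the maternal phase is unknown. The
phase-mirror device handles that: every marker is duplicated with flipped
alleles, linkage groups are built over the doubled marker set, and one group
of each mirrored pair is discarded afterwards. Grouping uses Fisher's exact
test on the 2x2 haplotype table with linkage declared in coupling phase
(r_hat < 0.5); ordering uses a minimum-spanning-tree backbone with 2-opt
refinement; map distances are Kosambi centimorgans summed over adjacent
recombination fractions. Scaffolds are anchored to groups by marker
majority, oriented by rank correlation, and flagged as putative chimeras
when a contiguous block of markers at one end maps to a different group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MIRROR_SUFFIX = "::m"


@dataclass
class GenotypeMatrix:
    """Haploid marker calls: markers x individuals over {0, 1, missing}.

    ``calls`` is a float array with NaN for missing. ``markers`` is a
    DataFrame indexed by marker id with ``scaffold`` and ``pos`` (bp,
    1-based) columns.
    """

    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape[0] != len(self.markers):
            raise ValueError("calls rows must match marker table")
        values = self.calls[~np.isnan(self.calls)]
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("calls must be binary (0/1) or missing")
        if not self.markers.index.is_unique:
            raise ValueError("marker ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[self.markers.index.get_loc(marker_id)]


@dataclass
class MarkerPair:
    r_hat: float
    n_informative: int
    p_linkage: float


@dataclass
class LinkageGroup:
    name: str
    marker_ids: list[str]
    positions_cm: list[float]


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    unplaced: list[str] = field(default_factory=list)

    def as_frame(self, markers: pd.DataFrame | None = None) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for mid, cm in zip(g.marker_ids, g.positions_cm):
                row = {"group": g.name, "marker": mid, "cm": cm}
                if markers is not None and mid in markers.index:
                    row["scaffold"] = markers.loc[mid, "scaffold"]
                    row["pos"] = markers.loc[mid, "pos"]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    group: str
    mean_cm: float
    orientation: str  # '+', '-', or 'unknown'
    n_markers: int
    chimera_flag: bool = False
    minority_group: str | None = None
    suggested_split_bp: int | None = None


# ---------------------------------------------------------------------------
# filtering / mirroring


def filter_markers(
    matrix: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.15,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with > ``max_missing`` missing data or MAF < ``min_maf``.

    Both boundaries are inclusive on the keep side (missing exactly 20% and
    MAF exactly 15% are kept). Returns the filtered matrix and a removal
    log with a reason per dropped marker.
    """
    miss = np.isnan(matrix.calls).mean(axis=1)
    with np.errstate(invalid="ignore"):
        freq1 = np.nanmean(matrix.calls, axis=1)
    maf = np.minimum(freq1, 1.0 - freq1)
    drop_missing = miss > max_missing
    drop_maf = maf < min_maf
    keep = ~(drop_missing | drop_maf)
    log_rows = []
    for i, mid in enumerate(matrix.markers.index):
        if keep[i]:
            continue
        reasons = []
        if drop_missing[i]:
            reasons.append(f"missing {miss[i]:.3f} > {max_missing}")
        if drop_maf[i]:
            reasons.append(f"MAF {maf[i]:.3f} < {min_maf}")
        log_rows.append({"marker": mid, "reason": "; ".join(reasons)})
    if not keep.any():
        raise ValueError("all markers removed by filtering")
    filtered = GenotypeMatrix(markers=matrix.markers.loc[keep], calls=matrix.calls[keep])
    return filtered, pd.DataFrame(log_rows, columns=["marker", "reason"])


def mirror_phase(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Duplicate every marker with flipped alleles (phase-mirror device).

    Mirror copies carry the ``::m`` id suffix; missing stays missing.
    Mirroring a mirrored matrix restores the original ids (involution).
    """
    if all(m.endswith(MIRROR_SUFFIX) or (m + MIRROR_SUFFIX) in matrix.markers.index
           for m in matrix.markers.index) and matrix.n_markers and matrix.n_markers % 2 == 0:
        # un-mirror: keep the original halves only
        originals = [m for m in matrix.markers.index if not m.endswith(MIRROR_SUFFIX)]
        idx = [matrix.markers.index.get_loc(m) for m in originals]
        return GenotypeMatrix(markers=matrix.markers.iloc[idx], calls=matrix.calls[idx])
    mirrored = 1.0 - matrix.calls
    markers_m = matrix.markers.copy()
    markers_m.index = [m + MIRROR_SUFFIX for m in matrix.markers.index]
    return GenotypeMatrix(
        markers=pd.concat([matrix.markers, markers_m]),
        calls=np.vstack([matrix.calls, mirrored]),
    )


def strip_mirror(marker_id: str) -> str:
    return marker_id[: -len(MIRROR_SUFFIX)] if marker_id.endswith(MIRROR_SUFFIX) else marker_id


# ---------------------------------------------------------------------------
# pairwise linkage


def _fisher_two_sided(n11, n10, n01, n00) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for arrays of 2x2 tables.

    Hypergeometric enumeration with a gammaln lookup table; the two-sided p
    sums all tables (fixed margins) whose probability does not exceed the
    observed one (with scipy's relative tolerance for float ties).
    """
    n11 = np.asarray(n11, dtype=np.int64).ravel()
    n10 = np.asarray(n10, dtype=np.int64).ravel()
    n01 = np.asarray(n01, dtype=np.int64).ravel()
    n00 = np.asarray(n00, dtype=np.int64).ravel()
    n = n11 + n10 + n01 + n00
    r1 = n11 + n10  # row margin
    c1 = n11 + n01  # column margin
    lg = gammaln(np.arange(int(n.max()) + 2))

    def log_pmf(k):
        # log P(X=k) for hypergeom(M=n, K=r1, N=c1), invalid k -> -inf
        valid = (k >= np.maximum(0, r1 + c1 - n)) & (k <= np.minimum(r1, c1))
        k = np.where(valid, k, 0)
        val = (
            lg[r1 + 1] - lg[k + 1] - lg[r1 - k + 1]
            + lg[n - r1 + 1] - lg[c1 - k + 1] - lg[n - r1 - (c1 - k) + 1]
            - (lg[n + 1] - lg[c1 + 1] - lg[n - c1 + 1])
        )
        return np.where(valid, val, -np.inf)

    obs = log_pmf(n11)
    kmax = int(np.minimum(r1, c1).max())
    p = np.zeros(len(n11))
    # enumerate the support in vectorized slabs over k
    for k in range(kmax + 1):
        lp = log_pmf(np.full_like(n11, k))
        include = lp <= obs + 1e-7  # scipy's relative gate on pmf ties
        p += np.where(include, np.exp(lp), 0.0)
    return np.minimum(p, 1.0)


def pairwise_linkage(m1: np.ndarray, m2: np.ndarray) -> MarkerPair:
    """Recombination fraction and linkage p-value for one marker pair.

    r_hat is the mismatch fraction over co-typed individuals; p comes from a
    two-sided Fisher exact test on the 2x2 haplotype table.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    ok = ~np.isnan(m1) & ~np.isnan(m2)
    n_inf = int(ok.sum())
    if n_inf < 2:
        raise ValueError(f"only {n_inf} co-typed individuals; need >= 2")
    a, b = m1[ok], m2[ok]
    mismatches = int((a != b).sum())
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    p = float(_fisher_two_sided([n11], [n10], [n01], [n00])[0])
    return MarkerPair(r_hat=mismatches / n_inf, n_informative=n_inf, p_linkage=p)


def _pair_tables(calls: np.ndarray) -> tuple[np.ndarray, ...]:
    """All-pairs 2x2 haplotype tables, missing-aware, via matrix products."""
    is1 = np.nan_to_num((calls == 1.0).astype(float))
    is0 = np.nan_to_num((calls == 0.0).astype(float))
    n11 = is1 @ is1.T
    n10 = is1 @ is0.T
    n01 = is0 @ is1.T
    n00 = is0 @ is0.T
    return (
        n11.astype(np.int64),
        n10.astype(np.int64),
        n01.astype(np.int64),
        n00.astype(np.int64),
    )


def pairwise_r_matrix(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r_hat, n_informative) matrices over all marker pairs."""
    n11, n10, n01, n00 = _pair_tables(calls)
    n_inf = n11 + n10 + n01 + n00
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n10 + n01) / n_inf
    return r, n_inf


# ---------------------------------------------------------------------------
# grouping


def group_markers(
    mirrored: GenotypeMatrix,
    p_cut: float = 1e-6,
    min_group_size: int = 2,
) -> tuple[list[list[str]], list[str]]:
    """Linkage groups over a mirrored matrix, with mirror-pair dedup.

    Edges join pairs with Fisher p < ``p_cut`` in coupling phase
    (r_hat < 0.5); groups are connected components (single-linkage
    transitive closure). Each group's mirror partner (the group holding the
    flipped copies) is identified and one of the two is dropped: the kept
    group is the one containing the lexicographically smallest original
    marker id. Returned marker ids have the mirror suffix stripped.
    Singleton groups below ``min_group_size`` are returned as unplaced.
    """
    ids = list(mirrored.markers.index)
    n11, n10, n01, n00 = _pair_tables(mirrored.calls)
    n_inf = n11 + n10 + n01 + n00
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n10 + n01) / n_inf
    iu, ju = np.triu_indices(len(ids), k=1)
    cand = (r[iu, ju] < 0.5) & (n_inf[iu, ju] >= 2)
    iu, ju = iu[cand], ju[cand]
    pvals = _fisher_two_sided(n11[iu, ju], n10[iu, ju], n01[iu, ju], n00[iu, ju])
    linked = pvals < p_cut

    # union-find over the doubled marker set
    parent = list(range(len(ids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(iu[linked], ju[linked]):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri

    comps: dict[int, list[str]] = {}
    for k, mid in enumerate(ids):
        comps.setdefault(find(k), []).append(mid)

    groups = []
    unplaced = []
    for members in comps.values():
        originals = {strip_mirror(m) for m in members}
        if len(originals) < len(members):
            raise ValueError(
                "a linkage group contains a marker and its own mirror; "
                "the genotype data are internally inconsistent"
            )
        if len(members) < min_group_size:
            unplaced.extend(sorted(originals))
        else:
            groups.append(sorted(members))

    # pair up mirror-duplicate groups and keep one of each pair
    by_key: dict[frozenset, list[list[str]]] = {}
    for g in groups:
        key = frozenset(strip_mirror(m) for m in g)
        by_key.setdefault(key, []).append(g)
    kept: list[list[str]] = []
    for key, pair in by_key.items():
        if len(pair) == 1:
            logger.warning(
                "group %s has no mirror partner; keeping it as-is", sorted(key)[:3]
            )
            kept.append(pair[0])
            continue
        if len(pair) > 2:
            raise ValueError("more than two groups share one marker set")
        smallest = min(key)
        chosen = pair[0] if smallest in pair[0] else pair[1]
        kept.append(chosen)
    kept.sort(key=lambda g: min(strip_mirror(m) for m in g))
    return kept, sorted(set(unplaced))


# ---------------------------------------------------------------------------
# ordering and distances


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = tanh(d/50) / 2."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def _path_cost(order: np.ndarray, r: np.ndarray) -> float:
    return float(r[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Local search on the open path: 2-opt segment reversals plus
    single-marker relocations, repeated to a local optimum. The relocation
    move matters — a lone misplaced marker is not reachable by reversals.
    Deterministic scan order."""
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                new = order.copy()
                new[i : j + 1] = new[i : j + 1][::-1]
                if _path_cost(new, r) < _path_cost(order, r) - 1e-12:
                    order = new
                    improved = True
        for i in range(n):
            for j in range(n):
                if j == i:
                    continue
                new = np.delete(order, i)
                new = np.insert(new, j if j < i else j, order[i])
                if _path_cost(new, r) < _path_cost(order, r) - 1e-12:
                    order = new
                    improved = True
    return order


def order_markers(group: list[str], matrix: GenotypeMatrix) -> list[str]:
    """Order one linkage group's markers along the chromosome.

    Minimum-spanning-tree backbone on the complete r_hat graph, a
    depth-first path from one end of the tree diameter, then 2-opt plus
    single-marker relocation refinement of the summed adjacent r_hat. The
    phase-free estimate min(r_hat, 1 - r_hat) is used, so ordering works on
    co-phased mirror groups and raw unknown-phase matrices alike. Ties
    break by marker id and the output is oriented so the first marker id
    sorts before the last.
    """
    if len(group) < 2:
        raise ValueError("group must have at least two markers")
    # deterministic input order; ties and orientation key on the stripped id
    # so the result is invariant to which mirror copy landed in the group
    group = sorted(group, key=strip_mirror)
    idx = [matrix.markers.index.get_loc(m) for m in group]
    calls = matrix.calls[idx]
    r, n_inf = pairwise_r_matrix(calls)
    r = np.minimum(r, 1.0 - r)
    if np.isnan(r[np.triu_indices(len(group), k=1)]).any():
        bad = np.argwhere(np.isnan(r))
        raise ValueError(
            f"r_hat undefined for {len(bad) // 2} marker pairs (no co-typed "
            "individuals); the r-hat graph is disconnected"
        )
    np.fill_diagonal(r, 0.0)

    mst = minimum_spanning_tree(np.where(r == 0, 1e-12, r)).toarray()
    adj = (mst > 0) | (mst.T > 0)

    def farthest(start: int) -> tuple[int, dict[int, int]]:
        # BFS in id-sorted neighbor order for determinism
        seen = {start: None}
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    v = int(v)
                    if v not in seen:
                        seen[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, seen

    end_a, _ = farthest(0)
    end_b, _ = farthest(end_a)
    start = min(end_a, end_b)

    # depth-first traversal from one diameter end gives the backbone order
    order = []
    seen = set()
    stack = [start]
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        order.append(u)
        nbrs = sorted((int(v) for v in np.flatnonzero(adj[u]) if int(v) not in seen), reverse=True)
        stack.extend(nbrs)
    order = _two_opt(np.array(order), r)

    uniq = np.unique(r[np.triu_indices(len(group), k=1)])
    if len(group) > 2 and len(uniq) == 1:
        logger.warning("all pairwise r equal in group; order is id-lexicographic")
        order = np.arange(len(group))

    ordered = [group[i] for i in order]
    if strip_mirror(ordered[0]) > strip_mirror(ordered[-1]):
        ordered.reverse()
    return ordered


def map_positions(ordered: list[str], matrix: GenotypeMatrix, max_r: float = 0.4999) -> list[float]:
    """Cumulative Kosambi cM along an ordered marker list.

    Positions are sums of adjacent-pair distances using the phase-free
    estimate min(r_hat, 1 - r_hat); an estimate of exactly 0.5 (possible
    with noise) is clamped to ``max_r`` with a warning.
    """
    pos = [0.0]
    for a, b in zip(ordered[:-1], ordered[1:]):
        pair = pairwise_linkage(matrix.column(a), matrix.column(b))
        r = min(pair.r_hat, 1.0 - pair.r_hat)
        if r >= 0.5:
            logger.warning("adjacent r_hat %.3f >= 0.5 between %s and %s; clamped", r, a, b)
            r = max_r
        pos.append(pos[-1] + float(kosambi_cm(r)))
    return pos


def split_gaps(gmap: GeneticMap, gap_cm: float = 70.0) -> GeneticMap:
    """Split any group at adjacent gaps larger than ``gap_cm``.

    A gap that large indicates a false fusion of two chromosomes; positions
    are re-zeroed per new group.
    """
    out = []
    for g in gmap.groups:
        pieces: list[tuple[list[str], list[float]]] = [([], [])]
        prev_cm = None
        for mid, cm in zip(g.marker_ids, g.positions_cm):
            if prev_cm is not None and cm - prev_cm > gap_cm:
                pieces.append(([], []))
            pieces[-1][0].append(mid)
            pieces[-1][1].append(cm)
            prev_cm = cm
        for k, (mids, cms) in enumerate(pieces):
            name = g.name if len(pieces) == 1 else f"{g.name}.{k + 1}"
            base = cms[0]
            out.append(LinkageGroup(name=name, marker_ids=mids, positions_cm=[c - base for c in cms]))
    return GeneticMap(groups=out, unplaced=gmap.unplaced)


# ---------------------------------------------------------------------------
# pipeline and anchoring


def build_map(
    matrix: GenotypeMatrix,
    p_cut: float = 1e-6,
    gap_cm: float = 70.0,
    max_missing: float = 0.20,
    min_maf: float = 0.15,
) -> GeneticMap:
    """Full pipeline: filter, mirror, group, dedup, order, position, split.

    The returned map carries original marker ids (mirror suffixes stripped)
    and is invariant to the unknown maternal phase of every marker.
    """
    filtered, _log = filter_markers(matrix, max_missing=max_missing, min_maf=min_maf)
    mirrored = mirror_phase(filtered)
    groups, unplaced = group_markers(mirrored, p_cut=p_cut)
    out_groups = []
    for k, group in enumerate(groups):
        ordered = order_markers(group, mirrored)
        cms = map_positions(ordered, mirrored)
        out_groups.append(
            LinkageGroup(
                name=f"LG{k + 1}",
                marker_ids=[strip_mirror(m) for m in ordered],
                positions_cm=cms,
            )
        )
    gmap = GeneticMap(groups=out_groups, unplaced=unplaced)
    return split_gaps(gmap, gap_cm=gap_cm)


def anchor_scaffolds(
    gmap: GeneticMap,
    markers: pd.DataFrame,
    min_chimera_markers: int = 5,
    min_abs_rho: float = 0.5,
) -> list[ScaffoldAnchor]:
    """Assign scaffolds to linkage groups; orient; flag putative chimeras.

    A scaffold goes to the group holding the majority of its mapped markers,
    with its mean cM position there. Orientation comes from the Spearman
    rank correlation of bp vs cM (|rho| >= ``min_abs_rho``, else unknown). A
    chimera is flagged when >= ``min_chimera_markers`` markers fall in a
    minority group AND they are positionally contiguous at one scaffold
    end; the suggested split is the bp midpoint between the two positional
    clusters. Scaffolds with no mapped marker are omitted (logged).
    """
    placed = gmap.as_frame(markers)
    anchors: list[ScaffoldAnchor] = []
    if placed.empty:
        return anchors
    for scaffold, sub in placed.groupby("scaffold", sort=True):
        counts = sub.groupby("group").size().sort_values(ascending=False)
        major = counts.index[0]
        major_rows = sub[sub["group"] == major]
        if len(major_rows) >= 3 and major_rows["pos"].nunique() > 1 and major_rows["cm"].nunique() > 1:
            rho = stats.spearmanr(major_rows["pos"], major_rows["cm"]).statistic
        else:
            rho = np.nan
        if np.isnan(rho) or abs(rho) < min_abs_rho:
            orientation = "unknown"
        else:
            orientation = "+" if rho > 0 else "-"
        anchor = ScaffoldAnchor(
            scaffold_id=str(scaffold),
            group=str(major),
            mean_cm=float(major_rows["cm"].mean()),
            orientation=orientation,
            n_markers=len(sub),
        )
        # chimera: a big enough contiguous minority block at one end
        for minority in counts.index[1:]:
            minority_rows = sub[sub["group"] == minority]
            if len(minority_rows) < min_chimera_markers:
                continue
            lo, hi = minority_rows["pos"].min(), minority_rows["pos"].max()
            others = sub[sub["group"] != minority]["pos"]
            at_low_end = (others > hi).all()
            at_high_end = (others < lo).all()
            if not (at_low_end or at_high_end):
                continue
            if at_low_end:
                split = int((hi + others.min()) // 2)
            else:
                split = int((others.max() + lo) // 2)
            anchor.chimera_flag = True
            anchor.minority_group = str(minority)
            anchor.suggested_split_bp = split
            break
        anchors.append(anchor)
    missing = set(markers["scaffold"].unique()) - set(placed["scaffold"].unique())
    for s in sorted(missing):
        logger.info("scaffold %s has no mapped marker; omitted from anchoring", s)
    return anchors


def anchors_table(anchors: list[ScaffoldAnchor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": a.scaffold_id,
                "group": a.group,
                "mean_cm": a.mean_cm,
                "orientation": a.orientation,
                "n_markers": a.n_markers,
                "chimera": a.chimera_flag,
                "minority_group": a.minority_group,
                "suggested_split_bp": a.suggested_split_bp,
            }
            for a in anchors
        ]
    )


# ---------------------------------------------------------------------------
# input


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a marker x individual genotype TSV.

    Columns: ``marker``, ``scaffold``, ``pos``, then one column per
    individual with values 0, 1 or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "scaffold": str})
    df = df.set_index("marker")
    meta = df[["scaffold", "pos"]]
    calls = df.drop(columns=["scaffold", "pos"]).to_numpy(dtype=float)
    return GenotypeMatrix(markers=meta, calls=calls)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read haploid GT calls from a VCF into a genotype matrix.

    Sites must be biallelic; heterozygous calls in a haploid individual are
    set missing and logged.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows, meta_rows, het = [], [], 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        calls = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                calls.append(np.nan)
            else:
                alleles = {a for a in gt if a is not None}
                if len(alleles) > 1:
                    het += 1
                    calls.append(np.nan)
                else:
                    calls.append(float(alleles.pop()))
        rows.append(calls)
        meta_rows.append(
            {"marker": rec.id or f"{rec.chrom}_{rec.pos}", "scaffold": rec.chrom, "pos": rec.pos}
        )
    if het:
        logger.warning("%d heterozygous haploid calls set to missing", het)
    meta = pd.DataFrame(meta_rows).set_index("marker")
    return GenotypeMatrix(markers=meta, calls=np.array(rows))
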