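"""Hi-C-assisted assembly stages.

Scaffolds are grouped into chromosomes by average-linkage hierarchical
clustering of their mean balanced trans contact frequency (karyotyping);
scaffolds whose bins disagree about their chromosome are cut into
subscaffolds at the disagreement points (misjoin splitting); subscaffolds
of one chromosome are ordered by greedy contact chaining with 2-opt
refinement and oriented by end-half contact asymmetry.  Set-aside
high-copy clusters are assigned to their preferred chromosome, and their
relative copy number is estimated from read coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .genome_io import BinTable, ContactMatrix

__all__ = [
    "ScaffoldSet",
    "KaryotypeResult",
    "ChromosomeScaffold",
    "scaffold_set_from_bins",
    "karyotype_cluster",
    "split_misjoins",
    "order_orient",
    "assign_high_copy",
    "copy_number",
]

MIN_SCAFFOLD_LEN = 40_000  # scaffolds below this are set aside, not clustered


@dataclass
class ScaffoldSet:
    """Scaffolds with their bin ranges in a genome-wide bin table."""

    scaffolds: pd.DataFrame  # name, length
    bin_table: BinTable
    min_length: int = MIN_SCAFFOLD_LEN

    @property
    def usable(self) -> pd.DataFrame:
        return self.scaffolds[self.scaffolds["length"] >= self.min_length]

    @property
    def below_min(self) -> list[str]:
        return list(
            self.scaffolds.loc[
                self.scaffolds["length"] < self.min_length, "name"
            ]
        )

    def bins_of(self, name: str) -> slice:
        return self.bin_table.chrom_slice(name)


@dataclass
class KaryotypeResult:
    assignment: dict[str, int]  # scaffold -> cluster id
    ambiguous: list[str]
    below_min: list[str]
    merge_heights: np.ndarray
    k: int
    affinity: pd.DataFrame | None = None  # scaffold x cluster mean contact


@dataclass
class ChromosomeScaffold:
    """Ordered, oriented subscaffolds of one chromosome."""

    members: list[tuple[str, str, float]]  # (name, orientation, confidence)

    @property
    def order(self) -> list[str]:
        return [m[0] for m in self.members]


def scaffold_set_from_bins(bin_table: BinTable) -> ScaffoldSet:
    df = pd.DataFrame(
        {
            "name": list(bin_table.chrom_lengths),
            "length": [bin_table.chrom_lengths[c] for c in bin_table.chrom_lengths],
        }
    )
    return ScaffoldSet(scaffolds=df, bin_table=bin_table)


def _balanced_csr(matrix: ContactMatrix):
    if matrix.weights is None:
        raise ValueError("matrix must be balanced")
    w = np.nan_to_num(matrix.weights, nan=0.0)
    C = matrix.counts.tocsr()
    import scipy.sparse as sp

    D = sp.diags(w)
    return (D @ C @ D).tocsr()


def _pair_mean_contact(B, sl_a: slice, sl_b: slice) -> float:
    sub = B[sl_a, sl_b]
    n = (sl_a.stop - sl_a.start) * (sl_b.stop - sl_b.start)
    return float(sub.sum()) / max(n, 1)


def karyotype_cluster(
    matrix: ContactMatrix,
    scaffolds: ScaffoldSet,
    k: int | None = None,
    ambiguity_ratio: float = 0.35,
    min_affinity_frac: float = 0.05,
) -> KaryotypeResult:
    """Cluster scaffolds into chromosome groups from trans contacts.

    The per-pair statistic is the mean balanced trans contact per bin pair
    (mean, not sum, so scaffold length does not dominate).  Because the
    rod-length contact cutoff makes chromosomes chain-like (scaffolds more
    than one rod length apart barely touch), clustering operates on the
    correlation of the log mean-contact *profiles* rather than on the raw
    pairwise contact, which propagates chromosome membership
    transitively.  Average-linkage clustering is cut at ``k`` clusters
    when given, otherwise at the largest gap in merge heights.

    A scaffold whose mean-contact affinity to its second-best cluster
    exceeds ``ambiguity_ratio`` times its best-cluster affinity is moved
    to the ambiguous set, as is a scaffold whose best affinity falls below
    ``min_affinity_frac`` of the cohort median (no informative linkage).
    """
    names = list(scaffolds.usable["name"])
    m = len(names)
    if k is not None and m < k:
        raise ValueError("fewer scaffolds than requested clusters")
    B = _balanced_csr(matrix)
    sim = np.zeros((m, m))
    sls = [scaffolds.bins_of(n) for n in names]
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = _pair_mean_contact(B, sls[i], sls[j])
    eps = sim[sim > 0].min() if (sim > 0).any() else 1e-12
    LS = np.log(sim + eps)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mask = np.ones(m, dtype=bool)
            mask[[i, j]] = False
            if mask.sum() >= 3:
                c = np.corrcoef(LS[i, mask], LS[j, mask])[0, 1]
                if not np.isfinite(c):
                    c = 0.0
            else:
                c = 1.0 if sim[i, j] > 0 else 0.0
            dist[i, j] = dist[j, i] = max(1.0 - c, 0.0)
    from scipy.spatial.distance import squareform

    Z = sch.linkage(squareform(dist, checks=False), method="average")
    heights = Z[:, 2]
    if k is None:
        gaps = np.diff(heights)
        k = m - (int(np.argmax(gaps)) + 1) if len(gaps) else 1
        k = max(k, 1)
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    labels = labels - 1

    # per-scaffold affinity to each cluster (mean contact to member bins)
    aff = np.zeros((m, k))
    for c in range(k):
        members = [i for i in range(m) if labels[i] == c]
        for i in range(m):
            vals = [
                _pair_mean_contact(B, sls[i], sls[j]) for j in members if j != i
            ]
            aff[i, c] = np.mean(vals) if vals else 0.0
    assignment, ambiguous = {}, []
    best_all = aff.max(axis=1)
    floor = min_affinity_frac * np.median(best_all)
    for i, name in enumerate(names):
        order = np.argsort(aff[i])[::-1]
        best, second = aff[i][order[0]], aff[i][order[1]] if k > 1 else 0.0
        if best <= 0 or best < floor:
            ambiguous.append(name)
            continue
        if k > 1 and second / best > ambiguity_ratio:
            ambiguous.append(name)
        else:
            assignment[name] = int(order[0])
    aff_df = pd.DataFrame(aff, index=names, columns=range(k))
    return KaryotypeResult(
        assignment=assignment,
        ambiguous=ambiguous,
        below_min=scaffolds.below_min,
        merge_heights=heights,
        k=k,
        affinity=aff_df,
    )


def _bin_cluster_affinity(B, bin_sl: slice, cluster_bins: dict[int, np.ndarray]):
    """Mean balanced contact of each bin in ``bin_sl`` to each cluster."""
    ks = sorted(cluster_bins)
    A = np.zeros((bin_sl.stop - bin_sl.start, len(ks)))
    sub = B[bin_sl, :]
    for ci, c in enumerate(ks):
        cols = cluster_bins[c]
        if len(cols) == 0:
            continue
        A[:, ci] = np.asarray(sub[:, cols].sum(axis=1)).ravel() / len(cols)
    return A, ks


def _smooth_labels(lab: np.ndarray, persistence: int) -> np.ndarray:
    """Absorb runs shorter than ``persistence`` into their longer neighbours."""
    lab = lab.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        i = 0
        while i < len(lab):
            j = i
            while j < len(lab) and lab[j] == lab[i]:
                j += 1
            runs.append((i, j))
            i = j
        if len(runs) <= 1:
            break
        lens = [(b - a) for a, b in runs]
        k = int(np.argmin(lens))
        if lens[k] >= persistence:
            break
        a, b = runs[k]
        if k == 0:
            lab[a:b] = lab[b]
        elif k == len(runs) - 1:
            lab[a:b] = lab[a - 1]
        else:
            left_len = runs[k - 1][1] - runs[k - 1][0]
            right_len = runs[k + 1][1] - runs[k + 1][0]
            lab[a:b] = lab[a - 1] if left_len >= right_len else lab[b]
        changed = True
    return lab


def split_misjoins(
    matrix: ContactMatrix,
    scaffolds: ScaffoldSet,
    karyotype: KaryotypeResult,
    persistence: int = 3,
) -> pd.DataFrame:
    """Cut scaffolds where the per-bin best chromosome changes.

    Every bin of a scaffold is assigned the cluster it contacts most (own
    scaffold excluded); runs shorter than ``persistence`` bins are absorbed
    so fine-bin noise does not fragment scaffolds.  A change point in the
    terminal ``persistence`` bins produces no cut but flags the scaffold
    low-confidence.  Homogeneous scaffolds pass through intact.

    Returns one row per subscaffold: scaffold, start, end (bp, scaffold
    coordinates), cluster, confident.
    """
    B = _balanced_csr(matrix)
    bt = scaffolds.bin_table
    res = bt.resolution
    cluster_bins: dict[int, np.ndarray] = {}
    for name, c in karyotype.assignment.items():
        sl = scaffolds.bins_of(name)
        cluster_bins.setdefault(c, [])
        cluster_bins[c].append(np.arange(sl.start, sl.stop))
    cluster_bins = {c: np.concatenate(v) for c, v in cluster_bins.items()}

    rows = []
    for name in scaffolds.scaffolds["name"]:
        sl = scaffolds.bins_of(name)
        length = int(scaffolds.scaffolds.set_index("name").at[name, "length"])
        own = np.arange(sl.start, sl.stop)
        cb = {
            c: np.setdiff1d(v, own, assume_unique=True)
            for c, v in cluster_bins.items()
        }
        A, ks = _bin_cluster_affinity(B, sl, cb)
        if A.size == 0 or A.shape[1] == 0:
            rows.append((name, 0, length, karyotype.assignment.get(name, -1), True))
            continue
        lab = np.array([ks[i] for i in A.argmax(axis=1)])
        sm = _smooth_labels(lab, persistence)
        cuts = np.flatnonzero(sm[1:] != sm[:-1]) + 1
        confident = True
        # raw change points inside the terminal persistence zone: flag only
        raw_cuts = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        edgey = [
            c
            for c in raw_cuts
            if c < persistence or c > len(lab) - persistence
        ]
        if edgey and len(cuts) == 0:
            confident = False
        bounds = [0] + [int(c) * res for c in cuts] + [length]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_lab = sm[a // res] if a // res < len(sm) else sm[-1]
            rows.append((name, a, b, int(seg_lab), confident))
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "cluster", "confident"]
    )


def subscaffold_members(
    subscaffolds: pd.DataFrame,
    cluster: int,
    scaffolds: ScaffoldSet,
    min_bins: int = 5,
) -> dict[str, slice]:
    """Bin ranges of one chromosome's subscaffolds, for ordering.

    ``subscaffolds`` is the output of :func:`split_misjoins`; names are
    ``scaffold`` or ``scaffold:start-end`` for split pieces.  Pieces
    shorter than ``min_bins`` bins are left out: junction slivers from the
    one-bin split uncertainty carry mixed signal and misplace easily.
    """
    res = scaffolds.bin_table.resolution
    out: dict[str, slice] = {}
    for r in subscaffolds[subscaffolds["cluster"] == cluster].itertuples():
        sl = scaffolds.bins_of(r.scaffold)
        b0 = sl.start + r.start // res
        b1 = min(sl.start + -(-r.end // res), sl.stop)
        if b1 - b0 < min_bins:
            continue
        whole = r.start == 0 and b1 == sl.stop
        name = r.scaffold if whole else f"{r.scaffold}:{r.start}-{r.end}"
        out[name] = slice(b0, b1)
    return out


def order_orient(
    matrix: ContactMatrix,
    members: list[str] | dict[str, slice],
    scaffolds: ScaffoldSet | None = None,
) -> ChromosomeScaffold:
    """Order and orient the subscaffolds of one chromosome.

    Ordering: greedy chaining by strongest inter-subscaffold mean contact,
    then 2-opt refinement of the adjacency-weighted score
    ``sum log(contact(i, j)) / |rank_i - rank_j|``.  Orientation: each
    member is flipped so that the half with stronger contact faces its
    neighbour; confidence is the normalised margin between the chosen and
    flipped orientation (0 for a single member, whose orientation is
    arbitrary).  Ties break lexicographically on subscaffold name.  A
    whole-chromosome reversal is an equivalent solution.
    """
    if len(members) == 0:
        raise ValueError("need at least one member")
    if isinstance(members, dict):
        sls = dict(members)
    else:
        if scaffolds is None:
            raise ValueError("scaffolds required when members are names")
        sls = {m: scaffolds.bins_of(m) for m in members}
    members = sorted(sls)
    if len(members) == 1:
        return ChromosomeScaffold(members=[(members[0], "+", 0.0)])
    B = _balanced_csr(matrix)
    n = len(members)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = _pair_mean_contact(B, sls[members[i]], sls[members[j]])

    eps = max(C.max(), 1e-12) * 1e-6

    def score(order):
        s = 0.0
        for a in range(n):
            for b in range(a + 1, n):
                s += np.log(C[order[a], order[b]] + eps) / (b - a)
        return s

    # greedy chain: start from strongest pair, extend the ends
    i0, j0 = np.unravel_index(np.argmax(C), C.shape)
    if C[i0, j0] == 0:
        chain = list(range(n))
    else:
        chain = [int(i0), int(j0)]
        rest = set(range(n)) - set(chain)
        while rest:
            best = (-np.inf, None, None)
            for r in sorted(rest):
                for endpos, end in ((0, chain[0]), (1, chain[-1])):
                    v = C[r, end]
                    if v > best[0]:
                        best = (v, r, endpos)
            _, r, endpos = best
            if endpos == 0:
                chain.insert(0, r)
            else:
                chain.append(r)
            rest.discard(r)
    # refinement: segment reversals (2-opt) plus single-element relocation
    improved = True
    while improved:
        improved = False
        base = score(chain)
        for a in range(n - 1):
            for b in range(a + 1, n):
                cand = chain[:a] + chain[a : b + 1][::-1] + chain[b + 1 :]
                if score(cand) > base + 1e-12:
                    chain, improved = cand, True
                    break
            if improved:
                break
        if improved:
            continue
        for a in range(n):
            rest = chain[:a] + chain[a + 1 :]
            for b in range(n):
                if b == a:
                    continue
                cand = rest[:b] + [chain[a]] + rest[b:]
                if score(cand) > base + 1e-12:
                    chain, improved = cand, True
                    break
            if improved:
                break
    # canonical direction: lexicographically smaller end first
    if members[chain[-1]] < members[chain[0]]:
        chain = chain[::-1]

    # orientation by end-half contact asymmetry toward neighbours
    out = []
    for pos, idx in enumerate(chain):
        sl = sls[members[idx]]
        nb = sl.stop - sl.start
        half = max(nb // 2, 1)
        left_half = slice(sl.start, sl.start + half)
        right_half = slice(sl.stop - half, sl.stop)
        s_plus = s_minus = 0.0
        if pos > 0:
            prev_sl = sls[members[chain[pos - 1]]]
            s_plus += _pair_mean_contact(B, left_half, prev_sl)
            s_minus += _pair_mean_contact(B, right_half, prev_sl)
        if pos < n - 1:
            nxt_sl = sls[members[chain[pos + 1]]]
            s_plus += _pair_mean_contact(B, right_half, nxt_sl)
            s_minus += _pair_mean_contact(B, left_half, nxt_sl)
        tot = s_plus + s_minus
        conf = abs(s_plus - s_minus) / tot if tot > 0 else 0.0
        orient = "+" if s_plus >= s_minus else "-"
        out.append((members[idx], orient, float(conf)))
    return ChromosomeScaffold(members=out)


def assign_high_copy(
    matrix: ContactMatrix,
    clusters: dict[str, list[str]],
    scaffolds: ScaffoldSet,
    karyotype: KaryotypeResult,
) -> pd.DataFrame:
    """Assign each set-aside cluster to its most-contacted chromosome.

    Returns a table cluster, chromosome (cluster id), margin (best over
    runner-up mean contact; ties assigned deterministically with margin 1).
    """
    B = _balanced_csr(matrix)
    chrom_bins: dict[int, np.ndarray] = {}
    for name, c in karyotype.assignment.items():
        sl = scaffolds.bins_of(name)
        chrom_bins.setdefault(c, [])
        chrom_bins[c].append(np.arange(sl.start, sl.stop))
    chrom_bins = {c: np.concatenate(v) for c, v in chrom_bins.items()}
    rows = []
    for cname in sorted(clusters):
        bins = np.concatenate(
            [np.arange(scaffolds.bins_of(m).start, scaffolds.bins_of(m).stop)
             for m in clusters[cname]]
        )
        ks = sorted(chrom_bins)
        means = np.array(
            [
                float(B[bins][:, chrom_bins[c]].sum())
                / max(len(bins) * len(chrom_bins[c]), 1)
                for c in ks
            ]
        )
        order = np.argsort(means)[::-1]
        best = means[order[0]]
        second = means[order[1]] if len(ks) > 1 else 0.0
        margin = best / second if second > 0 else np.inf
        rows.append((cname, int(ks[order[0]]), float(margin)))
    return pd.DataFrame(rows, columns=["cluster", "chromosome", "margin"])


def copy_number(
    coverage: pd.DataFrame,
    bin_table: BinTable,
    placed: list[str],
    clusters: dict[str, list[str]],
) -> pd.DataFrame:
    """Relative copy number of each cluster versus placed chromosomes.

    The reference level is the median per-bin coverage over all placed
    scaffolds (normalised to 1); each cluster's copy number is the median
    coverage of its bins divided by the reference.  Invariant under global
    coverage rescaling.
    """
    cov = coverage.set_index(["chrom", "start"])["value"]

    def bins_median(names):
        vals = []
        for nm in names:
            sub = bin_table.bins.iloc[bin_table.chrom_slice(nm)]
            vals.append(cov.loc[list(zip(sub["chrom"], sub["start"]))].to_numpy())
        return float(np.median(np.concatenate(vals)))

    ref = bins_median(placed)
    if ref == 0:
        raise ValueError("zero reference median coverage")
    rows = [("placed_reference", 1.0)]
    for cname in sorted(clusters):
        rows.append((cname, bins_median(clusters[cname]) / ref))
    return pd.DataFrame(rows, columns=["cluster", "copy_number"])
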