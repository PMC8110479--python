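"""Gene-orientation blocks, convergent/divergent sites, and genomic tracks.

Genes in this genome sit in alternating unidirectional blocks; block
junctions come in two flavours, convergent (plus block followed by minus
block, transcription heads colliding) and divergent (the opposite, the
bidirectional locus of a domain).  This module run-length encodes gene
strands into blocks, measures how improbable the observed orientation
persistence is under an independent-strand null, calls junction sites
(optionally requiring stranded expression over the flanking blocks), and
builds/aggregates genomic tracks: GC content, feature-centred profiles,
telomere-distance profiles and window-level track correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeAssembly

__all__ = [
    "find_blocks",
    "block_size_histogram",
    "cumulative_gene_fraction",
    "orientation_change_stats",
    "call_sites",
    "gc_track",
    "feature_profile",
    "feature_profile_stranded",
    "telomere_profile",
    "track_correlations",
]


def find_blocks(genes: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of consecutive same-strand genes per chromosome.

    ``genes`` must be sorted by chromosome then start (ties broken by end
    then id for deterministic encoding).  Returns one row per block with
    chromosome, strand, size, span and the index of its first gene.
    Blocks partition the gene sequence; adjacent blocks have opposite
    strands.
    """
    genes = genes.sort_values(["chrom", "start", "end", "gene_id"]).reset_index(
        drop=True
    )
    rows = []
    bid = 0
    for chrom, g in genes.groupby("chrom", sort=False):
        strands = g["strand"].to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if len(g) == 0:
            continue
        run_start = 0
        for i in range(1, len(g) + 1):
            if i == len(g) or strands[i] != strands[run_start]:
                rows.append(
                    (
                        bid,
                        chrom,
                        strands[run_start],
                        i - run_start,
                        int(starts[run_start]),
                        int(ends[run_start:i].max()),
                        run_start,
                    )
                )
                bid += 1
                run_start = i
    return pd.DataFrame(
        rows,
        columns=["block_id", "chrom", "strand", "size", "start", "end", "first_gene"],
    )


def block_size_histogram(blocks: pd.DataFrame) -> pd.DataFrame:
    h = blocks["size"].value_counts().sort_index()
    return pd.DataFrame({"size": h.index, "n_blocks": h.to_numpy()})


def cumulative_gene_fraction(blocks: pd.DataFrame) -> pd.DataFrame:
    """Fraction of genes found in blocks of at least each size."""
    total = blocks["size"].sum()
    sizes = np.arange(1, blocks["size"].max() + 1)
    frac = [
        blocks.loc[blocks["size"] >= k, "size"].sum() / total for k in sizes
    ]
    return pd.DataFrame({"min_size": sizes, "gene_fraction": frac})


def orientation_change_stats(genes: pd.DataFrame, window: int = 10) -> dict:
    """Orientation-change counts in sliding gene windows versus a fair-coin null.

    In each sliding window of ``window`` consecutive genes the number of
    adjacent opposite-strand pairs (0..window-1) is tallied.  The null
    assumes independent equiprobable orientations, i.e.
    Binomial(window-1, 1/2).  Chromosomes with fewer than ``window`` genes
    are skipped.  Returns observed and null distributions and their total
    variation distance.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    counts = np.zeros(window, dtype=float)
    for _, g in genes.groupby("chrom", sort=False):
        s = (g.sort_values(["start", "end"])["strand"] == "+").to_numpy()
        if len(s) < window:
            continue
        changes = (s[1:] != s[:-1]).astype(int)
        kernel = np.convolve(changes, np.ones(window - 1, dtype=int), "valid")
        idx, c = np.unique(kernel, return_counts=True)
        counts[idx] += c
    total = counts.sum()
    if total == 0:
        raise ValueError("no chromosome has enough genes for the window")
    observed = counts / total
    null = stats.binom.pmf(np.arange(window), window - 1, 0.5)
    tv = 0.5 * np.abs(observed - null).sum()
    return {
        "observed": observed,
        "null": null,
        "tv_distance": float(tv),
        "n_windows": int(total),
    }


def _block_covered_bp(block, track: pd.DataFrame, min_expr: float) -> float:
    t = track[
        (track["chrom"] == block.chrom)
        & (track["end"] > block.start)
        & (track["start"] < block.end)
        & (track["value"] >= min_expr)
    ]
    if t.empty:
        return 0.0
    return float(
        (np.minimum(t["end"], block.end) - np.maximum(t["start"], block.start)).sum()
    )


def call_sites(
    blocks: pd.DataFrame,
    min_block: int = 1,
    expression: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    min_expr: float = 1.0,
    min_covered: float = 0.5,
) -> pd.DataFrame:
    """Convergent/divergent junction sites between qualifying gene blocks.

    A block qualifies when its size is at least ``min_block`` and, if
    stranded expression is supplied as ``(plus_track, minus_track)``, when
    its own strand carries at least ``min_covered`` of the expressed base
    pairs (coverage >= ``min_expr``) within its span and some own-strand
    signal exists.  The criterion is a strand *share* rather than an
    absolute span fraction because transcribed gene bodies cover only part
    of a block's span.  Consecutive qualifying same-strand blocks (same
    strand because intervening blocks were disqualified) are merged before
    junctions are called.  Site position is the midpoint of the
    inter-block interval; an overlap (left end beyond right start) is
    flagged and the midpoint of the overlap used.  ``orientation`` is the
    left-block strand, so convergent sites are '+', divergent '-'.
    """
    qual = blocks[blocks["size"] >= min_block].copy()
    if expression is not None:
        plus, minus = expression
        keep = []
        for b in qual.itertuples():
            own = _block_covered_bp(b, plus if b.strand == "+" else minus, min_expr)
            other = _block_covered_bp(b, minus if b.strand == "+" else plus, min_expr)
            keep.append(own > 0 and own >= min_covered * (own + other))
        qual = qual[np.array(keep, dtype=bool)] if len(keep) else qual
    rows = []
    for chrom, g in qual.groupby("chrom", sort=False):
        g = g.sort_values("start").reset_index(drop=True)
        # merge consecutive same-strand qualifying blocks
        merged = []
        for b in g.itertuples():
            if merged and merged[-1]["strand"] == b.strand:
                merged[-1]["end"] = max(merged[-1]["end"], b.end)
                merged[-1]["right_id"] = b.block_id
            else:
                merged.append(
                    {
                        "strand": b.strand,
                        "start": b.start,
                        "end": b.end,
                        "left_id": b.block_id,
                        "right_id": b.block_id,
                    }
                )
        for left, right in zip(merged[:-1], merged[1:]):
            kind = "convergent" if left["strand"] == "+" else "divergent"
            pos = (left["end"] + right["start"]) // 2
            rows.append(
                (
                    chrom,
                    int(pos),
                    kind,
                    left["right_id"],
                    right["left_id"],
                    bool(left["end"] > right["start"]),
                    left["strand"],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "position",
            "kind",
            "left_block",
            "right_block",
            "overlap",
            "orientation",
        ],
    )


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def gc_track(
    assembly: GenomeAssembly, window: int = 10_000, step: int | None = None
) -> pd.DataFrame:
    """Windowed GC fraction among non-N bases; >50% N windows are undefined."""
    if assembly.sequence is None:
        raise ValueError("assembly has no sequence")
    step = step or window
    rows = []
    for chrom, L in assembly.chromosomes:
        seq = np.frombuffer(assembly.sequence[chrom].encode(), dtype="S1")
        is_gc = (seq == b"G") | (seq == b"C")
        is_n = seq == b"N"
        cg = np.concatenate(([0], np.cumsum(is_gc)))
        cn = np.concatenate(([0], np.cumsum(is_n)))
        for start in range(0, max(L - window, 0) + 1, step):
            end = min(start + window, L)
            n_n = cn[end] - cn[start]
            denom = (end - start) - n_n
            if n_n > 0.5 * (end - start) or denom == 0:
                val = np.nan
            else:
                val = (cg[end] - cg[start]) / denom
            rows.append((chrom, start, end, val))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


class _StepFun:
    """Window-mean sampler over a sorted interval track of one chromosome."""

    def __init__(self, track: pd.DataFrame, fill: float):
        t = track.sort_values("start")
        self.starts = t["start"].to_numpy(float)
        self.ends = t["end"].to_numpy(float)
        self.values = t["value"].to_numpy(float)
        self.fill = fill
        # integral of value over [0, x) at interval edges
        seg = self.values * (self.ends - self.starts)
        seg[~np.isfinite(seg)] = 0.0
        self.cum = np.concatenate(([0.0], np.cumsum(seg)))

    def _integral(self, x: np.ndarray) -> np.ndarray:
        k = np.searchsorted(self.starts, x, side="right") - 1
        kk = np.clip(k, 0, None)
        out = np.where(k >= 0, self.cum[kk], 0.0)
        inside = (k >= 0) & (x > self.starts[kk])
        frac = np.minimum(x, self.ends[kk]) - self.starts[kk]
        vals = np.where(np.isfinite(self.values[kk]), self.values[kk], 0.0)
        return out + np.where(inside, frac * vals, 0.0)

    def window_mean(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        if len(self.starts) == 0:
            return np.full(len(lo), self.fill)
        tot = self._integral(hi) - self._integral(lo)
        if np.isnan(self.fill):
            # covered width for normalisation; uncovered -> NaN
            covw = _covered_width(self.starts, self.ends, lo, hi)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(covw > 0, tot / covw, np.nan)
        return tot / np.maximum(hi - lo, 1)  # uncovered ground counts as zero


def _covered_width(starts, ends, lo, hi):
    seg = ends - starts
    cum = np.concatenate(([0.0], np.cumsum(seg)))

    def cov(x):
        k = np.searchsorted(starts, x, side="right") - 1
        kk = np.clip(k, 0, None)
        inside = (k >= 0) & (x > starts[kk])
        out = np.where(k >= 0, cum[kk], 0.0)
        return out + np.where(inside, np.minimum(x, ends[kk]) - starts[kk], 0.0)

    return cov(hi) - cov(lo)


def _profile_one_strand(
    track: pd.DataFrame,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank: int,
    window: int,
    step: int,
    fill: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    offsets = np.arange(-flank, flank - window + 1, step)
    acc = np.zeros(len(offsets))
    cnt = np.zeros(len(offsets))
    dropped = 0
    pos_col = "position" if "position" in sites.columns else "start"
    for chrom, g in sites.groupby("chrom", sort=False):
        t = track[track["chrom"] == chrom]
        sf = _StepFun(t, fill)
        L = chrom_lengths[chrom]
        for r in g.itertuples():
            pos = getattr(r, pos_col)
            orient = getattr(r, "orientation", "+")
            if pos - flank < 0 or pos + flank > L:
                dropped += 1
                continue
            offs = offsets if orient != "-" else (-offsets - window)
            vals = sf.window_mean(pos + offs, pos + offs + window)
            good = np.isfinite(vals)
            acc[good] += vals[good]
            cnt[good] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return offsets, mean, dropped


def feature_profile(
    track: pd.DataFrame,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank: int = 30_000,
    window: int = 100,
    step: int = 100,
    fill: float = np.nan,
) -> pd.DataFrame:
    """Per-offset mean of a track across a set of anchor sites.

    Sites with an ``orientation`` column are aligned (minus-oriented sites
    are mirrored).  Sites whose flank exceeds the chromosome are dropped
    and counted in the ``n_dropped`` attribute of the result.  ``fill``
    controls uncovered ground: NaN excludes it from the mean (sparse
    defined tracks like GC), 0.0 treats it as zero signal (coverage).
    """
    offsets, mean, dropped = _profile_one_strand(
        track, sites, chrom_lengths, flank, window, step, fill
    )
    if not np.isfinite(mean).any() and len(sites):
        raise ValueError("all sites dropped or undefined")
    df = pd.DataFrame({"offset": offsets, "mean": mean})
    df.attrs["n_dropped"] = dropped
    return df


def feature_profile_stranded(
    plus_track: pd.DataFrame,
    minus_track: pd.DataFrame,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank: int = 30_000,
    window: int = 100,
    step: int = 100,
) -> pd.DataFrame:
    """Orientation-aligned stranded profiles around anchor sites.

    For minus-oriented sites the offsets are mirrored and the two strands
    swapped, so the returned ``top``/``bottom`` columns are relative to the
    site orientation (top = sense of the left block).  Uncovered ground
    counts as zero coverage.
    """
    plus_sites = sites[sites.get("orientation", pd.Series("+", index=sites.index)) != "-"]
    minus_sites = sites[sites.get("orientation", pd.Series("+", index=sites.index)) == "-"]
    offs = None
    acc = {"top": None, "bottom": None}
    for subset, top_track, bottom_track in (
        (plus_sites, plus_track, minus_track),
        (minus_sites, minus_track, plus_track),
    ):
        if subset.empty:
            continue
        for key, tr in (("top", top_track), ("bottom", bottom_track)):
            o, m, _ = _profile_one_strand(
                tr, subset, chrom_lengths, flank, window, step, fill=0.0
            )
            m = np.nan_to_num(m) * len(subset)
            offs = o
            acc[key] = m if acc[key] is None else acc[key] + m
    n = len(plus_sites) + len(minus_sites)
    if n == 0 or offs is None:
        raise ValueError("no usable sites")
    return pd.DataFrame(
        {"offset": offs, "top": acc["top"] / n, "bottom": acc["bottom"] / n}
    )


def telomere_profile(
    track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    span: int = 2_500_000,
    min_chrom: int = 5_000_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Track averaged by distance to the nearest chromosome end.

    Both ends of every chromosome of length >= ``min_chrom`` contribute
    (the right end mirrored).  ``step`` defaults to the track's modal
    window width.
    """
    qual = [c for c, L in chrom_lengths.items() if L >= min_chrom]
    if not qual:
        raise ValueError("no chromosome satisfies min_chrom")
    if step is None:
        widths = (track["end"] - track["start"]).to_numpy()
        step = int(pd.Series(widths).mode().iloc[0])
    offs = np.arange(0, span, step, dtype=float)
    acc = np.zeros(len(offs))
    cnt = np.zeros(len(offs))
    for chrom in qual:
        t = track[track["chrom"] == chrom]
        if t.empty:
            continue
        sf = _StepFun(t, np.nan)
        L = chrom_lengths[chrom]
        for lo in (offs, L - offs - step):
            vals = sf.window_mean(lo, lo + step)
            good = np.isfinite(vals)
            acc[good] += vals[good]
            cnt[good] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return pd.DataFrame({"distance_to_end": offs, "mean": mean})


def track_correlations(tracks: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, int]:
    """Pairwise Pearson correlation of tracks sharing one bin grid."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    frames = []
    for name, t in tracks.items():
        f = t.set_index(["chrom", "start"])["value"].rename(name)
        frames.append(f)
    joined = pd.concat(frames, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 common defined bins")
    return joined.corr(method="pearson"), len(joined)
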