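"""Distance-decay expected model and feature-centred aggregate contact maps.

The expected model is the per-separation mean balanced contact, computed
per chromosome (a genome-pooled variant is available).  Pileups stack
observed/expected submatrices centred on anchors (boundaries, convergent
or divergent sites); obs/exp is averaged linearly across anchors per cell
and reported as log10 of that mean, which keeps sparse-count cells
unbiased.  Condition contrasts are elementwise log2 ratios of the
linear-scale pileups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import ContactMatrix

__all__ = [
    "ExpectedModel",
    "Pileup",
    "expected_by_distance",
    "obs_over_exp",
    "pileup",
    "compare_conditions",
]


@dataclass
class ExpectedModel:
    """Mean balanced contact per bin separation, per chromosome.

    ``raw`` holds the unsmoothed per-diagonal means, ``smooth`` the same
    after a 3-bin running mean in log space.  ``pooled`` is the
    genome-wide variant (cell-count weighted across chromosomes).
    """

    resolution: int
    raw: dict[str, np.ndarray]
    smooth: dict[str, np.ndarray]
    pooled: np.ndarray

    def expected(self, chrom: str | None, d: np.ndarray) -> np.ndarray:
        arr = self.pooled if chrom is None else self.smooth[chrom]
        d = np.clip(d, 0, len(arr) - 1)
        return arr[d]


def _log_runmean3(v: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        lg = np.log(v)
    out = np.full_like(lg, np.nan)
    for i in range(len(lg)):
        w = lg[max(0, i - 1) : i + 2]
        w = w[np.isfinite(w)]
        if len(w):
            out[i] = np.exp(w.mean())
    return out


def expected_by_distance(matrix: ContactMatrix) -> ExpectedModel:
    """Per-chromosome per-diagonal mean of balanced entries, log-smoothed."""
    bt = matrix.bin_table
    raw, smooth = {}, {}
    max_n = max(bt.n_bins_chrom(c) for c in bt.chrom_lengths)
    pooled_sum = np.zeros(max_n)
    pooled_cnt = np.zeros(max_n)
    for chrom in bt.chrom_lengths:
        M = matrix.dense(chrom, balanced=True)
        n = M.shape[0]
        e = np.full(n, np.nan)
        for d in range(n):
            diag = np.diagonal(M, d)
            good = np.isfinite(diag)
            if good.any():
                e[d] = diag[good].mean()
                pooled_sum[d] += diag[good].sum()
                pooled_cnt[d] += good.sum()
        raw[chrom] = e
        smooth[chrom] = _log_runmean3(e)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(pooled_cnt > 0, pooled_sum / pooled_cnt, np.nan)
    return ExpectedModel(
        resolution=bt.resolution, raw=raw, smooth=smooth, pooled=_log_runmean3(pooled)
    )


def obs_over_exp(
    matrix: ContactMatrix, chrom: str, expected: ExpectedModel
) -> np.ndarray:
    """Dense balanced observed/expected matrix of one chromosome."""
    M = matrix.dense(chrom, balanced=True)
    n = M.shape[0]
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    E = expected.expected(chrom, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        return M / E


@dataclass
class Pileup:
    """Average obs/exp submatrix around a set of anchors.

    ``linear`` is the per-cell mean of obs/exp across anchors;
    ``log10`` is log10 of that mean (floored); cells supported by fewer
    than ``min_sites`` anchors are NaN.
    """

    linear: np.ndarray
    log10: np.ndarray
    n_cells: np.ndarray
    flank: int
    resolution: int
    n_sites: int
    n_dropped: int


def pileup(
    matrix: ContactMatrix,
    sites: pd.DataFrame,
    expected: ExpectedModel,
    flank: int = 500_000,
    resolution: int = 10_000,
    floor: float = 1e-4,
    min_sites: int = 10,
) -> Pileup:
    """Stack obs/exp submatrices centred on anchor sites.

    Sites carry ``chrom`` and ``position`` (or ``start``); sites with an
    ``orientation`` column are aligned to a canonical left-block-plus
    orientation by mirroring minus-oriented sites.  Sites whose window
    leaves the chromosome are dropped and counted.
    """
    if matrix.bin_table.resolution != resolution:
        raise ValueError("matrix resolution does not match requested resolution")
    w = flank // resolution
    size = 2 * w + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    pos_col = "position" if "position" in sites.columns else "start"
    n_used = n_dropped = 0
    for chrom, g in sites.groupby("chrom", sort=False):
        if chrom not in matrix.bin_table.chrom_lengths:
            n_dropped += len(g)
            continue
        OE = obs_over_exp(matrix, chrom, expected)
        n = OE.shape[0]
        for r in g.itertuples():
            b = int(getattr(r, pos_col)) // resolution
            if b - w < 0 or b + w >= n:
                n_dropped += 1
                continue
            sub = OE[b - w : b + w + 1, b - w : b + w + 1]
            if getattr(r, "orientation", "+") == "-":
                sub = sub[::-1, ::-1]
            good = np.isfinite(sub)
            acc[good] += sub[good]
            cnt += good
            n_used += 1
    if n_used == 0:
        raise ValueError("no usable sites for pileup")
    with np.errstate(invalid="ignore", divide="ignore"):
        linear = np.where(cnt > 0, acc / cnt, np.nan)
    linear_masked = np.where(cnt >= min_sites, linear, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        lg = np.log10(np.maximum(linear_masked, floor))
    lg[~np.isfinite(lg)] = np.nan
    return Pileup(
        linear=linear_masked,
        log10=lg,
        n_cells=cnt,
        flank=flank,
        resolution=resolution,
        n_sites=n_used,
        n_dropped=n_dropped,
    )


def compare_conditions(a: Pileup, b: Pileup, floor: float = 1e-4) -> np.ndarray:
    """Elementwise log2 of the condition ratio from linear-scale pileups."""
    if (
        a.flank != b.flank
        or a.resolution != b.resolution
        or a.linear.shape != b.linear.shape
    ):
        raise ValueError("pileup geometries do not match")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(np.maximum(a.linear, floor) / np.maximum(b.linear, floor))
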