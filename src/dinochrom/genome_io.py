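"""Genome/annotation/matrix data model and I/O.

Everything downstream consumes the containers defined here: a
:class:`GenomeAssembly` (chromosome names, lengths, optional sequence), a
:class:`BinTable` (fixed-resolution genome tiling), a :class:`ContactMatrix`
(symmetric binned Hi-C counts plus multiplicative balancing weights), pairs
tables and genomic value tracks.

Internal coordinates are 0-based half-open throughout.  Formats that use
1-based coordinates (GFF3, pairs) are converted at the I/O boundary and
restored on write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeAssembly",
    "BinTable",
    "ContactMatrix",
    "FormatError",
    "bin_genome",
    "pairs_to_matrix",
    "ice_balance",
    "n_gap_scan",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_pairs",
    "write_pairs",
    "read_cool",
    "write_cool",
    "read_triplet",
    "write_triplet",
    "read_file",
    "write_file",
]

PAIRS_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


class FormatError(ValueError):
    """Malformed record in an on-disk file; carries the offending line number."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenomeAssembly:
    """Ordered set of chromosomes with lengths and optional sequence.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; names unique, lengths positive.
    sequence
        Optional mapping name -> nucleotide string over ``{A,C,G,T,N}``
        whose length must equal the declared chromosome length.
    """

    chromosomes: list[tuple[str, int]]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.sequence is not None:
            for name, length in self.chromosomes:
                if name in self.sequence and len(self.sequence[name]) != length:
                    raise ValueError(
                        f"sequence length of {name!r} does not match declared length"
                    )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass
class BinTable:
    """Fixed-resolution tiling of a genome.

    Bins tile each chromosome ``[0, length)`` left to right; all bins have
    width ``resolution`` except possibly the last per chromosome.  Bin ids
    are global, ordered by assembly chromosome order.
    """

    resolution: int
    bins: pd.DataFrame  # columns chrom, start, end
    chrom_lengths: dict[str, int]
    chrom_offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_offsets:
            offs, n = {}, 0
            for chrom, length in self.chrom_lengths.items():
                offs[chrom] = n
                n += -(-length // self.resolution)
            self.chrom_offsets = offs

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def n_bins_chrom(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.resolution)

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.n_bins_chrom(chrom))

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global bin id of a 0-based position."""
        return self.chrom_offsets[chrom] + pos // self.resolution


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with lazy balancing weights.

    ``counts`` stores raw symmetric counts (CSR); ``weights`` holds one
    multiplicative factor per bin with NaN marking masked bins.  The
    balanced value of a pixel is ``counts[i, j] * w[i] * w[j]``; raw and
    balanced views coexist on one container.
    """

    bin_table: BinTable
    counts: sp.csr_matrix
    weights: np.ndarray | None = None
    balanced: bool = False
    converged: bool | None = None

    def __post_init__(self) -> None:
        n = self.bin_table.n_bins
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin table")

    def check_symmetric(self, tol: float = 0.0) -> bool:
        d = abs(self.counts - self.counts.T)
        return d.max() <= tol if d.nnz else True

    def dense(self, chrom: str | None = None, balanced: bool = True) -> np.ndarray:
        """Dense (sub)matrix; balanced view has NaN at masked bins."""
        sl = self.bin_table.chrom_slice(chrom) if chrom else slice(None)
        m = np.asarray(self.counts[sl, sl].todense(), dtype=float)
        if balanced:
            if self.weights is None:
                raise ValueError("matrix is not balanced; no weights stored")
            w = self.weights[sl]
            m = m * w[:, None] * w[None, :]
        return m

    def marginals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


# ---------------------------------------------------------------------------
# binning and pairs aggregation
# ---------------------------------------------------------------------------


def bin_genome(assembly: GenomeAssembly, resolution: int) -> BinTable:
    """Tile every chromosome into ``resolution``-sized bins.

    The number of bins per chromosome is ``ceil(length / resolution)``; the
    last bin per chromosome is clipped to the chromosome end.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    chroms, starts, ends = [], [], []
    for name, length in assembly.chromosomes:
        edges = np.arange(0, length + resolution, resolution)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        chroms.extend([name] * (len(edges) - 1))
        starts.extend(edges[:-1])
        ends.extend(edges[1:])
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return BinTable(resolution=resolution, bins=df, chrom_lengths=assembly.lengths)


def pairs_to_matrix(
    pairs: pd.DataFrame, bin_table: BinTable
) -> tuple[ContactMatrix, int]:
    """Aggregate a pairs table into a symmetric binned contact matrix.

    Positions are 1-based (pairs convention).  Records whose position falls
    outside the declared chromosome length, or that reference an unknown
    chromosome, are discarded and tallied.  The matrix mass (upper triangle
    plus diagonal) equals the number of retained pairs.

    Returns
    -------
    (matrix, n_discarded)
    """
    res = bin_table.resolution
    n = bin_table.n_bins
    lengths = bin_table.chrom_lengths
    known = pairs["chrom1"].isin(lengths) & pairs["chrom2"].isin(lengths)
    p = pairs.loc[known]
    l1 = p["chrom1"].map(lengths).to_numpy()
    l2 = p["chrom2"].map(lengths).to_numpy()
    pos1 = p["pos1"].to_numpy()
    pos2 = p["pos2"].to_numpy()
    ok = (pos1 >= 1) & (pos1 <= l1) & (pos2 >= 1) & (pos2 <= l2)
    n_discarded = len(pairs) - int(ok.sum())
    p = p.loc[ok]
    off1 = p["chrom1"].map(bin_table.chrom_offsets).to_numpy()
    off2 = p["chrom2"].map(bin_table.chrom_offsets).to_numpy()
    b1 = off1 + (p["pos1"].to_numpy() - 1) // res
    b2 = off2 + (p["pos2"].to_numpy() - 1) // res
    i = np.minimum(b1, b2)
    j = np.maximum(b1, b2)
    upper = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    diag = sp.diags(upper.diagonal())
    counts = upper + upper.T - diag
    return ContactMatrix(bin_table=bin_table, counts=counts), n_discarded


# ---------------------------------------------------------------------------
# iterative correction (ICE)
# ---------------------------------------------------------------------------


def ice_balance(
    matrix: ContactMatrix,
    max_iter: int = 500,
    tol: float = 1e-5,
    mad_filter: float = 5.0,
) -> ContactMatrix:
    """Balance a symmetric matrix by iterative correction.

    Bins whose raw marginal is zero, or falls more than ``mad_filter``
    median absolute deviations *below* the median marginal of nonzero
    bins, are masked (weight NaN) and ignored.  The filter is one-sided:
    high-coverage bins carry genuine signal (telomeric compaction,
    high-copy sequence) and are balanced, not dropped.  Weights are scaled so the mean
    balanced marginal over unmasked bins is 1.  Convergence is declared
    when the coefficient of variation of unmasked marginals drops below
    ``tol``; failure to converge sets ``converged=False`` rather than
    raising.
    """
    scale = abs(matrix.counts).max() if matrix.counts.nnz else 1.0
    if not matrix.check_symmetric(tol=1e-9 * max(scale, 1.0)):
        raise ValueError("ice_balance requires a symmetric matrix")
    C = matrix.counts.astype(float)
    marg = np.asarray(C.sum(axis=1)).ravel()
    masked = marg == 0
    nz = marg[~masked]
    if nz.size:
        med = np.median(nz)
        mad = np.median(np.abs(nz - med))
        if mad > 0:
            masked |= marg < med - mad_filter * mad
    w = np.ones(C.shape[0])
    w[masked] = 0.0
    converged = False
    for _ in range(max_iter):
        m = w * (C @ w)
        live = m[~masked]
        if live.size == 0 or live.mean() == 0:
            break
        cv = live.std() / live.mean()
        if cv < tol:
            converged = True
            break
        s = m / live.mean()
        s[masked | (s == 0)] = 1.0
        w = w / s
    # normalise: mean balanced marginal over unmasked bins == 1
    m = w * (C @ w)
    mu = m[~masked].mean() if (~masked).any() else 0.0
    if mu > 0:
        w = w / np.sqrt(mu)
    weights = w.copy()
    weights[masked] = np.nan
    return ContactMatrix(
        bin_table=matrix.bin_table,
        counts=matrix.counts,
        weights=weights,
        balanced=True,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# sequence gap scan
# ---------------------------------------------------------------------------


def n_gap_scan(sequence: str, run_min: int = 24) -> bool:
    """True iff ``sequence`` contains no run of >= ``run_min`` consecutive Ns."""
    return re.search("N{%d,}" % run_min, sequence.upper()) is None


# ---------------------------------------------------------------------------
# formats
# ---------------------------------------------------------------------------


def read_fasta(path) -> GenomeAssembly:
    from Bio import SeqIO

    chroms, seqs = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        chroms.append((rec.id, len(s)))
        seqs[rec.id] = s
    if not chroms:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeAssembly(chromosomes=chroms, sequence=seqs)


def write_fasta(assembly: GenomeAssembly, path, width: int = 80) -> None:
    if assembly.sequence is None:
        raise ValueError("assembly has no sequence to write")
    with open(path, "w") as fh:
        for name, _ in assembly.chromosomes:
            fh.write(f">{name}\n")
            s = assembly.sequence[name]
            for k in range(0, len(s), width):
                fh.write(s[k : k + width] + "\n")


def read_gff3_genes(path, feature: str = "gene") -> pd.DataFrame:
    """Read gene records from GFF3 into a sorted 0-based half-open table.

    Returns columns ``gene_id, chrom, start, end, strand``.  GFF3 is 1-based
    inclusive; ``start`` is converted to 0-based on read.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            if f[2] != feature:
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: bad coordinates") from e
            if f[6] not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: strand must be + or -")
            m = re.search(r"ID=([^;]+)", f[8])
            gid = m.group(1) if m else f"{feature}_{ln}"
            rows.append((gid, f[0], start, end, f[6]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start", "end", "gene_id"]).reset_index(drop=True)


def write_gff3_genes(genes: pd.DataFrame, path, source: str = "dinochrom") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            fh.write(
                f"{r.chrom}\t{source}\tgene\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.gene_id}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open): chrom, start, end [, name, score, strand]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED columns")
            row = {"chrom": f[0], "start": int(f[1]), "end": int(f[2])}
            if len(f) > 3:
                row["name"] = f[3]
            if len(f) > 4:
                row["score"] = float(f[4]) if f[4] != "." else np.nan
            if len(f) > 5:
                row["strand"] = f[5]
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + [
        c for c in ("name", "score", "strand") if c in df.columns
    ]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph track; overlapping intervals within a chromosome are rejected."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    for chrom, g in df.groupby("chrom", sort=False):
        g = g.sort_values("start")
        bad = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            line = g.index[k + 1] + 1
            raise FormatError(f"{path}:{line}: overlapping intervals on {chrom}")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bedgraph(track: pd.DataFrame, path) -> None:
    t = track.dropna(subset=["value"])
    t[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_pairs(path) -> pd.DataFrame:
    """Read a 4DN-style pairs file (1-based positions)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise FormatError(f"{path}:{ln}: expected >= 7 pairs columns")
            rows.append((f[1], int(f[2]), f[5], f[3], int(f[4]), f[6]))
    return pd.DataFrame(rows, columns=PAIRS_COLUMNS)


def write_pairs(
    pairs: pd.DataFrame, path, chrom_lengths: dict[str, int] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        if chrom_lengths:
            for name, length in chrom_lengths.items():
                fh.write(f"#chromsize: {name} {length}\n")
        for k, r in enumerate(pairs.itertuples(index=False)):
            fh.write(
                f"p{k}\t{r.chrom1}\t{r.pos1}\t{r.chrom2}\t{r.pos2}\t"
                f"{r.strand1}\t{r.strand2}\n"
            )


def write_cool(matrix: ContactMatrix, path) -> None:
    """Write a single-resolution cooler-schema HDF5 container.

    Layout follows the cooler schema (chroms/bins/pixels/indexes groups with
    upper-triangle pixels) so files interoperate with cooler-aware tools.
    """
    import h5py

    bt = matrix.bin_table
    coo = sp.triu(matrix.counts).tocoo()
    order = np.lexsort((coo.col, coo.row))
    b1, b2, v = coo.row[order], coo.col[order], coo.data[order]
    names = list(bt.chrom_lengths)
    chrom_idx = {c: k for k, c in enumerate(names)}
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::Cooler"
        h5.attrs["format-version"] = 3
        h5.attrs["bin-size"] = bt.resolution
        h5.attrs["bin-type"] = "fixed"
        h5.attrs["nbins"] = bt.n_bins
        h5.attrs["nchroms"] = len(names)
        h5.attrs["nnz"] = len(v)
        g = h5.create_group("chroms")
        g.create_dataset("name", data=np.array(names, dtype="S"))
        g.create_dataset(
            "length", data=np.array([bt.chrom_lengths[c] for c in names], dtype="i8")
        )
        g = h5.create_group("bins")
        g.create_dataset(
            "chrom", data=bt.bins["chrom"].map(chrom_idx).to_numpy(dtype="i4")
        )
        g.create_dataset("start", data=bt.bins["start"].to_numpy(dtype="i8"))
        g.create_dataset("end", data=bt.bins["end"].to_numpy(dtype="i8"))
        if matrix.weights is not None:
            g.create_dataset("weight", data=matrix.weights)
        g = h5.create_group("pixels")
        g.create_dataset("bin1_id", data=b1.astype("i8"))
        g.create_dataset("bin2_id", data=b2.astype("i8"))
        g.create_dataset("count", data=v)
        g = h5.create_group("indexes")
        g.create_dataset(
            "bin1_offset",
            data=np.searchsorted(b1, np.arange(bt.n_bins + 1)).astype("i8"),
        )
        offs = [bt.chrom_offsets[c] for c in names] + [bt.n_bins]
        g.create_dataset("chrom_offset", data=np.array(offs, dtype="i8"))


def read_cool(path) -> ContactMatrix:
    import h5py

    with h5py.File(path, "r") as h5:
        names = [n.decode() for n in h5["chroms/name"][:]]
        lengths = dict(zip(names, h5["chroms/length"][:].tolist()))
        res = int(h5.attrs["bin-size"])
        chrom = [names[i] for i in h5["bins/chrom"][:]]
        bins = pd.DataFrame(
            {"chrom": chrom, "start": h5["bins/start"][:], "end": h5["bins/end"][:]}
        )
        bt = BinTable(resolution=res, bins=bins, chrom_lengths=lengths)
        b1 = h5["pixels/bin1_id"][:]
        b2 = h5["pixels/bin2_id"][:]
        v = h5["pixels/count"][:].astype(float)
        n = bt.n_bins
        upper = sp.coo_matrix((v, (b1, b2)), shape=(n, n)).tocsr()
        counts = upper + upper.T - sp.diags(upper.diagonal())
        weights = h5["bins/weight"][:] if "weight" in h5["bins"] else None
    return ContactMatrix(
        bin_table=bt,
        counts=counts,
        weights=weights,
        balanced=weights is not None,
    )


def write_triplet(matrix: ContactMatrix, path) -> None:
    """Plain-text triplet dialect: bin1_id<TAB>bin2_id<TAB>count, upper triangle,
    with a ``.bins.tsv`` sidecar carrying the bin table and weights."""
    coo = sp.triu(matrix.counts).tocoo()
    order = np.lexsort((coo.col, coo.row))
    pd.DataFrame(
        {"bin1_id": coo.row[order], "bin2_id": coo.col[order], "count": coo.data[order]}
    ).to_csv(path, sep="\t", index=False)
    side = matrix.bin_table.bins.copy()
    if matrix.weights is not None:
        side["weight"] = matrix.weights
    side.insert(0, "resolution", matrix.bin_table.resolution)
    side.to_csv(str(path) + ".bins.tsv", sep="\t", index=False)


def read_triplet(path) -> ContactMatrix:
    side = pd.read_csv(str(path) + ".bins.tsv", sep="\t")
    res = int(side["resolution"].iloc[0])
    lengths = side.groupby("chrom", sort=False)["end"].max().to_dict()
    bt = BinTable(
        resolution=res,
        bins=side[["chrom", "start", "end"]].copy(),
        chrom_lengths={c: int(v) for c, v in lengths.items()},
    )
    trip = pd.read_csv(path, sep="\t")
    n = bt.n_bins
    upper = sp.coo_matrix(
        (trip["count"].astype(float), (trip["bin1_id"], trip["bin2_id"])),
        shape=(n, n),
    ).tocsr()
    counts = upper + upper.T - sp.diags(upper.diagonal())
    weights = side["weight"].to_numpy() if "weight" in side.columns else None
    return ContactMatrix(
        bin_table=bt, counts=counts, weights=weights, balanced=weights is not None
    )


_READERS = {
    "fasta": read_fasta,
    "gff3": read_gff3_genes,
    "bed": read_bed,
    "bedgraph": read_bedgraph,
    "pairs": read_pairs,
    "cool": read_cool,
    "triplet": read_triplet,
}
_WRITERS = {
    "fasta": write_fasta,
    "gff3": write_gff3_genes,
    "bed": write_bed,
    "bedgraph": write_bedgraph,
    "pairs": write_pairs,
    "cool": write_cool,
    "triplet": write_triplet,
}


def read_file(path, kind: str):
    """Dispatching reader over the supported on-disk formats."""
    if kind not in _READERS:
        raise ValueError(f"unknown format kind {kind!r}")
    return _READERS[kind](path)


def write_file(obj, path, kind: str, **kw) -> None:
    if kind not in _WRITERS:
        raise ValueError(f"unknown format kind {kind!r}")
    _WRITERS[kind](obj, path, **kw)
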