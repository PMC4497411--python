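"""ChIP-seq read counting over flanked miRNA loci, fixed-dispersion NB
fold changes between subsets, and regression-through-the-origin linkage of
mark changes to miRNA expression changes.

Coordinates are 0-based half-open (BED convention) throughout; GFF input
(1-based inclusive) is converted at the reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MarkCountMatrix",
    "LinkResult",
    "read_loci_bed",
    "read_loci_gff",
    "read_reads_bed",
    "mirna_intervals",
    "count_reads",
    "nbglm_logfc",
    "origin_regression",
    "top_de_selection",
    "link_marks_to_expression",
    "coverage_bedgraph",
]


@dataclass
class MarkCountMatrix:
    """locus x track read counts; track labels are '<subset>|<mark>'."""

    counts: pd.DataFrame
    lib_sizes: pd.Series
    track_meta: pd.DataFrame  # index = track label, columns subset, mark


@dataclass
class LinkResult:
    slope: float
    se: float
    p: float
    n: int
    x: np.ndarray
    y: np.ndarray


def read_loci_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "symbol", "score", "strand"])
    return df[["symbol", "chrom", "start", "end", "strand"]].assign(partner="")


def read_loci_gff(path) -> pd.DataFrame:
    """miRBase-style GFF3: 1-based inclusive converted to 0-based half-open;
    the Name attribute is the symbol."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name", attrs.get("ID", "."))
            rows.append((name, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"]).assign(partner="")


def read_reads_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return df


def mirna_intervals(loci: pd.DataFrame, flank: int = 3000) -> pd.DataFrame:
    """Flanked counting intervals, one per merged locus.

    3p/5p partner records are merged to a single interval covering both,
    keyed by both symbols joined with '/'.  The interval is
    [start - flank, end + flank) clipped at 0.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    merged: dict[str, list] = {}
    seen = set()
    for _, rec in loci.iterrows():
        if rec["symbol"] in seen:
            continue
        partner = rec.get("partner", "") or ""
        if partner:
            prow = loci[loci["symbol"] == partner]
            symbols = sorted([rec["symbol"], partner])
            key = "/".join(symbols)
            start = min(rec["start"], *prow["start"]) if len(prow) else rec["start"]
            end = max(rec["end"], *prow["end"]) if len(prow) else rec["end"]
            seen.update(symbols)
        else:
            key = rec["symbol"]
            start, end = rec["start"], rec["end"]
            seen.add(key)
        merged[key] = [rec["chrom"], max(0, int(start) - flank), int(end) + flank,
                       sorted({rec["symbol"], partner} - {""})]
    rows = [(k, v[0], v[1], v[2], v[3]) for k, v in merged.items()]
    return pd.DataFrame(rows, columns=["locus", "chrom", "start", "end", "members"]).set_index("locus")


def _count_track(intervals: pd.DataFrame, reads: pd.DataFrame) -> pd.Series:
    """Overlap counts (>= 1 bp, strand-ignorant) per interval.

    For each chromosome: overlaps = (#read starts < interval end) -
    (#read ends <= interval start).
    """
    counts = pd.Series(0, index=intervals.index, dtype=np.int64)
    loci_chroms = set(intervals["chrom"])
    skipped = set(reads["chrom"]) - loci_chroms
    if skipped:
        logger.info("ignoring reads on chromosomes without loci: %s", sorted(skipped))
    for chrom, ivs in intervals.groupby("chrom"):
        sub = reads[reads["chrom"] == chrom]
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        began = np.searchsorted(starts, ivs["end"].to_numpy(), side="left")
        ended = np.searchsorted(ends, ivs["start"].to_numpy(), side="right")
        counts.loc[ivs.index] = began - ended
    return counts


def count_reads(intervals: pd.DataFrame, reads: dict[tuple[str, str], pd.DataFrame]) -> MarkCountMatrix:
    """Count reads from each (subset, mark) track over the intervals.

    Library size of a track is its total read count (including reads not
    overlapping any interval).
    """
    cols, libs, meta = {}, {}, []
    for (subset, mark), frame in reads.items():
        label = f"{subset}|{mark}"
        cols[label] = _count_track(intervals, frame)
        libs[label] = len(frame)
        meta.append((label, subset, mark))
    counts = pd.DataFrame(cols)
    track_meta = pd.DataFrame(meta, columns=["track", "subset", "mark"]).set_index("track")
    return MarkCountMatrix(counts=counts, lib_sizes=pd.Series(libs), track_meta=track_meta)


def nbglm_logfc(counts: pd.DataFrame, groups: pd.Series, lib_sizes: pd.Series | None = None,
                dispersion: float = 0.05, prior_count: float = 1.0) -> pd.DataFrame:
    """Per-locus log2 fold changes from a fixed-dispersion NB model.

    A library-size-scaled prior count is added to the counts (and twice the
    average to the library sizes), then a one-factor NB log-linear model
    with log effective-library offsets is fitted at the given dispersion by
    per-group Newton iteration on the score equation.  Returns the group
    log2 abundances; column '<a>_vs_<b>' gives log2FC for each ordered
    group pair.
    """
    y = counts.to_numpy(dtype=float)
    samples = list(counts.columns)
    groups = groups.reindex(samples)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = lib_sizes.reindex(samples).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    pvec = prior_count * lib / lib.mean()
    y_adj = y + pvec[None, :]
    offs = np.log(lib + 2 * pvec)

    result = {}
    for g in dict.fromkeys(groups):
        cols = [i for i, s in enumerate(samples) if groups.iloc[i] == g]
        yg = y_adj[:, cols]
        og = offs[cols]
        eo = np.exp(og)
        beta = np.log(yg.sum(axis=1) / eo.sum())
        phi = dispersion
        for _ in range(50):
            mu = np.exp(beta[:, None] + og[None, :])
            score = ((yg - mu) / (1.0 + phi * mu)).sum(axis=1)
            info = (mu * (1.0 + phi * yg) / (1.0 + phi * mu) ** 2).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        result[g] = beta
    out = pd.DataFrame({g: b / np.log(2) for g, b in result.items()}, index=counts.index)
    names = list(result)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}_vs_{b}"] = out[a] - out[b]
    return out


def origin_regression(x: np.ndarray, y: np.ndarray) -> LinkResult:
    """Least squares through the origin: slope = sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    sxx = float((x**2).sum())
    if sxx == 0:
        raise ValueError("all x values are zero")
    n = x.size
    slope = float((x * y).sum() / sxx)
    rss = float(((y - slope * x) ** 2).sum())
    se = float(np.sqrt(rss / ((n - 1) * sxx)))
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return LinkResult(slope=slope, se=se, p=p, n=n, x=x, y=y)


def top_de_selection(de_table: pd.DataFrame, n: int) -> list[str]:
    """First n probes by ascending p; ties broken by |logFC| descending,
    then probe symbol."""
    if n > len(de_table):
        logger.warning("requested top %d of %d rows: returning all", n, len(de_table))
        n = len(de_table)
    ranked = de_table.assign(_absfc=de_table["logFC"].abs()).sort_values(
        ["p", "_absfc", "probe"], ascending=[True, False, True], kind="stable"
    )
    return list(ranked["probe"].head(n))


def link_marks_to_expression(expr_de: pd.DataFrame, mark_counts: MarkCountMatrix,
                             subset_pair: tuple[str, str], n_top: int = 200,
                             n_heatmap: int = 140, dispersion: float = 0.05,
                             prior_count: float = 1.0) -> dict:
    """Origin-regression of expression log2FC on mark log2FC over the
    top-n DE miRNAs, per mark; also emits the heatmap matrix for the
    top ``n_heatmap`` selection.

    Expression log2FC (y) must be on the same subset pair as the mark
    comparison (x).
    """
    top = top_de_selection(expr_de, n_top)
    de = expr_de.set_index("probe")
    a, b = subset_pair
    results: dict = {"links": {}, "heatmap": None}
    heat_cols = {}
    for mark in sorted(set(mark_counts.track_meta["mark"])):
        tracks = mark_counts.track_meta[mark_counts.track_meta["mark"] == mark]
        labels = list(tracks.index)
        groups = pd.Series(tracks["subset"].to_numpy(), index=labels)
        sub = mark_counts.counts[labels]
        fc = nbglm_logfc(sub, groups, lib_sizes=mark_counts.lib_sizes[labels],
                         dispersion=dispersion, prior_count=prior_count)
        col = f"{a}_vs_{b}"
        if col not in fc.columns:
            col_rev = f"{b}_vs_{a}"
            fc[col] = -fc[col_rev]
        # map locus rows (possibly merged 'x/y' keys) to member symbols
        locus_fc = {}
        for locus, val in fc[col].items():
            for sym in str(locus).split("/"):
                locus_fc[sym] = val
        common = [m for m in top if m in locus_fc]
        if len(common) < 2:
            raise ValueError("fewer than 2 miRNAs shared between DE table and loci")
        x = np.array([locus_fc[m] for m in common])
        y = de.loc[common, "logFC"].to_numpy(dtype=float)
        results["links"][mark] = origin_regression(x, y)
        heat_cols[mark] = pd.Series(x, index=common)

    heat_top = [m for m in top_de_selection(expr_de, n_heatmap)
                if all(m in hc.index for hc in heat_cols.values())]
    heat = pd.DataFrame({"expression": de.loc[heat_top, "logFC"]})
    for mark, hc in heat_cols.items():
        heat[mark] = hc.reindex(heat_top)
    results["heatmap"] = heat
    return results


def coverage_bedgraph(reads: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Reads-per-million per-base coverage over a window, as bedGraph rows
    (visualization only)."""
    total = max(len(reads), 1)
    sub = reads[(reads["chrom"] == chrom) & (reads["end"] > start) & (reads["start"] < end)]
    cov = np.zeros(end - start)
    for s, e in zip(sub["start"], sub["end"]):
        cov[max(0, s - start):max(0, min(e, end) - start)] += 1
    cov = cov / total * 1e6
    rows, i = [], 0
    while i < len(cov):
        j = i
        while j + 1 < len(cov) and cov[j + 1] == cov[i]:
            j += 1
        if cov[i] != 0:
            rows.append((chrom, start + i, start + j + 1, cov[i]))
        i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
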