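"""Tumor miRNA-seq signature scoring.

Pipeline: collapse technical replicates (shared analyte IDs) and isoform
rows, CPM-filter, TMM normalization, log2-CPM with a scaled prior count,
then score each tumor against normal-subset signatures as
``sum(logFC * logCPM) / sum(|logFC|)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linear_de import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "collapse_replicates_and_isoforms",
    "filter_primary_tumors",
    "filter_cpm",
    "tmm_factors",
    "log_cpm",
    "signature_from_de",
    "signature_score",
    "score_table",
    "score_by_subtype",
]


@dataclass
class CountMatrix:
    """miRNA (possibly isoform-level) x sample integer read counts.

    ``parent`` maps row IDs to parent miRNA symbols; ``sample_annot`` is
    indexed by sample with columns analyte_id, subtype and (optionally)
    sample_type.
    """

    counts: pd.DataFrame
    sample_annot: pd.DataFrame
    parent: pd.Series | None = None
    norm_factors: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        if self.parent is None:
            self.parent = pd.Series(self.counts.index, index=self.counts.index)
        self.sample_annot = self.sample_annot.loc[self.counts.columns]

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def filter_primary_tumors(cm: CountMatrix) -> CountMatrix:
    """Keep only primary-solid-tumor samples when a sample_type field exists."""
    if "sample_type" not in cm.sample_annot.columns:
        return cm
    keep = cm.sample_annot["sample_type"] == "primary"
    return CountMatrix(counts=cm.counts.loc[:, keep[keep].index],
                       sample_annot=cm.sample_annot.loc[keep], parent=cm.parent)


def collapse_replicates_and_isoforms(cm: CountMatrix) -> CountMatrix:
    """Sum columns within analyte ID and rows within parent miRNA symbol."""
    annot = cm.sample_annot
    conflicts = annot.groupby("analyte_id")["subtype"].nunique()
    if (conflicts > 1).any():
        bad = conflicts.index[conflicts > 1][0]
        raise ValueError(f"conflicting subtype labels within analyte ID {bad!r}")

    by_analyte = cm.counts.T.groupby(annot["analyte_id"]).sum().T
    by_parent = by_analyte.groupby(cm.parent).sum()
    new_annot = (
        annot.reset_index()
        .drop_duplicates("analyte_id")
        .set_index("analyte_id")[[c for c in ("subtype", "sample_type") if c in annot.columns]]
    )
    new_annot = new_annot.loc[by_analyte.columns]
    new_annot["analyte_id"] = new_annot.index
    return CountMatrix(counts=by_parent, sample_annot=new_annot)


def filter_cpm(cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 29) -> CountMatrix:
    """Keep rows with CPM >= min_cpm (raw library sizes) in >= min_samples samples."""
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    cpm = cm.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(counts=cm.counts.loc[keep], sample_annot=cm.sample_annot,
                       parent=cm.parent.loc[keep] if cm.parent is not None else None)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    Reference sample: upper-quartile CPM closest to the mean upper-quartile.
    Per sample, gene-wise M/A values against the reference over genes
    positive in both are doubly trimmed (``trim_m`` on M, ``trim_a`` on A,
    both tails, rank-based) and combined by an inverse-asymptotic-variance
    weighted mean.  Factors are rescaled to have zero log-mean.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    cpm = counts / lib[None, :] * 1e6
    uq = np.quantile(cpm, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for i in range(counts.shape[1]):
        if i == ref:
            continue
        yi, ni = counts[:, i], lib[i]
        mask = (yi > 0) & (yr > 0)
        if not mask.any():
            raise ValueError(f"sample {cm.counts.columns[i]!r} shares no positive genes with the reference")
        m = np.log2((yi[mask] / ni) / (yr[mask] / nr))
        a = 0.5 * np.log2((yi[mask] / ni) * (yr[mask] / nr))
        v = (ni - yi[mask]) / (ni * yi[mask]) + (nr - yr[mask]) / (nr * yr[mask])
        n = m.size
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        if abs(f) < 1e-6:
            f = 0.0
        log_factors[i] = f
    log_factors -= log_factors.mean()
    return pd.Series(2.0**log_factors, index=cm.counts.columns)


def log_cpm(cm: CountMatrix, factors: pd.Series | None = None, prior: float = 0.25) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes with a
    library-size-scaled prior count.

    value = log2((count + p_i) / (L_i + 2 p_i) * 1e6) with
    L_i = libsize_i * factor_i and p_i = prior * L_i / mean(L).
    """
    if factors is None:
        factors = pd.Series(1.0, index=cm.counts.columns)
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    eff = lib * factors.reindex(cm.counts.columns).to_numpy(dtype=float)
    p = prior * eff / eff.mean()
    vals = np.log2((cm.counts.to_numpy(dtype=float) + p[None, :]) / (eff + 2 * p)[None, :] * 1e6)
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def signature_from_de(de_table: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """SignatureSet from a DE table: symbol -> logFC, restricted to FDR < fdr."""
    sig = de_table[de_table["FDR"] < fdr]
    if sig.empty:
        raise ValueError("no signature probes at the requested FDR")
    out = pd.Series(sig["logFC"].to_numpy(), index=sig["probe"].map(normalize_symbol))
    return out[~out.index.duplicated()]


def signature_score(sig: pd.Series, logcpm_col: pd.Series) -> float:
    """score = sum(logFC * logCPM) / sum(|logFC|) over present signature miRNAs."""
    idx = pd.Index(logcpm_col.index.map(normalize_symbol))
    lookup = pd.Series(logcpm_col.to_numpy(), index=idx)
    lookup = lookup[~lookup.index.duplicated()]
    present = sig.index.intersection(lookup.index)
    if len(present) == 0:
        raise ValueError("no signature miRNAs present in the expression column")
    if len(present) < len(sig):
        logger.info("dropping %d signature miRNAs absent from the matrix", len(sig) - len(present))
    fc = sig.loc[present]
    return float((fc * lookup.loc[present]).sum() / fc.abs().sum())


def score_table(signatures: dict[str, pd.Series], logcpm: pd.DataFrame,
                sample_annot: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor scores for each signature, with subtype labels attached."""
    rows = {}
    for name, sig in signatures.items():
        rows[name] = [signature_score(sig, logcpm[c]) for c in logcpm.columns]
    out = pd.DataFrame(rows, index=logcpm.columns)
    out["subtype"] = sample_annot.loc[logcpm.columns, "subtype"]
    return out


def score_by_subtype(scores: pd.DataFrame, signature: str, subtype: str) -> dict:
    """Five-number summaries per subtype plus a one-sided rank-sum p-value
    for the named subtype's scores versus all other subtypes pooled."""
    grouped = scores.groupby("subtype")[signature]
    summaries = {
        st: dict(zip(["min", "q1", "median", "q3", "max"],
                     np.quantile(v.to_numpy(), [0, 0.25, 0.5, 0.75, 1.0])))
        for st, v in grouped
    }
    result = {"summaries": summaries, "p": None}
    if scores["subtype"].nunique() < 2:
        return result
    target = scores.loc[scores["subtype"] == subtype, signature].to_numpy()
    rest = scores.loc[scores["subtype"] != subtype, signature].to_numpy()
    if len(target) >= 2 and len(rest) >= 2:
        result["p"] = float(stats.mannwhitneyu(target, rest, alternative="greater").pvalue)
    return result
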