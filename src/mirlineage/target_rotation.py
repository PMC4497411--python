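"""Directional rotation gene-set tests linking miRNA expression changes to
their predicted target mRNAs, plus barcode-plot data and hypergeometric GO
enrichment.

The rotation test projects each gene's expression onto the subspace spanned
by the tested contrast and the residual space (dimension d+1 where d is the
residual df), then replaces the contrast direction by uniformly random unit
vectors.  The set statistic is the mean of the per-gene moderated t values;
the one-sided p-value is (exceedances + 1)/(rotations + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .ct_preprocess import ExpressionMatrix
from .linear_de import bh_adjust, fit_f_dist, squeeze_var

logger = logging.getLogger(__name__)

__all__ = [
    "RotationTestResult",
    "RotationWorkspace",
    "load_target_map",
    "write_target_map",
    "roast_directional",
    "inverse_correlation_screen",
    "barcode_data",
    "select_inverse_de_targets",
    "go_enrichment",
]


@dataclass
class RotationTestResult:
    mirna: str | None
    set_size: int
    observed: float
    p: float
    exceedances: int
    direction: str
    n_rotations: int
    seed: int | None

    @property
    def mid_p(self) -> float:
        """Mid-p value (half-counts the observed statistic's own tie)."""
        return (self.exceedances + 0.5) / (self.n_rotations + 1)


def load_target_map(path, universe) -> dict[str, set]:
    """Read a miRNA->gene TSV (columns mirna, gene) and intersect the gene
    sets with the expression universe; emptied sets are dropped (logged)."""
    universe = set(universe)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"unparseable target map {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "mirna" not in cols or "gene" not in cols:
        raise ValueError(f"{path}: expected columns 'mirna' and 'gene'")
    bad = df[df[cols["mirna"]].isna() | df[cols["gene"]].isna()]
    if len(bad):
        raise ValueError(f"{path}: unparseable row at line {bad.index[0] + 2}")
    tmap: dict[str, set] = {}
    for mirna, group in df.groupby(cols["mirna"], sort=True):
        genes = set(group[cols["gene"]]) & universe
        if genes:
            tmap[mirna] = genes
    dropped = df[cols["mirna"]].nunique() - len(tmap)
    if dropped:
        logger.info("dropped %d miRNAs whose targets are all absent from the universe", dropped)
    return tmap


def write_target_map(tmap: dict[str, set], path) -> None:
    rows = [(m, g) for m in sorted(tmap) for g in sorted(tmap[m])]
    pd.DataFrame(rows, columns=["mirna", "gene"]).to_csv(path, sep="\t", index=False)


class RotationWorkspace:
    """Shared projection for rotation tests of many sets against one
    contrast.

    Reduces every gene's data to ``u`` in R^(d+1): first coordinate the
    contrast effect, remainder the residual effects.  Empirical-Bayes
    moderation hyperparameters are estimated once from all genes.
    """

    def __init__(self, mrna_expr: ExpressionMatrix | pd.DataFrame, design: pd.DataFrame,
                 contrast: pd.Series):
        values = mrna_expr.values if isinstance(mrna_expr, ExpressionMatrix) else mrna_expr
        Y = values.to_numpy(dtype=float)
        X = design.to_numpy(dtype=float)
        n, p = X.shape
        c = contrast.reindex(design.columns).fillna(0.0).to_numpy(dtype=float)
        if np.allclose(c, 0):
            raise ValueError("contrast is identically zero")
        self.df_residual = n - p
        if self.df_residual < 1:
            raise ValueError("no residual degrees of freedom")

        # Orthonormal reparameterization with the contrast as one coefficient,
        # placed last so the trailing QR block spans contrast + residuals.
        M = np.column_stack([c, np.eye(p)])
        Qc, _ = linalg.qr(M, mode="economic")
        Qc = Qc[:, :p]
        if Qc[:, 0] @ c < 0:
            Qc[:, 0] = -Qc[:, 0]
        Xr = X @ np.column_stack([Qc[:, 1:], Qc[:, 0]])
        Qfull, R = linalg.qr(Xr, mode="full")
        sign = np.sign(R[p - 1, p - 1])
        effects = Qfull.T @ Y.T  # (n, G)
        u = effects[p - 1:, :].copy()
        u[0, :] *= sign
        self.u = u  # (d+1, G)
        self.genes = pd.Index(values.index)
        self.sumsq = (u**2).sum(axis=0)
        s2 = (self.sumsq - u[0, :] ** 2) / self.df_residual
        self.s2 = s2
        self.df_prior, self.s2_prior = fit_f_dist(s2, self.df_residual)

    def moderated_t(self, b: np.ndarray, s2: np.ndarray) -> np.ndarray:
        s2_post = squeeze_var(s2, self.df_residual, self.df_prior, self.s2_prior)
        return b / np.sqrt(s2_post)

    def test(self, gene_set, direction: str, B: int = 9999,
             seed: int | None = None, rng: np.random.Generator | None = None,
             mirna: str | None = None) -> RotationTestResult:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        idx = self.genes.get_indexer(list(gene_set))
        missing = int((idx < 0).sum())
        if missing:
            logger.info("dropping %d set genes missing from the mRNA matrix", missing)
            idx = idx[idx >= 0]
        if len(idx) < 2:
            raise ValueError("gene set must contain at least 2 genes present in the data")
        u = self.u[:, idx]  # (d+1, m)
        sumsq = self.sumsq[idx]
        d = self.df_residual

        obs_t = self.moderated_t(u[0, :], self.s2[idx])
        observed = float(obs_t.mean())

        if rng is None:
            rng = np.random.default_rng(seed)
        r = rng.standard_normal((B, u.shape[0]))
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        b = r @ u  # (B, m)
        s2_rot = np.maximum(sumsq[None, :] - b**2, 0.0) / d
        t_rot = self.moderated_t(b, s2_rot)
        stats_rot = t_rot.mean(axis=1)

        if direction == "up":
            exceed = int((stats_rot >= observed).sum())
        else:
            exceed = int((stats_rot <= observed).sum())
        p = (exceed + 1) / (B + 1)
        return RotationTestResult(
            mirna=mirna, set_size=len(idx), observed=observed, p=p,
            exceedances=exceed, direction=direction, n_rotations=B, seed=seed,
        )


def roast_directional(mrna_expr, design: pd.DataFrame, contrast: pd.Series, gene_set,
                      direction: str, B: int = 9999, seed: int | None = None) -> RotationTestResult:
    """One-shot directional rotation gene-set test (see module docstring)."""
    ws = RotationWorkspace(mrna_expr, design, contrast)
    return ws.test(gene_set, direction, B=B, seed=seed)


def inverse_correlation_screen(de_table: pd.DataFrame, target_map: dict, mrna_expr,
                               design: pd.DataFrame, contrast: pd.Series,
                               B: int = 9999, seed: int | None = None) -> pd.DataFrame:
    """For each DE miRNA, test whether its targets move in the opposite
    direction; BH-adjust across the tested miRNAs.

    miRNAs with logFC exactly 0 (direction undefined) or without usable
    target sets are skipped with a logged reason.
    """
    ws = RotationWorkspace(mrna_expr, design, contrast)
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in de_table.iterrows():
        mirna, logfc = rec["probe"], rec["logFC"]
        if mirna not in target_map:
            continue
        if logfc == 0:
            logger.info("skipping %s: logFC is zero, inverse direction undefined", mirna)
            continue
        direction = "down" if logfc > 0 else "up"
        try:
            res = ws.test(target_map[mirna], direction, B=B, rng=rng, mirna=mirna)
        except ValueError as exc:
            logger.info("skipping %s: %s", mirna, exc)
            continue
        rows.append((mirna, float(logfc), direction, res.set_size, res.observed, res.p))
    out = pd.DataFrame(rows, columns=["mirna", "logFC", "direction", "set_size", "set_stat", "p"])
    if len(out):
        out["FDR"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "mirna"], kind="stable").reset_index(drop=True)
    else:
        out["FDR"] = []
    return out


@dataclass
class BarcodeData:
    ranked_stats: pd.Series  # descending
    member_positions: np.ndarray  # 1-based ranks of set members
    worm_x: np.ndarray  # relative rank positions in [0, 1]
    worm: np.ndarray  # relative enrichment minus uniform baseline


def barcode_data(stat_vector: pd.Series, gene_set, n_bins: int = 100) -> BarcodeData:
    """Rank genes by a statistic (descending) and compute member positions
    plus a smoothed relative-enrichment 'worm' (zero = uniform density)."""
    stats_arr = stat_vector.to_numpy(dtype=float)
    if not np.all(np.isfinite(stats_arr)):
        raise ValueError("statistics must be finite")
    order = np.argsort(-stats_arr, kind="stable")
    ranked = stat_vector.iloc[order]
    pos_lookup = {g: r + 1 for r, g in enumerate(ranked.index)}
    members = sorted(g for g in gene_set if g in pos_lookup)
    positions = np.array([pos_lookup[g] for g in members], dtype=int)

    n = len(ranked)
    x = (np.arange(n_bins) + 0.5) / n_bins
    worm = np.zeros(n_bins)
    if len(positions):
        rel = (positions - 0.5) / n
        bw = max(0.025, 1.0 / n_bins)
        diff = (x[:, None] - rel[None, :]) / bw
        dens = np.exp(-0.5 * diff**2).sum(axis=1) / (len(rel) * bw * np.sqrt(2 * np.pi))
        worm = dens - 1.0  # uniform density on [0, 1] is 1
    return BarcodeData(ranked_stats=ranked, member_positions=positions, worm_x=x, worm=worm)


def select_inverse_de_targets(mirna_de: pd.DataFrame, mrna_de: pd.DataFrame,
                              target_map: dict, mirna_fdr: float = 0.05,
                              mrna_fdr: float = 0.2) -> set:
    """Genes that are (i) a target of a DE miRNA and (ii) mRNA-DE at
    FDR < ``mrna_fdr`` with sign opposite to the miRNA's logFC."""
    mrna = mrna_de.set_index("probe")
    selected: set = set()
    for _, rec in mirna_de.iterrows():
        if rec["FDR"] >= mirna_fdr or rec["logFC"] == 0:
            continue
        targets = target_map.get(rec["probe"], set())
        for g in targets:
            if g not in mrna.index:
                continue
            grow = mrna.loc[g]
            if grow["FDR"] < mrna_fdr and grow["logFC"] * rec["logFC"] < 0:
                selected.add(g)
    return selected


def go_enrichment(selected, universe, annotation: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each term in ``annotation``
    (columns gene, term, optional term_name) among ``selected`` genes."""
    universe = set(universe)
    selected = set(selected) & universe
    if not selected:
        logger.warning("empty selection: no GO enrichment computed")
        return pd.DataFrame(columns=["term", "term_name", "overlap", "set_size",
                                     "term_size", "universe_size", "p", "FDR"])
    ann = annotation[annotation["gene"].isin(universe)]
    names = {}
    if "term_name" in ann.columns:
        names = ann.drop_duplicates("term").set_index("term")["term_name"].to_dict()
    N, k = len(universe), len(selected)
    rows = []
    for term, group in ann.groupby("term", sort=True):
        term_genes = set(group["gene"])
        K = len(term_genes)
        overlap = len(term_genes & selected)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, k))
        rows.append((term, names.get(term, ""), overlap, k, K, N, p))
    out = pd.DataFrame(rows, columns=["term", "term_name", "overlap", "set_size",
                                      "term_size", "universe_size", "p"])
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
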