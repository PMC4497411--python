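"""Probe-wise linear models with empirical-Bayes moderated t/F statistics,
plus the derived summaries (MDS coordinates, hierarchical clustering,
species batch removal) used for the subset comparisons.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.special import digamma, polygamma

from .ct_preprocess import ExpressionMatrix

__all__ = [
    "EPITHELIAL_SUBSETS",
    "STROMA_SUBSET",
    "FitResult",
    "EBayesResult",
    "fit_linear_model",
    "contrast_fit",
    "ebayes_moderate",
    "bh_adjust",
    "signature_de",
    "anova_de",
    "basal_vs_luminal_de",
    "stroma_vs_epithelium_de",
    "combined_species_de",
    "remove_species_batch",
    "mds_coordinates",
    "hierarchical_cluster",
    "subset_design",
    "match_symbols",
    "normalize_symbol",
]

EPITHELIAL_SUBSETS = ("MaSC/basal", "LP", "ML")
STROMA_SUBSET = "stroma"


@dataclass
class FitResult:
    """Per-probe least-squares fit for a shared design matrix.

    coefficients: probe x coefficient estimates (log2 units)
    stdev_unscaled: sqrt of the diagonal of (X'X)^-1 mapped through any
        contrast transform; multiply by the residual SD to get a standard
        error.
    sigma2: residual variances s_g^2
    df_residual: residual degrees of freedom (n - rank(X))
    cov_unscaled: (X'X)^-1 (or C'(X'X)^-1 C after a contrast transform)
    """

    coefficients: pd.DataFrame
    stdev_unscaled: pd.DataFrame
    sigma2: pd.Series
    df_residual: float
    cov_unscaled: np.ndarray

    @property
    def probes(self) -> pd.Index:
        return self.coefficients.index


@dataclass
class EBayesResult:
    df_prior: float
    s2_prior: float
    s2_post: pd.Series
    t: pd.DataFrame
    p_t: pd.DataFrame
    F: pd.Series
    p_F: pd.Series
    df_total: float


def fit_linear_model(expr: ExpressionMatrix | pd.DataFrame, design: pd.DataFrame) -> FitResult:
    """Ordinary least squares per probe against a common design matrix."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    Y = values.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError("design rows must align with expression samples")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name a collinear column for the error message
        _, r = np.linalg.qr(X)
        dep = [design.columns[j] for j in range(p) if abs(r[j, j]) < 1e-10 * max(1.0, abs(r).max())]
        raise ValueError(f"design matrix is not of full column rank (collinear: {dep})")
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("at least one residual degree of freedom is required")

    xtx = X.T @ X
    cov_unscaled = linalg.inv(xtx)
    beta = Y @ X @ cov_unscaled  # (G, p)
    resid = Y - beta @ X.T
    sigma2 = (resid**2).sum(axis=1) / df_resid
    stdev = np.sqrt(np.diag(cov_unscaled))
    probes = values.index
    return FitResult(
        coefficients=pd.DataFrame(beta, index=probes, columns=design.columns),
        stdev_unscaled=pd.DataFrame(
            np.broadcast_to(stdev, beta.shape).copy(), index=probes, columns=design.columns
        ),
        sigma2=pd.Series(sigma2, index=probes),
        df_residual=float(df_resid),
        cov_unscaled=cov_unscaled,
    )


def contrast_fit(fit: FitResult, contrasts: pd.DataFrame) -> FitResult:
    """Re-express a fit in terms of contrasts (columns of ``contrasts``)."""
    C = contrasts.to_numpy(dtype=float)
    if C.shape[0] != fit.coefficients.shape[1]:
        raise ValueError("contrast rows must match fit coefficients")
    beta = fit.coefficients.to_numpy() @ C
    cov = C.T @ fit.cov_unscaled @ C
    stdev = np.sqrt(np.diag(cov))
    return FitResult(
        coefficients=pd.DataFrame(beta, index=fit.probes, columns=contrasts.columns),
        stdev_unscaled=pd.DataFrame(
            np.broadcast_to(stdev, beta.shape).copy(), index=fit.probes, columns=contrasts.columns
        ),
        sigma2=fit.sigma2,
        df_residual=fit.df_residual,
        cov_unscaled=cov,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (df_prior, s2_prior) of a scaled-F distribution for sample
    variances by moment-matching log(s2) (digamma/trigamma inversion)."""
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least two variances")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = np.exp(emean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return float(df_prior), float(s2_prior)


def squeeze_var(s2: np.ndarray, df: float, df_prior: float, s2_prior: float) -> np.ndarray:
    """Posterior variances (d0*s0^2 + d*s^2)/(d0 + d), with the d0 = inf branch."""
    if np.isinf(df_prior):
        return np.full_like(np.asarray(s2, dtype=float), s2_prior)
    return (df_prior * s2_prior + df * np.asarray(s2, dtype=float)) / (df_prior + df)


def ebayes_moderate(fit: FitResult, df_prior: float | None = None) -> EBayesResult:
    """Empirical-Bayes moderated t and F statistics for a (contrast) fit.

    ``df_prior`` may be forced: 0 gives ordinary statistics, ``inf`` fixes
    every posterior variance at the prior.
    """
    s2 = fit.sigma2.to_numpy()
    d = fit.df_residual
    if df_prior is None:
        d0, s20 = fit_f_dist(s2, d)
    elif df_prior == 0:
        d0, s20 = 0.0, float(np.mean(s2))
    else:
        d0 = float(df_prior)
        _, s20 = fit_f_dist(s2, d)
    s2_post = squeeze_var(s2, d, d0, s20) if d0 > 0 else s2.copy()
    df_total = d + d0

    beta = fit.coefficients.to_numpy()
    stdev = fit.stdev_unscaled.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / (stdev * np.sqrt(s2_post)[:, None])
    if np.isinf(df_total):
        p_t = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_t = 2.0 * stats.t.sf(np.abs(t), df=df_total)

    # Moderated F across the full coefficient set of this fit.
    k = beta.shape[1]
    Uinv = linalg.inv(fit.cov_unscaled)
    quad = np.einsum("gi,ij,gj->g", beta, Uinv, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = quad / (k * s2_post)
    if np.isinf(df_total):
        p_F = stats.chi2.sf(k * F, df=k)
    else:
        p_F = stats.f.sf(F, dfn=k, dfd=df_total)

    probes = fit.probes
    return EBayesResult(
        df_prior=d0,
        s2_prior=s20,
        s2_post=pd.Series(s2_post, index=probes),
        t=pd.DataFrame(t, index=probes, columns=fit.coefficients.columns),
        p_t=pd.DataFrame(p_t, index=probes, columns=fit.coefficients.columns),
        F=pd.Series(F, index=probes),
        p_F=pd.Series(p_F, index=probes),
        df_total=df_total,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Subset contrasts


def subset_design(sample_meta: pd.DataFrame, subsets=None, species_covariate: bool = False) -> pd.DataFrame:
    """Cell-means design (one indicator column per subset), optionally with a
    species main-effect column (1 for the lexicographically later species)."""
    subs = sample_meta["subset"]
    if subsets is None:
        subsets = list(dict.fromkeys(subs))
    cols = {s: (subs == s).astype(float) for s in subsets}
    design = pd.DataFrame(cols, index=sample_meta.index)
    if species_covariate:
        species = sorted(sample_meta["species"].unique())
        if len(species) != 2:
            raise ValueError("species covariate requires exactly two species")
        design["species"] = (sample_meta["species"] == species[1]).astype(float)
    return design


def _de_table(logfc: pd.Series, stat: pd.Series, p: pd.Series, stat_name: str = "t") -> pd.DataFrame:
    fdr = bh_adjust(p.to_numpy())
    table = pd.DataFrame(
        {
            "probe": p.index,
            "logFC": logfc.reindex(p.index).to_numpy(),
            stat_name: stat.reindex(p.index).to_numpy(),
            "p": p.to_numpy(),
            "FDR": fdr,
        }
    )
    table["direction"] = np.where(table["logFC"] > 0, "up", np.where(table["logFC"] < 0, "down", "none"))
    table = table.sort_values(["p", "probe"], kind="stable").reset_index(drop=True)
    return table


def _contrast_de(expr: ExpressionMatrix, contrast: pd.Series, subsets, name: str,
                 species_covariate: bool = False) -> pd.DataFrame:
    mask = expr.sample_meta["subset"].isin(subsets)
    sub = expr.subset_samples(expr.sample_meta.index[mask])
    present = set(sub.sample_meta["subset"])
    missing = set(subsets) - present
    if missing:
        raise ValueError(f"subset label(s) absent from data: {sorted(missing)}")
    design = subset_design(sub.sample_meta, subsets=subsets, species_covariate=species_covariate)
    fit = fit_linear_model(sub, design)
    cvec = contrast.reindex(design.columns).fillna(0.0)
    cfit = contrast_fit(fit, pd.DataFrame({name: cvec}))
    eb = ebayes_moderate(cfit)
    return _de_table(cfit.coefficients[name], eb.t[name], eb.p_t[name])


def signature_de(expr: ExpressionMatrix, subset: str, species_covariate: bool = False) -> pd.DataFrame:
    """Subset-vs-average-of-the-other-two contrast within the three
    epithelial subsets; signature probes are rows with FDR < 0.05."""
    if subset not in EPITHELIAL_SUBSETS:
        raise ValueError(f"unknown epithelial subset {subset!r}")
    others = [s for s in EPITHELIAL_SUBSETS if s != subset]
    contrast = pd.Series({subset: 1.0, others[0]: -0.5, others[1]: -0.5})
    return _contrast_de(expr, contrast, EPITHELIAL_SUBSETS, f"{subset}_vs_rest",
                        species_covariate=species_covariate)


def anova_de(expr: ExpressionMatrix, species_covariate: bool = False) -> pd.DataFrame:
    """Moderated F-test over the two-contrast basis spanning the three
    epithelial subset differences."""
    mask = expr.sample_meta["subset"].isin(EPITHELIAL_SUBSETS)
    sub = expr.subset_samples(expr.sample_meta.index[mask])
    if set(EPITHELIAL_SUBSETS) - set(sub.sample_meta["subset"]):
        raise ValueError("all three epithelial subsets are required")
    design = subset_design(sub.sample_meta, subsets=EPITHELIAL_SUBSETS,
                           species_covariate=species_covariate)
    fit = fit_linear_model(sub, design)
    a, b, c = EPITHELIAL_SUBSETS
    contrasts = pd.DataFrame(
        {f"{a}_vs_{b}": pd.Series({a: 1.0, b: -1.0}), f"{a}_vs_{c}": pd.Series({a: 1.0, c: -1.0})}
    ).reindex(design.columns).fillna(0.0)
    cfit = contrast_fit(fit, contrasts)
    eb = ebayes_moderate(cfit)
    # logFC column: largest-magnitude pairwise difference, for reporting only
    fc = cfit.coefficients
    lead = fc.abs().to_numpy().argmax(axis=1)
    logfc = pd.Series(fc.to_numpy()[np.arange(len(fc)), lead], index=fc.index)
    return _de_table(logfc, eb.F, eb.p_F, stat_name="F")


def basal_vs_luminal_de(expr: ExpressionMatrix, species_covariate: bool = False) -> pd.DataFrame:
    """MaSC/basal versus the average of the two luminal subsets."""
    contrast = pd.Series({"MaSC/basal": 1.0, "LP": -0.5, "ML": -0.5})
    return _contrast_de(expr, contrast, EPITHELIAL_SUBSETS, "basal_vs_luminal",
                        species_covariate=species_covariate)


def stroma_vs_epithelium_de(expr: ExpressionMatrix, species_covariate: bool = False) -> pd.DataFrame:
    """Stroma versus the average of the three epithelial subsets."""
    third = 1.0 / 3.0
    contrast = pd.Series(
        {STROMA_SUBSET: 1.0, "MaSC/basal": -third, "LP": -third, "ML": -third}
    )
    subsets = (*EPITHELIAL_SUBSETS, STROMA_SUBSET)
    return _contrast_de(expr, contrast, subsets, "stroma_vs_epithelium",
                        species_covariate=species_covariate)


# ---------------------------------------------------------------------------
# Cross-species analysis

_SPECIES_PREFIX = re.compile(r"^(mmu-|hsa-)", flags=re.IGNORECASE)


def normalize_symbol(probe: str) -> str:
    """Strip species prefixes and lowercase; arm suffixes (3p/5p) are kept."""
    return _SPECIES_PREFIX.sub("", probe.strip()).lower()


def match_symbols(mouse_probes, human_probes) -> pd.DataFrame:
    """Match probe IDs across species by normalized miRNA symbol.

    Returns a frame with columns (symbol, mouse_probe, human_probe); probes
    whose normalized symbol is duplicated within a species are dropped.
    """
    def uniq(probes):
        sym = pd.Series(list(probes), name="probe")
        frame = pd.DataFrame({"probe": sym, "symbol": sym.map(normalize_symbol)})
        return frame.drop_duplicates("symbol", keep=False)

    m, h = uniq(mouse_probes), uniq(human_probes)
    merged = m.merge(h, on="symbol", suffixes=("_mouse", "_human"))
    return merged.rename(columns={"probe_mouse": "mouse_probe", "probe_human": "human_probe"})


def stack_species(mouse_expr: ExpressionMatrix, human_expr: ExpressionMatrix,
                  symbol_map: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Stack the two species matrices on symbol-matched probes."""
    if symbol_map is None:
        symbol_map = match_symbols(mouse_expr.probes, human_expr.probes)
    if symbol_map.empty:
        raise ValueError("no probes matched between species")
    mv = mouse_expr.values.loc[symbol_map["mouse_probe"]].to_numpy()
    hv = human_expr.values.loc[symbol_map["human_probe"]].to_numpy()
    cols = [f"mouse:{s}" for s in mouse_expr.samples] + [f"human:{s}" for s in human_expr.samples]
    values = pd.DataFrame(np.hstack([mv, hv]), index=symbol_map["symbol"].to_numpy(), columns=cols)
    meta = pd.concat(
        [
            mouse_expr.sample_meta.assign(species="mouse").set_axis(cols[: len(mouse_expr.samples)]),
            human_expr.sample_meta.assign(species="human").set_axis(cols[len(mouse_expr.samples):]),
        ]
    )
    classes = pd.Series("target", index=values.index)
    return ExpressionMatrix(values=values, probe_class=classes, sample_meta=meta,
                            normalized=mouse_expr.normalized and human_expr.normalized)


def combined_species_de(mouse_expr: ExpressionMatrix, human_expr: ExpressionMatrix,
                        symbol_map: pd.DataFrame | None = None,
                        contrast: str = "basal_vs_luminal") -> pd.DataFrame:
    """Joint DE on symbol-matched probes with a species main-effect covariate.

    ``contrast`` is one of 'basal_vs_luminal', 'anova', or
    'signature:<subset>'.
    """
    stacked = stack_species(mouse_expr, human_expr, symbol_map)
    if contrast == "anova":
        return anova_de(stacked, species_covariate=True)
    if contrast == "basal_vs_luminal":
        return basal_vs_luminal_de(stacked, species_covariate=True)
    if contrast.startswith("signature:"):
        return signature_de(stacked, contrast.split(":", 1)[1], species_covariate=True)
    raise ValueError(f"unknown contrast {contrast!r}")


def remove_species_batch(stacked: ExpressionMatrix, covariate: pd.Series | None = None) -> ExpressionMatrix:
    """Subtract the fitted species/batch effect, protecting subset effects.

    Fits subset cell-means plus the covariate and removes only the
    covariate's fitted contribution.  Intended for clustering and
    visualization, not inference.
    """
    meta = stacked.sample_meta
    if covariate is None:
        species = sorted(meta["species"].unique())
        covariate = (meta["species"] == species[-1]).astype(float)
    covariate = covariate.reindex(meta.index).astype(float)
    design = subset_design(meta)
    design["__batch__"] = covariate
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("batch covariate is confounded with subset structure")
    fit = fit_linear_model(stacked, design)
    effect = np.outer(fit.coefficients["__batch__"].to_numpy(), covariate.to_numpy())
    values = stacked.values - effect
    return replace(stacked, values=values)


# ---------------------------------------------------------------------------
# Visual summaries


def mds_coordinates(expr: ExpressionMatrix, top_k: int = 500) -> pd.DataFrame:
    """Classical 2-D scaling of pairwise 'typical log-fold-change' distances.

    The distance between two samples is the root-mean-square of the top_k
    largest absolute log2 differences for that pair (top_k capped at the
    probe count).  The sign of each dimension is fixed by making its
    largest-magnitude loading positive.
    """
    values = expr.values.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 3:
        raise ValueError("MDS requires at least 3 samples")
    k = min(top_k, values.shape[0])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (values[:, i] - values[:, j]) ** 2
            top = np.partition(diff2, len(diff2) - k)[len(diff2) - k:]
            D[i, j] = D[j, i] = np.sqrt(top.mean())
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    idx = np.argsort(eigval)[::-1][:2]
    coords = eigvec[:, idx] * np.sqrt(np.maximum(eigval[idx], 0.0))
    for dim in range(coords.shape[1]):
        lead = np.argmax(np.abs(coords[:, dim]))
        if coords[lead, dim] < 0:
            coords[:, dim] = -coords[:, dim]
    return pd.DataFrame(coords, index=expr.samples, columns=["dim1", "dim2"])


def hierarchical_cluster(expr: ExpressionMatrix) -> dict:
    """Average-linkage clustering of samples on Euclidean distances.

    Returns ``{"merges": (n-1, 4) linkage array, "leaf_order": labels}``.
    Sample columns are taken in label-sorted order so ties resolve
    deterministically.
    """
    samples = sorted(expr.samples)
    if len(samples) < 2:
        raise ValueError("clustering requires at least 2 samples")
    values = expr.values[samples].to_numpy(dtype=float)
    d = pdist(values.T, metric="euclidean")
    Z = linkage(d, method="average")
    order = [samples[i] for i in leaves_list(Z)]
    return {"merges": Z, "leaf_order": order}
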