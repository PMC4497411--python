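"""TaqMan Ct preprocessing: reading Ct exports, log2 transform,
housekeeping-weighted cyclic loess normalization and expression filtering.

Ct values are converted to a log2 expression scale as ``E = 40.5 - Ct``
with undetected wells ceilinged at Ct = 40 (so E = 0.5).  Normalization is
all-pairs cyclic loess with housekeeping probes up-weighted (default
100-fold), span 0.7, five iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._loess import weighted_loess

logger = logging.getLogger(__name__)

__all__ = [
    "CtPlateSet",
    "ExpressionMatrix",
    "NormalizationParams",
    "CtFormatError",
    "HOUSEKEEPING_SETS",
    "NEGATIVE_CONTROL_PROBES",
    "read_ct_export",
    "write_ct_export",
    "ct_to_log2",
    "cyclic_loess_normalize",
    "filter_expressed",
]

PROBE_CLASSES = ("target", "housekeeping", "negative_control")

CT_CEILING = 40.0
CT_MAX_VALID = 45.0
LOG2_OFFSET = 40.5

#: Housekeeping small-RNA probes per species.
HOUSEKEEPING_SETS = {
    "mouse": frozenset({"U6"}),
    "human": frozenset({"U6", "RNU6B", "RNU24", "RNU43", "RNU44", "RNU48"}),
}

#: Plant spike-in probe used as a negative control on each plate.
NEGATIVE_CONTROL_PROBES = frozenset({"ath-miR159a"})


class CtFormatError(ValueError):
    """Raised when a Ct export file is malformed."""


@dataclass(frozen=True)
class NormalizationParams:
    """Parameters of the cyclic loess normalization."""

    span: float = 0.7
    iterations: int = 5
    housekeeping_weight: float = 100.0
    method: str = "all-pairs"

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.housekeeping_weight < 1:
            raise ValueError("housekeeping_weight must be >= 1")


@dataclass
class CtPlateSet:
    """Long-format Ct records plus per-sample metadata.

    ``records`` has columns (sample, probe, probe_class, ct);
    ``sample_meta`` is indexed by sample with columns species, subset,
    replicate (extra columns allowed).
    """

    records: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "probe", "probe_class", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise CtFormatError(f"missing required columns: {sorted(missing)}")
        bad_class = set(self.records["probe_class"]) - set(PROBE_CLASSES)
        if bad_class:
            raise CtFormatError(f"unknown probe_class values: {sorted(bad_class)}")
        ct = self.records["ct"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ct)) or ct.min() < 0 or ct.max() > CT_CEILING:
            raise ValueError("Ct values must lie in [0, 40] after reading")
        dup = self.records.duplicated(subset=["sample", "probe"])
        if dup.any():
            pairs = self.records.loc[dup, ["sample", "probe"]].iloc[0]
            raise CtFormatError(
                f"duplicate (sample, probe) rows, e.g. ({pairs['sample']}, {pairs['probe']})"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.sample_meta.index)


@dataclass
class ExpressionMatrix:
    """probe x sample log2 expression with probe classes and sample metadata."""

    values: pd.DataFrame
    probe_class: pd.Series
    sample_meta: pd.DataFrame
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe IDs")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        self.probe_class = self.probe_class.reindex(self.values.index)

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return replace(
            self,
            values=self.values[samples],
            sample_meta=self.sample_meta.loc[samples],
        )

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "probe"
        out.to_csv(path, sep="\t")


def read_ct_export(path, sample_meta: pd.DataFrame | None = None) -> CtPlateSet:
    """Read a Ct export CSV into a :class:`CtPlateSet`.

    Expected columns: sample, probe, probe_class, ct.  "Undetermined" and
    empty Ct entries are coerced to the ceiling Ct = 40.  Optional metadata
    columns (species, subset, replicate) are used to build ``sample_meta``
    when one is not supplied.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["sample", "probe", "probe_class", "ct"]
    for col in required:
        if col not in df.columns:
            raise CtFormatError(f"{path}: missing required column '{col}'")

    raw = df["ct"].str.strip()
    undetected = raw.str.lower().isin({"undetermined", "undet", ""})
    ct = pd.to_numeric(raw.where(~undetected, other=str(CT_CEILING)), errors="coerce")
    if ct.isna().any():
        bad = raw[ct.isna()].iloc[0]
        raise CtFormatError(f"{path}: unparseable Ct value '{bad}'")
    if (ct < 0).any() or (ct > CT_MAX_VALID).any():
        raise ValueError(f"{path}: Ct values outside [0, {CT_MAX_VALID}]")
    ct = ct.clip(upper=CT_CEILING)

    records = pd.DataFrame(
        {
            "sample": df["sample"].str.strip(),
            "probe": df["probe"].str.strip(),
            "probe_class": df["probe_class"].str.strip(),
            "ct": ct.astype(float),
        }
    )

    if sample_meta is None:
        meta_cols = [c for c in ("species", "subset", "replicate") if c in df.columns]
        meta = df[["sample", *meta_cols]].drop_duplicates("sample").set_index("sample")
        sample_meta = meta
    return CtPlateSet(records=records, sample_meta=sample_meta)


def write_ct_export(plates: CtPlateSet, path, undetermined_token: bool = False) -> None:
    """Write a plate set back to the CSV shape read by :func:`read_ct_export`."""
    df = plates.records.copy()
    meta = plates.sample_meta
    for col in meta.columns:
        df[col] = df["sample"].map(meta[col])
    if undetermined_token:
        df["ct"] = df["ct"].map(
            lambda v: "Undetermined" if v >= CT_CEILING else repr(float(v))
        )
    df.to_csv(path, index=False)


def ct_to_log2(plates: CtPlateSet) -> ExpressionMatrix:
    """Transform Ct to log2 expression: ``E = 40.5 - min(Ct, 40)``."""
    rec = plates.records
    expr = rec.assign(value=LOG2_OFFSET - rec["ct"].clip(upper=CT_CEILING))
    values = expr.pivot(index="probe", columns="sample", values="value")
    if values.isna().any().any():
        raise ValueError("every sample must share the same probe universe")
    probe_class = rec.drop_duplicates("probe").set_index("probe")["probe_class"]
    values = values[plates.samples]  # preserve metadata sample order
    return ExpressionMatrix(
        values=values,
        probe_class=probe_class.reindex(values.index),
        sample_meta=plates.sample_meta.copy(),
        normalized=False,
    )


def cyclic_loess_normalize(
    expr: ExpressionMatrix, params: NormalizationParams | None = None
) -> ExpressionMatrix:
    """All-pairs cyclic loess normalization with housekeeping up-weighting.

    Per iteration and for every unordered sample pair (i, j) an MA loess
    (M = E_i - E_j on A = (E_i + E_j)/2) is fitted with housekeeping probes
    up-weighted; the fitted trend, scaled by 1/(2*(n-1)), is accumulated as
    a subtraction from sample i and an addition to sample j.  Adjustments
    are applied at the end of each iteration, so the result is equivariant
    to sample ordering.  Negative-control probes are excluded from the fit
    but adjusted along with everything else.
    """
    if params is None:
        params = NormalizationParams()
    n = len(expr.samples)
    if n < 2:
        warnings.warn("fewer than 2 samples: normalization is a no-op")
        return replace(expr, normalized=True)
    classes = expr.probe_class.to_numpy()
    fit_mask = classes != "negative_control"
    if not fit_mask.any():
        raise ValueError("no probes available to fit the normalization")
    fit_weights = np.where(classes[fit_mask] == "housekeeping", params.housekeeping_weight, 1.0)

    E = expr.values.to_numpy(dtype=float).copy()
    scale = 1.0 / (2.0 * (n - 1))
    for _ in range(params.iterations):
        adjust = np.zeros_like(E)
        for i, j in combinations(range(n), 2):
            m = E[fit_mask, i] - E[fit_mask, j]
            a = 0.5 * (E[fit_mask, i] + E[fit_mask, j])
            fitted = weighted_loess(a, m, weights=fit_weights, span=params.span, max_eval=200)
            # Predict at every probe's A (including excluded controls) by
            # interpolating the fitted trend.
            a_all = 0.5 * (E[:, i] + E[:, j])
            order = np.argsort(a)
            trend = np.interp(a_all, a[order], fitted[order])
            adjust[:, i] -= trend * scale
            adjust[:, j] += trend * scale
        E += adjust

    values = pd.DataFrame(E, index=expr.values.index, columns=expr.values.columns)
    prov = dict(expr.provenance)
    prov["normalization"] = {
        "method": params.method,
        "span": params.span,
        "iterations": params.iterations,
        "housekeeping_weight": params.housekeeping_weight,
    }
    return replace(expr, values=values, normalized=True, provenance=prov)


def filter_expressed(
    expr: ExpressionMatrix, min_value: float = 2.0, min_samples: int = 3
) -> ExpressionMatrix:
    """Keep target probes expressed (value >= min_value) in >= min_samples samples.

    Housekeeping and negative-control probes are dropped from the analysis
    set; the dropped classes are recorded under ``provenance['controls']``.
    """
    classes = expr.probe_class
    is_target = classes == "target"
    counts = (expr.values.ge(min_value)).sum(axis=1)
    keep = is_target & (counts >= min_samples)
    if not keep.any():
        raise ValueError("filter removed every probe")
    prov = dict(expr.provenance)
    prov["controls"] = {
        "housekeeping": list(classes.index[classes == "housekeeping"]),
        "negative_control": list(classes.index[classes == "negative_control"]),
    }
    prov["filter"] = {"min_value": min_value, "min_samples": min_samples}
    return replace(
        expr,
        values=expr.values.loc[keep],
        probe_class=classes.loc[keep],
        provenance=prov,
    )
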