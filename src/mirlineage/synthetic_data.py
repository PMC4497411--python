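"""Synthetic input generators with planted ground truth.

Every pipeline input format (TaqMan Ct plates, mRNA log2 matrices,
miRNA-seq count matrices, ChIP read BEDs with miRNA loci) can be generated
with a known statistical structure so that recovery and null-calibration
tests have an exact truth to compare against.  All generators are
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ct_preprocess import (
    CT_CEILING,
    HOUSEKEEPING_SETS,
    LOG2_OFFSET,
    CtPlateSet,
    ExpressionMatrix,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "DEFAULT_SUBSETS",
    "gen_ct_plates",
    "gen_mrna_matrix",
    "gen_tumor_counts",
    "gen_chip_reads",
    "write_ground_truth",
]

DEFAULT_SUBSETS = ("MaSC/basal", "LP", "ML", "stroma")
EPITHELIAL = ("MaSC/basal", "LP", "ML")

#: documented arbitrary constants
DEFAULT_NB_DISPERSION = 0.1
DEFAULT_HOUSEKEEPING_SD = 0.1


@dataclass
class SyntheticConfig:
    """Knobs for all four generators.  Fields beyond the Ct-plate block are
    used only by the generator they are named after."""

    # Ct plates
    n_probes: int = 400
    n_housekeeping: int = 1
    n_replicates: int = 4
    subsets: tuple = DEFAULT_SUBSETS
    n_planted_per_subset: int = 10
    effect_size: float = 3.0
    noise_sd: float = 0.5
    plate_shift_sd: float = 0.0
    undetected_fraction: float = 0.0
    seed: int = 0
    species: str = "mouse"
    housekeeping_sd: float = DEFAULT_HOUSEKEEPING_SD
    base_low: float = 8.0
    base_high: float = 25.0

    # mRNA matrix
    n_genes: int = 2000
    n_targets_per_mirna: int = 30
    n_decoys_per_mirna: int = 30
    mrna_coupling: float = -1.0
    mrna_noise_sd: float = 0.5
    mrna_replicates: int = 5

    # tumor counts
    subtypes: tuple = ("LumA", "LumB", "Her2", "Basal", "Normal")
    n_tumors_per_subtype: int = 20
    tumor_elevation: float = 2.0
    nb_dispersion: float = DEFAULT_NB_DISPERSION
    tumor_lib_size: int = 1_000_000
    n_background_mirnas: int = 200
    replicate_fraction: float = 0.1
    isoform_fraction: float = 0.1
    subset_to_subtype: tuple = (("MaSC/basal", "Normal"), ("LP", "Basal"), ("ML", "LumB"))

    # ChIP reads
    n_loci: int = 200
    chip_subsets: tuple = ("MaSC/basal", "LP")
    marks: tuple = ("H3K4me3", "H3K27me3")
    coupling_active: float = 0.5
    coupling_repressive: float = -0.5
    reads_per_locus: float = 500.0
    background_reads: int = 2000
    read_length: int = 36
    chip_expr_sd: float = 1.0
    chip_mark_sd: float = 1.0
    locus_width: int = 80
    locus_spacing: int = 20_000
    n_isoform_pairs: int = 5
    genome_size: int = 50_000_000

    def __post_init__(self) -> None:
        if self.n_housekeeping < 1:
            raise ValueError("n_housekeeping must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.undetected_fraction < 1:
            raise ValueError("undetected_fraction must be in [0, 1)")
        if self.n_replicates < 3:
            raise ValueError("at least three replicates per subset are required")


@dataclass
class GroundTruth:
    """Planted effects, filled in progressively by the generators."""

    planted_de: dict = field(default_factory=dict)  # probe -> (subset, signed log2 effect)
    target_truth: dict = field(default_factory=dict)  # miRNA -> list of true target genes
    tumor_truth: dict = field(default_factory=dict)  # miRNA -> (subtype, log2 elevation)
    chip_truth: dict = field(default_factory=dict)  # see gen_chip_reads

    def validate_coupling(self) -> None:
        slopes = self.chip_truth.get("coupling", {})
        if slopes.get("H3K27me3", -1.0) > 0:
            raise ValueError("repressive-mark coupling slope must be <= 0")
        if slopes.get("H3K4me3", 1.0) < 0:
            raise ValueError("active-mark coupling slope must be >= 0")


def _probe_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    prefix = {"mouse": "mmu", "human": "hsa"}.get(config.species, config.species)
    targets = [f"{prefix}-miR-{i:04d}" for i in range(1, config.n_probes + 1)]
    known_hk = sorted(HOUSEKEEPING_SETS.get(config.species, frozenset()))
    hk = (known_hk + [f"HK{i}" for i in range(1, config.n_housekeeping + 1)])[: config.n_housekeeping]
    return targets, hk


def gen_ct_plates(config: SyntheticConfig) -> tuple[CtPlateSet, GroundTruth]:
    """Generate a TaqMan Ct plate set with planted subset-specific probes.

    Expression is simulated on the log2 scale (Gaussian noise), converted to
    Ct = 40.5 - E and clipped to [0, 40].  Housekeeping probes have
    subset-independent means; all probes of a sample share its plate shift.
    A random ``undetected_fraction`` of target-probe wells is forced to the
    Ct = 40 ceiling.
    """
    rng = np.random.default_rng(config.seed)
    targets, hks = _probe_names(config)
    subsets = list(config.subsets)
    samples, subset_of = [], {}
    for sub in subsets:
        for r in range(1, config.n_replicates + 1):
            name = f"{config.species}_{sub.replace('/', '-')}_{r}"
            samples.append(name)
            subset_of[name] = sub

    base = rng.uniform(config.base_low, config.base_high, size=config.n_probes)
    truth = GroundTruth()
    effects = np.zeros((config.n_probes, len(subsets)))
    if config.effect_size > 0 and config.n_planted_per_subset > 0:
        order = rng.permutation(config.n_probes)
        pos = 0
        for si, sub in enumerate(subsets):
            for _ in range(config.n_planted_per_subset):
                if pos >= len(order):
                    break
                g = order[pos]
                pos += 1
                effects[g, si] = config.effect_size
                truth.planted_de[targets[g]] = (sub, float(config.effect_size))

    plate_shift = rng.normal(0.0, config.plate_shift_sd, size=len(samples))
    rows = []
    for j, sample in enumerate(samples):
        si = subsets.index(subset_of[sample])
        e = base + effects[:, si] + rng.normal(0.0, config.noise_sd, size=config.n_probes)
        e = e + plate_shift[j]
        ct = np.clip(LOG2_OFFSET - e, 0.0, CT_CEILING)
        if config.undetected_fraction > 0:
            mask = rng.random(config.n_probes) < config.undetected_fraction
            ct[mask] = CT_CEILING
        for g, probe in enumerate(targets):
            rows.append((sample, probe, "target", ct[g]))
        # housekeeping bases spread over the abundance range so the loess
        # trend is anchored across A
        for hk_i, probe in enumerate(hks):
            hk_base = 12.0 + 12.0 * hk_i / max(1, len(hks) - 1) if len(hks) > 1 else 18.0
            e_hk = hk_base + plate_shift[j] + rng.normal(0.0, config.housekeeping_sd)
            rows.append((sample, probe, "housekeeping", float(np.clip(LOG2_OFFSET - e_hk, 0.0, CT_CEILING))))
        rows.append((sample, "ath-miR159a", "negative_control", CT_CEILING))

    records = pd.DataFrame(rows, columns=["sample", "probe", "probe_class", "ct"])
    meta = pd.DataFrame(
        {
            "species": config.species,
            "subset": [subset_of[s] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return CtPlateSet(records=records, sample_meta=meta), truth


def gen_mrna_matrix(truth: GroundTruth, config: SyntheticConfig) -> tuple[ExpressionMatrix, dict]:
    """Generate an mRNA log2 matrix whose planted-miRNA targets move with
    the opposite sign, plus a target map (true targets + decoys).

    A target gene of a miRNA planted with effect ``e`` in subset ``s``
    receives effect ``mrna_coupling * e`` in that subset.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    subsets = list(EPITHELIAL)
    samples, subset_of = [], {}
    for sub in subsets:
        for r in range(1, config.mrna_replicates + 1):
            name = f"mrna_{sub.replace('/', '-')}_{r}"
            samples.append(name)
            subset_of[name] = sub

    effects = np.zeros((config.n_genes, len(subsets)))
    target_map: dict[str, set] = {}
    planted = [
        (mirna, sub, eff)
        for mirna, (sub, eff) in sorted(truth.planted_de.items())
        if sub in subsets
    ]
    free = list(rng.permutation(config.n_genes))
    for mirna, sub, eff in planted:
        n_t = min(config.n_targets_per_mirna, len(free))
        chosen = [free.pop() for _ in range(n_t)]
        si = subsets.index(sub)
        for g in chosen:
            effects[g, si] += config.mrna_coupling * eff
        tset = {genes[g] for g in chosen}
        decoys = rng.choice(config.n_genes, size=config.n_decoys_per_mirna, replace=False)
        truth.target_truth[mirna] = sorted(tset)
        target_map[mirna] = tset | {genes[g] for g in decoys}

    base = rng.uniform(4.0, 12.0, size=config.n_genes)
    mat = np.empty((config.n_genes, len(samples)))
    for j, sample in enumerate(samples):
        si = subsets.index(subset_of[sample])
        mat[:, j] = base + effects[:, si] + rng.normal(0.0, config.mrna_noise_sd, size=config.n_genes)

    values = pd.DataFrame(mat, index=genes, columns=samples)
    meta = pd.DataFrame(
        {"species": config.species, "subset": [subset_of[s] for s in samples],
         "replicate": [int(s.rsplit("_", 1)[1]) for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    expr = ExpressionMatrix(
        values=values, probe_class=pd.Series("target", index=values.index),
        sample_meta=meta, normalized=True,
    )
    return expr, target_map


def gen_tumor_counts(truth: GroundTruth, config: SyntheticConfig):
    """Generate a tumor miRNA-seq count matrix with subtype-elevated
    signature miRNAs, technical-replicate analyte IDs and isoform rows.

    Returns ``(counts, parent, sample_annot)``: counts is row x sample,
    ``parent`` maps row IDs to parent miRNA symbols, ``sample_annot`` has
    columns (analyte_id, subtype, sample_type).
    """
    rng = np.random.default_rng(config.seed + 2)
    sub_map = dict(config.subset_to_subtype)
    subtypes = list(config.subtypes)
    if len(subtypes) < 2 or config.n_tumors_per_subtype < 2:
        raise ValueError("need >=2 subtypes with >=2 tumors each")

    sig_mirnas = [
        (mirna, sub_map[sub])
        for mirna, (sub, _eff) in sorted(truth.planted_de.items())
        if sub in sub_map
    ]
    background = [f"bg-miR-{i:04d}" for i in range(1, config.n_background_mirnas + 1)]
    mirnas = [m for m, _ in sig_mirnas] + background
    elevated_subtype = {m: st for m, st in sig_mirnas}
    for m, st in sig_mirnas:
        truth.tumor_truth[m] = (st, float(config.tumor_elevation))

    n_mir = len(mirnas)
    rel = 2.0 ** rng.uniform(2.0, 10.0, size=n_mir)  # relative abundances

    columns, analyte, subtype_of = [], {}, {}
    col_specs = []  # (sample_id, subtype, depth_factor)
    for st in subtypes:
        for t in range(1, config.n_tumors_per_subtype + 1):
            aid = f"analyte_{st}_{t}"
            n_cols = 2 if rng.random() < config.replicate_fraction else 1
            for c in range(n_cols):
                sid = f"{aid}_r{c + 1}"
                columns.append(sid)
                analyte[sid] = aid
                subtype_of[sid] = st
                col_specs.append((sid, st, 1.0 / n_cols))

    counts = np.empty((n_mir, len(columns)), dtype=np.int64)
    for j, (sid, st, depth) in enumerate(col_specs):
        lam = rel.copy()
        boost = np.array([m in elevated_subtype and elevated_subtype[m] == st for m in mirnas])
        lam[boost] *= 2.0**config.tumor_elevation
        lam = lam / lam.sum() * config.tumor_lib_size * depth
        if config.nb_dispersion <= 0:
            counts[:, j] = rng.poisson(lam)
        else:
            shape = 1.0 / config.nb_dispersion
            counts[:, j] = rng.poisson(rng.gamma(shape, lam / shape))

    df = pd.DataFrame(counts, index=mirnas, columns=columns)

    # split a fraction of rows into two isoform rows by binomial thinning
    n_iso = int(round(config.isoform_fraction * n_mir))
    iso_rows = sorted(rng.choice(n_mir, size=n_iso, replace=False))
    rows, parents = [], []
    for i, m in enumerate(mirnas):
        if i in iso_rows:
            half = rng.binomial(df.iloc[i].to_numpy(), 0.5)
            rows.append(pd.Series(half, index=columns, name=f"{m}-5p"))
            rows.append(pd.Series(df.iloc[i].to_numpy() - half, index=columns, name=f"{m}-3p"))
            parents += [m, m]
        else:
            rows.append(df.iloc[i])
            parents.append(m)
    out = pd.DataFrame(rows)
    parent = pd.Series(parents, index=out.index)
    annot = pd.DataFrame(
        {
            "analyte_id": [analyte[c] for c in columns],
            "subtype": [subtype_of[c] for c in columns],
            "sample_type": "primary",
        },
        index=pd.Index(columns, name="sample"),
    )
    return out, parent, annot


def gen_chip_reads(truth: GroundTruth, config: SyntheticConfig):
    """Generate miRNA loci and ChIP reads with mark effects coupled to
    per-locus expression log2 fold changes.

    For each locus an expression log2FC (between the two chip subsets) is
    drawn; the mark log2FC is ``expr_logfc / coupling`` plus noise so that
    regressing expression on mark counts through the origin recovers the
    coupling slope.  Isoform pairs share one genomic interval; reads are
    generated once per interval.

    Returns ``(loci, reads, expr_logfc)``: loci is a BED-like frame with a
    ``partner`` column, ``reads`` maps (subset, mark) to a BED-like frame,
    and ``expr_logfc`` is a per-symbol Series of planted expression log2FCs
    (first chip subset vs second).
    """
    rng = np.random.default_rng(config.seed + 3)
    if len(config.chip_subsets) != 2:
        raise ValueError("exactly two subsets are compared")
    coupling = {"H3K4me3": config.coupling_active, "H3K27me3": config.coupling_repressive}
    truth.chip_truth["coupling"] = dict(coupling)
    truth.validate_coupling()

    n = config.n_loci
    symbols = [f"chip-miR-{i:04d}" for i in range(1, n + 1)]
    starts = 10_000 + np.arange(n) * config.locus_spacing
    loci_rows = []
    iso = set(rng.choice(n, size=min(config.n_isoform_pairs, n), replace=False).tolist())
    for i, sym in enumerate(symbols):
        s, e = int(starts[i]), int(starts[i] + config.locus_width)
        if i in iso:
            loci_rows.append((f"{sym}-5p", "chr1", s, e, "+", f"{sym}-3p"))
            loci_rows.append((f"{sym}-3p", "chr1", s, e, "+", f"{sym}-5p"))
        else:
            loci_rows.append((sym, "chr1", s, e, "+", ""))
    loci = pd.DataFrame(loci_rows, columns=["symbol", "chrom", "start", "end", "strand", "partner"])

    expr_fc = rng.normal(0.0, config.chip_expr_sd, size=n)
    mark_fc = {}
    for mark in config.marks:
        c = coupling.get(mark, 0.0)
        if c == 0.0:
            mark_fc[mark] = rng.normal(0.0, config.chip_mark_sd, size=n)
        else:
            mark_fc[mark] = expr_fc / c
    # per-record maps: isoform partners share their parent locus's effects
    record_of = {i: [r[0] for r in loci_rows if r[0].startswith(symbols[i])] for i in range(n)}
    truth.chip_truth["mark_logfc"] = {
        mark: {rec: float(fc[i]) for i in range(n) for rec in record_of[i]}
        for mark, fc in mark_fc.items()
    }
    truth.chip_truth["expr_logfc"] = {
        rec: float(expr_fc[i]) for i in range(n) for rec in record_of[i]
    }

    reads: dict[tuple[str, str], pd.DataFrame] = {}
    flank = 1000
    for mark in config.marks:
        for k, subset in enumerate(config.chip_subsets):
            sign = +0.5 if k == 0 else -0.5
            lam = config.reads_per_locus * 2.0 ** (sign * mark_fc[mark])
            chrom, rstart = [], []
            for i in range(n):
                cnt = rng.poisson(lam[i])
                lo = max(0, int(starts[i]) - flank)
                hi = int(starts[i]) + config.locus_width + flank
                pos = rng.integers(lo, hi, size=cnt)
                chrom += ["chr1"] * cnt
                rstart.append(pos)
            bg = rng.integers(0, config.genome_size, size=config.background_reads)
            rstart.append(bg)
            chrom += ["chr1"] * config.background_reads
            start_arr = np.concatenate(rstart) if rstart else np.empty(0, dtype=int)
            frame = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start_arr,
                    "end": start_arr + config.read_length,
                    "name": [f"read{i}" for i in range(len(start_arr))],
                    "score": 0,
                    "strand": "+",
                }
            )
            reads[(subset, mark)] = frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    expr_logfc = pd.Series(truth.chip_truth["expr_logfc"])
    return loci, reads, expr_logfc


# ---------------------------------------------------------------------------
# Writers (all plain text)


def write_matrix_tsv(values: pd.DataFrame, path, index_name: str = "probe") -> None:
    out = values.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def write_bed(frame: pd.DataFrame, path, name_col: str = "name") -> None:
    cols = ["chrom", "start", "end", name_col, "score" if "score" in frame else None, "strand"]
    bed = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": frame["start"],
            "end": frame["end"],
            "name": frame[name_col] if name_col in frame else ".",
            "score": frame["score"] if "score" in frame else 0,
            "strand": frame["strand"] if "strand" in frame else "+",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Flat key-value text dump of the ground truth."""
    lines = []
    for probe, (sub, eff) in sorted(truth.planted_de.items()):
        lines.append(f"planted_de\t{probe}\t{sub}\t{eff}")
    for mirna, genes in sorted(truth.target_truth.items()):
        lines.append(f"target_truth\t{mirna}\t{','.join(genes)}")
    for mirna, (st, eff) in sorted(truth.tumor_truth.items()):
        lines.append(f"tumor_truth\t{mirna}\t{st}\t{eff}")
    for mark, slope in sorted(truth.chip_truth.get("coupling", {}).items()):
        lines.append(f"chip_coupling\t{mark}\t{slope}")
    Path(path).write_text("\n".join(lines) + "\n")
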