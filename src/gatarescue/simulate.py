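"""Synthetic rescue-assay data generator.

Emulates the statistical structure of a transcription-factor genetic-rescue
experiment in enhancer-knockout hematopoietic progenitors: four conditions
(wild type + empty vector, knockout + empty vector, knockout + wild-type
factor, knockout + pathogenic variant), four replicates each, negative-
binomial RNA counts with designed per-gene regulatory categories, ATAC-like
peaks whose accessibility shifts track those categories, and random DNA
peak sequences with GATA/E-box/ETS/EBF motifs planted at category-dependent
densities.

All randomness flows from one seed through fixed, named sub-streams, so
adding a stage never perturbs the draws of an earlier stage and identical
configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("WT_empty", "KO_empty", "KO_rescue", "KO_variant")

#: Regulatory ground-truth categories. "shared" = regulated by both the
#: wild-type factor and the variant; "ectopic" = regulated by the variant
#: only; "enhancer_only" = responds to enhancer loss but not to re-expression.
CATEGORIES = (
    "gata2_only_activated",
    "shared_activated",
    "gata2_only_repressed",
    "shared_repressed",
    "ectopic_activated",
    "ectopic_repressed",
    "enhancer_only",
    "unregulated",
)

# Default category proportions chosen so that expected class sizes at
# n_genes=14,000 approximate the published rescue-assay DEG tallies
# (1,061 factor-activated of which 144 shared; 1,077 factor-repressed of
# which 381 shared; 132/282 ectopic; ~1,168 enhancer-only).
DEFAULT_PROPORTIONS = {
    "gata2_only_activated": 917 / 14000,
    "shared_activated": 144 / 14000,
    "gata2_only_repressed": 696 / 14000,
    "shared_repressed": 381 / 14000,
    "ectopic_activated": 132 / 14000,
    "ectopic_repressed": 282 / 14000,
    "enhancer_only": 1168 / 14000,
}

#: IUPAC consensus strings for the default planted motif families.
DEFAULT_MOTIF_CONSENSI = {
    "WGATAR": "WGATAR",
    "Ebox": "CANNTG",
    "ETS": "AGGAAR",
    "EBF": "TCCCNNGGGA",
}

# Planted occurrences per kb by peak class. "activated"/"repressed" refer to
# the regulatory side of the peak's linked gene; "neutral" is everything else.
DEFAULT_MOTIF_DENSITIES = {
    "WGATAR": {"activated": 2.0, "repressed": 0.5, "neutral": 0.5},
    "Ebox": {"activated": 1.0, "repressed": 0.5, "neutral": 0.5},
    "ETS": {"activated": 0.5, "repressed": 1.5, "neutral": 0.5},
    "EBF": {"activated": 0.2, "repressed": 1.0, "neutral": 0.2},
}

DEFAULT_PEAK_LINK_PROBABILITIES = {
    "activated": {"opening": 0.35, "closing": 0.086},
    "repressed": {"opening": 0.05, "closing": 0.40},
    "neutral": {"opening": 0.01, "closing": 0.01},
}

# Fixed sub-stream indices; append-only so earlier stages stay reproducible.
_STREAMS = {
    "annotation": 0,
    "truth": 1,
    "counts": 2,
    "peaks": 3,
    "sequences": 4,
    "occupancy": 5,
}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic rescue experiment."""

    n_genes: int = 14000
    n_replicates: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    #: |log2 fold change| magnitude of the rescue (or, for ectopic genes,
    #: variant) contrast per category.
    effect_size_lfc: Mapping[str, float] = field(
        default_factory=lambda: {c: 2.5 for c in CATEGORIES if c != "unregulated"}
    )
    #: Variant effect relative to the wild-type factor at shared genes, on the
    #: log2FC scale (published medians: 65% for activation, 56% for repression).
    variant_retained_activation: float = 0.65
    variant_retained_repression: float = 0.56
    #: Probability that a factor-regulated gene also responds to enhancer loss
    #: (the Venn overlap 916/2138 in the published three-way comparison).
    enhancer_coregulation_prob: float = 0.43
    #: NB dispersion alpha (variance = mu + alpha * mu^2); scalar or
    #: (low, high) range sampled log-uniformly per gene.
    dispersion: float | tuple[float, float] = 0.05
    #: Target library totals, drawn log-uniformly per sample.
    library_size_range: tuple[float, float] = (2e6, 4e6)
    #: log2 of per-gene baseline mean drawn uniformly in this range.
    baseline_log2_range: tuple[float, float] = (2.0, 10.0)
    peak_rate: float = 2.0
    peak_width: int = 400
    peak_max_offset: int = 25000
    #: log2 of per-peak baseline accessibility drawn uniformly in this range.
    peak_baseline_log2_range: tuple[float, float] = (4.0, 8.0)
    peak_shift_lfc: float = 2.5
    peak_link_probabilities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_PEAK_LINK_PROBABILITIES.items()
        }
    )
    motif_consensi: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_CONSENSI)
    )
    motif_densities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_MOTIF_DENSITIES.items()
        }
    )
    # Occupancy-set generation (CUT&Tag-like): probability a factor peak is
    # placed at a regulated gene, probability the variant retains it, and the
    # probability a peak sequence receives one extra planted WGATAR.
    occupancy_prob: Mapping[str, float] = field(
        default_factory=lambda: {"activated": 561 / 1061, "repressed": 190 / 1077}
    )
    occupancy_retention: Mapping[str, float] = field(
        default_factory=lambda: {"activated": 33 / 561, "repressed": 20 / 190}
    )
    occupancy_wgatar_plant_prob: Mapping[str, float] = field(
        default_factory=lambda: {"activated": 0.40, "repressed": 0.30}
    )
    occupancy_peak_width: int = 300
    gene_length_log10_range: tuple[float, float] = (2.7, 4.7)
    genome_size: int = 1_000_000_000
    chromosome: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be nonnegative")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be positive")
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        if any(p < 0 for p in self.category_proportions.values()):
            raise ConfigurationError("category proportions must be nonnegative")
        if sum(self.category_proportions.values()) > 1 + 1e-12:
            raise ConfigurationError("category proportions sum to more than 1")
        if any(m < 0 for m in self.effect_size_lfc.values()):
            raise ConfigurationError("effect sizes must be nonnegative")
        if self.library_size_range[0] <= 0:
            raise ConfigurationError("library sizes must be positive")
        if self.peak_width > self.genome_size:
            raise ConfigurationError("peak width exceeds genome size")
        if self.genome_size < 1:
            raise ConfigurationError("genome_size must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Seeded generator for a named stage sub-stream."""
        key = _STREAMS[stage]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


@dataclass
class SimTruth:
    """Ground truth emitted by the generator.

    ``genes`` carries one row per gene: the true category, the true log2
    fold change for each of the three contrasts (positive = activated by
    the enhancer / factor / variant), and the baseline mean in the
    knockout-empty condition. ``peaks`` and ``motifs`` are filled by
    :func:`simulate_peaks_and_sequences`.
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame | None = None
    motifs: pd.DataFrame | None = None


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Minimal gene annotation: id, chromosome, strand, TSS (0-based), length."""
    config.validate()
    rng = config.rng("annotation")
    n = config.n_genes
    gene_ids = [f"g{i:06d}" for i in range(n)]
    tss = rng.integers(0, config.genome_size, size=n)
    strand = rng.choice(np.array(["+", "-"]), size=n)
    lo, hi = config.gene_length_log10_range
    length = np.maximum(1, np.round(10 ** rng.uniform(lo, hi, size=n))).astype(int)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": config.chromosome,
            "strand": strand,
            "tss": tss,
            "length": length,
        }
    ).set_index("gene_id", drop=False)


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw per-gene categories and contrast-consistent true log2 fold changes."""
    config.validate()
    rng = config.rng("truth")
    n = config.n_genes

    cats = list(config.category_proportions)
    probs = [config.category_proportions[c] for c in cats]
    cats.append("unregulated")
    probs.append(max(0.0, 1.0 - sum(probs)))
    category = rng.choice(np.array(cats, dtype=object), size=n, p=np.asarray(probs) / sum(probs))

    lfc_enh = np.zeros(n)
    lfc_rescue = np.zeros(n)
    lfc_variant = np.zeros(n)
    coreg = rng.random(n) < config.enhancer_coregulation_prob
    enh_sign = rng.choice(np.array([1.0, -1.0]), size=n)

    for cat in CATEGORIES:
        idx = np.flatnonzero(category == cat)
        if idx.size == 0 or cat == "unregulated":
            continue
        m = float(config.effect_size_lfc.get(cat, 0.0))
        if cat == "enhancer_only":
            lfc_enh[idx] = m * enh_sign[idx]
        elif cat.startswith("ectopic"):
            sign = 1.0 if cat.endswith("activated") else -1.0
            lfc_variant[idx] = sign * m
        else:
            sign = 1.0 if cat.endswith("activated") else -1.0
            lfc_rescue[idx] = sign * m
            if cat.startswith("shared"):
                retained = (
                    config.variant_retained_activation
                    if sign > 0
                    else config.variant_retained_repression
                )
                lfc_variant[idx] = retained * lfc_rescue[idx]
            # Enhancer loss removes the factor's effect at a subset of its
            # targets (one global dosage latent; see methods note).
            lfc_enh[idx] = np.where(coreg[idx], lfc_rescue[idx], 0.0)

    lo, hi = config.baseline_log2_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=n)

    if isinstance(config.dispersion, tuple):
        dlo, dhi = config.dispersion
        alpha = np.exp(rng.uniform(np.log(dlo), np.log(dhi), size=n))
    else:
        alpha = np.full(n, float(config.dispersion))

    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:06d}" for i in range(n)],
            "category": category,
            "lfc_enh": lfc_enh,
            "lfc_rescue": lfc_rescue,
            "lfc_variant": lfc_variant,
            "baseline": baseline,
            "dispersion": alpha,
        }
    ).set_index("gene_id", drop=False)
    return SimTruth(genes=genes)


def sample_table(config: SimConfig) -> pd.DataFrame:
    """Sample-to-condition map with stable sample names cond_rep."""
    rows = [
        {"sample": f"{cond}_{r + 1}", "condition": cond}
        for cond in config.conditions
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(rows).set_index("sample", drop=False)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, variance = mu + alpha*mu^2) draws; Poisson limit as alpha -> 0."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = alpha < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def _condition_means(truth: SimTruth) -> pd.DataFrame:
    """Expected expression per condition; KO_empty is the baseline."""
    g = truth.genes
    return pd.DataFrame(
        {
            "WT_empty": g["baseline"] * 2.0 ** g["lfc_enh"],
            "KO_empty": g["baseline"],
            "KO_rescue": g["baseline"] * 2.0 ** g["lfc_rescue"],
            "KO_variant": g["baseline"] * 2.0 ** g["lfc_variant"],
        },
        index=g.index,
    )


def simulate_counts(
    config: SimConfig, truth: SimTruth, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Gene x sample integer count table under the NB model.

    Per-gene mean in condition c is baseline * 2^(true log2FC to c) times a
    per-sample library factor drawn log-uniformly from ``library_size_range``
    (normalized to the expected baseline total).
    """
    config.validate()
    if not truth.genes.index.equals(annotation.index):
        raise ConfigurationError("truth and annotation must cover the same genes")
    rng = config.rng("counts")
    samples = sample_table(config)
    means = _condition_means(truth)

    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    base_total = float(means["KO_empty"].sum())
    factors = lib / base_total if base_total > 0 else np.ones_like(lib)

    alpha = truth.genes["dispersion"].to_numpy()
    cols = {}
    for s, f in zip(samples["sample"], factors):
        cond = samples.loc[s, "condition"]
        mu = means[cond].to_numpy() * f
        cols[s] = _nb_draw(rng, mu, alpha)
    return pd.DataFrame(cols, index=truth.genes.index)


def realize_iupac(rng: np.random.Generator, consensus: str) -> str:
    """One concrete instance of an IUPAC consensus (N -> uniform base)."""
    return "".join(rng.choice(list(_IUPAC[c])) for c in consensus.upper())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _gene_side(category: str) -> str:
    if category.endswith("_activated"):
        return "activated"
    if category.endswith("_repressed"):
        return "repressed"
    return "neutral"


def simulate_peaks_and_sequences(
    config: SimConfig, truth: SimTruth, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, str], SimTruth]:
    """Peaks with NB accessibility counts plus peak DNA with planted motifs.

    Each gene receives Poisson(``peak_rate``) peaks placed within
    ``peak_max_offset`` of its TSS (half-open intervals, clipped to the
    genome). For regulated genes, one peak may carry a true accessibility
    shift (opening/closing) with the configured per-side link probabilities;
    for shared genes the variant-contrast shift is scaled by the retained
    fraction, and for ectopic genes only the variant contrast shifts.
    Sequences are uniform-random DNA with motif instances planted per kb at
    class-dependent densities; every plant is recorded in the manifest.

    Returns (peak count table with interval columns, sequences by peak id,
    truth updated with per-peak ground truth and the motif manifest).
    """
    config.validate()
    if config.peak_width > config.genome_size:
        raise ConfigurationError("peak width exceeds genome size")
    rng = config.rng("peaks")
    genes = truth.genes

    records = []
    for gene_id, cat, tss in zip(genes["gene_id"], genes["category"], annotation["tss"]):
        n_peaks = rng.poisson(config.peak_rate)
        if n_peaks == 0:
            continue
        side = _gene_side(cat)
        link = config.peak_link_probabilities.get(side, {})
        u = rng.random()
        p_open = link.get("opening", 0.0)
        p_close = link.get("closing", 0.0)
        if u < p_open:
            event = "opening"
        elif u < p_open + p_close:
            event = "closing"
        else:
            event = "none"
        event_peak = rng.integers(n_peaks) if event != "none" else -1
        for j in range(n_peaks):
            offset = int(rng.integers(-config.peak_max_offset, config.peak_max_offset + 1))
            start = int(np.clip(tss + offset, 0, config.genome_size - config.peak_width))
            shift_rescue = 0.0
            shift_variant = 0.0
            if j == event_peak:
                shift = config.peak_shift_lfc if event == "opening" else -config.peak_shift_lfc
                if cat.startswith("ectopic"):
                    shift_variant = shift
                else:
                    shift_rescue = shift
                    if cat.startswith("shared"):
                        retained = (
                            config.variant_retained_activation
                            if cat.endswith("activated")
                            else config.variant_retained_repression
                        )
                        shift_variant = retained * shift
            records.append(
                {
                    "gene_id": gene_id,
                    "start": start,
                    "end": start + config.peak_width,
                    "shift_rescue": shift_rescue,
                    "shift_variant": shift_variant,
                    "side": side,
                }
            )

    peak_truth = pd.DataFrame(
        records,
        columns=["gene_id", "start", "end", "shift_rescue", "shift_variant", "side"],
    )
    peak_truth.insert(0, "peak_id", [f"peak{i:06d}" for i in range(len(peak_truth))])
    peak_truth.insert(1, "chrom", config.chromosome)
    peak_truth = peak_truth.set_index("peak_id", drop=False)

    # Accessibility counts: same NB machinery, conditions share the library
    # factors' scale (drawn fresh here — ATAC libraries are independent).
    samples = sample_table(config)
    n_peaks = len(peak_truth)
    lo, hi = config.peak_baseline_log2_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=n_peaks)
    alpha = (
        float(config.dispersion)
        if not isinstance(config.dispersion, tuple)
        else float(np.sqrt(config.dispersion[0] * config.dispersion[1]))
    )
    cond_mu = {
        "WT_empty": baseline * 2.0 ** peak_truth["shift_rescue"].to_numpy(),
        "KO_empty": baseline,
        "KO_rescue": baseline * 2.0 ** peak_truth["shift_rescue"].to_numpy(),
        "KO_variant": baseline * 2.0 ** peak_truth["shift_variant"].to_numpy(),
    }
    lib_factors = np.exp(rng.uniform(np.log(0.8), np.log(1.25), size=len(samples)))
    counts = {}
    for s, f in zip(samples["sample"], lib_factors):
        cond = samples.loc[s, "condition"]
        counts[s] = _nb_draw(rng, cond_mu[cond] * f, np.full(n_peaks, alpha))
    peak_counts = pd.DataFrame(counts, index=peak_truth.index)
    peak_table = pd.concat(
        [peak_truth[["peak_id", "chrom", "start", "end"]], peak_counts], axis=1
    )

    # Sequence class for motif planting follows the linked gene's side, but
    # only peaks that actually carry a shift count as activated/repressed.
    shifted = (peak_truth["shift_rescue"] != 0) | (peak_truth["shift_variant"] != 0)
    seq_class = np.where(shifted, peak_truth["side"], "neutral")

    seq_rng = config.rng("sequences")
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    manifest_rows = []
    for peak_id, cls, width in zip(
        peak_truth["peak_id"], seq_class, peak_truth["end"] - peak_truth["start"]
    ):
        seq = list(seq_rng.choice(bases, size=width))
        for motif, consensus in config.motif_consensi.items():
            density = config.motif_densities.get(motif, {}).get(cls, 0.0)
            k = seq_rng.poisson(density * width / 1000.0)
            m = len(consensus)
            for _ in range(k):
                if width < m:
                    break
                pos = int(seq_rng.integers(0, width - m + 1))
                instance = realize_iupac(seq_rng, consensus)
                strand = "+" if seq_rng.random() < 0.5 else "-"
                planted = instance if strand == "+" else reverse_complement(instance)
                seq[pos : pos + m] = list(planted)
                manifest_rows.append(
                    {"seq_id": peak_id, "motif": motif, "start": pos, "strand": strand}
                )
        sequences[peak_id] = "".join(seq)

    manifest = pd.DataFrame(manifest_rows, columns=["seq_id", "motif", "start", "strand"])
    updated = SimTruth(genes=truth.genes, peaks=peak_truth, motifs=manifest)
    return peak_table, sequences, updated


def simulate_occupancy(
    config: SimConfig, truth: SimTruth, annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Factor and variant occupancy peak sets (CUT&Tag-like) with sequences.

    Factor peaks are placed near the TSS of factor-regulated genes with a
    per-side occupancy probability; the variant retains each factor peak with
    a small per-side retention probability and additionally gains peaks at
    ectopically regulated genes. Each returned frame carries BED-like interval
    columns plus the peak sequence (random DNA, optionally with one extra
    planted WGATAR instance).
    """
    config.validate()
    rng = config.rng("occupancy")
    genes = truth.genes
    bases = np.array(list("ACGT"))
    width = config.occupancy_peak_width

    def _make_peak(gene_id: str, label: str, idx: int, side: str) -> dict:
        tss = int(annotation.loc[gene_id, "tss"])
        offset = int(rng.integers(-2000, 2001))
        start = int(np.clip(tss + offset, 0, config.genome_size - width))
        seq = list(rng.choice(bases, size=width))
        if rng.random() < config.occupancy_wgatar_plant_prob.get(side, 0.0):
            pos = int(rng.integers(0, width - 6 + 1))
            seq[pos : pos + 6] = list(realize_iupac(rng, "WGATAR"))
        return {
            "peak_id": f"{label}_occ{idx:05d}",
            "chrom": config.chromosome,
            "start": start,
            "end": start + width,
            "gene_id": gene_id,
            "side": side,
            "sequence": "".join(seq),
        }

    factor_rows, variant_rows = [], []
    fi = vi = 0
    for gene_id, cat in zip(genes["gene_id"], genes["category"]):
        side = _gene_side(cat)
        if cat.startswith(("gata2_only", "shared")):
            if rng.random() < config.occupancy_prob.get(side, 0.0):
                peak = _make_peak(gene_id, "factor", fi, side)
                factor_rows.append(peak)
                fi += 1
                if rng.random() < config.occupancy_retention.get(side, 0.0):
                    retained = dict(peak)
                    retained["peak_id"] = f"variant_occ{vi:05d}"
                    variant_rows.append(retained)
                    vi += 1
        elif cat.startswith("ectopic"):
            if rng.random() < 0.10:
                variant_rows.append(_make_peak(gene_id, "variant", vi, side))
                vi += 1

    cols = ["peak_id", "chrom", "start", "end", "gene_id", "side", "sequence"]
    factor = pd.DataFrame(factor_rows, columns=cols)
    variant = pd.DataFrame(variant_rows, columns=cols)
    return {"factor": factor.set_index("peak_id", drop=False) if len(factor) else factor,
            "variant": variant.set_index("peak_id", drop=False) if len(variant) else variant}


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable form of a SimConfig."""
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    kwargs = dict(d)
    for k in (
        "conditions",
        "dispersion",
        "library_size_range",
        "baseline_log2_range",
        "peak_baseline_log2_range",
        "gene_length_log10_range",
    ):
        if k in kwargs and isinstance(kwargs[k], list):
            kwargs[k] = tuple(kwargs[k])
    return SimConfig(**kwargs)
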