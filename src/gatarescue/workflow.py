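"""Configuration-driven end-to-end pipeline.

Stages run in a fixed order — simulate/ingest, the three expression
contrasts, the regulatory catalog, chromatin integration, motif grammar
statistics, occupancy integration, summaries — and the report layer only
collects numbers the stage functions already computed (rounding happens
here and nowhere upstream). Synthetic mode additionally emits
truth-versus-inferred confusion tables and the category recovery rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, diffexpr, io, motifs, occupancy, regclass, simulate

logger = logging.getLogger("gatarescue")

#: truth category -> expected catalog class
TRUTH_TO_CATEGORY = {
    "gata2_only_activated": "I.II",
    "shared_activated": "I.I",
    "gata2_only_repressed": "II.II",
    "shared_repressed": "II.I",
    "ectopic_activated": "III",
    "ectopic_repressed": "IV",
    "enhancer_only": "none",
    "unregulated": "none",
}

CONTRAST_PAIRS = {
    "enhancer": ("KO_empty", "WT_empty"),
    "rescue": ("KO_empty", "KO_rescue"),
    "variant": ("KO_empty", "KO_variant"),
}


@dataclass
class PipelineConfig:
    """Exactly one of ``sim`` (synthetic mode) or ``inputs`` (file paths)."""

    sim: simulate.SimConfig | None = None
    inputs: dict[str, str] | None = None
    lfc_min: float = 1.0
    alpha: float = 0.05
    tpm_min: float = 1.0
    spacer_bounds: tuple[int, int] = (6, 14)
    double_spacer_max: int = 5
    promoter_window: tuple[int, int] = (-2000, 100)
    max_link_dist: int | None = 100_000
    percent_decimals: int = 0
    seed: int | None = None
    outdir: str | None = None

    def validate(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim / inputs must be set")
        for name in ("lfc_min", "alpha", "tpm_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Pre-flight checks on real-data inputs (or the synthetic config).

    Fatal: malformed BED lines (start >= end, with line numbers), a missing
    condition, fewer than 2 replicates of a condition. Warning: FASTA ids
    that do not match peak ids (analysis then proceeds on the intersection),
    chromosome names present in one file but not another.
    """
    report = ValidationReport()
    if config.sim is not None:
        try:
            config.sim.validate()
        except simulate.ConfigurationError as exc:
            report.errors.append(str(exc))
        return report
    paths = config.inputs or {}
    samples = None
    if "counts" in paths:
        try:
            _, samples = io.read_counts_tsv(paths["counts"])
        except Exception as exc:  # malformed table is fatal
            report.errors.append(f"counts unreadable: {exc}")
    if samples is not None:
        present = set(samples["condition"])
        for cond in simulate.CONDITIONS:
            if cond not in present:
                report.errors.append(f"missing condition: {cond}")
            elif (samples["condition"] == cond).sum() < 2:
                report.errors.append(f"condition {cond} has fewer than 2 replicates")
    chrom_sets = {}
    if "peaks_bed" in paths:
        with open(paths["peaks_bed"]) as fh:
            chroms = set()
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except (IndexError, ValueError):
                    report.errors.append(f"peaks_bed line {lineno}: malformed BED line")
                    continue
                if start >= end:
                    report.errors.append(
                        f"peaks_bed line {lineno}: start >= end ({start} >= {end})"
                    )
                chroms.add(fields[0])
            chrom_sets["peaks_bed"] = chroms
    if "annotation" in paths:
        try:
            ann = io.read_annotation_tsv(paths["annotation"])
            chrom_sets["annotation"] = set(ann["chrom"])
        except Exception as exc:
            report.errors.append(f"annotation unreadable: {exc}")
    if len(chrom_sets) > 1:
        names = list(chrom_sets)
        for other in names[1:]:
            if chrom_sets[names[0]] != chrom_sets[other]:
                report.warnings.append(
                    f"chromosome names differ between {names[0]} and {other}"
                )
    if "fasta" in paths and "peaks_bed" in paths:
        seqs = io.read_fasta(paths["fasta"])
        peaks = io.read_bed6(paths["peaks_bed"])
        missing = set(peaks["peak_id"]) - set(seqs)
        if missing:
            report.warnings.append(
                f"{len(missing)} peak ids missing from FASTA; using the intersection"
            )
    return report


def _sanitize(obj):
    """JSON-safe deep copy: numpy scalars -> python, NaN/inf -> None."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_digest(report: dict) -> str:
    payload = json.dumps(_sanitize(report), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _cohort_sets(catalog: pd.DataFrame) -> dict[str, set[str]]:
    if len(catalog) == 0:
        keys = ["factor_activated", "factor_repressed", "mutual_activated",
                "mutual_repressed", "ectopic_activated", "ectopic_repressed"]
        return {k: set() for k in keys}
    act = catalog["category_activated"]
    rep = catalog["category_repressed"]
    gid = catalog["gene_id"]
    return {
        "factor_activated": set(gid[act.isin(["I.I", "I.II"])]),
        "factor_repressed": set(gid[rep.isin(["II.I", "II.II"])]),
        "mutual_activated": set(gid[act == "I.I"]),
        "mutual_repressed": set(gid[rep == "II.I"]),
        "ectopic_activated": set(gid[act == "III"]),
        "ectopic_repressed": set(gid[rep == "IV"]),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the report bundle.

    Deterministic given the configuration seed; every intermediate is
    serialized under ``outdir`` when set. A stage failure raises with the
    stage name in the log, leaving earlier outputs in place.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        for sub in ("inputs", "contrasts", "catalog", "chromatin", "motifs",
                    "occupancy", "report"):
            (outdir / sub).mkdir(parents=True, exist_ok=True)

    report: dict = {"mode": "synthetic" if config.sim else "real"}

    logger.info("stage: ingest")
    if config.sim is not None:
        sim_config = config.sim
        if config.seed is not None:
            sim_config = dataclasses.replace(sim_config, seed=config.seed)
        annotation = simulate.simulate_annotation(sim_config)
        truth = simulate.simulate_truth(sim_config)
        counts = simulate.simulate_counts(sim_config, truth, annotation)
        samples = simulate.sample_table(sim_config)
        peak_table, sequences, truth = simulate.simulate_peaks_and_sequences(
            sim_config, truth, annotation
        )
        occ_sets = simulate.simulate_occupancy(sim_config, truth, annotation)
        if outdir:
            io.write_config_yaml(sim_config, outdir / "inputs" / "sim_config.yaml")
            io.write_counts_tsv(counts, samples, outdir / "inputs" / "counts.tsv")
            io.write_annotation_tsv(annotation, outdir / "inputs" / "annotation.tsv")
            io.write_bed6(peak_table, outdir / "inputs" / "peaks.bed")
            io.write_fasta(sequences, outdir / "inputs" / "peaks.fasta")
            io.write_truth_json(truth, outdir / "inputs" / "truth.json")
    else:
        paths = config.inputs
        counts, samples = io.read_counts_tsv(paths["counts"])
        annotation = io.read_annotation_tsv(paths["annotation"])
        peak_bed = io.read_bed6(paths["peaks_bed"]) if "peaks_bed" in paths else None
        peak_counts_df = (
            pd.read_csv(paths["peak_counts"], sep="\t", index_col="peak_id")
            if "peak_counts" in paths
            else None
        )
        peak_table = None
        if peak_bed is not None and peak_counts_df is not None:
            peak_table = peak_bed[["peak_id", "chrom", "start", "end"]].join(
                peak_counts_df
            )
        sequences = io.read_fasta(paths["fasta"]) if "fasta" in paths else {}
        truth = None
        occ_sets = None
        if "occupancy_factor" in paths and "occupancy_variant" in paths:
            occ_sets = {
                "factor": io.read_bed6(paths["occupancy_factor"]),
                "variant": io.read_bed6(paths["occupancy_variant"]),
            }

    by_cond = {
        c: list(samples.loc[samples["condition"] == c, "sample"])
        for c in simulate.CONDITIONS
    }

    logger.info("stage: contrasts")
    tpm = diffexpr.compute_tpm(counts, annotation["length"]) if len(counts) else counts * 0.0
    sf = (
        diffexpr.size_factors(counts, pseudo_reference=True)
        if len(counts)
        else pd.Series(1.0, index=counts.columns)
    )
    contrasts: dict[str, pd.DataFrame] = {}
    degs: dict[str, diffexpr.DEGSet] = {}
    for name, (cond_a, cond_b) in CONTRAST_PAIRS.items():
        if len(counts):
            res = diffexpr.nb_wald_contrast(
                counts, by_cond[cond_a], by_cond[cond_b], size_factors_=sf, tpm=tpm
            )
        else:
            res = pd.DataFrame(columns=diffexpr.CONTRAST_COLUMNS)
        contrasts[name] = res
        degs[name] = diffexpr.call_degs(res, lfc_min=config.lfc_min, alpha=config.alpha)
        if outdir:
            io.write_contrast_tsv(res, outdir / "contrasts" / f"{name}.tsv")
    report["deg_counts"] = {
        name: {"activated": len(d.activated), "repressed": len(d.repressed)}
        for name, d in degs.items()
    }

    logger.info("stage: catalog")
    catalog = regclass.build_catalog(degs["enhancer"], degs["rescue"], degs["variant"])
    counts_by_class = regclass.category_counts(catalog)
    report["category_counts"] = counts_by_class
    report["venn_counts"] = {
        side: regclass.venn_counts(catalog, side) for side in ("activated", "repressed")
    }
    report["fraction_summary"] = regclass.summarize_fractions(counts_by_class).to_dict(
        orient="records"
    )
    report["rescue_fraction"] = regclass.rescue_fraction(
        contrasts["enhancer"], contrasts["rescue"]
    ) if len(counts) else {}
    if len(counts):
        retained = regclass.retained_activity(
            contrasts["rescue"],
            contrasts["variant"],
            tpm,
            filter_samples={
                "activated": by_cond["KO_rescue"],
                "repressed": by_cond["KO_empty"],
            },
            lfc_min=config.lfc_min,
            tpm_min=config.tpm_min,
        )
        report["retained_activity"] = {
            side: {k: v for k, v in d.items() if k != "table"}
            for side, d in retained.items()
        }
        scans = {}
        for mode in ("ectopic", "impairment"):
            scan = regclass.cutoff_robustness_scan(
                contrasts["rescue"], contrasts["variant"], mode=mode,
                lfc_min=config.lfc_min,
            )
            scans[mode] = {
                "table": scan.table.to_dict(orient="records"),
                "mannwhitney_p": scan.mannwhitney_p,
            }
            if outdir:
                scan.table.to_csv(
                    outdir / "catalog" / f"robustness_{mode}.tsv", sep="\t", index=False
                )
        report["robustness"] = scans
    if outdir and len(catalog):
        catalog.to_csv(outdir / "catalog" / "catalog.tsv", sep="\t", index=False)

    if config.sim is not None and truth is not None:
        inferred = (
            catalog["category"] if len(catalog) else pd.Series(dtype=object)
        )
        genes = truth.genes
        expected = genes["category"].map(TRUTH_TO_CATEGORY)
        observed = inferred.reindex(genes.index).fillna("none")
        confusion = pd.crosstab(expected, observed, dropna=False)
        report["confusion"] = confusion.to_dict()
        lfcs = genes[["lfc_enh", "lfc_rescue", "lfc_variant"]].to_numpy()
        regulated_lfcs = np.where(lfcs == 0, np.inf, np.abs(lfcs))
        strong = (regulated_lfcs.min(axis=1) >= 1.5) & (genes["baseline"] >= 50)
        strong &= genes["category"].isin(
            [c for c in simulate.CATEGORIES if c not in ("unregulated", "enhancer_only")]
        )
        n_strong = int(strong.sum())
        n_correct = int((expected[strong] == observed[strong]).sum())
        report["category_recovery"] = {
            "n_strong_effect": n_strong,
            "n_correct": n_correct,
            "pct": 100.0 * n_correct / n_strong if n_strong else None,
        }
        if outdir:
            confusion.to_csv(outdir / "report" / "confusion.tsv", sep="\t")

    logger.info("stage: chromatin")
    cohorts = _cohort_sets(catalog)
    if peak_table is not None and len(peak_table):
        sample_cols = [c for c in peak_table.columns if c in set(samples["sample"])]
        pk_counts = peak_table[sample_cols]
        pk_sf = diffexpr.size_factors(pk_counts, pseudo_reference=True)
        peak_stats = {}
        for name in ("rescue", "variant"):
            cond_a, cond_b = CONTRAST_PAIRS[name]
            peak_stats[name] = chromatin.differential_peaks(
                pk_counts, by_cond[cond_a], by_cond[cond_b],
                lfc_thresh=config.lfc_min, alpha=config.alpha, size_factors_=pk_sf,
            )
            if outdir:
                io.write_contrast_tsv(
                    peak_stats[name], outdir / "chromatin" / f"peaks_{name}.tsv"
                )
        deg_universe = degs["rescue"].genes | degs["variant"].genes
        links = chromatin.link_to_nearest_deg(
            peak_table, deg_universe, annotation, max_dist=config.max_link_dist
        )
        if outdir:
            links.to_csv(outdir / "chromatin" / "links.tsv", sep="\t", index=False)
        transitions = {}
        for name in ("rescue", "variant"):
            classes = dict(zip(peak_stats[name]["peak_id"], peak_stats[name]["class"]))
            _, props = chromatin.classify_transitions(links, classes, cohorts)
            transitions[name] = props.to_dict(orient="records")
            if outdir:
                props.to_csv(
                    outdir / "chromatin" / f"transitions_{name}.tsv", sep="\t", index=False
                )
        report["transitions"] = transitions

        # Promoter-window accessibility at factor-regulated genes, compared
        # between the knockout-empty and rescue conditions (signed-rank).
        reg_genes = sorted(cohorts["factor_activated"] | cohorts["factor_repressed"])
        if reg_genes:
            prom = chromatin.promoter_signal(
                peak_table, pk_counts, annotation.loc[reg_genes],
                window=config.promoter_window, size_factors_=pk_sf,
            )
            prom_summary = {}
            for side in ("factor_activated", "factor_repressed"):
                genes_side = sorted(cohorts[side] & set(prom.index))
                if len(genes_side) >= 5:
                    empty_mean = prom.loc[genes_side, by_cond["KO_empty"]].mean(axis=1)
                    rescue_mean = prom.loc[genes_side, by_cond["KO_rescue"]].mean(axis=1)
                    stat, p = chromatin.rank_tests(
                        rescue_mean.to_numpy(), empty_mean.to_numpy(),
                        kind="signed_rank_paired",
                    )
                    prom_summary[side] = {"n": len(genes_side), "signed_rank_p": p}
            report["promoter"] = prom_summary

        logger.info("stage: motifs")
        if sequences:
            classes = dict(zip(peak_stats["rescue"]["peak_id"], peak_stats["rescue"]["class"]))
            linked = links.dropna(subset=["gene_id"])
            seq_classes: dict[str, dict[str, str]] = {"activated": {}, "repressed": {}}
            for pid, gid in zip(linked["peak_id"], linked["gene_id"]):
                if classes.get(pid, "unchanged") == "unchanged" or pid not in sequences:
                    continue
                if gid in cohorts["factor_activated"]:
                    seq_classes["activated"][pid] = sequences[pid]
                elif gid in cohorts["factor_repressed"]:
                    seq_classes["repressed"][pid] = sequences[pid]
            seq_classes = {k: v for k, v in seq_classes.items() if v}
            if len(seq_classes) == 2:
                stats_df, tests_df = motifs.peak_set_motif_stats(seq_classes)
                report["motif_stats"] = stats_df.to_dict(orient="records")
                report["motif_tests"] = tests_df.to_dict(orient="records")
                if outdir:
                    stats_df.to_csv(outdir / "motifs" / "stats.tsv", sep="\t", index=False)
                    tests_df.to_csv(outdir / "motifs" / "tests.tsv", sep="\t", index=False)

    logger.info("stage: occupancy")
    if occ_sets is not None and len(occ_sets["factor"]):
        ov = occupancy.overlap_sets(occ_sets["factor"], occ_sets["variant"])
        factor_counts, _ = occupancy.link_occupancy_to_catalog(
            occ_sets["factor"], catalog, annotation, max_dist=config.max_link_dist
        )
        shared_counts, _ = occupancy.link_occupancy_to_catalog(
            ov.a_shared, catalog, annotation, max_dist=config.max_link_dist
        ) if len(ov.a_shared) else ({"activated": 0, "repressed": 0}, None)
        variant_counts, _ = occupancy.link_occupancy_to_catalog(
            occ_sets["variant"], catalog, annotation, max_dist=config.max_link_dist
        ) if len(occ_sets["variant"]) else ({"activated": 0, "repressed": 0}, None)
        loss = occupancy.occupancy_loss_summary(
            {
                side: (factor_counts[side], shared_counts[side])
                for side in ("activated", "repressed")
            }
        )
        report["occupancy"] = {
            "overlap": ov.counts,
            "factor_per_cohort": factor_counts,
            "variant_per_cohort": variant_counts,
            "loss_summary": loss,
        }
        if "sequence" in occ_sets["factor"].columns:
            _, flinks = occupancy.link_occupancy_to_catalog(
                occ_sets["factor"], catalog, annotation, max_dist=config.max_link_dist
            )
            act_set = cohorts["factor_activated"]
            rep_set = cohorts["factor_repressed"]
            seq_act, seq_rep = {}, {}
            for pid, gid in zip(flinks["peak_id"], flinks["gene_id"]):
                if gid in act_set:
                    seq_act[pid] = occ_sets["factor"].loc[pid, "sequence"]
                elif gid in rep_set:
                    seq_rep[pid] = occ_sets["factor"].loc[pid, "sequence"]
            if seq_act and seq_rep:
                report["occupancy"]["wgatar_distribution"] = (
                    occupancy.wgatar_distribution_compare(seq_act, seq_rep)
                )

    report = _sanitize(report)
    report["digest"] = report_digest(report)
    if outdir:
        (outdir / "report" / "report.json").write_text(json.dumps(report, indent=2))
        _write_report_tsv(report, outdir / "report" / "report.tsv")
    logger.info("pipeline complete")
    return report


def _flatten(prefix: str, obj, rows: list) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            _flatten(f"{prefix}[{i}]", v, rows)
    else:
        rows.append((prefix, obj))


def _write_report_tsv(report: dict, path: Path) -> None:
    rows: list = []
    _flatten("", report, rows)
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, sep="\t", index=False)
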