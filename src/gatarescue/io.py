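"""Readers and writers for the package's plain-text interchange formats.

Counts as gene x sample TSV with a sample-to-condition sidecar, peaks as
BED6 (0-based half-open, written natively), sequences as FASTA (Biopython),
gene annotation as TSV (0-based TSS, documented in the header comment of
docs/methods.md), ground truth as JSON, and configs as YAML. Every writer
round-trips through its paired reader without loss.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimConfig, SimTruth, config_from_dict, config_to_dict


def write_counts_tsv(counts: pd.DataFrame, samples: pd.DataFrame, path) -> None:
    path = Path(path)
    counts.to_csv(path, sep="\t", index_label="gene_id")
    samples[["sample", "condition"]].to_csv(
        path.with_suffix(".samples.tsv"), sep="\t", index=False
    )


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(path.with_suffix(".samples.tsv"), sep="\t")
    return counts, samples.set_index("sample", drop=False)


def write_bed6(peaks: pd.DataFrame, path, name_col: str = "peak_id") -> None:
    """BED6: chrom, start, end, name, score, strand (strand '.' if absent)."""
    df = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int),
            "end": peaks["end"].astype(int),
            "name": peaks[name_col],
            "score": peaks["score"] if "score" in peaks else 0,
            "strand": peaks["strand"] if "strand" in peaks else ".",
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "peak_id", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "peak_id": str},
    )
    return df.set_index("peak_id", drop=False)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation[["gene_id", "chrom", "strand", "tss", "length"]].to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return df.set_index("gene_id", drop=False)


def write_truth_json(truth: SimTruth, path) -> None:
    payload = {
        "genes": truth.genes.to_dict(orient="records"),
        "peaks": None if truth.peaks is None else truth.peaks.to_dict(orient="records"),
        "motifs": None if truth.motifs is None else truth.motifs.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    genes = pd.DataFrame(payload["genes"]).set_index("gene_id", drop=False)
    peaks = None
    if payload["peaks"] is not None:
        peaks = pd.DataFrame(payload["peaks"])
        if len(peaks):
            peaks = peaks.set_index("peak_id", drop=False)
    motifs = None
    if payload["motifs"] is not None:
        motifs = pd.DataFrame(
            payload["motifs"], columns=["seq_id", "motif", "start", "strand"]
        )
    return SimTruth(genes=genes, peaks=peaks, motifs=motifs)


def write_config_yaml(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config)))


def read_config_yaml(path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def write_contrast_tsv(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)


def read_contrast_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return df.set_index("gene_id", drop=False)


def dataclass_to_json(obj, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(obj), default=str))
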