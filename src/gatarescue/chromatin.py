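"""Differential chromatin accessibility and its integration with DEGs.

Peaks are tested with the same NB Wald engine as genes, classified as
opening / closing / unchanged at |log2FC| > 1 (strict) and adjusted
p < 0.05, assigned to the nearest differentially expressed gene by
midpoint-to-TSS distance, and summarized as per-cohort chromatin-transition
proportions. The module also houses the nonparametric statistics used for
those comparisons: the two-sample proportion test with continuity
correction and the Wilcoxon/Mann-Whitney rank tests, plus strand-aware
promoter-window signal aggregation.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import nb_wald_contrast


def differential_peaks(
    peak_counts: pd.DataFrame,
    samples_A: Sequence[str],
    samples_B: Sequence[str],
    lfc_thresh: float = 1.0,
    alpha: float = 0.05,
    size_factors_: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-peak NB Wald statistics plus an accessibility class.

    ``opening`` requires log2FC strictly above ``lfc_thresh`` with adjusted
    p below ``alpha``; ``closing`` is the mirror; everything else (including
    a boundary log2FC of exactly 1.0) is ``unchanged``.
    """
    res = nb_wald_contrast(peak_counts, samples_A, samples_B, size_factors_=size_factors_)
    lfc = res["log2fc"].to_numpy()
    padj = res["padj"].to_numpy()
    with np.errstate(invalid="ignore"):
        sig = np.isfinite(padj) & (padj < alpha)
        cls = np.where(
            sig & (lfc > lfc_thresh),
            "opening",
            np.where(sig & (lfc < -lfc_thresh), "closing", "unchanged"),
        )
    res = res.rename(columns={"gene_id": "peak_id"})
    res["class"] = cls
    return res


def link_to_nearest_deg(
    peaks: pd.DataFrame,
    deg_genes: set[str],
    annotation: pd.DataFrame,
    max_dist: int | None = None,
) -> pd.DataFrame:
    """Assign each peak to the nearest DEG by |midpoint - TSS|.

    Ties (two DEGs exactly equidistant) break to the lexicographically
    smaller gene id. Peaks with no DEG on their chromosome, or beyond
    ``max_dist`` when set, come back unlinked (gene_id NaN). The signed
    distance is strand-aware: positive means the peak lies downstream of
    the TSS in the gene's orientation.
    """
    ann = annotation[annotation["gene_id"].isin(deg_genes)].reset_index(drop=True)
    out_rows = []
    by_chrom = {c: g.sort_values(["tss", "gene_id"]) for c, g in ann.groupby("chrom")}
    for _, peak in peaks.iterrows():
        mid = (int(peak["start"]) + int(peak["end"])) // 2
        genes = by_chrom.get(peak["chrom"])
        row = {
            "peak_id": peak["peak_id"],
            "gene_id": None,
            "distance": np.nan,
            "abs_distance": np.nan,
        }
        if genes is not None and len(genes):
            tss = genes["tss"].to_numpy()
            d = np.abs(tss - mid)
            best = d.min()
            if max_dist is None or best <= max_dist:
                cand = genes.iloc[np.flatnonzero(d == best)]
                gene = cand.sort_values("gene_id").iloc[0]
                signed = mid - int(gene["tss"])
                if gene["strand"] == "-":
                    signed = -signed
                row.update(
                    gene_id=gene["gene_id"],
                    distance=signed,
                    abs_distance=int(best),
                )
        out_rows.append(row)
    return pd.DataFrame(
        out_rows, columns=["peak_id", "gene_id", "distance", "abs_distance"]
    )


def classify_transitions(
    links: pd.DataFrame,
    peak_classes: Mapping[str, str],
    cohorts: Mapping[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene chromatin-transition labels and per-cohort proportions.

    A gene is ``opening`` if at least one linked peak opens and ``closing``
    if at least one closes; a gene with both counts in *both* numerators
    (the published per-side proportions are reported independently and need
    not partition). Cohort proportions are NaN for empty cohorts.
    """
    linked = links.dropna(subset=["gene_id"])
    opening_genes: set[str] = set()
    closing_genes: set[str] = set()
    for peak_id, gene_id in zip(linked["peak_id"], linked["gene_id"]):
        cls = peak_classes.get(peak_id, "unchanged")
        if cls == "opening":
            opening_genes.add(gene_id)
        elif cls == "closing":
            closing_genes.add(gene_id)

    all_genes = sorted(set().union(*cohorts.values()) if cohorts else set())
    gene_table = pd.DataFrame(
        {
            "gene_id": all_genes,
            "opening": [g in opening_genes for g in all_genes],
            "closing": [g in closing_genes for g in all_genes],
        }
    )
    rows = []
    for name, genes in cohorts.items():
        n = len(genes)
        x_open = len(genes & opening_genes)
        x_close = len(genes & closing_genes)
        rows.append(
            {
                "cohort": name,
                "n_genes": n,
                "n_opening": x_open,
                "n_closing": x_close,
                "pct_opening": 100.0 * x_open / n if n else float("nan"),
                "pct_closing": 100.0 * x_close / n if n else float("nan"),
            }
        )
    return gene_table, pd.DataFrame(rows)


def proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> tuple[float, float]:
    """Two-sample test for equality of proportions (pooled z, Yates correction).

    Returns (z, two-sided p); z is floored at 0 when the continuity
    correction exceeds the observed difference, giving p = 1. Matches the
    classical chi-square-with-1-df formulation (statistic = z**2).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    diff = abs(p1 - p2)
    cc = min(diff, 0.5 * (1 / n1 + 1 / n2)) if continuity else 0.0
    z = (diff - cc) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return float(z), float(p)


def rank_tests(
    x,
    y=None,
    kind: str = "mann_whitney_two_sample",
    alternative: str = "two-sided",
    exact_max: int = 25,
) -> tuple[float, float]:
    """Wilcoxon-family rank tests with exact small-sample distributions.

    ``kind`` is one of:

    * ``rank_sum_vs_zero_shift`` — one-sample signed-rank of values against
      a zero shift (used for "did accessibility move" on per-gene signals);
    * ``signed_rank_paired`` — Wilcoxon signed-rank on paired samples;
    * ``mann_whitney_two_sample`` — Mann-Whitney U.

    For n <= ``exact_max`` without ties/zeros the exact null distribution is
    used; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    if kind in ("rank_sum_vs_zero_shift", "signed_rank_paired"):
        if kind == "signed_rank_paired":
            if y is None:
                raise ValueError("paired test needs y")
            d = x - np.asarray(y, dtype=float)
        else:
            d = x
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        nz = d[d != 0]
        method = "exact" if len(nz) <= exact_max else "approx"
        res = stats.wilcoxon(nz, alternative=alternative, method=method)
        return float(res.statistic), float(res.pvalue)
    if kind == "mann_whitney_two_sample":
        if y is None:
            raise ValueError("two-sample test needs y")
        y = np.asarray(y, dtype=float)
        method = "exact" if max(len(x), len(y)) <= exact_max else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown kind {kind!r}")


def promoter_window(tss: int, strand: str, window: tuple[int, int] = (-2000, 100)):
    """Half-open strand-oriented promoter interval around a TSS.

    For a plus-strand gene the window (-2000, +100) is [tss-2000, tss+100);
    for a minus-strand gene the mirror [tss-100, tss+2000).
    """
    w0, w1 = window
    if strand == "-":
        return tss - w1, tss - w0
    return tss + w0, tss + w1


def promoter_signal(
    peaks: pd.DataFrame,
    peak_counts: pd.DataFrame,
    annotation: pd.DataFrame,
    window: tuple[int, int] = (-2000, 100),
    size_factors_: pd.Series | None = None,
) -> pd.DataFrame:
    """Summed normalized accessibility in each gene's promoter window.

    Peaks overlapping the strand-oriented window by at least one base
    contribute their normalized counts; genes without overlapping peaks get
    zero rows. Annotation rows without a strand fall back to the plus-strand
    convention with a warning.
    """
    if (annotation["strand"].isin(["+", "-"])).all():
        strands = annotation["strand"]
    else:
        warnings.warn("unstranded annotation entries; using plus-strand windows")
        strands = annotation["strand"].where(annotation["strand"].isin(["+", "-"]), "+")
    norm = peak_counts.to_numpy(dtype=float)
    if size_factors_ is not None:
        norm = norm / size_factors_.reindex(peak_counts.columns).to_numpy(dtype=float)
    norm = pd.DataFrame(norm, index=peak_counts.index, columns=peak_counts.columns)

    out = pd.DataFrame(
        0.0, index=annotation.index, columns=peak_counts.columns
    )
    by_chrom = {c: g for c, g in peaks.groupby("chrom")}
    for gene_id, chrom, tss, strand in zip(
        annotation["gene_id"], annotation["chrom"], annotation["tss"], strands
    ):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        w0, w1 = promoter_window(int(tss), strand, window)
        hit = (sub["start"].to_numpy() < w1) & (sub["end"].to_numpy() > w0)
        if hit.any():
            out.loc[gene_id] = norm.loc[sub.index[hit]].sum(axis=0).to_numpy()
    return out
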