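"""Occupancy peak-set integration (CUT&Tag-like factor vs variant).

Compares the chromatin occupancy peak sets of the wild-type factor and the
variant, links occupancy peaks to the regulatory catalog's activated and
repressed gene cohorts, and computes the occupancy-loss and WGATAR-
distribution summaries. "Reduced occupancy" is operationalized as factor
peaks with no overlapping variant peak (loss = factor_total - shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .chromatin import link_to_nearest_deg, proportion_test
from .motifs import WGATAR, MotifPattern, scan_iupac
from .regclass import fold_ratio, percent


@dataclass
class OverlapResult:
    """Peak-level overlap classification of two interval sets."""

    shared_pairs: int      # distinct overlapping (a, b) pairs; symmetric
    a_shared: pd.DataFrame
    a_only: pd.DataFrame
    b_shared: pd.DataFrame
    b_only: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared_pairs": self.shared_pairs,
            "a_shared": len(self.a_shared),
            "a_only": len(self.a_only),
            "b_shared": len(self.b_shared),
            "b_only": len(self.b_only),
        }


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom"):
        t = IntervalTree()
        for start, end, pid in zip(grp["start"], grp["end"], grp["peak_id"]):
            if start >= end:
                raise ValueError(f"invalid interval for {pid}: [{start}, {end})")
            t.addi(int(start), int(end), pid)
        trees[chrom] = t
    return trees


def overlap_sets(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> OverlapResult:
    """Classify two BED-like peak sets into shared and exclusive peaks.

    A peak is shared when it overlaps any peak of the other set by at least
    ``min_overlap`` bases; the pair count is symmetric between the sets.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees_b = _trees(b) if len(b) else {}
    pairs = 0
    a_flags = []
    for chrom, start, end in zip(a.get("chrom", []), a.get("start", []), a.get("end", [])):
        tree = trees_b.get(chrom)
        n = 0
        if tree is not None:
            for iv in tree.overlap(int(start), int(end)):
                if min(iv.end, int(end)) - max(iv.begin, int(start)) >= min_overlap:
                    n += 1
        pairs += n
        a_flags.append(n > 0)
    trees_a = _trees(a) if len(a) else {}
    b_flags = []
    for chrom, start, end in zip(b.get("chrom", []), b.get("start", []), b.get("end", [])):
        tree = trees_a.get(chrom)
        hit = False
        if tree is not None:
            for iv in tree.overlap(int(start), int(end)):
                if min(iv.end, int(end)) - max(iv.begin, int(start)) >= min_overlap:
                    hit = True
                    break
        b_flags.append(hit)
    a_flags = pd.Series(a_flags, index=a.index, dtype=bool) if len(a) else pd.Series(dtype=bool)
    b_flags = pd.Series(b_flags, index=b.index, dtype=bool) if len(b) else pd.Series(dtype=bool)
    return OverlapResult(
        shared_pairs=pairs,
        a_shared=a[a_flags] if len(a) else a,
        a_only=a[~a_flags] if len(a) else a,
        b_shared=b[b_flags] if len(b) else b,
        b_only=b[~b_flags] if len(b) else b,
    )


def link_occupancy_to_catalog(
    peaks: pd.DataFrame,
    catalog: pd.DataFrame,
    annotation: pd.DataFrame,
    max_dist: int | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Count occupancy peaks at activated versus repressed catalog loci.

    Each peak is assigned to the nearest factor-regulated gene (classes
    I.x or II.x, reusing the nearest-DEG linker) and tallied by the linked
    gene's side; unlinkable peaks are counted separately.
    """
    if len(catalog):
        activated = set(catalog.loc[catalog["category_activated"].isin(["I.I", "I.II"]), "gene_id"])
        repressed = set(catalog.loc[catalog["category_repressed"].isin(["II.I", "II.II"]), "gene_id"])
    else:
        activated, repressed = set(), set()
    regulated = activated | repressed
    links = link_to_nearest_deg(peaks, regulated, annotation, max_dist=max_dist)
    counts = {"activated": 0, "repressed": 0, "unlinked": 0}
    for gene_id in links["gene_id"]:
        if gene_id in activated:
            counts["activated"] += 1
        elif gene_id in repressed:
            counts["repressed"] += 1
        else:
            counts["unlinked"] += 1
    return counts, links


def occupancy_loss_summary(
    counts: dict[str, tuple[int, int]]
) -> dict[str, float]:
    """Occupancy-loss percentages and the activated/repressed fold ratio.

    ``counts`` maps each side to (factor peak total, shared-with-variant
    count); loss% = 100 * (factor - shared)/factor with half-up integer
    rounding, and the fold ratio compares the factor totals between sides
    (1 decimal). Zero denominators yield NaN, never 0.
    """
    out: dict[str, float] = {}
    for side, (factor_total, shared) in counts.items():
        out[f"loss_pct_{side}"] = percent(factor_total - shared, factor_total, 0)
        out[f"n_factor_{side}"] = factor_total
        out[f"n_shared_{side}"] = shared
    if "activated" in counts and "repressed" in counts:
        out["fold_activated_vs_repressed"] = fold_ratio(
            counts["activated"][0], counts["repressed"][0], 1
        )
    return out


def wgatar_distribution_compare(
    sequences_activated: dict[str, str],
    sequences_repressed: dict[str, str],
    pattern: MotifPattern = WGATAR,
) -> dict[str, float]:
    """Fraction of peaks containing the GATA consensus per cohort, with the
    continuity-corrected two-proportion test between cohorts."""
    if not sequences_activated or not sequences_repressed:
        raise ValueError("both cohorts need at least one sequence")
    x1 = sum(1 for s in sequences_activated.values() if scan_iupac(s, pattern))
    x2 = sum(1 for s in sequences_repressed.values() if scan_iupac(s, pattern))
    n1, n2 = len(sequences_activated), len(sequences_repressed)
    z, p = proportion_test(x1, n1, x2, n2, continuity=True)
    return {
        "frac_activated": x1 / n1,
        "frac_repressed": x2 / n2,
        "x_activated": x1,
        "n_activated": n1,
        "x_repressed": x2,
        "n_repressed": n2,
        "z": z,
        "p": p,
    }
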