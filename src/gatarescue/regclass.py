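"""Regulatory-class catalog and rescue/variant summary statistics.

Genes are partitioned by how the wild-type factor and the pathogenic
variant restore (or fail to restore) their expression in enhancer-knockout
progenitors:

* ``I``    factor-activated (union of I.I and I.II)
* ``I.I``  factor- and variant-activated (shared)
* ``I.II`` only factor-activated
* ``II``   factor-repressed (union of II.I and II.II)
* ``II.I`` factor- and variant-repressed
* ``II.II`` only factor-repressed
* ``III``  ectopically activated (variant only)
* ``IV``   ectopically repressed (variant only)

The module also computes rescue fractions (sign-concordance of enhancer and
rescue contrasts without a significance cutoff), retained variant activity
relative to the factor, adjusted-p cutoff robustness scans, percent-of-
maximal regulation for spacer-variant panels, z-scored expression, and the
half-up percentage arithmetic used for every printed summary number.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEGSet, call_degs

CATEGORY_ACTIVATED = {"shared": "I.I", "only_factor": "I.II", "ectopic": "III"}
CATEGORY_REPRESSED = {"shared": "II.I", "only_factor": "II.II", "ectopic": "IV"}


def percent(x: float, n: float, decimals: int = 0) -> float:
    """100*x/n rounded half-up to ``decimals``; NaN for a zero denominator."""
    if n == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * x / n).quantize(q, rounding=ROUND_HALF_UP))


def fold_ratio(a: float, b: float, decimals: int = 1) -> float:
    """a/b rounded half-up; NaN for a zero denominator."""
    if b == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(a / b).quantize(q, rounding=ROUND_HALF_UP))


def build_catalog(
    deg_enh: DEGSet, deg_rescue: DEGSet, deg_variant: DEGSet
) -> pd.DataFrame:
    """Per-gene regulatory catalog over the three contrasts.

    Directions are kept per contrast; a gene activated in one contrast and
    repressed in another is never forced into a single direction — it gets
    per-side category labels and ``discordant=True``. The ``category``
    column is the single label when the sides agree (at most one side
    assigned), else ``"discordant"``.
    """
    genes = sorted(deg_enh.genes | deg_rescue.genes | deg_variant.genes)
    rows = []
    for g in genes:
        enh = deg_enh.directions.get(g)
        res = deg_rescue.directions.get(g)
        var = deg_variant.directions.get(g)

        cat_act = None
        if res == "activated":
            cat_act = "I.I" if var == "activated" else "I.II"
        elif var == "activated":
            cat_act = "III"
        cat_rep = None
        if res == "repressed":
            cat_rep = "II.I" if var == "repressed" else "II.II"
        elif var == "repressed":
            cat_rep = "IV"

        discordant = (cat_act is not None and cat_rep is not None) or (
            enh is not None and res is not None and enh != res
        )
        if cat_act is not None and cat_rep is None:
            category = cat_act
        elif cat_rep is not None and cat_act is None:
            category = cat_rep
        elif cat_act is None and cat_rep is None:
            category = "none"
        else:
            category = "discordant"

        region_parts = []
        if enh:
            region_parts.append("enh")
        if res:
            region_parts.append("rescue")
        if var:
            region_parts.append("variant")
        rows.append(
            {
                "gene_id": g,
                "enh_direction": enh or "none",
                "rescue_direction": res or "none",
                "variant_direction": var or "none",
                "category_activated": cat_act or "none",
                "category_repressed": cat_rep or "none",
                "category": category,
                "venn_region": "+".join(region_parts),
                "discordant": discordant,
            }
        )
    cols = [
        "gene_id", "enh_direction", "rescue_direction", "variant_direction",
        "category_activated", "category_repressed", "category", "venn_region",
        "discordant",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.set_index("gene_id", drop=False) if len(out) else out


def venn_counts(catalog: pd.DataFrame, side: str) -> dict[str, int]:
    """Counts per Venn region over the three contrasts for one side
    (``activated`` or ``repressed``)."""
    if side not in ("activated", "repressed"):
        raise ValueError("side must be 'activated' or 'repressed'")
    counts: dict[str, int] = {}
    if len(catalog) == 0:
        return counts
    for _, row in catalog.iterrows():
        parts = [
            tag
            for tag, col in (
                ("enh", "enh_direction"),
                ("rescue", "rescue_direction"),
                ("variant", "variant_direction"),
            )
            if row[col] == side
        ]
        if parts:
            region = "+".join(parts)
            counts[region] = counts.get(region, 0) + 1
    return counts


def category_counts(catalog: pd.DataFrame) -> dict[str, int]:
    """Class sizes including the roll-up classes I and II."""
    if len(catalog) == 0:
        base = {}
    else:
        act = catalog["category_activated"].value_counts().to_dict()
        rep = catalog["category_repressed"].value_counts().to_dict()
        base = {k: v for k, v in {**act, **rep}.items() if k != "none"}
    for k in ("I.I", "I.II", "II.I", "II.II", "III", "IV"):
        base.setdefault(k, 0)
    base["I"] = base["I.I"] + base["I.II"]
    base["II"] = base["II.I"] + base["II.II"]
    return base


def summarize_fractions(counts: dict[str, int]) -> pd.DataFrame:
    """Printed-style percentage summary from class counts.

    For each side: the shared percentage (variant retained regulation) and
    its complement (regulation the variant failed to retain), at both the
    0- and 1-decimal precisions used in print.
    """
    rows = []
    for side, total_key, shared_key in (
        ("activated", "I", "I.I"),
        ("repressed", "II", "II.I"),
    ):
        n = counts.get(total_key, 0)
        x = counts.get(shared_key, 0)
        rows.append(
            {
                "side": side,
                "n_factor_regulated": n,
                "n_shared": x,
                "pct_shared": percent(x, n, 0),
                "pct_not_shared": percent(n - x, n, 1),
            }
        )
    return pd.DataFrame(rows)


def rescue_fraction(
    contrast_enh: pd.DataFrame, contrast_rescue: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Fraction of endogenously regulated genes whose rescue contrast is
    sign-concordant (|log2FC| > 0, no significance cutoff).

    The enhancer contrast orientation is comparator-over-knockout, so a
    positive enhancer log2FC marks a gene activated by the endogenous factor.
    """
    enh = contrast_enh["log2fc"].reindex(contrast_rescue.index)
    res = contrast_rescue["log2fc"]
    out = {}
    for side, sign in (("activated", 1.0), ("repressed", -1.0)):
        endo = sign * enh > 0
        n = int(endo.sum())
        x = int((endo & (sign * res > 0)).sum())
        out[side] = {
            "fraction": x / n if n else float("nan"),
            "percent": percent(x, n, 0),
            "x": x,
            "n": n,
        }
    return out


def retained_activity(
    contrast_rescue: pd.DataFrame,
    contrast_variant: pd.DataFrame,
    tpm: pd.DataFrame,
    filter_samples: dict[str, list[str]],
    lfc_min: float = 1.0,
    tpm_min: float = 1.0,
    require_both: bool = True,
    scale: str = "log2",
) -> dict[str, dict]:
    """Variant activity as a percentage of factor activity at mutually
    regulated genes.

    A gene qualifies on the activated side when its rescue log2FC >= lfc_min
    (and, with ``require_both``, the variant log2FC too), is sign-concordant,
    and passes the expression filter: TPM >= tpm_min in every replicate of
    the rescue condition for activation and of the knockout-empty condition
    for repression (``filter_samples`` maps side -> sample columns).

    ``scale='log2'`` (default) reports 100 * log2FC_variant / log2FC_rescue;
    ``scale='linear'`` reports 100 * (2^|v| - 1)/(2^|r| - 1). Returns per-side
    tables with counts, the number dropped by the TPM filter, and medians.
    """
    if scale not in ("log2", "linear"):
        raise ValueError("scale must be 'log2' or 'linear'")
    res = contrast_rescue["log2fc"]
    var = contrast_variant["log2fc"].reindex(res.index)
    out: dict[str, dict] = {}
    for side, sign in (("activated", 1.0), ("repressed", -1.0)):
        qual = sign * res >= lfc_min
        if require_both:
            qual &= sign * var >= lfc_min
        else:
            qual &= sign * var > 0
        cols = filter_samples[side]
        pass_tpm = (tpm.reindex(res.index)[cols] >= tpm_min).all(axis=1)
        dropped = int((qual & ~pass_tpm).sum())
        keep = qual & pass_tpm
        r, v = res[keep], var[keep]
        if scale == "log2":
            ratio = 100.0 * v / r
        else:
            ratio = 100.0 * (2.0 ** np.abs(v) - 1.0) / (2.0 ** np.abs(r) - 1.0)
        out[side] = {
            "table": pd.DataFrame(
                {"log2fc_rescue": r, "log2fc_variant": v, "retained_pct": ratio}
            ),
            "count": int(keep.sum()),
            "dropped_by_tpm": dropped,
            "median_retained_pct": float(np.median(ratio)) if keep.any() else float("nan"),
        }
    return out


@dataclass
class RobustnessScan:
    """Percentages per adjusted-p cutoff, split by direction, with the
    Mann-Whitney comparison of the two percentage series."""

    table: pd.DataFrame  # columns: cutoff, pct_activated, pct_repressed
    mannwhitney_u: float
    mannwhitney_p: float


DEFAULT_CUTOFFS = tuple(np.round(np.arange(1, 11) * 0.01, 2))


def cutoff_robustness_scan(
    contrast_rescue: pd.DataFrame,
    contrast_variant: pd.DataFrame,
    cutoffs=DEFAULT_CUTOFFS,
    mode: str = "ectopic",
    lfc_min: float = 1.0,
) -> RobustnessScan:
    """Re-call DEG sets at each adjusted-p cutoff and tabulate set differences.

    ``mode='ectopic'``: percentage of variant-regulated genes that are not
    factor-regulated. ``mode='impairment'``: percentage of factor-regulated
    genes not variant-regulated. The activated and repressed percentage
    vectors are compared with a two-sided Mann-Whitney U test. Percentages
    need not be monotone in the cutoff.
    """
    cutoffs = list(cutoffs)
    if len(cutoffs) < 2:
        raise ValueError("need at least 2 cutoffs")
    if mode not in ("ectopic", "impairment"):
        raise ValueError("mode must be 'ectopic' or 'impairment'")
    rows = []
    for c in cutoffs:
        deg_res = call_degs(contrast_rescue, lfc_min=lfc_min, alpha=c)
        deg_var = call_degs(contrast_variant, lfc_min=lfc_min, alpha=c)
        row = {"cutoff": c}
        for side in ("activated", "repressed"):
            res_side = getattr(deg_res, side)
            var_side = getattr(deg_var, side)
            if mode == "ectopic":
                x, n = len(var_side - res_side), len(var_side)
            else:
                x, n = len(res_side - var_side), len(res_side)
            row[f"pct_{side}"] = 100.0 * x / n if n else float("nan")
            row[f"x_{side}"], row[f"n_{side}"] = x, n
        rows.append(row)
    table = pd.DataFrame(rows)
    u, p = np.nan, np.nan
    act, rep = table["pct_activated"].dropna(), table["pct_repressed"].dropna()
    if len(act) and len(rep):
        method = "exact" if max(len(act), len(rep)) <= 25 else "asymptotic"
        result = stats.mannwhitneyu(act, rep, alternative="two-sided", method=method)
        u, p = float(result.statistic), float(result.pvalue)
    return RobustnessScan(table=table, mannwhitney_u=u, mannwhitney_p=p)


def percent_max_regulation(
    expression: pd.DataFrame,
    direction: str,
    empty_col: str = "empty",
    full_col: str = "full_rescue",
    retained_threshold: float = 50.0,
) -> pd.DataFrame:
    """Percent of maximal regulation per spacer variant per gene.

    Activation: 100*(v - empty)/(full - empty); repression:
    100*(empty - v)/(empty - full). Values may fall outside [0, 100]. Genes
    with zero dynamic range (empty == full) are excluded. Each variant value
    is classified against the 50% line; exactly 50% counts as retained.
    """
    if direction not in ("activation", "repression"):
        raise ValueError("direction must be 'activation' or 'repression'")
    empty = expression[empty_col]
    full = expression[full_col]
    dyn = full - empty
    usable = dyn != 0
    variants = [c for c in expression.columns if c not in (empty_col, full_col)]
    rows = {}
    for v in variants:
        val = expression[v]
        if direction == "activation":
            pct = 100.0 * (val - empty) / dyn
        else:
            pct = 100.0 * (empty - val) / -dyn
        rows[v] = pct.where(usable)
    out = pd.DataFrame(rows, index=expression.index)
    out = out[usable]
    classified = out >= retained_threshold
    classified.columns = [f"{c}_retained" for c in classified.columns]
    return pd.concat([out, classified], axis=1)


def zscore_expression(fpkm: pd.DataFrame, pseudo: float = 1e-3) -> pd.DataFrame:
    """Per-gene z-score of log10(FPKM + pseudo) across samples (population SD).

    Zero-variance rows come back as all-zero z-vectors.
    """
    if (fpkm < 0).any().any():
        raise ValueError("FPKM values must be nonnegative")
    logged = np.log10(fpkm + pseudo)
    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    z = logged.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    return z.where(sd > 0, 0.0)


def expressed_filter(
    tpm: pd.DataFrame,
    min_tpm: float = 1.0,
    scope: str = "all_conditions",
    samples: list[str] | None = None,
) -> set[str]:
    """Genes with TPM >= min_tpm (inclusive) in every relevant replicate.

    ``scope='all_conditions'`` requires the threshold in every sample of the
    table; ``scope='all_replicates_of_condition'`` restricts the check to the
    given ``samples`` (the replicates of one condition).
    """
    if scope == "all_replicates_of_condition":
        if samples is None:
            raise ValueError("samples required for all_replicates_of_condition scope")
        sub = tpm[samples]
    elif scope == "all_conditions":
        sub = tpm
    else:
        raise ValueError(f"unknown scope {scope!r}")
    keep = (sub >= min_tpm).all(axis=1)
    return set(tpm.index[keep])
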