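"""Negative-binomial differential expression for two-group contrasts.

The engine mirrors the standard bulk RNA-seq workflow: median-of-ratios
normalization, per-gene NB Wald tests with moderated method-of-moments
dispersions, Benjamini-Hochberg adjustment, and DEG calling at
|log2FC| >= 1 and adjusted p < 0.05.

Orientation convention: ``nb_wald_contrast(counts, samples_A, samples_B)``
reports log2FC of group B over group A. Throughout the package the reference
group A is the knockout-empty condition and B the comparator (wild type or a
rescue construct), so a positive log2FC means the enhancer/factor/variant
*activates* the gene.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

#: Pseudo-count (in normalized-count units) for fold changes of zero groups.
PSEUDOCOUNT = 0.5

CONTRAST_COLUMNS = [
    "gene_id", "base_mean", "log2fc", "se", "pvalue", "padj",
    "tpm_mean_A", "tpm_mean_B",
]


class NormalizationError(ValueError):
    pass


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The per-gene reference is the geometric mean across samples over genes
    expressed in every sample; each sample's factor is the median ratio of
    its counts to that reference. With ``pseudo_reference=True`` the
    reference is instead the geometric mean over *positive* counts only,
    which tolerates tables where no single gene is expressed everywhere.
    """
    x = counts.to_numpy(dtype=float)
    if x.size == 0:
        return pd.Series(np.ones(counts.shape[1]), index=counts.columns)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    if pseudo_reference:
        pos = x > 0
        ngood = pos.sum(axis=1)
        keep = ngood > 0
        logref = np.full(x.shape[0], -np.inf)
        logref[keep] = np.where(pos[keep], logx[keep], 0.0).sum(axis=1) / ngood[keep]
    else:
        keep = (x > 0).all(axis=1)
        if not keep.any():
            raise NormalizationError(
                "no gene has nonzero counts in all samples; "
                "re-run with pseudo_reference=True"
            )
        logref = np.where(keep, logx.mean(axis=1), -np.inf)
    factors = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        log_ratios = logx[keep, j] - logref[keep]
        log_ratios = log_ratios[np.isfinite(log_ratios)]
        if log_ratios.size == 0:
            raise NormalizationError(f"sample {counts.columns[j]} shares no expressed gene")
        factors[j] = np.median(np.exp(log_ratios))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; every column sums to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be >= 1")
    rpk = counts.div(lengths / 1e3, axis=0)
    denom = rpk.sum(axis=0)
    return rpk.div(denom.where(denom > 0, 1.0), axis=1) * 1e6


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _mom_dispersion(norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """Pooled within-group method-of-moments dispersion estimates."""
    a, b = norm[:, idx_a], norm[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - mu_a[:, None]) ** 2).sum(axis=1) + ((b - mu_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / (na + nb - 2)
    mu_pool = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu_pool) / mu_pool**2
    raw = np.where(mu_pool > 0, raw, np.nan)
    return np.clip(raw, 0.0, None), mu_pool


def _moderate_dispersion(raw: np.ndarray, mu_pool: np.ndarray, weight: float = 0.5):
    """Shrink moment estimates 50/50 toward a lowess mean-dispersion trend.

    The trend is fit on the natural dispersion scale against log10 mean;
    shrinking arithmetically (rather than geometrically) avoids the downward
    bias that floored moment estimates would impose in log space.
    """
    ok = np.isfinite(raw) & (mu_pool > 0)
    trend = np.full(raw.shape, np.nan)
    if ok.sum() >= 10:
        logmu = np.log10(mu_pool[ok])
        fit = lowess(raw[ok], logmu, frac=0.4, it=1, return_sorted=True)
        trend[ok] = np.interp(np.log10(mu_pool[ok]), fit[:, 0], fit[:, 1])
    elif ok.any():
        trend[ok] = raw[ok].mean()
    trend = np.clip(trend, 1e-8, None)
    moderated = np.where(ok, (1 - weight) * raw + weight * trend, np.nan)
    return np.clip(moderated, 1e-8, None)


def nb_wald_contrast(
    counts: pd.DataFrame,
    samples_A: Sequence[str],
    samples_B: Sequence[str],
    size_factors_: pd.Series | None = None,
    tpm: pd.DataFrame | None = None,
    dispersion_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B versus group A.

    log2FC = log2((mu_B + eps)/(mu_A + eps)) on normalized counts with
    pseudo-count eps = 0.5; the Wald z uses a delta-method standard error
    from the NB variance mu + alpha*mu^2 at the moderated dispersion.
    Genes with zero counts in every sample get log2FC 0, p 1, and are
    excluded from the BH adjustment (padj = NaN).
    """
    samples_A, samples_B = list(samples_A), list(samples_B)
    if len(samples_A) < 2 or len(samples_B) < 2:
        raise ValueError("each group needs at least 2 replicates")
    sub = counts[samples_A + samples_B]
    if size_factors_ is None:
        size_factors_ = size_factors(sub, pseudo_reference=True)
    sf = size_factors_.reindex(sub.columns).to_numpy(dtype=float)
    norm = sub.to_numpy(dtype=float) / sf

    idx_a = np.arange(len(samples_A))
    idx_b = np.arange(len(samples_A), len(samples_A) + len(samples_B))
    na, nb = len(samples_A), len(samples_B)
    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    base_mean = norm.mean(axis=1)

    raw_alpha, mu_pool = _mom_dispersion(norm, idx_a, idx_b)
    alpha = _moderate_dispersion(raw_alpha, mu_pool, weight=dispersion_weight)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)

    eps = PSEUDOCOUNT
    log2fc = np.log2((mu_b + eps) / (mu_a + eps))

    # Var(mean of normalized counts) = mu * mean(1/sf)/n + alpha*mu^2/n,
    # mapped to the log2 scale by the delta method at mu + eps.
    inv_a = np.mean(1.0 / sf[idx_a])
    inv_b = np.mean(1.0 / sf[idx_b])
    var_a = mu_a * inv_a / na + alpha * mu_a**2 / na
    var_b = mu_b * inv_b / nb + alpha * mu_b**2 / nb
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((var_a / (mu_a + eps) ** 2 + var_b / (mu_b + eps) ** 2) / ln2sq)

    allzero = sub.to_numpy().sum(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(allzero, 0.0, log2fc)
    pvalue = np.where(allzero, 1.0, pvalue)
    se = np.where(allzero, np.nan, se)

    padj = np.full(len(sub), np.nan)
    tested = ~allzero
    if tested.any():
        padj[tested] = bh_adjust(pvalue[tested])

    result = pd.DataFrame(
        {
            "gene_id": sub.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "dispersion": alpha,
        },
        index=sub.index,
    )
    if tpm is not None:
        result["tpm_mean_A"] = tpm[samples_A].mean(axis=1).reindex(sub.index)
        result["tpm_mean_B"] = tpm[samples_B].mean(axis=1).reindex(sub.index)
    else:
        result["tpm_mean_A"] = np.nan
        result["tpm_mean_B"] = np.nan
    return result


class DEGSet:
    """Differentially expressed genes with a direction per gene.

    ``activated`` means higher in the comparator (group B) than in the
    reference (group A); with the package's contrast orientation this is
    "activated by the enhancer/factor/variant".
    """

    def __init__(self, directions: dict[str, str]):
        bad = {g: d for g, d in directions.items() if d not in ("activated", "repressed")}
        if bad:
            raise ValueError(f"invalid directions: {bad}")
        self.directions = dict(directions)

    @property
    def activated(self) -> set[str]:
        return {g for g, d in self.directions.items() if d == "activated"}

    @property
    def repressed(self) -> set[str]:
        return {g for g, d in self.directions.items() if d == "repressed"}

    @property
    def genes(self) -> set[str]:
        return set(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    def __contains__(self, gene: str) -> bool:
        return gene in self.directions


def call_degs(
    result: pd.DataFrame,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    lfc_strict: bool = False,
) -> DEGSet:
    """DEGs at |log2FC| >= lfc_min (or strictly > with ``lfc_strict``) and
    adjusted p strictly below ``alpha``."""
    lfc = result["log2fc"].to_numpy(dtype=float)
    padj = result["padj"].to_numpy(dtype=float)
    mag = np.abs(lfc)
    pass_lfc = mag > lfc_min if lfc_strict else mag >= lfc_min
    with np.errstate(invalid="ignore"):
        hit = pass_lfc & (padj < alpha)
    hit &= np.isfinite(padj)
    directions = {
        g: ("activated" if f > 0 else "repressed")
        for g, f, h in zip(result["gene_id"], lfc, hit)
        if h
    }
    return DEGSet(directions)
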