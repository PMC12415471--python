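"""Normalization, FPKM, candidate filters, and NB differential expression.

The differential-expression stage models counts with a negative binomial
(variance mu + alpha*mu^2), normalizes libraries with median-of-ratios size
factors, and tests log2 fold changes with a Wald statistic whose standard
error comes from the NB variance via the delta method.  Multiple testing is
controlled with the Benjamini–Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountMatrix:
    """Nonnegative integer counts (features x samples) with labels.

    ``counts`` is indexed by feature id; ``classes`` maps feature id to an
    RNA class (mRNA/lncRNA/circRNA/miRNA); ``groups`` maps sample id to one
    of the two groups "A"/"B".
    """

    counts: pd.DataFrame
    classes: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        counts_per_group = self.groups.loc[self.counts.columns].value_counts()
        if (counts_per_group < 2).any():
            raise ValueError("need at least 2 samples per group")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[feature_ids],
            classes=self.classes.loc[feature_ids],
            groups=self.groups,
        )


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    The per-feature geometric mean is taken over samples; features with any
    zero count are excluded from estimation (the standard convention).  The
    factor of a sample is the median over usable features of
    count / geometric mean.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    x = df.to_numpy(dtype=float)
    usable = (x > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no usable features: every feature has a zero count")
    logx = np.log(x[usable])
    log_geomean = logx.mean(axis=1)
    factors = np.exp(np.median(logx - log_geomean[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="size_factor")


def fpkm(
    counts: pd.DataFrame | CountMatrix,
    lengths: pd.Series,
    mapped_fragments: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    fpkm = count / (length_kb * mapped_millions); by default the mapped
    fragment total of a sample is its column sum.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = df.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for features: {sorted(missing)[:10]}")
    if mapped_fragments is None:
        mapped_fragments = df.sum(axis=0)
    len_kb = lengths.loc[df.index].to_numpy(dtype=float) / 1000.0
    mapped_m = mapped_fragments.loc[df.columns].to_numpy(dtype=float) / 1e6
    return pd.DataFrame(
        df.to_numpy(dtype=float) / (len_kb[:, None] * mapped_m[None, :]),
        index=df.index,
        columns=df.columns,
    )


def gene_fpkm(transcript_fpkm: pd.DataFrame, gene_of: pd.Series) -> pd.DataFrame:
    """Gene-level FPKM as the sum of the FPKM values of its transcripts."""
    return transcript_fpkm.groupby(gene_of.loc[transcript_fpkm.index]).sum()


def filter_srna_reads(
    read_lengths, min_len: int = 18, max_len: int = 30
) -> np.ndarray:
    """Indices of small-RNA reads retained by the length filter [18, 30] nt."""
    lengths = np.asarray(read_lengths)
    if (lengths < 0).any():
        raise ValueError("read lengths must be nonnegative")
    return np.flatnonzero((lengths >= min_len) & (lengths <= max_len))


def filter_lncrna_candidates(
    annotation: pd.DataFrame, min_length: int = 200, min_exons: int = 2
) -> list[str]:
    """lncRNA candidate ids passing length (> min_length, strict) and exon count.

    The exon-number cutoff is a configurable choice (default >= 2); the
    length rule is strictly greater than 200 bp.
    """
    keep = (annotation["length"] > min_length) & (annotation["exon_count"] >= min_exons)
    return annotation.loc[keep, "feature_id"].tolist()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending; padj_(i) = min_{j>=i} p_(j) * m / j, capped at 1;
    values are returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _trend_dispersion(mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares over the MoM estimates."""
    ok = (mean > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 10:
        pooled = float(np.nanmean(np.where(ok, alpha_mom, np.nan)))
        return np.full_like(mean, max(pooled, 0.0))

    def fit(mask: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones(mask.sum()), 1.0 / mean[mask]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[mask], rcond=None)
        return coef

    coef = fit(ok)
    # one-step trimming so a minority of genuinely high-dispersion features
    # does not drag the trend for the bulk
    resid = alpha_mom - (coef[0] + coef[1] / np.maximum(mean, 1e-8))
    mad = np.median(np.abs(resid[ok] - np.median(resid[ok])))
    if mad > 0:
        keep = ok & (np.abs(resid) <= 5.0 * mad)
        if keep.sum() >= 10:
            coef = fit(keep)
    fitted = coef[0] + coef[1] / np.maximum(mean, 1e-8)
    return np.maximum(fitted, 0.0)


def de_test(
    cm: CountMatrix,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
    dispersion_mode: str = "trend",
    use_padj: bool = True,
) -> pd.DataFrame:
    """Two-group NB Wald differential-expression test.

    Counts are normalized by median-of-ratios size factors.  The log2 fold
    change (group B over A) uses a pseudocount; the NB dispersion is
    estimated per feature by method of moments on normalized counts
    (pooled within-group variance) and, in the default "trend" mode,
    stabilized through a mean–dispersion trend shared across features.
    The Wald statistic log2fc / SE(log2fc) is referred to a standard
    normal, two-sided; BH adjustment yields padj, and ``significant`` is
    padj < alpha (raw p if ``use_padj`` is False).
    """
    if dispersion_mode not in ("trend", "gene"):
        raise ValueError("dispersion_mode must be 'trend' or 'gene'")
    factors = size_factors(cm)
    norm = cm.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    a_cols = [cm.counts.columns.get_loc(s) for s in cm.samples_in("A")]
    b_cols = [cm.counts.columns.get_loc(s) for s in cm.samples_in("B")]
    ya, yb = norm[:, a_cols], norm[:, b_cols]
    na, nb = ya.shape[1], yb.shape[1]
    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    base_mean = norm.mean(axis=1)

    var_a = ya.var(axis=1, ddof=1)
    var_b = yb.var(axis=1, ddof=1)
    pooled_var = (var_a * (na - 1) + var_b * (nb - 1)) / (na + nb - 2)
    grand = (mean_a * na + mean_b * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(grand > 0, (pooled_var - grand) / grand**2, np.nan)
    if dispersion_mode == "trend":
        disp = _trend_dispersion(grand, alpha_mom)
    else:
        disp = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    disp = np.maximum(disp, dispersion_floor)

    c = pseudocount
    log2fc = np.log2(mean_b + c) - np.log2(mean_a + c)
    ln2sq = np.log(2.0) ** 2
    var_mean_a = (mean_a + disp * mean_a**2) / na
    var_mean_b = (mean_b + disp * mean_b**2) / nb
    se2 = var_mean_a / ((mean_a + c) ** 2 * ln2sq) + var_mean_b / (
        (mean_b + c) ** 2 * ln2sq
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    crit = padj if use_padj else p
    result = pd.DataFrame(
        {
            "rna_class": cm.classes.loc[cm.counts.index].to_numpy(),
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "significant": crit < alpha,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=cm.counts.index,
    )
    assert not result[["log2fc", "p", "padj"]].isna().any().any()
    return result
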