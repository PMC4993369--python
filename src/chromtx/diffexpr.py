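"""Count-based expression quantification and two-group differential expression.

The statistical stack is a self-contained analogue of the classic
voom/limma+edgeR workflow for RNA-seq counts: between-sample normalization by
the trimmed mean of M-values (TMM), log2-CPM expression values, a moderated
two-sample t-statistic whose per-gene variance is shrunk toward a fitted
mean-variance trend with a moments-estimated prior degrees of freedom
(empirical-Bayes squeezing), and Benjamini-Hochberg step-up FDR control.
Calls follow the conventional fold-change and FDR thresholds:
``methods`` (FDR < 0.01), ``fig5`` (p < 0.005, >= 4-fold), ``fig6``
(p < 0.05, >= 4-fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "THRESHOLD_PROFILES",
    "rpkm",
    "log2_rpkm",
    "tmm_factors",
    "de_test",
    "classify_de",
]

#: Named (lfc_cut, p_cut, use_fdr) threshold profiles.
THRESHOLD_PROFILES: dict[str, dict] = {
    "methods": {"lfc_cut": 2.0, "p_cut": 0.01, "use_fdr": True},
    "fig5": {"lfc_cut": 2.0, "p_cut": 0.005, "use_fdr": True},
    "fig6": {"lfc_cut": 2.0, "p_cut": 0.05, "use_fdr": True},
}


@dataclass
class CountMatrix:
    """Gene x sample integer counts with group labels and feature lengths."""

    counts: pd.DataFrame                    # genes x samples
    groups: pd.Series                       # sample -> group label
    lengths: pd.Series | None = None        # gene -> exon/ORF length (bp)
    library_sizes: pd.Series | None = None  # sample -> total counts (default: column sums)

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.groups = self.groups.reindex(c.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if self.library_sizes is None:
            self.library_sizes = c.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(c.columns).astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("non-positive library size")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(c.index).astype(float)
            if (self.lengths <= 0).any():
                raise ValueError("non-positive feature length")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class DEResult:
    """Per-gene two-group test output (``log2fc`` is group1 minus group2)."""

    table: pd.DataFrame  # log2fc, t, p, fdr, mean_log2cpm, call + group means
    contrast: tuple[str, str]
    prior_df: float = np.nan
    tmm: pd.Series | None = None


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kb of feature per million library reads: c*1e9/(lib*len)."""
    if counts.lengths is None:
        raise ValueError("feature lengths required for RPKM")
    scale = np.outer(1.0 / counts.lengths, 1.0 / counts.library_sizes) * 1e9
    return counts.counts * scale


def log2_rpkm(counts: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 RPKM with a half-count pseudocount so zero counts stay finite."""
    if counts.lengths is None:
        raise ValueError("feature lengths required for RPKM")
    shifted = counts.counts + pseudocount
    scale = np.outer(1.0 / counts.lengths, 1.0 / counts.library_sizes) * 1e9
    return np.log2(shifted * scale)


def _choose_reference(cpm: pd.DataFrame) -> str:
    """Sample whose 75th percentile of nonzero-gene CPM is closest to the mean."""
    uq = cpm.apply(lambda col: np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample vs the reference, per-gene M (log2 ratio of
    library-scaled proportions) and A (average log2 abundance) are computed
    over genes expressed in both; the top and bottom ``trim_m`` of genes by M
    and ``trim_a`` by A are removed and the factor is 2 to the
    inverse-variance-weighted mean of the surviving M values (binomial
    delta-method weights).  Factors multiply library sizes to give effective
    sizes.
    """
    c = counts.counts.to_numpy(dtype=float)
    libs = counts.library_sizes.to_numpy()
    samples = list(counts.counts.columns)
    if len(samples) < 2:
        raise ValueError("TMM needs at least two samples")
    cpm = counts.counts / libs * 1e6
    ref = reference if reference is not None else _choose_reference(cpm)
    r = samples.index(ref)
    factors = np.ones(len(samples))
    for k in range(len(samples)):
        if k == r:
            continue
        yk, yr = c[:, k], c[:, r]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"no genes expressed in both {samples[k]} and {ref}")
        pk, pr = yk[ok] / libs[k], yr[ok] / libs[r]
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        # asymptotic variance of M (delta method on two binomials)
        w = (libs[k] - yk[ok]) / (libs[k] * yk[ok]) + (libs[r] - yr[ok]) / (libs[r] * yr[ok])
        n = len(M)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        factors[k] = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    out = pd.Series(factors, index=samples, name="tmm_factor")
    out.attrs["reference"] = ref
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float, amean: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical-Bayes variance squeezing toward a lowess mean-variance trend.

    Models s2 ~ trend * F(df, d0); the prior df d0 comes from matching the
    excess variance of log s2 over its theoretical chi-square scatter
    (moments estimator).  Returns posterior variances and d0.
    """
    eps = 1e-12
    z = np.log(np.maximum(s2, eps))
    fit = lowess(z, amean, frac=0.5, it=3, return_sorted=False)
    e = z - fit
    # bias-correct: E[log(s2/sigma2)] = digamma(df/2) - log(df/2)
    bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        prior_bias = special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        s2_prior = np.exp(fit + np.mean(e) - bias + prior_bias)
    else:
        d0 = np.inf
        s2_prior = np.exp(fit + np.mean(e) - bias)
    if np.isinf(d0):
        return s2_prior, d0
    post = (df * s2 + d0 * s2_prior) / (df + d0)
    return post, d0


def de_test(
    counts: CountMatrix,
    contrast: tuple[str, str],
    lfc_cut: float = 2.0,
    p_cut: float = 0.01,
    use_fdr: bool = True,
    profile: str | None = None,
    prior_count: float = 0.5,
) -> DEResult:
    """Moderated two-sample t-test on TMM-adjusted log2-CPM.

    ``contrast = (group1, group2)`` tests group1 minus group2 (by convention
    mutant vs wild type, so positive log2FC means up in the mutant).  Genes
    all-zero in both groups are reported as ``ns`` with log2FC 0 and p 1.
    Deterministic given inputs.
    """
    if profile is not None:
        prof = THRESHOLD_PROFILES[profile]
        lfc_cut, p_cut, use_fdr = prof["lfc_cut"], prof["p_cut"], prof["use_fdr"]
    g1, g2 = contrast
    s1, s2_ = counts.samples_in(g1), counts.samples_in(g2)
    if len(s1) < 2 or len(s2_) < 2:
        raise ValueError("need >= 2 replicates per group")
    factors = tmm_factors(counts)
    eff_lib = counts.library_sizes * factors
    logcpm = np.log2(
        (counts.counts + prior_count).div(eff_lib + 1.0, axis=1) * 1e6
    )
    x1 = logcpm[s1].to_numpy()
    x2 = logcpm[s2_].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = m1 - m2
    df_resid = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    amean = logcpm.mean(axis=1).to_numpy()
    s2_post, d0 = _squeeze_var(s2, df_resid, amean)
    df_total = np.inf if np.isinf(d0) else df_resid + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    allzero = (
        (counts.counts[s1].sum(axis=1) == 0) & (counts.counts[s2_].sum(axis=1) == 0)
    ).to_numpy()
    lfc = np.where(allzero, 0.0, lfc)
    p = np.where(allzero, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "mean_log2cpm": amean,
        },
        index=counts.counts.index,
    )
    if counts.lengths is not None:
        lr = log2_rpkm(counts)
        table[f"mean_log2rpkm_{g1}"] = lr[s1].mean(axis=1)
        table[f"mean_log2rpkm_{g2}"] = lr[s2_].mean(axis=1)
    table["call"] = classify_de(table, lfc_cut=lfc_cut, p_cut=p_cut, use_fdr=use_fdr)
    return DEResult(table, contrast, prior_df=d0, tmm=factors)


def classify_de(
    table: pd.DataFrame,
    lfc_cut: float = 2.0,
    p_cut: float = 0.01,
    fdr_cut: float | None = None,
    use_fdr: bool = True,
) -> pd.Series:
    """Call genes up_in_mutant / up_in_WT / ns at fold-change and FDR cuts.

    up_in_mutant iff log2FC >= lfc_cut and (FDR or p) < cut; up_in_WT iff
    log2FC <= -lfc_cut under the same significance rule; otherwise ns.
    """
    if fdr_cut is not None:  # backward-friendly alias
        p_cut, use_fdr = fdr_cut, True
    sig = (table["fdr"] if use_fdr else table["p"]) < p_cut
    call = pd.Series("ns", index=table.index, name="call")
    call[(table["log2fc"] >= lfc_cut) & sig] = "up_in_mutant"
    call[(table["log2fc"] <= -lfc_cut) & sig] = "up_in_WT"
    return call
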