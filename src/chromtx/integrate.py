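"""Mark x expression integration: gene groups, category enrichment, K9 domains.

This module crosses per-gene chromatin-mark levels with differential-expression
calls and functional categories:

* mark-tier splits at the published thresholds (low iff log2 level <= 5 for
  H3K4me3, <= 2 for H3K36me3; boundary values are low);
* correlation groups G1-G4 (primary metabolism) / G5-G8 (secondary
  metabolism): low/high mark x up-in-WT/up-in-mutant;
* one-sided hypergeometric enrichment of a category within a gene set;
* per-category deregulation percentages and mark-level summaries;
* H3K9me3 domain calling (thresholded runs with gap merging) and SM-cluster
  flanking classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .tracks import BinnedTrack

__all__ = [
    "MARK_TIER_THRESHOLDS",
    "split_by_mark",
    "assign_groups",
    "category_enrichment",
    "deregulation_fractions",
    "category_mark_summary",
    "call_k9_domains",
    "cluster_flanking",
]

#: Published log2-level split points per mark (boundary goes to "low").
MARK_TIER_THRESHOLDS: dict[str, float] = {"H3K4me3": 5.0, "H3K36me3": 2.0}

# group labels: (tier, call) -> label; base index 1 for PM (G1-G4), 5 for SM (G5-G8)
_GROUP_OFFSETS = {
    ("low", "up_in_WT"): 0,
    ("low", "up_in_mutant"): 1,
    ("high", "up_in_WT"): 2,
    ("high", "up_in_mutant"): 3,
}


def split_by_mark(
    levels: pd.Series, mark: str | None = None, threshold_log2: float | None = None
) -> pd.Series:
    """Tier genes as low (level <= threshold) or high (> threshold).

    ``levels`` are per-gene log2 mark levels; NaN entries (e.g. genes whose
    window is mostly off-contig) are excluded and reported via the
    ``skipped`` attribute on the returned series.
    """
    if threshold_log2 is None:
        if mark is None or mark not in MARK_TIER_THRESHOLDS:
            raise ValueError(
                f"no default threshold for mark {mark!r}; "
                f"known: {sorted(MARK_TIER_THRESHOLDS)}"
            )
        threshold_log2 = MARK_TIER_THRESHOLDS[mark]
    ok = levels.notna()
    tier = pd.Series(
        np.where(levels[ok] <= threshold_log2, "low", "high"),
        index=levels.index[ok],
        name="mark_tier",
    )
    tier.attrs["skipped"] = list(levels.index[~ok])
    tier.attrs["threshold_log2"] = threshold_log2
    return tier


def assign_groups(
    tiers: pd.Series, de_calls: pd.Series, base: int = 1
) -> pd.DataFrame:
    """Assign correlation groups from mark tier x DE call.

    G(base+0) = low & up_in_WT, G(base+1) = low & up_in_mutant,
    G(base+2) = high & up_in_WT, G(base+3) = high & up_in_mutant; genes with
    ``ns`` calls (or without a tier) get no group.  ``base=1`` yields G1-G4
    (primary metabolism), ``base=5`` G5-G8 (secondary metabolism).
    """
    idx = tiers.index.intersection(de_calls.index)
    out = pd.DataFrame(
        {"mark_tier": tiers.reindex(idx), "call": de_calls.reindex(idx)}, index=idx
    )
    labels = pd.Series(pd.NA, index=idx, dtype="object", name="group")
    for (tier, call), off in _GROUP_OFFSETS.items():
        labels[(out["mark_tier"] == tier) & (out["call"] == call)] = f"G{base + off}"
    out["group"] = labels
    return out


@dataclass
class EnrichmentResult:
    """One-sided (upper-tail) hypergeometric overlap test of set vs category."""

    k: int  # category genes in set
    K: int  # category size
    n: int  # set size
    N: int  # universe size
    p: float
    odds_ratio: float

    @property
    def table(self) -> np.ndarray:
        """2x2 table [[cat&set, cat-not-set], [other&set, other-not-set]]."""
        return np.array(
            [
                [self.k, self.K - self.k],
                [self.n - self.k, self.N - self.K - (self.n - self.k)],
            ]
        )


def category_enrichment(
    gene_set, categories: pd.Series, target_category: str, universe=None
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric enrichment of a category in a gene set.

    ``categories`` maps gene id -> category label; the universe defaults to
    all mapped genes.  p = P(overlap >= observed) under sampling without
    replacement — exact for any genome-scale N.
    """
    categories = categories.dropna()
    universe = pd.Index(universe) if universe is not None else categories.index
    gene_set = pd.Index(gene_set).intersection(universe)
    cat_genes = categories.index[categories == target_category].intersection(universe)
    N, K, n = len(universe), len(cat_genes), len(gene_set)
    if K == 0:
        raise ValueError(f"category {target_category!r} empty in universe")
    k = len(gene_set.intersection(cat_genes))
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
    a, b = k, K - k
    c, d = n - k, N - K - (n - k)
    odds = (a * d) / (b * c) if b * c else np.inf
    return EnrichmentResult(k=k, K=K, n=n, N=N, p=min(p, 1.0), odds_ratio=odds)


def deregulation_fractions(de_calls: pd.Series, categories: pd.Series) -> pd.DataFrame:
    """Percent up / down / either per category (denominator = category size)."""
    rows = []
    for cat, members in categories.groupby(categories):
        idx = members.index
        calls = de_calls.reindex(idx)
        n = len(idx)
        up = int((calls == "up_in_mutant").sum())
        down = int((calls == "up_in_WT").sum())
        rows.append(
            {
                "category": cat,
                "n_genes": n,
                "n_up": up,
                "n_down": down,
                "pct_up": 100.0 * up / n,
                "pct_down": 100.0 * down / n,
                "pct_deregulated": 100.0 * (up + down) / n,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def category_mark_summary(
    levels: pd.Series, categories: pd.Series, compare: tuple[str, str] = ("CSF", "SM")
) -> pd.DataFrame:
    """Median/quartiles of log2 mark level per category + rank-sum comparison.

    The two categories named in ``compare`` are additionally tested against
    each other with a two-sided Mann-Whitney U; its p-value is attached to
    the result's ``attrs["mannwhitney_p"]``.
    """
    rows = []
    for cat, members in categories.groupby(categories):
        vals = levels.reindex(members.index).dropna()
        rows.append(
            {
                "category": cat,
                "n": len(vals),
                "q25": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "median": float(vals.median()) if len(vals) else np.nan,
                "q75": float(vals.quantile(0.75)) if len(vals) else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    a = levels.reindex(categories.index[categories == compare[0]]).dropna()
    b = levels.reindex(categories.index[categories == compare[1]]).dropna()
    if len(a) and len(b):
        out.attrs["mannwhitney_p"] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )
    return out


def call_k9_domains(
    binned: BinnedTrack,
    threshold_cpm: float | None = None,
    min_len: int = 2000,
    merge_gap: int = 500,
) -> pd.DataFrame:
    """Call broad heterochromatic domains on a (H3K9me3) binned track.

    Maximal runs of bins at or above ``threshold_cpm`` (default: 4x the
    genome-wide median of nonzero bin values) are merged across gaps of at
    most ``merge_gap`` bp and filtered to ``min_len`` bp.  Returns BED-like
    rows (chrom, start, end, mean_cpm), deterministic.
    """
    if threshold_cpm is None:
        nz = np.concatenate([v[v > 0] for v in binned.data.values()]) if binned.data else []
        threshold_cpm = 4.0 * float(np.median(nz)) if len(nz) else np.inf
    step = binned.step
    rows = []
    for chrom in sorted(binned.data):
        vals = binned.data[chrom]
        L = binned.genome_lengths.get(chrom, len(vals) * step)
        above = vals >= threshold_cpm
        if not above.any():
            continue
        # runs of True at bin resolution
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([idx[0]], idx[breaks + 1])) * step
        run_ends = np.minimum((np.concatenate((idx[breaks], [idx[-1]])) + 1) * step, L)
        # merge across small gaps
        merged = [[run_starts[0], run_ends[0]]]
        for s, e in zip(run_starts[1:], run_ends[1:]):
            if s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_len:
                seg = vals[s // step: (e + step - 1) // step]
                rows.append(
                    {"chrom": chrom, "start": int(s), "end": int(e),
                     "mean_cpm": float(seg.mean())}
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_cpm"])


def cluster_flanking(
    domains: pd.DataFrame, ann: GenomeAnnotation, max_gap: int = 5000
) -> pd.DataFrame:
    """Classify each SM cluster by proximity of heterochromatic domains.

    For each cluster's outermost coordinates, the distance to the nearest
    domain entirely left of the start and right of the end is measured
    (0 when a domain overlaps the boundary); sides within ``max_gap`` bp are
    flanked.  Classification: both / one / none.
    """
    ext = ann.cluster_extents()
    rows = []
    for cid, cl in ext.iterrows():
        sub = domains[domains["chrom"] == cl["chrom"]] if len(domains) else domains
        left = right = np.inf
        for _, d in sub.iterrows():
            if d["end"] <= cl["start"]:
                left = min(left, cl["start"] - d["end"])
            elif d["start"] >= cl["end"]:
                right = min(right, d["start"] - cl["end"])
            else:  # domain overlaps the cluster boundary region
                if d["start"] < cl["start"]:
                    left = 0
                if d["end"] > cl["end"]:
                    right = 0
        fl, fr = left <= max_gap, right <= max_gap
        rows.append(
            {
                "cluster_id": cid,
                "chrom": cl["chrom"],
                "start": int(cl["start"]),
                "end": int(cl["end"]),
                "dist_left": left,
                "dist_right": right,
                "flanked_left": fl,
                "flanked_right": fr,
                "classification": "both" if fl and fr else ("one" if fl or fr else "none"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "dist_left", "dist_right",
            "flanked_left", "flanked_right", "classification",
        ],
    ).set_index("cluster_id")
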