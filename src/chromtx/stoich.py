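"""Histone-PTM stoichiometry from peptide-form relative abundances.

Input is a long-format table of (site, form, strain, abundance) where a site
is a proteolytic histone peptide carrying one or more modifiable residues
(e.g. H3K4; the composite H3K9K14 and H3K27K36 peptides keep their joint form
labels — the per-residue marginals are not identifiable from form-level
ratios and are not deconvolved).  Abundances per site and strain are
normalized to fractions summing to 1; aggregates (total methylation) and
strain comparisons (absolute percentage-point and relative percent change)
are computed on the normalized fractions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "METHYL_FORMS",
    "form_fractions",
    "aggregate_methylation",
    "compare_strains",
    "stoichiometry_summary",
]

#: Form labels that count as carrying at least one methyl group.
METHYL_FORMS = ("me1", "me2", "me3")


def _validate_long(table: pd.DataFrame) -> pd.DataFrame:
    required = {"site", "form", "strain", "abundance"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if (table["abundance"] < 0).any():
        raise ValueError("negative abundance")
    return table


def form_fractions(table: pd.DataFrame, warn_tol: float = 0.01) -> pd.DataFrame:
    """Renormalize per-(site, strain) abundances to fractions summing to 1.

    Inputs may be percentages, raw intensities or fractions; groups whose sum
    deviates from 1 by more than ``warn_tol`` after interpreting them as
    fractions-of-100 or fractions-of-1 are renormalized with a warning.
    """
    t = _validate_long(table).copy()
    out = []
    for (site, strain), grp in t.groupby(["site", "strain"], sort=True):
        total = grp["abundance"].sum()
        if total <= 0:
            raise ValueError(f"all-zero abundances for {site}/{strain}")
        frac = grp["abundance"] / total
        # warn when input was plausibly meant as fractions but is inconsistent
        if abs(total - 1.0) <= 0.5 and abs(total - 1.0) > warn_tol:
            warnings.warn(
                f"{site}/{strain}: input fractions sum to {total:.4f}; renormalized",
                stacklevel=2,
            )
        g = grp.copy()
        g["fraction"] = frac
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    return res[["site", "form", "strain", "fraction"]]


def aggregate_methylation(fractions: pd.DataFrame, site: str, strain: str) -> float:
    """Percent of peptides at ``site`` carrying at least one methyl group.

    Sums the me1 + me2 + me3 fractions; for a pure methyl site this equals
    100 minus the unmodified (me0) percentage exactly.
    """
    sub = fractions[(fractions["site"] == site) & (fractions["strain"] == strain)]
    if sub.empty:
        raise KeyError(f"no rows for site {site!r}, strain {strain!r}")
    return float(sub.loc[sub["form"].isin(METHYL_FORMS), "fraction"].sum() * 100.0)


def compare_strains(
    fractions: pd.DataFrame, site: str, form: str, wt: str, mutant: str
) -> tuple[float, float]:
    """(absolute change in percentage points, relative change in %) mutant vs WT."""
    def _get(strain: str) -> float:
        sub = fractions[
            (fractions["site"] == site)
            & (fractions["form"] == form)
            & (fractions["strain"] == strain)
        ]
        if sub.empty:
            raise KeyError(f"no row for {site}/{form}/{strain}")
        return float(sub["fraction"].iloc[0])

    w, m = _get(wt), _get(mutant)
    absolute_pp = (m - w) * 100.0
    relative_pct = (m - w) / w * 100.0 if w != 0 else np.inf if m != 0 else 0.0
    return absolute_pp, relative_pct


def stoichiometry_summary(
    fractions: pd.DataFrame, wt: str = "WT", mutant: str | None = None
) -> pd.DataFrame:
    """Per-site per-strain form percentages plus methylation aggregates.

    When ``mutant`` is given, absolute (pp) and relative (%) changes of each
    form vs the wild-type strain are included.
    """
    rows = []
    for (site, strain), grp in fractions.groupby(["site", "strain"], sort=True):
        for _, r in grp.iterrows():
            row = {
                "site": site,
                "strain": strain,
                "form": r["form"],
                "percent": r["fraction"] * 100.0,
            }
            if mutant is not None and strain == mutant:
                try:
                    abs_pp, rel = compare_strains(fractions, site, r["form"], wt, mutant)
                    row["abs_change_pp"], row["rel_change_pct"] = abs_pp, rel
                except KeyError:
                    pass
            rows.append(row)
        has_methyl = grp["form"].isin(METHYL_FORMS).any()
        if has_methyl:
            rows.append(
                {
                    "site": site,
                    "strain": strain,
                    "form": "total_methylated",
                    "percent": aggregate_methylation(fractions, site, strain),
                }
            )
    return pd.DataFrame(rows)
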