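"""Synthetic genomes, coverage tracks, count matrices and peptide tables.

The generator plants the structure the downstream analysis assumes, with
exported ground truth, so the whole pipeline is testable without external
data:

* gene-anchored mark kernels — H3K4me3 as a Gaussian bump over the first
  ~500 bp of the coding region (center +250, sigma 150), H3Ac over the first
  nucleosome (+75, sigma 75), H3K36me3 as a linear ramp rising toward the
  stop codon, H3K9me3 as rectangular blocks at chromosome termini and at the
  flanks of a configurable fraction of SM clusters;
* negative-binomial counts with planted 4-fold strain effects whose
  per-category rates default to the 48-h deregulation rates of the emulated dataset
  (SM genes far more often down in the mutant than basic-metabolism genes);
* a large CSF category vs a small category of physically clustered SM genes,
  with SM genes planted at one eighth of the CSF H3K4me3 amplitude;
* Dirichlet-noised peptide-form fraction tables around the measured
  wild-type/mutant stoichiometries.

All randomness flows from one seed through numpy ``SeedSequence`` spawn keys:
(0,) genome, (1, mark, strain) coverage, (2,) counts, (3,) peptides.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    GenomeAnnotation,
    write_bed,
    write_category_map,
    write_gff3,
)
from .tracks import CoverageTrack, write_bedgraph

__all__ = [
    "MARKS",
    "STRAINS",
    "SimConfig",
    "GroundTruth",
    "gen_genome",
    "gen_coverage",
    "gen_counts",
    "gen_peptide_table",
    "default_peptide_truth",
    "write_fixtures",
]

MARKS = ("H3K4me3", "H3Ac", "H3K36me3", "H3K9me3")
STRAINS = ("WT", "kdmBD")

_TIER_MULT = {"low": 0.25, "mid": 1.0, "high": 2.0}
# SM genes carry a fraction of the CSF amplitude per activating mark
_SM_ATTENUATION = {"H3K4me3": 0.125, "H3Ac": 0.25, "H3K36me3": 0.25}


def _default_mark_params() -> dict:
    return {
        "H3K4me3": {"center": 250, "sigma": 150, "amp": 30.0},
        "H3Ac": {"center": 75, "sigma": 75, "amp": 20.0},
        "H3K36me3": {"amp": 20.0},
        "H3K9me3": {"height": 15.0, "block_len": 5000},
    }


@dataclass
class SimConfig:
    """Benchmark-condition parameters for the synthetic genome and data.

    DE rates default to the emulated 48-h per-direction deregulation rates
    (401/5676 down and 547/5676 up in the mutant for basic-metabolism genes;
    97/149 down and 22/149 up for SM genes) with a planted |log2FC| of 2
    (4-fold) and 4 replicates per group.
    """

    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 220
    gene_length_range: tuple[int, int] = (900, 2400)
    n_sm_clusters: int = 4
    sm_cluster_size: int = 6
    frac_k9_flanked_clusters: float = 0.5
    mark_shape_params: dict = field(default_factory=_default_mark_params)
    background_lambda: float = 1.0
    nb_mean_logsd: float = 1.0
    nb_dispersion: float = 0.05
    planted_lfc: float = 2.0
    frac_de_down: float = 401 / 5676   # CSF genes up in WT (down in mutant)
    frac_de_up: float = 547 / 5676     # CSF genes up in mutant
    sm_frac_down: float = 97 / 149
    sm_frac_up: float = 22 / 149
    n_replicates: int = 4
    depth: float = 2_000_000.0
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_k9_flanked_clusters", "frac_de_down", "frac_de_up",
                     "sm_frac_down", "sm_frac_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_de_down + self.frac_de_up > 1 or self.sm_frac_down + self.sm_frac_up > 1:
            raise ValueError("per-direction DE fractions must sum to <= 1")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid gene_length_range")
        if self.chrom_length % 10:
            raise ValueError("chrom_length must be a multiple of the 10-bp bin grid")
        if self.n_sm_clusters * self.sm_cluster_size > self.n_genes:
            raise ValueError("more SM-cluster genes than genes")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group for DE testing")
        margin = self.mark_shape_params["H3K9me3"]["block_len"]
        per_chrom = -(-self.n_genes // self.n_chromosomes)
        budget = self.chrom_length - 2 * margin
        need = per_chrom * hi + (per_chrom + 1) * 10
        if need > budget:
            raise ValueError(
                f"infeasible packing: {per_chrom} genes up to {hi} bp need {need} bp "
                f"but only {budget} bp fit between the terminal {margin}-bp margins "
                f"of a {self.chrom_length}-bp chromosome"
            )

    def rng(self, *spawn_key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn_key))


@dataclass
class GroundTruth:
    """Planted truth: per-gene table, per-cluster table, peptide fractions."""

    genes: pd.DataFrame     # category, cluster_id, tier, baseline, true_<mark>, de_direction, true_lfc
    clusters: pd.DataFrame  # chrom, start, end, k9_flanked (+ block coords)
    peptides: pd.DataFrame  # site, form, strain, fraction


def default_peptide_truth() -> pd.DataFrame:
    """Measured histone H3 peptide-form stoichiometries used as planted truth.

    H3K4 (T3-R8 peptide): WT me3/me2/me1 = 47.5/13.5/10.3 %, me0 by
    complement; mutant me3 = 57 % with the remainder scaled down
    proportionally.  H3K9K14 composite peptide: K9me3-containing forms at
    1.53 % (WT) vs 0.2 % (mutant); unmodified 22 % vs 6 %, acetylated rest.
    """
    rows = [
        ("H3K4", "me0", "WT", 0.287),
        ("H3K4", "me1", "WT", 0.103),
        ("H3K4", "me2", "WT", 0.135),
        ("H3K4", "me3", "WT", 0.475),
        ("H3K4", "me0", "kdmBD", 0.287 * 0.43 / 0.525),
        ("H3K4", "me1", "kdmBD", 0.103 * 0.43 / 0.525),
        ("H3K4", "me2", "kdmBD", 0.135 * 0.43 / 0.525),
        ("H3K4", "me3", "kdmBD", 0.57),
        ("H3K9K14", "me3", "WT", 0.0153),
        ("H3K9K14", "unmod", "WT", 0.22),
        ("H3K9K14", "ac", "WT", 1.0 - 0.0153 - 0.22),
        ("H3K9K14", "me3", "kdmBD", 0.002),
        ("H3K9K14", "unmod", "kdmBD", 0.06),
        ("H3K9K14", "ac", "kdmBD", 1.0 - 0.002 - 0.06),
    ]
    return pd.DataFrame(rows, columns=["site", "form", "strain", "fraction"])


def _round10(x: int) -> int:
    return int(x) - int(x) % 10


def gen_genome(config: SimConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Generate a non-overlapping gene annotation with planted ground truth.

    Genes sit on a 10-bp grid between heterochromatin-sized terminal margins;
    SM clusters are contiguous runs of genes on one chromosome.  Per-gene
    truth records category, expression tier, baseline mean, relative mark
    amplitudes and the planted DE direction/log2FC; per-cluster truth records
    the flanking-domain flag and block coordinates.
    """
    config.validate()
    rng = config.rng(0)
    lo, hi = config.gene_length_range
    margin = config.mark_shape_params["H3K9me3"]["block_len"]
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    counts = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    counts[: config.n_genes % config.n_chromosomes] += 1

    rows = []
    gi = 0
    for chrom, n in zip(chroms, counts):
        lengths = np.array([_round10(v) for v in rng.integers(lo, hi + 1, n)])
        lengths = np.maximum(lengths, _round10(lo) or 10)
        space = config.chrom_length - 2 * margin
        slack = space - lengths.sum()
        if slack < 0:
            raise ValueError("infeasible packing: genes exceed chromosome budget")
        gaps = rng.multinomial(slack // 10, np.full(n + 1, 1.0 / (n + 1))) * 10
        pos = margin
        for j in range(n):
            pos += gaps[j]
            start = _round10(pos)
            end = start + lengths[j]
            rows.append(
                {
                    "gene_id": f"g{gi:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": rng.choice(["+", "-"]),
                    "category": "CSF",
                    "cluster_id": np.nan,
                }
            )
            pos = end
            gi += 1
    genes = pd.DataFrame(rows).set_index("gene_id")

    # contiguous SM-cluster runs, non-overlapping, each inside one chromosome
    order = genes.reset_index()
    taken: set[int] = set()
    cluster_rows = []
    cid = 0
    attempts = 0
    while cid < config.n_sm_clusters:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place SM clusters; reduce count or size")
        chrom = chroms[int(rng.integers(len(chroms)))]
        members = order.index[order["chrom"] == chrom]
        if len(members) < config.sm_cluster_size:
            continue
        s = int(rng.integers(0, len(members) - config.sm_cluster_size + 1))
        run = list(members[s: s + config.sm_cluster_size])
        if any(i in taken for i in run):
            continue
        taken.update(run)
        ids = order.loc[run, "gene_id"]
        genes.loc[ids, "category"] = "SM"
        genes.loc[ids, "cluster_id"] = float(cid)
        cluster_rows.append(
            {
                "cluster_id": cid,
                "chrom": chrom,
                "start": int(genes.loc[ids, "start"].min()),
                "end": int(genes.loc[ids, "end"].max()),
            }
        )
        cid += 1
    clusters = pd.DataFrame(
        cluster_rows, columns=["cluster_id", "chrom", "start", "end"]
    ).set_index("cluster_id")

    # flanking flags: exactly round(frac * n) clusters, chosen at random
    n_flanked = int(round(config.frac_k9_flanked_clusters * len(clusters)))
    flagged = rng.permutation(len(clusters))[:n_flanked]
    clusters["k9_flanked"] = False
    clusters.loc[clusters.index[flagged], "k9_flanked"] = True
    block = config.mark_shape_params["H3K9me3"]["block_len"]
    clusters["block_left_start"] = np.maximum(clusters["start"] - block, 0)
    clusters["block_right_end"] = np.minimum(clusters["end"] + block, config.chrom_length)

    # expression tiers and baselines
    mu = rng.normal(5.0, config.nb_mean_logsd, len(genes))
    baseline = 2.0 ** mu
    tier_edges = np.quantile(mu, [1 / 3, 2 / 3])
    tier = np.where(mu <= tier_edges[0], "low", np.where(mu <= tier_edges[1], "mid", "high"))

    truth_genes = pd.DataFrame(
        {
            "category": genes["category"],
            "cluster_id": genes["cluster_id"],
            "tier": tier,
            "baseline": baseline,
        },
        index=genes.index,
    )
    for mark in ("H3K4me3", "H3Ac", "H3K36me3"):
        level = pd.Series(tier, index=genes.index).map(_TIER_MULT)
        level[genes["category"] == "SM"] *= _SM_ATTENUATION[mark]
        truth_genes[f"true_{mark}"] = level
    truth_genes["true_H3K9me3"] = 0.0

    # planted DE directions (+1 = up in mutant, -1 = up in WT)
    u = rng.random(len(genes))
    is_sm = (genes["category"] == "SM").to_numpy()
    p_down = np.where(is_sm, config.sm_frac_down, config.frac_de_down)
    p_up = np.where(is_sm, config.sm_frac_up, config.frac_de_up)
    direction = np.where(u < p_down, -1, np.where(u < p_down + p_up, 1, 0))
    truth_genes["de_direction"] = direction
    truth_genes["true_lfc"] = direction * config.planted_lfc

    ann = GenomeAnnotation(genes, {c: config.chrom_length for c in chroms})
    truth = GroundTruth(truth_genes, clusters, default_peptide_truth())
    return ann, truth


def gen_coverage(
    ann: GenomeAnnotation,
    truth: GroundTruth,
    mark: str,
    strain: str = "WT",
    config: SimConfig | None = None,
) -> CoverageTrack:
    """Poisson per-bp coverage around the mark's kernel plus uniform background.

    The mutant strain doubles the H3K4me3 amplitude of genes planted up in
    the mutant and halves it for genes planted down, mirroring the observed
    coupling between this mark and transcription.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; supported: {list(MARKS)}")
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}; supported: {list(STRAINS)}")
    config = config or SimConfig()
    rng = config.rng(1, MARKS.index(mark), STRAINS.index(strain))
    params = config.mark_shape_params[mark]
    lam = {
        c: np.full(L, config.background_lambda, dtype=float)
        for c, L in ann.chrom_lengths.items()
    }

    if mark == "H3K9me3":
        height = params["height"]
        block = params["block_len"]
        for c, arr in lam.items():
            arr[:block] += height
            arr[-block:] += height
        for _, cl in truth.clusters.iterrows():
            if not cl["k9_flanked"]:
                continue
            arr = lam[cl["chrom"]]
            arr[int(cl["block_left_start"]): int(cl["start"])] += height
            arr[int(cl["end"]): int(cl["block_right_end"])] += height
    else:
        for gid, row in ann.genes.iterrows():
            level = float(truth.genes.loc[gid, f"true_{mark}"])
            if mark == "H3K4me3" and strain == "kdmBD":
                d = int(truth.genes.loc[gid, "de_direction"])
                level *= 2.0 if d == 1 else (0.5 if d == -1 else 1.0)
            if level <= 0:
                continue
            glen = int(row["end"] - row["start"])
            arr = lam[row["chrom"]]
            if mark == "H3K36me3":
                kern = params["amp"] * level * (np.arange(glen) + 1) / glen
                offsets = np.arange(glen)
            else:
                offsets = np.arange(-500, min(glen, 1500))
                kern = (
                    params["amp"] * level
                    * np.exp(-0.5 * ((offsets - params["center"]) / params["sigma"]) ** 2)
                )
            if row["strand"] == "+":
                genomic = int(row["start"]) + offsets
            else:
                genomic = int(row["end"]) - offsets - 1
            ok = (genomic >= 0) & (genomic < len(arr))
            np.add.at(arr, genomic[ok], kern[ok])

    data = {c: rng.poisson(a).astype(float) for c, a in sorted(lam.items())}
    total = sum(a.sum() for a in data.values())
    track = CoverageTrack(data, total_mapped_reads=max(1, int(round(total / config.read_length))))
    return track


def default_design(config: SimConfig) -> pd.Series:
    """Sample -> group labels: n_replicates per strain."""
    labels = {}
    for strain in STRAINS:
        for r in range(config.n_replicates):
            labels[f"{strain}_{r + 1}"] = strain
    return pd.Series(labels, name="group")


def gen_counts(
    ann: GenomeAnnotation,
    truth: GroundTruth,
    design: pd.Series | None = None,
    config: SimConfig | None = None,
):
    """Negative-binomial gene x sample counts with the planted strain effects.

    Mean for gene g in sample s is ``depth x lib_s x p_g x 2^lfc_g`` (lfc
    applied in mutant samples), with NB dispersion ``nb_dispersion``
    (Poisson in the limit of zero dispersion).  Library factors jitter the
    per-sample depth by ~10 %.
    """
    from .diffexpr import CountMatrix  # local import to avoid cycle

    config = config or SimConfig()
    design = design if design is not None else default_design(config)
    for grp, cnt in design.value_counts().items():
        if cnt < 2:
            raise ValueError(f"group {grp!r} has {cnt} replicate(s); need >= 2")
    rng = config.rng(2)
    base = truth.genes["baseline"].to_numpy()
    p = base / base.sum()
    lfc = truth.genes["true_lfc"].to_numpy()
    cols = {}
    for sample, grp in design.items():
        lib = config.depth * rng.lognormal(0.0, 0.1)
        mu = lib * p * (2.0 ** lfc if grp == "kdmBD" else 1.0)
        if config.nb_dispersion < 1e-8:
            cols[sample] = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            cols[sample] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(cols, index=ann.genes.index)
    return CountMatrix(counts, groups=design, lengths=ann.orf_length)


def gen_peptide_table(
    true_fractions: pd.DataFrame,
    noise_concentration: float = 200.0,
    seed: int | None = None,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Observed peptide-form abundances: Dirichlet around the true fractions.

    Per (site, strain), observed fractions are drawn from
    Dirichlet(concentration x truth) restricted to forms with positive truth
    (zeros stay exactly zero); an infinite concentration returns the truth.
    Input fractions must sum to 1 per site and strain within 1e-9.
    """
    if noise_concentration <= 0:
        raise ValueError("noise_concentration must be positive")
    if seed is None:
        rng = (config or SimConfig()).rng(3)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    out = []
    for (site, strain), grp in true_fractions.groupby(["site", "strain"], sort=True):
        frac = grp["fraction"].to_numpy(dtype=float)
        if (frac < 0).any():
            raise ValueError(f"negative true fraction for {site}/{strain}")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"true fractions for {site}/{strain} sum to {frac.sum()!r}, not 1"
            )
        obs = frac.copy()
        if np.isfinite(noise_concentration):
            pos = frac > 0
            obs[pos] = rng.dirichlet(noise_concentration * frac[pos])
        g = grp.copy()
        g["abundance"] = obs
        out.append(g[["site", "form", "strain", "abundance"]])
    return pd.concat(out, ignore_index=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixtures(
    out_dir,
    ann: GenomeAnnotation,
    truth: GroundTruth,
    coverage: dict[str, CoverageTrack] | None = None,
    counts=None,
    peptides: pd.DataFrame | None = None,
) -> dict:
    """Write all artifacts as plain-text files and return a checksum manifest.

    Annotation goes out as GFF3 and BED6, coverage as bedGraph (with mapped-
    read totals in the manifest), counts/design/categories/peptides/truth as
    TSV.  Identical inputs produce byte-identical files.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}

    def _note(path, **meta):
        files[path.name] = {"sha256": _sha256(path), **meta}

    p = out / "annotation.gff3"
    write_gff3(ann, p)
    _note(p)
    p = out / "annotation.bed"
    write_bed(ann, p)
    _note(p)
    p = out / "categories.tsv"
    write_category_map(ann, p)
    _note(p)

    for name, track in (coverage or {}).items():
        p = out / f"coverage_{name}.bedgraph"
        write_bedgraph(track, p)
        _note(p, total_mapped_reads=track.total_mapped_reads)

    if counts is not None:
        p = out / "counts.tsv"
        counts.counts.to_csv(p, sep="\t", index_label="gene_id")
        _note(p)
        p = out / "design.tsv"
        counts.groups.rename("group").to_csv(p, sep="\t", index_label="sample_id")
        _note(p)
        p = out / "orf_lengths.tsv"
        counts.lengths.rename("orf_length").to_csv(p, sep="\t", index_label="gene_id")
        _note(p)

    if peptides is not None:
        p = out / "peptide_forms.tsv"
        peptides.to_csv(p, sep="\t", index=False)
        _note(p)

    p = out / "truth_genes.tsv"
    truth.genes.to_csv(p, sep="\t", index_label="gene_id")
    _note(p)
    p = out / "truth_clusters.tsv"
    truth.clusters.to_csv(p, sep="\t", index_label="cluster_id")
    _note(p)
    p = out / "truth_peptides.tsv"
    truth.peptides.to_csv(p, sep="\t", index=False)
    _note(p)

    manifest = {"files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
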