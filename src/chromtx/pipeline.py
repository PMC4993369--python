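"""End-to-end orchestration: simulate, normalize, profile, test, integrate.

``run_demo`` drives every stage on a synthetic genome and writes a report
bundle of plain TSV tables mirroring the headline analyses: metagene
profiles, per-gene mark quantification, differential expression, G1-G4 group
counts, category deregulation percentages and mark summaries, K9-domain
flanking of SM clusters, and the peptide stoichiometry summary.  A JSON run
log records parameters, seeds and output checksums; identical configs give
byte-identical bundles.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import diffexpr, integrate, metagene, stoich, synthetic, tracks

__all__ = ["run_demo", "load_report"]


def run_demo(
    out_dir,
    config: synthetic.SimConfig | None = None,
    profile: str = "fig6",
    window: int = 100,
    step: int = 10,
    k9_min_len: int = 2000,
    k9_merge_gap: int = 500,
    flank_max_gap: int = 5000,
    write_fixture_files: bool = True,
) -> dict:
    """Run the full synthetic pipeline and write a report bundle.

    Returns a dict of in-memory results keyed by stage.  The ``fig6``
    threshold profile (4-fold, FDR < 0.05) is the default contrast for the
    category-level statistics.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or synthetic.SimConfig()
    log: dict = {"config": _jsonable(asdict(cfg)), "profile": profile, "stages": []}

    def _stage(name):
        log["stages"].append({"name": name, "t": round(time.time() - t0, 3)})

    # 1. simulate
    ann, truth = synthetic.gen_genome(cfg)
    coverage = {
        f"{mark}_{strain}": synthetic.gen_coverage(ann, truth, mark, strain, cfg)
        for mark in synthetic.MARKS
        for strain in synthetic.STRAINS
    }
    counts = synthetic.gen_counts(ann, truth, config=cfg)
    peptides = synthetic.gen_peptide_table(truth.peptides, config=cfg)
    if write_fixture_files:
        synthetic.write_fixtures(out / "fixtures", ann, truth, coverage, counts, peptides)
    _stage("simulate")

    # 2. normalize + smooth every track
    binned = {
        name: tracks.smooth_and_bin(tracks.cpm_normalize(tr), window=window, step=step)
        for name, tr in coverage.items()
    }
    _stage("tracks")

    # 3. metagene profiles and per-gene quantification (WT H3K4me3 anchor=ATG)
    atg_spec = metagene.WindowSpec("ATG", 500, 1500)
    quant = {
        name: metagene.quantify_gene_mark(b, ann, atg_spec)
        for name, b in binned.items()
        if not name.startswith("H3K9me3")
    }
    k4 = quant["H3K4me3_WT"]
    profiles = {
        "H3K4me3_WT_all": metagene.metagene_profile(
            metagene.gene_windows(binned["H3K4me3_WT"], ann, atg_spec)
        ),
        "H3Ac_WT_all": metagene.metagene_profile(
            metagene.gene_windows(binned["H3Ac_WT"], ann, atg_spec)
        ),
        "H3K36me3_WT_all": metagene.metagene_profile(
            metagene.gene_windows(
                binned["H3K36me3_WT"], ann, metagene.WindowSpec("STOP", 1500, 500)
            )
        ),
    }
    _stage("metagene")

    # 4. differential expression (mutant vs WT)
    de = diffexpr.de_test(counts, contrast=("kdmBD", "WT"), profile=profile)
    _stage("de")

    # 5. integration: tiers, groups, categories, enrichment
    tiers = integrate.split_by_mark(
        k4["log2_window_mean"].where(k4["usable"]), mark="H3K4me3"
    )
    groups = integrate.assign_groups(tiers, de.table["call"])
    categories = ann.genes["category"]
    dereg = integrate.deregulation_fractions(de.table["call"], categories)
    down_genes = de.table.index[de.table["call"] == "up_in_WT"]
    enrich = integrate.category_enrichment(down_genes, categories, "SM")
    mark_summary = integrate.category_mark_summary(k4["log2_window_mean"], categories)
    _stage("integrate")

    # 6. H3K9me3 domains and SM-cluster flanking
    domains = integrate.call_k9_domains(
        binned["H3K9me3_WT"], min_len=k9_min_len, merge_gap=k9_merge_gap
    )
    flanks = integrate.cluster_flanking(domains, ann, max_gap=flank_max_gap)
    _stage("k9_domains")

    # 7. peptide stoichiometry
    fracs = stoich.form_fractions(peptides)
    stoich_summary = stoich.stoichiometry_summary(fracs, wt="WT", mutant="kdmBD")
    _stage("stoichiometry")

    # write report tables
    for name, prof in profiles.items():
        prof.to_csv(out / f"profile_{name}.tsv", sep="\t")
    k4.to_csv(out / "quant_H3K4me3_WT.tsv", sep="\t", index_label="gene_id")
    de.table.to_csv(out / "de_results.tsv", sep="\t", index_label="gene_id")
    groups.to_csv(out / "gene_groups.tsv", sep="\t", index_label="gene_id")
    group_counts = groups["group"].value_counts().sort_index()
    group_counts.rename("n_genes").to_csv(out / "group_counts.tsv", sep="\t", index_label="group")
    dereg.to_csv(out / "category_deregulation.tsv", sep="\t")
    pd.DataFrame(
        [{"set": "down_in_mutant", "category": "SM", "k": enrich.k, "K": enrich.K,
          "n": enrich.n, "N": enrich.N, "odds_ratio": enrich.odds_ratio, "p": enrich.p}]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    ms = mark_summary.copy()
    ms["mannwhitney_p_CSF_vs_SM"] = mark_summary.attrs.get("mannwhitney_p")
    ms.to_csv(out / "category_mark_summary.tsv", sep="\t")
    domains.to_csv(out / "k9_domains.bed", sep="\t", index=False, header=False)
    flanks.to_csv(out / "cluster_flanking.tsv", sep="\t")
    stoich_summary.to_csv(out / "stoichiometry.tsv", sep="\t", index=False)

    log["elapsed_s"] = round(time.time() - t0, 3)
    log["outputs"] = {
        p.name: synthetic._sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return {
        "annotation": ann,
        "truth": truth,
        "binned": binned,
        "quant": quant,
        "profiles": profiles,
        "de": de,
        "tiers": tiers,
        "groups": groups,
        "group_counts": group_counts,
        "deregulation": dereg,
        "enrichment": enrich,
        "mark_summary": mark_summary,
        "domains": domains,
        "flanks": flanks,
        "stoichiometry": stoich_summary,
    }


def load_report(out_dir) -> dict[str, pd.DataFrame]:
    """Read back the TSV tables of a completed demo run."""
    out = Path(out_dir)
    tables = {}
    for p in sorted(out.glob("*.tsv")):
        tables[p.stem] = pd.read_csv(p, sep="\t")
    return tables


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
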