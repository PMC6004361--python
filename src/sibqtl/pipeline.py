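"""End-to-end study driver.

Chains the whole mapping workflow on one synthetic family: phenotype split
and extreme pools -> pooled Fst scan -> exon/promoter candidate nomination ->
barcoded amplicon re-sequencing of a candidate panel -> demultiplexing and
genotyping -> kinship MLM association -> genotype / genotype-combination
effect summaries.  Used by the numbered analysis scripts, the acceptance
script and the replicate-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bsa, effects, mlm
from .demux import BarcodeScheme, DemuxReport, demux_pairs
from .genotyping import AmpliconTarget, GenotypeMatrix, filter_sites, genotype_samples
from .simulate import (
    Pedigree,
    SimConfig,
    generate_amplicon_reads,
    make_amplicon_targets,
    random_barcode_scheme,
    simulate_family,
    simulate_pool_counts,
)

__all__ = ["StudyResult", "make_gene_features", "choose_panel", "run_study"]


def make_gene_features(
    ped: Pedigree,
    halfwidth: int = 50,
    noncoding_every: int = 10,
) -> list[bsa.GeneFeature]:
    """Synthetic annotation: one gene per marker with an exon spanning the
    marker position; every ``noncoding_every``-th neutral marker instead gets
    an intergenic ("other") feature, so annotation-based exclusion is
    exercised."""
    feats = []
    for i, rec in enumerate(ped.markers.itertuples(index=False)):
        kind = "exon"
        if rec.role == "neutral" and noncoding_every and i % noncoding_every == 0:
            kind = "other"
        elif rec.role == "helper":
            kind = "promoter"
        feats.append(
            bsa.GeneFeature(
                gene_id=f"gene_{rec.site_id}",
                contig=rec.contig,
                start=max(1, rec.pos - halfwidth),
                end=rec.pos + halfwidth,
                feature_kind=kind,
            )
        )
    return feats


@dataclass
class StudyResult:
    config: SimConfig
    ped: Pedigree
    phen: pd.DataFrame
    pools: dict[str, list[str]]
    fst_table: pd.DataFrame
    hits: pd.DataFrame
    candidates: pd.DataFrame
    candidate_genes: list[str]
    panel: list[str]
    scheme: BarcodeScheme
    targets: list[AmpliconTarget]
    demux_report: DemuxReport
    matrix: GenotypeMatrix
    filtered: GenotypeMatrix
    kinship: pd.DataFrame
    scans: dict[str, mlm.ScanResult]
    top_site: str
    genotype_summaries: pd.DataFrame
    combination_summaries: pd.DataFrame = field(default=None)
    dominance: pd.DataFrame = field(default=None)
    combo_sites: tuple[str, str] | None = None


def choose_panel(
    fst: pd.DataFrame, candidates: pd.DataFrame, panel_size: int
) -> list[str]:
    """Re-sequencing panel: candidate sites first, padded with the next
    Fst-ranked covered sites up to ``panel_size``."""
    panel = list(dict.fromkeys(candidates.site_id)) if len(candidates) else []
    ranked = (
        fst[fst.pass_support & fst.pass_coverage]
        .sort_values(["fst", "contig", "pos"], ascending=[False, True, True])
        .site_id.tolist()
    )
    for site in ranked:
        if len(panel) >= panel_size:
            break
        if site not in panel:
            panel.append(site)
    return panel[:panel_size]


def run_study(
    config: SimConfig,
    panel_size: int = 12,
    min_fst: float = 0.5,
    min_coverage: int = 20,
    min_allele_reads: int = 4,
    traits: tuple[str, ...] = ("weight_g", "length_mm"),
    combo_alpha: float = 0.1,
) -> StudyResult:
    """Run the full mapping pipeline on one simulated family."""
    ped, phen = simulate_family(config)
    fast_tab, slow_tab, pools = simulate_pool_counts(ped, phen, config)

    fst = bsa.fst_table(
        fast_tab, slow_tab,
        min_allele_reads=min_allele_reads, min_fst=min_fst, min_coverage=min_coverage,
    )
    hits = fst[fst.pass_all].sort_values(
        ["fst", "contig", "pos"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    features = make_gene_features(ped)
    candidates, genes = bsa.annotate_candidates(hits, features)
    panel = choose_panel(fst, candidates, panel_size)

    scheme = random_barcode_scheme(list(ped.dosage.index), config.rng(105))
    targets = make_amplicon_targets(ped, panel, config.rng(106))
    reads = generate_amplicon_reads(ped, scheme, targets, config)
    by_sample, report = demux_pairs(reads, scheme)
    matrix = genotype_samples(by_sample, targets)
    filtered = filter_sites(matrix)

    kinship = mlm.centered_ibs_kinship(filtered)
    scans = {
        trait: mlm.association_scan(filtered, phen, trait=trait, K=kinship)
        for trait in traits
    }

    weight_scan = scans[traits[0]].table
    tested = weight_scan[weight_scan.testable]
    top_site = tested.sort_values("p").site_id.iloc[0]
    gt = filtered.genotype_labels(top_site)
    summaries = effects.genotype_summary(gt, phen, site_label=f"{top_site}:")

    # two-locus combinations among loci passing p < combo_alpha in any trait
    union_sites: list[str] = []
    for scan in scans.values():
        tab = scan.table
        union_sites.extend(tab.loc[tab.p < combo_alpha, "site_id"])
    union_sites = list(dict.fromkeys(union_sites))
    combos = None
    dominance = None
    combo_sites = None
    if len(union_sites) >= 2:
        ranked = (
            weight_scan.set_index("site_id").loc[union_sites].sort_values("p").index
        )
        combo_sites = (ranked[0], ranked[1])
        combos = effects.combination_summary(
            filtered.genotype_labels(combo_sites[0]),
            filtered.genotype_labels(combo_sites[1]),
            phen,
            site_labels=(f"{combo_sites[0]}:", f"{combo_sites[1]}:"),
        )
        all_rows = pd.concat([summaries, combos], ignore_index=True)
    else:
        all_rows = summaries
    family_row = summaries[summaries.label == "family"].iloc[0]
    dominance = effects.rank_dominant(all_rows, family_row)

    return StudyResult(
        config=config,
        ped=ped,
        phen=phen,
        pools=pools,
        fst_table=fst,
        hits=hits,
        candidates=candidates,
        candidate_genes=genes,
        panel=panel,
        scheme=scheme,
        targets=targets,
        demux_report=report,
        matrix=matrix,
        filtered=filtered,
        kinship=kinship,
        scans=scans,
        top_site=top_site,
        genotype_summaries=summaries,
        combination_summaries=combos,
        dominance=dominance,
        combo_sites=combo_sites,
    )
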