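"""End-to-end orchestration: gold standard -> features -> prediction ->
network -> annotation -> modules -> enrichment -> interolog evaluation.

All randomness flows from one base seed; stage outputs are pure functions of
(inputs, config, seed), so a rerun with the same configuration is
byte-identical. Wall-clock timings are logged but never written to output
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import core_io
from .annotation import Schedule, annotate_unknown
from .bayes import LRModel, high_confidence_set, write_scored_pairs
from .core_io import PairSet, merge_networks
from .enrichment import (map_interologs, overlap_significance,
                         pathway_enrichment, significant_enrichments)
from .evidence import (cluster_feature, coexpression_feature, domain_feature,
                       fusion_feature, neighborhood_feature,
                       phylo_profile_feature, ssbp_feature,
                       write_feature_table)
from .gold_standard import build_gold_standard, validate_gold_standard
from .modules import MCODEParams, detect_subnetworks
from .synthetic import (SyntheticWorld, WorldConfig, evaluate_recovery,
                        generate_world, write_world)

log = logging.getLogger("cyanonet")


@dataclass
class RunConfig:
    """Every knob of the full pipeline, serializable alongside the outputs."""

    seed: int = 17
    world: WorldConfig = field(default_factory=WorldConfig)

    # evidence parameters
    coexpr_alpha: float = 0.05
    max_intervening: int = 5       # gene-neighborhood window (genes)
    min_genomes: int = 1
    operon_max_gap: int = 300      # bp
    fusion_max_overlap: float = 0.2

    # integration
    n_bins: int = 5
    pseudocount: float = 1.0
    cutoff: float = 5.0

    # annotation
    go_depth: int = 5
    repeats: int = 100
    noise_fraction: float = 0.1
    schedule: Schedule = field(default_factory=Schedule)

    # modules / enrichment
    mcode: MCODEParams = field(default_factory=MCODEParams)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_features(world: SyntheticWorld, cfg: RunConfig, gs):
    """The seven evidence tables over every catalog pair."""
    pairs = world.all_pairs()
    coexpr, retained = coexpression_feature(
        world.expression, pairs, gs.gsp, gs.gsn, alpha=cfg.coexpr_alpha)
    features = [
        coexpr,
        ssbp_feature(world.annotations, world.ontology, pairs),
        domain_feature(world.domain_assign, world.ddi, pairs),
        phylo_profile_feature(world.profiles, pairs),
        neighborhood_feature(world.ref_genomes, world.orthologs, pairs,
                             max_intervening=cfg.max_intervening,
                             min_genomes=cfg.min_genomes),
        fusion_feature(world.fusion_hits, pairs,
                       max_overlap_frac=cfg.fusion_max_overlap),
        cluster_feature(world.study_genome, pairs, max_gap=cfg.operon_max_gap),
    ]
    return features, retained


def run_all(config: RunConfig | None = None, out_dir=None,
            world: SyntheticWorld | None = None) -> dict:
    """Execute the whole synthetic study; returns the machine-readable summary.

    With ``out_dir`` given, every stage's output is written there (world
    files, gold-standard report, feature tables, model, scored pairs,
    network, annotations, modules, enrichment, interolog report, summary).
    """
    cfg = config or RunConfig()
    t_start = time.perf_counter()

    def _stage(name):
        log.info("stage %s (t=%.1fs)", name, time.perf_counter() - t_start)

    _stage("simulate")
    if world is None:
        world = generate_world(cfg.world, seed=cfg.seed)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_world(world, os.path.join(out_dir, "world"))

    _stage("goldstandard")
    gs = build_gold_standard(world.gsp, world.catalog, world.ontology)
    gs_report = validate_gold_standard(gs, world.catalog, world.ontology)

    _stage("features")
    features, retained = compute_features(world, cfg, gs)

    _stage("predict")
    model = LRModel(n_bins=cfg.n_bins, pseudocount=cfg.pseudocount,
                    cutoff=cfg.cutoff)
    model.fit(features, gs)
    scored = model.score_all(features, exclude=gs.gsp)
    high = high_confidence_set(scored)
    metrics = evaluate_recovery(world, scored, cutoff=cfg.cutoff)

    _stage("merge")
    odds = {s.pair: s.posterior_odds for s in scored}
    network = merge_networks(gs.gsp, high, posterior_odds=odds)

    _stage("annotate")
    annot, annot_report = annotate_unknown(
        network, world.annotations, world.ontology, depth=cfg.go_depth,
        schedule=cfg.schedule, repeats=cfg.repeats, base_seed=cfg.seed,
        noise_fraction=cfg.noise_fraction)
    recovery = annotation_recovery(world, annot)

    _stage("modules")
    subnets = detect_subnetworks(network, cfg.mcode)

    _stage("enrich")
    enrich = pathway_enrichment(subnets, world.pathways, alpha=cfg.alpha) \
        if subnets else []
    n_sig = len(significant_enrichments(enrich, alpha=cfg.alpha))

    _stage("interolog")
    interolog = map_interologs(high, world.foreign_orthologs,
                               world.foreign_ppis)
    truth_rest = PairSet(pairs=world.truth.pairs - world.gsp.pairs,
                         label="predicted")
    n = len(world.catalog)
    overlap_p = overlap_significance(high, truth_rest, n * (n - 1) // 2) \
        if len(high) else 1.0

    summary = {
        "seed": cfg.seed,
        "gold_standard": gs_report,
        "retained_datasets": retained,
        "prior_odds": model.prior_odds,
        "n_scored": len(scored),
        "n_high_confidence": len(high),
        "n_network_edges": network.number_of_edges(),
        "n_network_proteins": network.number_of_nodes(),
        "recovery": metrics,
        "annotation": {
            "report": annot_report,
            "n_proteins_annotated": len(annot.assignments),
            "module_term_recovery": recovery,
        },
        "n_subnetworks": len(subnets),
        "n_significant_enrichments": n_sig,
        "interolog": {
            sp: {"mapped": len(si.mapped), "conserved": len(si.conserved),
                 "fraction": si.fraction}
            for sp, si in interolog.per_species.items()
        },
        "interolog_fraction_of_mapped": interolog.fraction_of_mapped,
        "overlap_p_value": overlap_p,
    }

    if out_dir is not None:
        _write_outputs(out_dir, cfg, gs, features, model, scored, network,
                       annot, subnets, enrich, summary)
    _stage("done")
    return summary


def annotation_recovery(world: SyntheticWorld, annot) -> dict:
    """Fraction of newly annotated unknown proteins whose accepted terms
    include their planted module's level-5 term."""
    free = [p for p in annot.assignments
            if not world.catalog.is_annotated.get(p, False)]
    if not free:
        return {"n_free_annotated": 0, "fraction_correct": None}
    correct = sum(
        1 for p in free
        if world.module_terms[world.module_assignment[p]] in annot.assignments[p])
    return {"n_free_annotated": len(free),
            "fraction_correct": correct / len(free)}


def _write_outputs(out_dir, cfg, gs, features, model, scored, network, annot,
                   subnets, enrich, summary) -> None:
    d = str(out_dir)
    os.makedirs(os.path.join(d, "features"), exist_ok=True)
    core_io.write_pair_list(gs.gsp, f"{d}/gsp.tsv")
    core_io.write_pair_list(gs.gsn, f"{d}/gsn.tsv")
    for feat in features:
        write_feature_table(feat, f"{d}/features/{feat.feature_name}.tsv")
    model.save(f"{d}/model.json")
    write_scored_pairs(scored, f"{d}/scored.tsv")
    core_io.write_network(network, f"{d}/network.sif", f"{d}/network_attrs.tsv")
    core_io.write_annotations(annot, f"{d}/predicted_annotations.tsv")
    with open(f"{d}/modules.tsv", "w", encoding="utf-8") as fh:
        fh.write("# rank\tcore_size\textended_size\tscore\tcore_nodes\n")
        for sub in subnets:
            fh.write(f"{sub.rank}\t{len(sub.core_nodes)}\t"
                     f"{len(sub.extended_nodes)}\t{sub.score:.6g}\t"
                     f"{','.join(sorted(sub.core_nodes))}\n")
    with open(f"{d}/enrichment.tsv", "w", encoding="utf-8") as fh:
        fh.write("# subnetwork\tpathway\tk\tK\tn\tN\tp_value\tadjusted_p\n")
        for r in enrich:
            fh.write(f"{r.subnetwork_id}\t{r.pathway_id}\t{r.k}\t{r.K}\t"
                     f"{r.n}\t{r.N}\t{r.p_value:.6g}\t{r.adjusted_p:.6g}\n")
    with open(f"{d}/config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(f"{d}/summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
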