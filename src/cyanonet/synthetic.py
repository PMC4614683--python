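"""Synthetic benchmark world with the statistical structure the pipeline assumes.

The generator plants a modular interactome (dense within functional modules,
sparse between them) over a toy protein catalog, then emits every evidence
layer the predictor consumes so that each layer carries a configurable
amount of signal about the planted truth:

* a GO-like DAG with one level-5 term per module, and known proteins
  annotated to (descendants of) their module term;
* expression datasets driven by per-module latent profiles plus noise, and
  one pure-noise dataset to exercise dataset retention;
* domain assignments and a domain-domain interaction catalogue enriched for
  combinations realised by true pairs;
* a study genome laying module genes out in operon-like runs, reference
  genomes conserving that adjacency, and ortholog presence/absence profiles
  correlated within modules;
* fusion hit tables for a fraction of true pairs;
* pathway membership mirroring the modules; and
* foreign interactomes containing the ortholog image of a subset of true
  pairs, for interolog evaluation.

Setting every signal strength to zero produces a null world in which all
evidence layers are independent of the planted truth. Regeneration from the
same (config, seed) is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import core_io
from .core_io import (AnnotationTable, ExpressionMatrix, GenomeTable, Ontology,
                      Pair, PairSet, ProteinCatalog, canonical_pair)

BP_ROOT = "GO:1000000"
CC_ROOT = "GO:2000000"
MF_ROOT = "GO:3000000"


@dataclass
class WorldConfig:
    """All generator parameters; defaults define the standard benchmark world."""

    n_proteins: int = 300
    n_modules: int = 8
    within_p: float = 0.25          # within-module edge probability
    background_p: float = 0.002     # cross-module edge probability
    frac_unknown: float = 0.6       # fraction of function-unknown proteins
    gsp_fraction: float = 0.3       # fraction of truth revealed as known PPIs

    # localization / catalog
    n_locations: int = 4
    loc_flip: float = 0.25          # prob. a protein's location ignores its module
    mobility_p: float = 0.05

    # expression
    n_informative_datasets: int = 2
    n_samples: int = 20
    expression_signal: float = 1.0  # latent-profile amplitude
    expression_noise_sd: float = 0.7

    # GO annotations (drives the SSBP feature and annealing recovery)
    annotation_signal: float = 0.9  # prob. a known protein gets its own module term

    # domains
    n_domains: int = 150
    domains_per_protein: int = 2
    n_random_ddi: int = 40
    domain_signal: float = 0.8      # fraction of true pairs with a planted DDI

    # genome context
    n_ref_genomes: int = 4
    ortholog_p: float = 0.7         # ortholog presence per reference genome
    neighborhood_signal: float = 0.7
    operon_signal: float = 0.7
    n_profile_genomes: int = 10
    profile_signal: float = 0.8
    fusion_signal: float = 0.3      # fraction of true pairs with a fusion target
    fusion_noise: float = 0.05      # noise fusions, as a fraction of true pairs

    # pathways
    pathway_member_p: float = 0.8
    pathway_noise_p: float = 0.02

    # foreign interactomes
    n_foreign_species: int = 2
    foreign_ortholog_p: float = 0.6
    foreign_conserved_fraction: float = 0.5
    foreign_noise_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_proteins < 2 * self.n_modules:
            raise ValueError("modules would have fewer than 2 proteins each")
        if not (0 <= self.within_p <= 1 and 0 <= self.background_p <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if not 0 <= self.frac_unknown < 1:
            raise ValueError("frac_unknown must lie in [0, 1)")
        if self.n_locations < 2:
            raise ValueError("need at least two cellular locations")

    def null(self) -> "WorldConfig":
        """Copy with every evidence signal zeroed (null world)."""
        return dataclasses.replace(
            self, expression_signal=0.0, annotation_signal=0.0,
            domain_signal=0.0, neighborhood_signal=0.0, operon_signal=0.0,
            profile_signal=0.0, fusion_signal=0.0, loc_flip=1.0)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    catalog: ProteinCatalog
    truth: PairSet
    module_assignment: dict[str, int]
    gsp: PairSet
    ontology: Ontology
    module_terms: dict[int, str]            # module -> level-5 BP term
    annotations: AnnotationTable
    expression: list[ExpressionMatrix]
    domain_assign: dict[str, frozenset[str]]
    ddi: set[frozenset[str]]
    study_genome: GenomeTable
    ref_genomes: list[GenomeTable]
    orthologs: dict[tuple[str, str], str]   # (protein, genome) -> gene
    profiles: pd.DataFrame
    fusion_hits: pd.DataFrame
    pathways: dict[str, set[str]]
    foreign_orthologs: dict[str, dict[str, str]]
    foreign_ppis: dict[str, PairSet]

    @property
    def proteins(self) -> list[str]:
        return self.catalog.protein_ids

    def truth_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from((p.a, p.b) for p in self.truth)
        return g

    def all_pairs(self) -> list[Pair]:
        ps = self.proteins
        return [canonical_pair(ps[i], ps[j])
                for i in range(len(ps)) for j in range(i + 1, len(ps))]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _protein_ids(n: int) -> list[str]:
    return [f"syn{i:04d}" for i in range(1, n + 1)]


def _plant_interactome(cfg: WorldConfig, modules: dict[str, int],
                       rng: np.random.Generator) -> PairSet:
    proteins = sorted(modules)
    pairs: set[Pair] = set()
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            p = cfg.within_p if modules[a] == modules[b] else cfg.background_p
            if rng.random() < p:
                pairs.add(canonical_pair(a, b))
    return PairSet(pairs=pairs, label="merged")


def _build_ontology(cfg: WorldConfig) -> tuple[Ontology, dict[int, str]]:
    """BP spine of depth 4, one module term at depth 5, one child at depth 6;
    CC root with one child per location; MF root only."""
    parents: dict[str, frozenset[str]] = {BP_ROOT: frozenset()}
    namespace = {BP_ROOT: "biological_process"}
    spine = [BP_ROOT]
    for d in range(1, 5):
        t = f"GO:10000{d:02d}"
        parents[t] = frozenset({spine[-1]})
        namespace[t] = "biological_process"
        spine.append(t)
    module_terms: dict[int, str] = {}
    for m in range(cfg.n_modules):
        mt = f"GO:1100{m:02d}"
        dt = f"GO:1200{m:02d}"
        parents[mt] = frozenset({spine[-1]})
        parents[dt] = frozenset({mt})
        namespace[mt] = namespace[dt] = "biological_process"
        module_terms[m] = mt
    namespace[CC_ROOT] = "cellular_component"
    parents[CC_ROOT] = frozenset()
    for loc in range(cfg.n_locations):
        t = f"GO:2100{loc:02d}"
        parents[t] = frozenset({CC_ROOT})
        namespace[t] = "cellular_component"
    namespace[MF_ROOT] = "molecular_function"
    parents[MF_ROOT] = frozenset()
    names = {t: t.lower().replace(":", "_") for t in namespace}
    return Ontology(parents=parents, namespace=namespace, names=names), module_terms


def _location_term(loc: int) -> str:
    return f"GO:2100{loc:02d}"


def _layout_genome(genome_id: str, genes: list[str],
                   modules: dict[str, int], signal: float,
                   rng: np.random.Generator) -> GenomeTable:
    """Order genes module-contiguously, relocating each gene with prob. 1-signal;
    same-module neighbours get operon-like strands/gaps with prob. ~signal."""
    ordered = sorted(genes, key=lambda g: (modules[g], g))
    n = len(ordered)
    relocate = rng.random(n) >= signal
    keep = [g for g, r in zip(ordered, relocate) if not r]
    moved = [g for g, r in zip(ordered, relocate) if r]
    order = list(keep)
    for g in moved:
        order.insert(int(rng.integers(0, len(order) + 1)), g)
    rows = []
    pos = 1
    prev_strand = "+"
    prev_module = None
    for g in order:
        length = int(rng.integers(600, 1500))
        same_module = modules[g] == prev_module
        p_small = 0.15 + 0.75 * signal if same_module else 0.15
        p_keep = 0.5 + 0.5 * signal if same_module else 0.5
        gap = int(rng.integers(20, 250)) if rng.random() < p_small \
            else int(rng.integers(500, 3000))
        strand = prev_strand if rng.random() < p_keep \
            else ("+" if rng.random() < 0.5 else "-")
        start = pos + gap
        rows.append((g, "chr", start, start + length - 1, strand))
        pos = start + length - 1
        prev_strand = strand
        prev_module = modules[g]
    df = pd.DataFrame(rows, columns=["gene_id", "replicon", "start", "end",
                                     "strand"])
    return GenomeTable(genome_id=genome_id, genes=df)


def generate_world(config: WorldConfig | None = None, seed: int = 17
                   ) -> SyntheticWorld:
    """Generate the complete toy world; bit-identical given (config, seed)."""
    cfg = config or WorldConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    proteins = _protein_ids(cfg.n_proteins)
    modules = {p: i % cfg.n_modules for i, p in enumerate(proteins)}

    truth = _plant_interactome(cfg, modules, rng)
    onto, module_terms = _build_ontology(cfg)

    # catalog: annotation status, module-correlated localization, mobility
    known_mask = rng.random(cfg.n_proteins) >= cfg.frac_unknown
    is_ann = {p: bool(k) for p, k in zip(proteins, known_mask)}
    loc_terms = {}
    mobility = {}
    for p in proteins:
        if rng.random() < cfg.loc_flip:
            loc = int(rng.integers(0, cfg.n_locations))
        else:
            loc = modules[p] % cfg.n_locations
        loc_terms[p] = frozenset({_location_term(loc)})
        mobility[p] = bool(rng.random() < cfg.mobility_p)
    catalog = ProteinCatalog(is_annotated=is_ann, localization_terms=loc_terms,
                             mobility_flag=mobility)

    # GO annotations of known proteins (BP): own module term with prob.
    # annotation_signal, else a uniform random module; half the annotations
    # sit one level deeper to exercise level mapping
    assignments = {}
    for p in proteins:
        if not is_ann[p]:
            continue
        if rng.random() < cfg.annotation_signal:
            m = modules[p]
        else:
            m = int(rng.integers(0, cfg.n_modules))
        term = module_terms[m]
        if rng.random() < 0.5:
            term = f"GO:1200{m:02d}"  # depth-6 child
        assignments[p] = frozenset({term})
    annotations = AnnotationTable(assignments=assignments)

    # GSP: seeded random sample of the truth
    truth_sorted = sorted(truth.pairs)
    n_gsp = max(1, int(round(cfg.gsp_fraction * len(truth_sorted))))
    gsp_idx = rng.choice(len(truth_sorted), size=n_gsp, replace=False)
    gsp = PairSet(pairs={truth_sorted[i] for i in gsp_idx}, label="GSP")

    # expression: informative datasets share per-module latent profiles
    expression = []
    for d in range(cfg.n_informative_datasets):
        latent = rng.normal(size=(cfg.n_modules, cfg.n_samples))
        noise = rng.normal(scale=cfg.expression_noise_sd,
                           size=(cfg.n_proteins, cfg.n_samples))
        vals = np.vstack([cfg.expression_signal * latent[modules[p]]
                          for p in proteins]) + noise
        df = pd.DataFrame(vals, index=proteins,
                          columns=[f"s{j:02d}" for j in range(cfg.n_samples)])
        expression.append(ExpressionMatrix(dataset_id=f"expr_info{d}", values=df))
    noise_vals = rng.normal(size=(cfg.n_proteins, cfg.n_samples))
    expression.append(ExpressionMatrix(
        dataset_id="expr_noise",
        values=pd.DataFrame(noise_vals, index=proteins,
                            columns=[f"s{j:02d}" for j in range(cfg.n_samples)])))

    # domains and domain-domain interactions
    domain_pool = [f"PF{i:05d}" for i in range(1, cfg.n_domains + 1)]
    domain_assign = {
        p: frozenset(rng.choice(domain_pool, size=cfg.domains_per_protein,
                                replace=False))
        for p in proteins}
    ddi: set[frozenset[str]] = set()
    while len(ddi) < cfg.n_random_ddi:
        d1, d2 = rng.choice(domain_pool, size=2, replace=False)
        ddi.add(frozenset((d1, d2)))
    for pair in truth_sorted:
        if rng.random() < cfg.domain_signal:
            da = sorted(domain_assign[pair.a])
            db = sorted(domain_assign[pair.b])
            d1 = da[int(rng.integers(0, len(da)))]
            d2 = db[int(rng.integers(0, len(db)))]
            if d1 != d2:
                ddi.add(frozenset((d1, d2)))

    # genomes: the study genome (gene ids = protein ids) plus reference
    # genomes holding orthologs with conserved neighbourhood
    study = _layout_genome("study", proteins, modules, cfg.operon_signal, rng)
    ref_genomes = []
    orthologs: dict[tuple[str, str], str] = {}
    for r in range(cfg.n_ref_genomes):
        gid = f"ref{r + 1}"
        present = [p for p in proteins if rng.random() < cfg.ortholog_p]
        gene_names = {p: f"{gid}_{p}" for p in present}
        ref_modules = {gene_names[p]: modules[p] for p in present}
        gt = _layout_genome(gid, list(gene_names.values()), ref_modules,
                            cfg.neighborhood_signal, rng)
        ref_genomes.append(gt)
        for p in present:
            orthologs[(p, gid)] = gene_names[p]

    # phylogenetic profiles: per-module base pattern with flip noise
    pg_cols = [f"pg{j:02d}" for j in range(1, cfg.n_profile_genomes + 1)]
    base = rng.random((cfg.n_modules, cfg.n_profile_genomes)) < 0.5
    flip_p = 0.5 * (1 - cfg.profile_signal)
    prof = np.zeros((cfg.n_proteins, cfg.n_profile_genomes), dtype=int)
    for i, p in enumerate(proteins):
        row = base[modules[p]].copy()
        flips = rng.random(cfg.n_profile_genomes) < flip_p
        row = row ^ flips
        prof[i] = row.astype(int)
    profiles = pd.DataFrame(prof, index=proteins, columns=pg_cols)

    # fusion hits: true pairs (and a few noise pairs) share a target with
    # near-disjoint spans
    fusion_rows = []
    target_no = 0
    for pair in truth_sorted:
        if rng.random() < cfg.fusion_signal:
            target_no += 1
            t = f"fusion_t{target_no:04d}"
            fusion_rows.append((pair.a, t, 1, 150))
            fusion_rows.append((pair.b, t, 171, 320))
    n_noise_fusion = int(round(cfg.fusion_noise * len(truth_sorted)))
    for _ in range(n_noise_fusion):
        i, j = rng.choice(cfg.n_proteins, size=2, replace=False)
        target_no += 1
        t = f"fusion_t{target_no:04d}"
        fusion_rows.append((proteins[i], t, 1, 150))
        fusion_rows.append((proteins[j], t, 171, 320))
    fusion_hits = pd.DataFrame(
        fusion_rows, columns=["query", "target", "target_start", "target_end"])

    # pathways mirror modules
    pathways: dict[str, set[str]] = {}
    for m in range(cfg.n_modules):
        members = {p for p in proteins
                   if (modules[p] == m and rng.random() < cfg.pathway_member_p)
                   or (modules[p] != m and rng.random() < cfg.pathway_noise_p)}
        pathways[f"path{m:02d}"] = members

    # foreign interactomes: ortholog image of a subset of the truth + noise
    foreign_orthologs: dict[str, dict[str, str]] = {}
    foreign_ppis: dict[str, PairSet] = {}
    for s in range(cfg.n_foreign_species):
        sp = f"species{chr(ord('A') + s)}"
        omap = {p: f"{sp}_{p}" for p in proteins
                if rng.random() < cfg.foreign_ortholog_p}
        edges: set[Pair] = set()
        for pair in truth_sorted:
            if pair.a in omap and pair.b in omap \
                    and rng.random() < cfg.foreign_conserved_fraction:
                edges.add(canonical_pair(omap[pair.a], omap[pair.b]))
        foreign_genes = sorted(omap.values())
        n_noise = int(round(cfg.foreign_noise_fraction * len(edges)))
        added = 0
        while added < n_noise and len(foreign_genes) >= 2:
            i, j = rng.choice(len(foreign_genes), size=2, replace=False)
            e = canonical_pair(foreign_genes[i], foreign_genes[j])
            if e not in edges:
                edges.add(e)
                added += 1
        foreign_orthologs[sp] = omap
        foreign_ppis[sp] = PairSet(pairs=edges, label="predicted")

    return SyntheticWorld(
        config=cfg, seed=seed, catalog=catalog, truth=truth,
        module_assignment=modules, gsp=gsp, ontology=onto,
        module_terms=module_terms, annotations=annotations,
        expression=expression, domain_assign=domain_assign, ddi=ddi,
        study_genome=study, ref_genomes=ref_genomes, orthologs=orthologs,
        profiles=profiles, fusion_hits=fusion_hits, pathways=pathways,
        foreign_orthologs=foreign_orthologs, foreign_ppis=foreign_ppis)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir) -> dict:
    """Emit every input file in the standard formats plus a hashed manifest."""
    os.makedirs(out_dir, exist_ok=True)
    d = str(out_dir)

    core_io.write_catalog(world.catalog, f"{d}/catalog.tsv")
    core_io.write_pair_list(world.truth, f"{d}/truth.tsv")
    core_io.write_pair_list(world.gsp, f"{d}/gsp.tsv")
    core_io.write_obo_lite(world.ontology, f"{d}/go.obo")
    core_io.write_annotations(world.annotations, f"{d}/annotations.tsv")
    for mat in world.expression:
        core_io.write_expression(mat, f"{d}/expression_{mat.dataset_id}.tsv")
    with open(f"{d}/domains.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tdomain_id\n")
        for p in sorted(world.domain_assign):
            for dom in sorted(world.domain_assign[p]):
                fh.write(f"{p}\t{dom}\n")
    with open(f"{d}/ddi.tsv", "w", encoding="utf-8") as fh:
        fh.write("# domain_1\tdomain_2\n")
        for pair in sorted(tuple(sorted(x)) for x in world.ddi):
            fh.write(f"{pair[0]}\t{pair[-1] if len(pair) > 1 else pair[0]}\n")
    core_io.write_genome_tables([world.study_genome] + world.ref_genomes,
                                f"{d}/genomes.tsv")
    with open(f"{d}/orthologs.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tgenome_id\tgene_id\n")
        for (p, g), gene in sorted(world.orthologs.items()):
            fh.write(f"{p}\t{g}\t{gene}\n")
    core_io.write_profiles(world.profiles, f"{d}/profiles.tsv")
    world.fusion_hits.to_csv(f"{d}/fusion_hits.tsv", sep="\t", index=False)
    with open(f"{d}/pathways.tsv", "w", encoding="utf-8") as fh:
        fh.write("# pathway_id\tprotein_id\n")
        for pid in sorted(world.pathways):
            for p in sorted(world.pathways[pid]):
                fh.write(f"{pid}\t{p}\n")
    with open(f"{d}/modules.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tmodule\n")
        for p in sorted(world.module_assignment):
            fh.write(f"{p}\t{world.module_assignment[p]}\n")
    for sp in sorted(world.foreign_orthologs):
        with open(f"{d}/foreign_{sp}_orthologs.tsv", "w", encoding="utf-8") as fh:
            fh.write("# protein_id\tforeign_gene\n")
            for p, g in sorted(world.foreign_orthologs[sp].items()):
                fh.write(f"{p}\t{g}\n")
        core_io.write_pair_list(world.foreign_ppis[sp],
                                f"{d}/foreign_{sp}_ppis.tsv")

    files = sorted(f for f in os.listdir(d)
                   if f.endswith((".tsv", ".obo")))
    hashes = {}
    for f in files:
        with open(f"{d}/{f}", "rb") as fh:
            hashes[f] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "seed": world.seed,
        "config": dataclasses.asdict(world.config),
        "files": hashes,
    }
    with open(f"{d}/manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def read_world(in_dir) -> SyntheticWorld:
    """Reload a world directory written by :func:`write_world`."""
    d = str(in_dir)
    with open(f"{d}/manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    cfg = WorldConfig(**manifest["config"])
    catalog = core_io.read_catalog(f"{d}/catalog.tsv")
    truth = core_io.read_pair_list(f"{d}/truth.tsv", label="merged")
    gsp = core_io.read_pair_list(f"{d}/gsp.tsv", label="GSP")
    onto = core_io.read_obo_lite(f"{d}/go.obo")
    annotations = core_io.read_annotations(f"{d}/annotations.tsv")
    expression = []
    for f in sorted(os.listdir(d)):
        if f.startswith("expression_") and f.endswith(".tsv"):
            expression.append(core_io.read_expression(
                f"{d}/{f}", dataset_id=f[len("expression_"):-len(".tsv")]))
    domain_assign: dict[str, set[str]] = {}
    for _, (p, dom) in core_io._iter_rows(f"{d}/domains.tsv", n_cols=2):
        domain_assign.setdefault(p, set()).add(dom)
    ddi = {frozenset((a, b))
           for _, (a, b) in core_io._iter_rows(f"{d}/ddi.tsv", n_cols=2)}
    genomes = core_io.read_genome_table(f"{d}/genomes.tsv")
    study = next(g for g in genomes if g.genome_id == "study")
    refs = [g for g in genomes if g.genome_id != "study"]
    orthologs = {(p, g): gene for _, (p, g, gene)
                 in core_io._iter_rows(f"{d}/orthologs.tsv", n_cols=3)}
    profiles = core_io.read_profiles(f"{d}/profiles.tsv")
    fusion_hits = pd.read_csv(f"{d}/fusion_hits.tsv", sep="\t")
    pathways: dict[str, set[str]] = {}
    for _, (pid, p) in core_io._iter_rows(f"{d}/pathways.tsv", n_cols=2):
        pathways.setdefault(pid, set()).add(p)
    modules = {p: int(m) for _, (p, m)
               in core_io._iter_rows(f"{d}/modules.tsv", n_cols=2)}
    module_terms = {m: f"GO:1100{m:02d}" for m in sorted(set(modules.values()))}
    foreign_orthologs: dict[str, dict[str, str]] = {}
    foreign_ppis: dict[str, PairSet] = {}
    for f in sorted(os.listdir(d)):
        if f.startswith("foreign_") and f.endswith("_orthologs.tsv"):
            sp = f[len("foreign_"):-len("_orthologs.tsv")]
            foreign_orthologs[sp] = {
                p: g for _, (p, g) in core_io._iter_rows(f"{d}/{f}", n_cols=2)}
            foreign_ppis[sp] = core_io.read_pair_list(
                f"{d}/foreign_{sp}_ppis.tsv")
    return SyntheticWorld(
        config=cfg, seed=manifest["seed"], catalog=catalog, truth=truth,
        module_assignment=modules, gsp=gsp, ontology=onto,
        module_terms=module_terms, annotations=annotations,
        expression=expression,
        domain_assign={p: frozenset(s) for p, s in domain_assign.items()},
        ddi=ddi, study_genome=study, ref_genomes=refs, orthologs=orthologs,
        profiles=profiles, fusion_hits=fusion_hits, pathways=pathways,
        foreign_orthologs=foreign_orthologs, foreign_ppis=foreign_ppis)


# ---------------------------------------------------------------------------
# evaluation against the planted truth
# ---------------------------------------------------------------------------

def evaluate_recovery(world: SyntheticWorld, scored, cutoff: float = 5.0
                      ) -> dict:
    """AUROC / precision / recall of posterior odds against the planted truth.

    GSP pairs are excluded from both predictions and truth (they were given
    to the model). Recall counts all non-GSP truth pairs, whether scored or
    not.
    """
    truth = world.truth.pairs - world.gsp.pairs
    labels = []
    scores = []
    for s in scored:
        if s.pair in world.gsp.pairs:
            continue
        labels.append(1 if s.pair in truth else 0)
        scores.append(s.posterior_odds)
    if len(set(labels)) < 2:
        raise ValueError("scored set contains a single class; AUROC undefined")
    auroc = float(roc_auc_score(labels, scores))
    high = [s.pair for s in scored
            if s.is_high_confidence and s.pair not in world.gsp.pairs
            and s.posterior_odds > cutoff]
    tp = sum(1 for p in high if p in truth)
    precision = tp / len(high) if high else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return {
        "auroc": auroc,
        "n_scored": len(labels),
        "n_truth": len(truth),
        "n_high_confidence": len(high),
        "precision_at_cutoff": precision,
        "recall_at_cutoff": recall,
    }
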