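"""The seven per-pair evidence features behind the interaction predictor.

Each feature maps a protein pair to a number (or boolean) whose distribution
differs between interacting and non-interacting pairs:

* ``coexpression`` — Pearson correlation of expression profiles, Fisher-z
  averaged across the datasets in which co-expression is informative.
* ``ssbp`` — smallest shared biological process: the protein count of the
  most specific GO BP term annotating both proteins (small = specific).
* ``domain`` — number of cross-pair domain combinations known to interact.
* ``phylo_profile`` — Jaccard similarity of ortholog presence/absence
  profiles across reference genomes.
* ``neighborhood`` — fraction of reference genomes in which orthologs of the
  two proteins are chromosomal neighbours.
* ``fusion`` — whether homologs of the two proteins fuse into one protein
  chain elsewhere (Rosetta-stone evidence).
* ``cluster`` — whether the two genes sit in the same predicted operon.

Missing evidence is represented as absence (the pair is simply not in the
table), never as zero; the integrator treats absent features as likelihood
ratio 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (AnnotationTable, ExpressionMatrix, GenomeTable, Ontology,
                      Pair, PairSet)

FEATURE_NAMES = ("coexpression", "ssbp", "domain", "phylo_profile",
                 "neighborhood", "fusion", "cluster")
BOOLEAN_FEATURES = frozenset({"fusion", "cluster"})


@dataclass
class FeatureTable:
    """Per-pair values for one named evidence feature; absent pairs = no evidence."""

    feature_name: str
    values: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        if self.feature_name in BOOLEAN_FEATURES:
            bad = {v for v in self.values.values() if v not in (0, 1)}
            if bad:
                raise ValueError(f"{self.feature_name}: non-boolean values {bad}")
        if self.feature_name == "coexpression":
            arr = np.asarray(list(self.values.values()), dtype=float)
            if arr.size and (np.abs(arr) > 1 + 1e-12).any():
                raise ValueError("coexpression values must lie in [-1, 1]")

    @property
    def is_boolean(self) -> bool:
        return self.feature_name in BOOLEAN_FEATURES

    def __len__(self) -> int:
        return len(self.values)

    def get(self, pair: Pair):
        return self.values.get(pair)


def write_feature_table(table: FeatureTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# feature={table.feature_name}\n")
        for pair in sorted(table.values):
            fh.write(f"{pair.a}\t{pair.b}\t{table.values[pair]:.6g}\n")


def read_feature_table(path, feature_name: str) -> FeatureTable:
    from .core_io import _iter_rows, canonical_pair
    values = {}
    for _, (a, b, v) in _iter_rows(path, n_cols=3):
        values[canonical_pair(a, b)] = float(v)
    return FeatureTable(feature_name=feature_name, values=values)


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def _pairwise_pearson(mat: ExpressionMatrix, pairs: Iterable[Pair]
                      ) -> dict[Pair, float]:
    """Pearson r per pair; rows with zero variance yield no value."""
    df = mat.values
    genes = df.index
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=1)
    ok = {g for g, s in zip(genes, sd) if s > 0}
    idx = {g: i for i, g in enumerate(genes)}
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc ** 2).sum(axis=1))
    out = {}
    for pair in pairs:
        if pair.a in ok and pair.b in ok:
            i, j = idx[pair.a], idx[pair.b]
            r = float(np.dot(xc[i], xc[j]) / (norm[i] * norm[j]))
            out[pair] = float(np.clip(r, -1.0, 1.0))
    return out


def retained_datasets(datasets: Sequence[ExpressionMatrix], gsp: PairSet,
                      gsn: PairSet, alpha: float = 0.05) -> list[str]:
    """Dataset ids in which co-expression is informative for interaction.

    A dataset is retained iff its GSP-pair correlations exceed its GSN-pair
    correlations by a one-sided Mann-Whitney U test at ``alpha``.
    """
    keep = []
    for mat in datasets:
        r_pos = list(_pairwise_pearson(mat, gsp.sorted()).values())
        r_neg = list(_pairwise_pearson(mat, gsn.sorted()).values())
        if len(r_pos) < 2 or len(r_neg) < 2:
            continue
        res = stats.mannwhitneyu(r_pos, r_neg, alternative="greater")
        if res.pvalue < alpha:
            keep.append(mat.dataset_id)
    return keep


def coexpression_feature(datasets: Sequence[ExpressionMatrix],
                         pairs: Iterable[Pair], gsp: PairSet, gsn: PairSet,
                         alpha: float = 0.05
                         ) -> tuple[FeatureTable, list[str]]:
    """Fisher-z mean of per-dataset Pearson r across retained datasets.

    Correlations are z-transformed, averaged over the datasets in which the
    pair is measured, and back-transformed, so each dataset contributes on a
    variance-stabilised scale. Pairs absent from every retained dataset are
    missing. If no dataset is retained the feature is emitted empty with a
    warning and the integrator treats it as uninformative.
    """
    if not datasets:
        raise ValueError("need at least one expression dataset")
    pairs = list(pairs)
    keep_ids = retained_datasets(datasets, gsp, gsn, alpha=alpha)
    kept = [m for m in datasets if m.dataset_id in keep_ids]
    if not kept:
        warnings.warn("no expression dataset retained; co-expression is empty")
        return FeatureTable(feature_name="coexpression"), []
    zsum: dict[Pair, float] = {}
    zcnt: dict[Pair, int] = {}
    for mat in kept:
        for pair, r in _pairwise_pearson(mat, pairs).items():
            z = float(np.arctanh(np.clip(r, -0.999999, 0.999999)))
            zsum[pair] = zsum.get(pair, 0.0) + z
            zcnt[pair] = zcnt.get(pair, 0) + 1
    values = {p: float(np.tanh(zsum[p] / zcnt[p])) for p in zsum}
    return FeatureTable(feature_name="coexpression", values=values), keep_ids


# ---------------------------------------------------------------------------
# smallest shared biological process
# ---------------------------------------------------------------------------

def ssbp_feature(annot: AnnotationTable, onto: Ontology,
                 pairs: Iterable[Pair]) -> FeatureTable:
    """Size (in annotated proteins) of the most specific shared BP term.

    Annotations are propagated to is_a ancestors first, so two proteins
    annotated below a common term still share it. Pairs with no shared BP
    term are missing. Smaller values mean a more specific shared process.
    """
    prop = annot.propagated(onto, namespace="biological_process")
    term_size: dict[str, int] = {}
    for terms in prop.values():
        for t in terms:
            term_size[t] = term_size.get(t, 0) + 1
    values = {}
    for pair in pairs:
        shared = prop.get(pair.a, frozenset()) & prop.get(pair.b, frozenset())
        if shared:
            values[pair] = float(min(term_size[t] for t in shared))
    return FeatureTable(feature_name="ssbp", values=values)


# ---------------------------------------------------------------------------
# domain-domain interactions
# ---------------------------------------------------------------------------

def domain_feature(domain_assign: Mapping[str, Iterable[str]],
                   ddi: Iterable[tuple[str, str]],
                   pairs: Iterable[Pair]) -> FeatureTable:
    """Count of cross-pair domain combinations present in the DDI catalogue.

    Unordered: (D1, D2) and (D2, D1) are the same interaction. Zero counts
    are informative (both proteins have domains, none interact); a pair is
    missing only if either protein has no domain assignment.
    """
    ddi_set = {frozenset(d) for d in ddi}
    doms = {p: set(ds) for p, ds in domain_assign.items()}
    values = {}
    for pair in pairs:
        da, db = doms.get(pair.a), doms.get(pair.b)
        if not da or not db:
            continue
        count = sum(1 for x in da for y in db if frozenset((x, y)) in ddi_set)
        values[pair] = float(count)
    return FeatureTable(feature_name="domain", values=values)


# ---------------------------------------------------------------------------
# phylogenetic profiles
# ---------------------------------------------------------------------------

def phylo_profile_feature(profiles: pd.DataFrame,
                          pairs: Iterable[Pair]) -> FeatureTable:
    """Jaccard similarity of presence sets across reference genomes.

    All-zero profiles carry no signal and make the pair missing.
    """
    presence = {g: frozenset(profiles.columns[profiles.loc[g] == 1])
                for g in profiles.index}
    values = {}
    for pair in pairs:
        pa, pb = presence.get(pair.a), presence.get(pair.b)
        if not pa or not pb:
            continue
        values[pair] = len(pa & pb) / len(pa | pb)
    return FeatureTable(feature_name="phylo_profile", values=values)


# ---------------------------------------------------------------------------
# gene neighborhood
# ---------------------------------------------------------------------------

def _gene_ranks(genome: GenomeTable) -> dict[str, tuple[str, int]]:
    """(replicon, positional rank) per gene, ranks by start coordinate."""
    out = {}
    for repl, sub in genome.genes.groupby("replicon"):
        ordered = sub.sort_values(["start", "gene_id"])
        for rank, gene in enumerate(ordered["gene_id"]):
            out[gene] = (str(repl), rank)
    return out


def neighborhood_feature(genomes: Sequence[GenomeTable],
                         orthologs: Mapping[tuple[str, str], str],
                         pairs: Iterable[Pair],
                         max_intervening: int = 5,
                         min_genomes: int = 1) -> FeatureTable:
    """Fraction of informative genomes where the orthologs are neighbours.

    A genome is informative for a pair if it contains orthologs of both
    proteins; the pair counts as a neighbour there if both orthologs lie on
    the same replicon with at most ``max_intervening`` genes between them.
    Pairs informative in fewer than ``min_genomes`` genomes are missing.
    """
    ranks = {g.genome_id: _gene_ranks(g) for g in genomes}
    values = {}
    for pair in pairs:
        informative = 0
        close = 0
        for g in genomes:
            ga = orthologs.get((pair.a, g.genome_id))
            gb = orthologs.get((pair.b, g.genome_id))
            if ga is None or gb is None:
                continue
            ra = ranks[g.genome_id].get(ga)
            rb = ranks[g.genome_id].get(gb)
            if ra is None or rb is None:
                continue
            informative += 1
            if ra[0] == rb[0] and abs(ra[1] - rb[1]) - 1 <= max_intervening:
                close += 1
        if informative >= min_genomes:
            values[pair] = close / informative
    return FeatureTable(feature_name="neighborhood", values=values)


# ---------------------------------------------------------------------------
# gene fusion
# ---------------------------------------------------------------------------

def fusion_feature(hits: pd.DataFrame, pairs: Iterable[Pair],
                   max_overlap_frac: float = 0.2) -> FeatureTable:
    """Rosetta-stone evidence: both proteins hit one target on distinct spans.

    ``hits`` columns: query, target, target_start, target_end. The feature is
    1 iff some target is hit by both pair members with span overlap below
    ``max_overlap_frac`` of the shorter span (near-disjoint spans indicate a
    genuine fusion rather than shared homology).
    """
    by_query: dict[str, list[tuple[str, int, int]]] = {}
    for row in hits.itertuples(index=False):
        by_query.setdefault(str(row.query), []).append(
            (str(row.target), int(row.target_start), int(row.target_end)))
    values = {}
    for pair in pairs:
        ha = by_query.get(pair.a, [])
        hb = by_query.get(pair.b, [])
        fused = 0
        for ta, sa, ea in ha:
            for tb, sb, eb in hb:
                if ta != tb:
                    continue
                overlap = min(ea, eb) - max(sa, sb) + 1
                shorter = min(ea - sa, eb - sb) + 1
                if overlap < max_overlap_frac * shorter:
                    fused = 1
                    break
            if fused:
                break
        values[pair] = float(fused)
    return FeatureTable(feature_name="fusion", values=values)


# ---------------------------------------------------------------------------
# gene cluster (operon co-membership)
# ---------------------------------------------------------------------------

def predict_operons(genome: GenomeTable, max_gap: int = 300) -> dict[str, int]:
    """Operon id per gene: maximal runs of same-replicon, same-strand genes
    whose successive intergenic gaps are at most ``max_gap`` bp."""
    operon_of: dict[str, int] = {}
    next_id = 0
    for _, sub in genome.genes.groupby("replicon", sort=True):
        ordered = sub.sort_values(["start", "gene_id"]).itertuples(index=False)
        prev = None
        for row in ordered:
            new_run = (prev is None or row.strand != prev.strand
                       or row.start - prev.end - 1 > max_gap)
            if new_run:
                next_id += 1
            operon_of[row.gene_id] = next_id
            prev = row
    return operon_of


def cluster_feature(genome: GenomeTable, pairs: Iterable[Pair],
                    max_gap: int = 300) -> FeatureTable:
    """1 iff both genes of the pair lie in the same predicted operon."""
    operon_of = predict_operons(genome, max_gap=max_gap)
    values = {}
    for pair in pairs:
        oa, ob = operon_of.get(pair.a), operon_of.get(pair.b)
        if oa is None or ob is None:
            continue
        values[pair] = float(oa == ob)
    return FeatureTable(feature_name="cluster", values=values)
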