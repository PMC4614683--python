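"""Hypergeometric enrichment of sub-networks, overlap tests, and interolog evaluation.

Pathway enrichment asks, for each sub-network and pathway, how surprising
the observed overlap k is when n annotated sub-network proteins are drawn
from a population of N annotated proteins containing K pathway members:
p = P(X >= k) for X ~ Hypergeometric(N, K, n). P-values are
Benjamini-Hochberg adjusted within each sub-network and called significant
when the adjusted p is strictly below alpha (default 0.05).

Interolog evaluation maps predicted pairs through ortholog tables into
foreign interactomes: a prediction is conserved in a species when some
ortholog image of the pair is a known interaction there. Orthologs come
from reciprocal best hits with a strict E-value cutoff (< 1e-10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import Pair, PairSet, canonical_pair
from .modules import SubNetwork


# ---------------------------------------------------------------------------
# hypergeometric machinery
# ---------------------------------------------------------------------------

def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    subnetwork_id: int
    pathway_id: str
    k: int          # pathway members in the sub-network
    K: int          # pathway size in the population
    n: int          # annotated sub-network proteins
    N: int          # annotated population
    p_value: float
    adjusted_p: float = 1.0

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds pathway or sub-network size")

    @property
    def significant(self) -> bool:
        return self.adjusted_p < 0.05


def pathway_enrichment(subnets: Sequence[SubNetwork],
                       pathway_map: Mapping[str, set[str]],
                       alpha: float = 0.05,
                       population: set[str] | None = None
                       ) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every sub-network against every pathway.

    The population defaults to proteins carrying at least one pathway
    annotation (pass ``population`` to widen it, e.g. to the whole genome).
    BH adjustment is applied across the tests of each sub-network;
    significance is ``adjusted_p < alpha`` strictly.
    """
    if not pathway_map:
        raise ValueError("empty pathway universe")
    pathways = {pid: set(members) for pid, members in pathway_map.items()}
    annotated = set().union(*pathways.values())
    pop = set(population) if population is not None else annotated
    N = len(pop)
    results: list[EnrichmentResult] = []
    for sub in subnets:
        nodes = set(sub.extended_nodes) & pop
        n = len(nodes)
        batch = []
        for pid in sorted(pathways):
            members = pathways[pid] & pop
            K = len(members)
            k = len(nodes & members)
            p = hypergeom_tail(k, K, n, N) if n else 1.0
            batch.append(EnrichmentResult(
                subnetwork_id=sub.rank, pathway_id=pid, k=k, K=K, n=n, N=N,
                p_value=p))
        if batch:
            _, adj, _, _ = multipletests([r.p_value for r in batch],
                                         method="fdr_bh")
            for r, q in zip(batch, adj):
                r.adjusted_p = float(q)
        results.extend(batch)
    return results


def significant_enrichments(results: Sequence[EnrichmentResult],
                            alpha: float = 0.05) -> list[EnrichmentResult]:
    return [r for r in results if r.adjusted_p < alpha]


def overlap_significance(predicted: PairSet, reference: PairSet,
                         universe_pairs: int) -> float:
    """Hypergeometric p-value for the overlap of two pair sets.

    The universe is the number of possible pairs; the overlap of the
    predicted set with the reference plays the role of the draw's successes.
    """
    overlap = len(predicted.pairs & reference.pairs)
    return hypergeom_tail(overlap, len(reference), len(predicted),
                          universe_pairs)


# ---------------------------------------------------------------------------
# interologs
# ---------------------------------------------------------------------------

def reciprocal_best_hits(similarity: pd.DataFrame,
                         cutoff: float = 1e-10) -> dict[str, str]:
    """Ortholog map from reciprocal best hits at a strict E-value cutoff.

    ``similarity`` columns: protein_a, protein_b, evalue (a and b from the
    two species). (x, y) is an ortholog pair iff y is x's minimum-E-value
    hit, x is y's, and both E-values are < cutoff. Ties on the minimum are
    broken lexically with a warning. The returned map contains both
    directions (x -> y and y -> x).
    """
    best_a: dict[str, tuple[float, str]] = {}
    best_b: dict[str, tuple[float, str]] = {}
    ties = 0
    for row in similarity.itertuples(index=False):
        a, b, e = str(row.protein_a), str(row.protein_b), float(row.evalue)
        for best, key, other in ((best_a, a, b), (best_b, b, a)):
            cur = best.get(key)
            if cur is None or e < cur[0]:
                best[key] = (e, other)
            elif e == cur[0] and other < cur[1]:
                best[key] = (e, other)
                ties += 1
            elif e == cur[0]:
                ties += 1
    if ties:
        warnings.warn(f"{ties} best-hit ties broken lexically")
    out: dict[str, str] = {}
    for a, (ea, b) in sorted(best_a.items()):
        eb, back = best_b.get(b, (None, None))
        if back == a and ea < cutoff and eb < cutoff:
            out[a] = b
            out[b] = a
    return out


@dataclass
class SpeciesInterologs:
    species: str
    mapped: set[Pair] = field(default_factory=set)     # both members have orthologs
    conserved: set[Pair] = field(default_factory=set)  # ortholog image is a foreign edge

    def __post_init__(self) -> None:
        if not self.conserved <= self.mapped:
            raise ValueError("conserved pairs must be mapped")

    @property
    def fraction(self) -> float:
        return len(self.conserved) / len(self.mapped) if self.mapped else 0.0


@dataclass
class InterologReport:
    per_species: dict[str, SpeciesInterologs]
    n_predicted: int

    @property
    def conserved_union(self) -> set[Pair]:
        out: set[Pair] = set()
        for si in self.per_species.values():
            out |= si.conserved
        return out

    @property
    def fraction_of_mapped(self) -> float:
        mapped = set().union(*(si.mapped for si in self.per_species.values())) \
            if self.per_species else set()
        return len(self.conserved_union) / len(mapped) if mapped else 0.0

    @property
    def fraction_of_predicted(self) -> float:
        return len(self.conserved_union) / self.n_predicted if self.n_predicted else 0.0


def map_interologs(predicted: PairSet,
                   ortholog_maps: Mapping[str, Mapping[str, str]],
                   foreign_ppis: Mapping[str, PairSet]) -> InterologReport:
    """Conservation of predicted pairs through orthology into foreign interactomes.

    A pair is *mapped* in species s when both members have orthologs there
    and the images differ; it is *conserved* when that image pair is an edge
    of the species' known interactome. The per-species fraction uses mapped
    pairs as the denominator; the fraction over all predictions is also
    reported.
    """
    per_species: dict[str, SpeciesInterologs] = {}
    for species in sorted(ortholog_maps):
        omap = ortholog_maps[species]
        foreign = foreign_ppis.get(species, PairSet(label="predicted"))
        si = SpeciesInterologs(species=species)
        for pair in predicted:
            oa, ob = omap.get(pair.a), omap.get(pair.b)
            if oa is None or ob is None or oa == ob:
                continue
            si.mapped.add(pair)
            if canonical_pair(oa, ob) in foreign:
                si.conserved.add(pair)
        per_species[species] = si
    return InterologReport(per_species=per_species, n_predicted=len(predicted))
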