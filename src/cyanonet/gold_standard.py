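"""Gold standard positive/negative pair sets for likelihood-ratio calibration.

The positive set (GSP) is the curated list of experimentally confirmed
interactions. The negative set (GSN) is built combinatorially: pairs of
proteins annotated to disjoint cellular locations, excluding possibly mobile
or secreted proteins (whose location is unreliable) and any pair already in
the GSP. Location comparison uses direct cellular-component terms plus their
is_a ancestors with the namespace root removed — every protein trivially
shares the root, so keeping it would empty the negative set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (AnnotationTable, Ontology, Pair, PairSet, ProteinCatalog,
                      canonical_pair)


@dataclass
class GoldStandard:
    gsp: PairSet
    gsn: PairSet
    universe_size: int  # all unordered protein pairs over the catalog

    @property
    def prior_odds(self) -> float:
        from .bayes import prior_odds
        return prior_odds(len(self.gsp), len(self.gsn))


def build_gsp(raw: PairSet, catalog: ProteinCatalog) -> PairSet:
    """Validate and label the known-interaction pair set.

    Pairs are already canonical and deduplicated by construction; pairs that
    reference proteins absent from the catalog are an error, and an empty
    result is an error because calibration would be impossible.
    """
    offenders = sorted({p for pair in raw for p in pair if p not in catalog})
    if offenders:
        raise ValueError(f"GSP references unknown proteins: {offenders[:10]}")
    if not raw.pairs:
        raise ValueError("GSP is empty; cannot calibrate likelihood ratios")
    return PairSet(pairs=set(raw.pairs), label="GSP")


def effective_locations(catalog: ProteinCatalog,
                        ontology: Ontology | None = None) -> dict[str, frozenset[str]]:
    """Location term set per protein used for negative-set comparison.

    With an ontology, direct CC terms are propagated to ancestors and the CC
    root is removed; without one, the direct terms are used as-is.
    """
    if ontology is None:
        return dict(catalog.localization_terms)
    cc_root = ontology.roots.get("cellular_component")
    annot = AnnotationTable(assignments=catalog.localization_terms)
    prop = annot.propagated(ontology, namespace="cellular_component")
    return {p: frozenset(ts - {cc_root}) for p, ts in prop.items()}


def build_gsn(catalog: ProteinCatalog, gsp: PairSet,
              ontology: Ontology | None = None,
              max_size: int | None = None, seed: int = 0) -> PairSet:
    """Enumerate the gold standard negative set.

    A pair qualifies iff both proteins have non-empty location sets with empty
    intersection, neither is mobility-flagged, and the pair is not in the GSP.
    Deterministic given the catalog; ``max_size`` optionally subsamples with
    the given seed (default: keep all).
    """
    locs = effective_locations(catalog, ontology)
    eligible = [p for p in catalog.protein_ids
                if locs.get(p) and not catalog.mobility_flag[p]]
    pairs: set[Pair] = set()
    for i, x in enumerate(eligible):
        lx = locs[x]
        for y in eligible[i + 1:]:
            if lx.isdisjoint(locs[y]):
                pair = canonical_pair(x, y)
                if pair not in gsp:
                    pairs.add(pair)
    if not pairs:
        raise ValueError("GSN construction yielded no pairs; calibration impossible")
    if max_size is not None and len(pairs) > max_size:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=max_size, replace=False)
        ordered = sorted(pairs)
        pairs = {ordered[i] for i in keep}
    return PairSet(pairs=pairs, label="GSN")


def build_gold_standard(raw_gsp: PairSet, catalog: ProteinCatalog,
                        ontology: Ontology | None = None,
                        gsn_max: int | None = None, seed: int = 0) -> GoldStandard:
    gsp = build_gsp(raw_gsp, catalog)
    gsn = build_gsn(catalog, gsp, ontology, max_size=gsn_max, seed=seed)
    n = len(catalog)
    return GoldStandard(gsp=gsp, gsn=gsn, universe_size=n * (n - 1) // 2)


def validate_gold_standard(gs: GoldStandard,
                           catalog: ProteinCatalog | None = None,
                           ontology: Ontology | None = None) -> dict:
    """Assert the gold-standard invariants; return a count report."""
    overlap = gs.gsp.pairs & gs.gsn.pairs
    if overlap:
        raise ValueError(f"GSP/GSN overlap: {sorted(overlap)[:5]}")
    if catalog is not None:
        locs = effective_locations(catalog, ontology)
        for pair in gs.gsn:
            if catalog.mobility_flag.get(pair.a) or catalog.mobility_flag.get(pair.b):
                raise ValueError(f"GSN pair {pair} includes a mobility-flagged protein")
            if locs[pair.a] & locs[pair.b]:
                raise ValueError(f"GSN pair {pair} shares a location term")
    return {
        "n_gsp": len(gs.gsp),
        "n_gsn": len(gs.gsn),
        "overlap": 0,
        "universe_size": gs.universe_size,
        "gsp_proteins": len(gs.gsp.proteins()),
        "gsn_proteins": len(gs.gsn.proteins()),
    }
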