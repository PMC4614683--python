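"""Network-based GO annotation of function-unknown proteins by simulated annealing.

Known proteins keep their annotations, mapped up to a fixed ontology level
(the 5th level below the namespace root by default). Unknown proteins are
assigned one candidate term each, and the assignment is relaxed by
Metropolis simulated annealing that minimizes the number of network edges
whose endpoints share no term — interacting proteins tend to work in the
same process, so a good assignment leaves few cross-class edges.

A single run yields one label per protein; the procedure is repeated many
times (default 100) with different seeds, and a term is accepted for a
protein only when its cross-run frequency is strictly larger than a
background-noise threshold estimated from a random sample of the frequency
table (mean + 2 SD of 10% of the cells by default) — this filters out
assignments that arise from random drift rather than network structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core_io import AnnotationTable, Ontology


# ---------------------------------------------------------------------------
# ontology levels
# ---------------------------------------------------------------------------

def level_terms(onto: Ontology, depth: int = 5,
                namespace: str = "biological_process") -> set[str]:
    """Terms whose minimum is_a distance from the namespace root equals ``depth``."""
    return {t for t, ns in onto.namespace.items()
            if ns == namespace and onto.depth(t) == depth}


def level_ancestors(onto: Ontology, term: str, depth: int) -> set[str]:
    """Ancestors of ``term`` (term included) lying exactly at ``depth``."""
    pool = {term} | set(onto.ancestors(term))
    return {t for t in pool if onto.depth(t) == depth}


def fixed_assignments(annot: AnnotationTable, onto: Ontology, depth: int = 5,
                      namespace: str = "biological_process"
                      ) -> dict[str, frozenset[str]]:
    """Map each annotated protein's terms to their level-``depth`` ancestors.

    Terms shallower than ``depth`` carry no level-``depth`` information and
    are dropped; proteins left with no terms are omitted.
    """
    out = {}
    for pid, terms in annot.assignments.items():
        mapped: set[str] = set()
        for t in terms:
            if onto.namespace[t] != namespace:
                continue
            mapped |= level_ancestors(onto, t, depth)
        if mapped:
            out[pid] = frozenset(mapped)
    return out


# ---------------------------------------------------------------------------
# annealing state and energy
# ---------------------------------------------------------------------------

@dataclass
class AnnotationState:
    """Assignment of terms to proteins: immutable known part, mutable unknown part."""

    fixed: dict[str, frozenset[str]]
    free: dict[str, frozenset[str]]
    energy: int

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.fixed.get(protein) or self.free.get(protein) or frozenset()


def energy(network: nx.Graph, state: AnnotationState) -> int:
    """Number of edges whose endpoints share no term (recomputed from scratch).

    Endpoints that are neither annotated nor assigned share nothing, so their
    edges always count.
    """
    e = 0
    for u, v in network.edges:
        if not (state.terms_of(u) & state.terms_of(v)):
            e += 1
    return e


@dataclass
class Schedule:
    """Geometric cooling schedule for the Metropolis sampler.

    ``steps_per_temp`` moves are attempted at each temperature, starting at
    ``t0`` and multiplying by ``gamma`` until the temperature drops below
    ``t_min``. ``t0 = 0`` gives a purely greedy descent.
    """

    t0: float = 1.0
    gamma: float = 0.9
    steps_per_temp: int | None = None  # default: 5 x number of free proteins
    t_min: float = 0.01

    def temperatures(self) -> list[float]:
        if self.t0 <= self.t_min:
            return [max(self.t0, 0.0)]
        temps = []
        t = self.t0
        while t >= self.t_min:
            temps.append(t)
            t *= self.gamma
        return temps


class AnnealingEngine:
    """Incremental-energy Metropolis sampler over single-term reassignments.

    Maintains the energy under single-protein single-term moves; the
    incremental bookkeeping is checked against :func:`energy` in tests.
    """

    def __init__(self, network: nx.Graph, fixed: Mapping[str, frozenset[str]],
                 candidate_terms: Sequence[str]):
        if not candidate_terms:
            raise ValueError("candidate term set is empty")
        self.nodes = sorted(network.nodes)
        self.candidates = sorted(set(candidate_terms))
        n_idx = {n: i for i, n in enumerate(self.nodes)}
        t_idx = {t: i for i, t in enumerate(self.candidates)}
        self.t_idx = t_idx
        # fixed nodes: set of candidate-term indices (terms outside the
        # candidate set can never be matched by a free assignment, but two
        # fixed nodes may share them — handled via the constant part below)
        self.fixed_terms: list[frozenset[int] | None] = [None] * len(self.nodes)
        for p, terms in fixed.items():
            if p in n_idx:
                self.fixed_terms[n_idx[p]] = frozenset(
                    t_idx[t] for t in terms if t in t_idx)
        self.free_nodes = [i for i, ft in enumerate(self.fixed_terms) if ft is None]
        self.assignment: dict[int, int] = {}
        # split edges: fixed-fixed edges contribute a constant energy
        self.adj: list[list[int]] = [[] for _ in self.nodes]
        self.const_energy = 0
        full_fixed = {p: frozenset(terms) for p, terms in fixed.items()}
        for u, v in network.edges:
            iu, iv = n_idx[u], n_idx[v]
            if self.fixed_terms[iu] is not None and self.fixed_terms[iv] is not None:
                if not (full_fixed.get(u, frozenset()) & full_fixed.get(v, frozenset())):
                    self.const_energy += 1
            else:
                self.adj[iu].append(iv)
                self.adj[iv].append(iu)
        self.energy: int | None = None

    def initialize(self, rng: np.random.Generator) -> None:
        terms = rng.integers(0, len(self.candidates), size=len(self.free_nodes))
        self.assignment = {u: int(t) for u, t in zip(self.free_nodes, terms)}
        self.energy = self._recompute()

    def _edge_cost(self, u: int, v: int) -> int:
        tu = self._terms(u)
        tv = self._terms(v)
        return 0 if (tu & tv) else 1

    def _terms(self, u: int) -> frozenset[int]:
        ft = self.fixed_terms[u]
        if ft is not None:
            return ft
        t = self.assignment.get(u)
        return frozenset() if t is None else frozenset((t,))

    def _recompute(self) -> int:
        e = self.const_energy
        seen = set()
        for u in range(len(self.nodes)):
            for v in self.adj[u]:
                key = (u, v) if u < v else (v, u)
                if key not in seen:
                    seen.add(key)
                    e += self._edge_cost(u, v)
        return e

    def delta(self, u: int, new_term: int) -> int:
        """Energy change of reassigning free node ``u`` to ``new_term``."""
        old = self.assignment[u]
        if old == new_term:
            return 0
        d = 0
        for v in self.adj[u]:
            ft = self.fixed_terms[v]
            tv = ft if ft is not None else frozenset((self.assignment[v],))
            d += (0 if new_term in tv else 1) - (0 if old in tv else 1)
        return d

    def apply(self, u: int, new_term: int) -> int:
        d = self.delta(u, new_term)
        self.assignment[u] = new_term
        self.energy += d
        return d

    def run(self, schedule: Schedule, rng: np.random.Generator) -> None:
        if not self.free_nodes:
            return
        if self.energy is None:
            self.initialize(rng)
        n_free = len(self.free_nodes)
        steps = schedule.steps_per_temp or 5 * n_free
        for t in schedule.temperatures():
            us = rng.integers(0, n_free, size=steps)
            ts = rng.integers(0, len(self.candidates), size=steps)
            unif = rng.random(size=steps)
            for k in range(steps):
                u = self.free_nodes[int(us[k])]
                new_term = int(ts[k])
                d = self.delta(u, new_term)
                if d <= 0:
                    accept = True
                elif t <= 0:
                    accept = False
                else:
                    accept = unif[k] < np.exp(-d / t)
                if accept:
                    self.assignment[u] = new_term
                    self.energy += d

    def state(self, fixed: Mapping[str, frozenset[str]]) -> AnnotationState:
        free = {self.nodes[u]: frozenset((self.candidates[t],))
                for u, t in sorted(self.assignment.items())}
        return AnnotationState(fixed=dict(fixed), free=free,
                               energy=int(self.energy))


def anneal(network: nx.Graph, fixed: Mapping[str, frozenset[str]],
           candidate_terms: Sequence[str], schedule: Schedule | None = None,
           seed: int = 0) -> AnnotationState:
    """One annealing run; deterministic given the seed.

    With no free proteins the fixed assignment is returned unchanged (its
    energy still computed).
    """
    schedule = schedule or Schedule()
    fixed = {p: frozenset(ts) for p, ts in fixed.items()}
    engine = AnnealingEngine(network, fixed, candidate_terms)
    rng = np.random.default_rng(seed)
    if not engine.free_nodes:
        st = AnnotationState(fixed=dict(fixed), free={}, energy=0)
        st.energy = energy(network, st)
        return st
    engine.initialize(rng)
    engine.run(schedule, rng)
    return engine.state(fixed)


# ---------------------------------------------------------------------------
# repeated runs, background noise, final assignment
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Cross-run assignment frequencies: counts(protein, term) in [0, repeats]."""

    counts: dict[tuple[str, str], int]
    repeats: int
    free_proteins: tuple[str, ...] = ()
    candidate_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = {k: c for k, c in self.counts.items()
               if c < 0 or c > self.repeats}
        if bad:
            raise ValueError(f"counts outside [0, repeats]: {list(bad)[:5]}")


def repeat_anneal(network: nx.Graph, fixed: Mapping[str, frozenset[str]],
                  candidate_terms: Sequence[str],
                  schedule: Schedule | None = None, repeats: int = 100,
                  base_seed: int = 0) -> FrequencyTable:
    """Run the annealer ``repeats`` times (seeds base_seed+i) and tally labels."""
    schedule = schedule or Schedule()
    fixed = {p: frozenset(ts) for p, ts in fixed.items()}
    counts: dict[tuple[str, str], int] = {}
    free_proteins: tuple[str, ...] = ()
    for i in range(repeats):
        engine = AnnealingEngine(network, fixed, candidate_terms)
        rng = np.random.default_rng(base_seed + i)
        if not engine.free_nodes:
            break
        engine.initialize(rng)
        engine.run(schedule, rng)
        free_proteins = tuple(engine.nodes[u] for u in engine.free_nodes)
        for u, t in engine.assignment.items():
            key = (engine.nodes[u], engine.candidates[t])
            counts[key] = counts.get(key, 0) + 1
    return FrequencyTable(counts=counts, repeats=repeats,
                          free_proteins=free_proteins,
                          candidate_terms=tuple(sorted(set(candidate_terms))))


def background_noise(freq: FrequencyTable, fraction: float = 0.1,
                     seed: int = 0) -> float:
    """Noise threshold: mean + 2 SD of a random sample of frequency-table cells.

    The cell universe is every (free protein, candidate term) combination,
    zeros included; ``fraction`` of the cells (at least one) are sampled
    without replacement with the given seed.
    """
    if not freq.free_proteins or not freq.candidate_terms:
        raise ValueError("empty frequency table; nothing to sample")
    cells = [(p, t) for p in freq.free_proteins for t in freq.candidate_terms]
    n_sample = max(1, int(round(fraction * len(cells))))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cells), size=n_sample, replace=False)
    sample = np.array([freq.counts.get(cells[i], 0) for i in chosen], dtype=float)
    return float(sample.mean() + 2 * sample.std())


def assign_terms(freq: FrequencyTable, threshold: float) -> AnnotationTable:
    """Keep (protein, term) pairs whose frequency is strictly above the threshold."""
    assign: dict[str, set[str]] = {}
    for (p, t), c in freq.counts.items():
        if c > threshold:
            assign.setdefault(p, set()).add(t)
    return AnnotationTable(
        assignments={p: frozenset(ts) for p, ts in assign.items()})


def annotate_unknown(network: nx.Graph, annot: AnnotationTable, onto: Ontology,
                     depth: int = 5,
                     namespaces: Iterable[str] = ("biological_process",),
                     schedule: Schedule | None = None, repeats: int = 100,
                     base_seed: int = 0, noise_fraction: float = 0.1
                     ) -> tuple[AnnotationTable, dict]:
    """Full annotation pipeline over one or more namespaces.

    Candidate terms are the level-``depth`` terms appearing among the fixed
    (known) annotations of the network; if none exist, all level-``depth``
    terms of the namespace are used. Returns the accepted annotations and a
    per-namespace report (threshold, counts).
    """
    merged: dict[str, set[str]] = {}
    report: dict[str, dict] = {}
    for ns in namespaces:
        fixed = fixed_assignments(annot, onto, depth=depth, namespace=ns)
        fixed = {p: ts for p, ts in fixed.items() if p in network}
        candidates = sorted({t for ts in fixed.values() for t in ts})
        if not candidates:
            candidates = sorted(level_terms(onto, depth=depth, namespace=ns))
        if not candidates:
            report[ns] = {"candidates": 0, "assigned": 0, "threshold": None}
            continue
        freq = repeat_anneal(network, fixed, candidates, schedule=schedule,
                             repeats=repeats, base_seed=base_seed)
        if not freq.free_proteins:
            report[ns] = {"candidates": len(candidates), "assigned": 0,
                          "threshold": None}
            continue
        threshold = background_noise(freq, fraction=noise_fraction,
                                     seed=base_seed)
        accepted = assign_terms(freq, threshold)
        for p, ts in accepted.assignments.items():
            merged.setdefault(p, set()).update(ts)
        report[ns] = {
            "candidates": len(candidates),
            "free_proteins": len(freq.free_proteins),
            "threshold": threshold,
            "assigned": len(accepted.assignments),
        }
    table = AnnotationTable(
        assignments={p: frozenset(ts) for p, ts in merged.items()})
    return table, report
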