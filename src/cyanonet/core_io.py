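"""Domain types, pair canonicalization, and readers/writers for every file the pipeline touches.

All tab-separated inputs are UTF-8, tab-delimited, with ``#``-prefixed comment
lines. Protein pairs are undirected everywhere: they are canonicalized
(lexicographic order) at construction and nothing downstream handles
orientation. Genome coordinates are 1-based inclusive (GenBank convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd


class FormatError(ValueError):
    """A file violated its format contract (column counts, cycles, bad values)."""


# ---------------------------------------------------------------------------
# pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Pair:
    """An unordered protein pair stored in canonical (lexicographic) order."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-pair forbidden: {self.a!r}")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    def __iter__(self):
        return iter((self.a, self.b))


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical :class:`Pair` for two protein ids.

    Commutative and idempotent: ``canonical_pair(a, b) == canonical_pair(b, a)``.
    Self-pairs are rejected.
    """
    if not a or not b:
        raise ValueError("protein ids must be non-empty")
    return Pair(a, b)


@dataclass
class PairSet:
    """A deduplicated set of canonical pairs with a provenance label."""

    pairs: set[Pair] = field(default_factory=set)
    label: str = "predicted"

    VALID_LABELS = frozenset({"GSP", "GSN", "predicted", "merged"})

    def __post_init__(self) -> None:
        if self.label not in self.VALID_LABELS:
            raise ValueError(f"unknown PairSet label {self.label!r}")
        self.pairs = set(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.pairs

    def __iter__(self):
        return iter(self.pairs)

    def sorted(self) -> list[Pair]:
        return sorted(self.pairs)

    def proteins(self) -> set[str]:
        return {p for pair in self.pairs for p in pair}


# ---------------------------------------------------------------------------
# protein catalog
# ---------------------------------------------------------------------------

@dataclass
class ProteinCatalog:
    """Per-protein metadata: annotation status, cellular location, mobility.

    ``localization_terms`` holds GO cellular-component identifiers; proteins
    with an empty set are ineligible for negative-set construction.
    ``mobility_flag`` marks possibly mobile or secreted proteins, which are
    excluded from the negative set because their location is unreliable.
    """

    is_annotated: dict[str, bool] = field(default_factory=dict)
    localization_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    mobility_flag: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid in self.is_annotated:
            if not pid:
                raise ValueError("protein_id must be non-empty")
        self.localization_terms = {
            p: frozenset(self.localization_terms.get(p, frozenset()))
            for p in self.is_annotated
        }
        self.mobility_flag = {
            p: bool(self.mobility_flag.get(p, False)) for p in self.is_annotated
        }

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.is_annotated)

    def __contains__(self, pid: str) -> bool:
        return pid in self.is_annotated

    def __len__(self) -> int:
        return len(self.is_annotated)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass
class Ontology:
    """A GO-like DAG restricted to id / name / namespace / is_a.

    ``parents`` maps each term to its direct is_a parents. Each namespace has
    a single root (the unique term with no parents in that namespace).
    """

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parents = {t: frozenset(ps) for t, ps in self.parents.items()}
        for t, ns in self.namespace.items():
            if ns not in NAMESPACES:
                raise FormatError(f"unknown namespace {ns!r} for term {t}")
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.namespace:
                    raise FormatError(f"term {t} has unknown parent {p}")
                if self.namespace[p] != self.namespace[t]:
                    raise FormatError(f"is_a edge {t}->{p} crosses namespaces")
        self._check_acyclic()
        self._roots = {}
        for ns in sorted(set(self.namespace.values())):
            roots = [t for t, n in self.namespace.items()
                     if n == ns and not self.parents.get(t)]
            if len(roots) != 1:
                raise FormatError(f"namespace {ns} has {len(roots)} roots, expected 1")
            self._roots[ns] = roots[0]
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, int] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise FormatError(f"cyclic is_a relation involving term {cycle[0][0]}")

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def root(self, namespace: str) -> str:
        return self._roots[namespace]

    @property
    def roots(self) -> dict[str, str]:
        return dict(self._roots)

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term``, excluding the term itself."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def depth(self, term: str) -> int:
        """Minimum is_a distance from the namespace root (root has depth 0)."""
        cached = self._depth_cache.get(term)
        if cached is not None:
            return cached
        ps = self.parents.get(term, frozenset())
        d = 0 if not ps else 1 + min(self.depth(p) for p in ps)
        self._depth_cache[term] = d
        return d


def read_obo_lite(path) -> Ontology:
    """Read an OBO file (id / name / namespace / is_a subset) into an :class:`Ontology`.

    Cyclic is_a relations and unknown namespaces are rejected.
    """
    graph = obonet.read_obo(path)
    parents: dict[str, frozenset[str]] = {}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            raise FormatError(f"term {term} has no namespace")
        namespace[term] = ns
        names[term] = data.get("name", term)
        parents[term] = frozenset(
            v for _, v, key in graph.out_edges(term, keys=True) if key == "is_a"
        )
    return Ontology(parents=parents, namespace=namespace, names=names)


def write_obo_lite(onto: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(onto.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {onto.names.get(term, term)}\n")
            fh.write(f"namespace: {onto.namespace[term]}\n")
            for p in sorted(onto.parents[term]):
                fh.write(f"is_a: {p}\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Direct GO annotations per protein; implied ancestors are computed on demand."""

    assignments: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = {p: frozenset(ts) for p, ts in self.assignments.items()}

    def validate_against(self, onto: Ontology) -> None:
        for p, terms in self.assignments.items():
            unknown = terms - onto.terms
            if unknown:
                raise FormatError(
                    f"protein {p} annotated to unknown terms {sorted(unknown)}")

    def propagated(self, onto: Ontology, namespace: str | None = None
                   ) -> dict[str, frozenset[str]]:
        """Direct terms plus all is_a ancestors, optionally one namespace only."""
        out = {}
        for p, terms in self.assignments.items():
            full: set[str] = set()
            for t in terms:
                full.add(t)
                full.update(onto.ancestors(t))
            if namespace is not None:
                full = {t for t in full if onto.namespace[t] == namespace}
            out[p] = frozenset(full)
        return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """One expression dataset: genes x samples, gene ids aligned to the catalog."""

    dataset_id: str
    values: pd.DataFrame  # index = gene_id, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise FormatError(
                f"dataset {self.dataset_id}: need >= 3 samples for correlation, "
                f"got {self.values.shape[1]}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(
                f"dataset {self.dataset_id}: duplicate gene rows {list(dups)[:5]}")


@dataclass
class GenomeTable:
    """Gene coordinates for one genome; 1-based inclusive start/end."""

    genome_id: str
    genes: pd.DataFrame  # columns: gene_id, replicon, start, end, strand

    REQUIRED = ("gene_id", "replicon", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.genes.columns)
        if missing:
            raise FormatError(f"genome {self.genome_id}: missing columns {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            raise FormatError(f"genome {self.genome_id}: duplicate gene ids")
        if (self.genes["start"] > self.genes["end"]).any():
            raise FormatError(f"genome {self.genome_id}: start > end")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise FormatError(f"genome {self.genome_id}: strand must be +/-")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

#: The PPI network container: a simple undirected :class:`networkx.Graph`
#: with per-edge ``provenance`` (subset of {"GSP", "predicted"}) and
#: ``posterior_odds`` where predicted.
Network = nx.Graph

def merge_networks(gsp: PairSet, predicted: PairSet,
                   posterior_odds: Mapping[Pair, float] | None = None) -> nx.Graph:
    """Union the known and predicted pair sets into one simple undirected network.

    Edges present in both carry provenance ``{"GSP", "predicted"}``; predicted
    edges carry their posterior odds when provided. Idempotent: merging the
    same sets twice yields the same network.
    """
    g = nx.Graph()
    for pair in sorted(gsp.pairs):
        g.add_edge(pair.a, pair.b, provenance={"GSP"})
    for pair in sorted(predicted.pairs):
        if g.has_edge(pair.a, pair.b):
            g.edges[pair.a, pair.b]["provenance"].add("predicted")
        else:
            g.add_edge(pair.a, pair.b, provenance={"predicted"})
        if posterior_odds is not None and pair in posterior_odds:
            g.edges[pair.a, pair.b]["posterior_odds"] = float(posterior_odds[pair])
    return g


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _iter_rows(path, n_cols: int | None = None):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if n_cols is not None and len(fields) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}")
            yield lineno, fields


def read_pair_list(path, label: str = "predicted") -> PairSet:
    """Read a two-column pair list into a deduplicated canonical :class:`PairSet`.

    Self-pair rows are dropped with a warning; malformed rows raise with the
    line number.
    """
    pairs: set[Pair] = set()
    raw_rows = 0
    self_pairs = 0
    for lineno, (a, b) in _iter_rows(path, n_cols=2):
        raw_rows += 1
        if a == b:
            self_pairs += 1
            continue
        pairs.add(canonical_pair(a, b))
    if self_pairs:
        warnings.warn(f"{path}: dropped {self_pairs} self-pair rows of {raw_rows}")
    return PairSet(pairs=pairs, label=label)


def write_pair_list(ps: PairSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pair list\tlabel={ps.label}\n")
        for pair in ps.sorted():
            fh.write(f"{pair.a}\t{pair.b}\n")


def read_annotations(path) -> AnnotationTable:
    """Read a two-column (protein_id, term_id) annotation table; duplicates collapse."""
    assign: dict[str, set[str]] = {}
    for _, (pid, term) in _iter_rows(path, n_cols=2):
        assign.setdefault(pid, set()).add(term)
    return AnnotationTable(assignments={p: frozenset(ts) for p, ts in assign.items()})


def write_annotations(annot: AnnotationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tterm_id\n")
        for pid in sorted(annot.assignments):
            for term in sorted(annot.assignments[pid]):
                fh.write(f"{pid}\t{term}\n")


def read_catalog(path) -> ProteinCatalog:
    """Read protein catalog TSV: protein_id, is_annotated(0/1), localization
    (comma-separated GO CC ids or '-'), mobility_flag(0/1)."""
    is_ann: dict[str, bool] = {}
    loc: dict[str, frozenset[str]] = {}
    mob: dict[str, bool] = {}
    for lineno, fields in _iter_rows(path, n_cols=4):
        pid, ann, locs, mobile = fields
        if pid in is_ann:
            raise FormatError(f"{path}:{lineno}: duplicate protein {pid}")
        is_ann[pid] = ann == "1"
        loc[pid] = frozenset() if locs == "-" else frozenset(locs.split(","))
        mob[pid] = mobile == "1"
    return ProteinCatalog(is_annotated=is_ann, localization_terms=loc,
                          mobility_flag=mob)


def write_catalog(cat: ProteinCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tis_annotated\tlocalization\tmobility_flag\n")
        for pid in cat.protein_ids:
            locs = ",".join(sorted(cat.localization_terms[pid])) or "-"
            fh.write(f"{pid}\t{int(cat.is_annotated[pid])}\t{locs}\t"
                     f"{int(cat.mobility_flag[pid])}\n")


def read_expression(path, dataset_id: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV: header row of sample ids, first column gene id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene rows")
    df = df.astype(float)
    name = dataset_id if dataset_id is not None else _stem(path)
    return ExpressionMatrix(dataset_id=name, values=df)


def write_expression(mat: ExpressionMatrix, path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="gene_id",
                      float_format="%.6g")


def read_genome_table(path) -> list[GenomeTable]:
    """Read genome TSV (genome_id, gene_id, replicon, start, end, strand) into
    one :class:`GenomeTable` per genome_id."""
    rows = []
    for lineno, fields in _iter_rows(path, n_cols=6):
        gid, gene, repl, start, end, strand = fields
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        rows.append((gid, gene, repl, start_i, end_i, strand))
    df = pd.DataFrame(rows, columns=["genome_id", "gene_id", "replicon",
                                     "start", "end", "strand"])
    out = []
    for gid in sorted(df["genome_id"].unique()):
        sub = df[df["genome_id"] == gid].drop(columns="genome_id")
        out.append(GenomeTable(genome_id=gid, genes=sub.reset_index(drop=True)))
    return out


def write_genome_tables(genomes: Iterable[GenomeTable], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# genome_id\tgene_id\treplicon\tstart\tend\tstrand\n")
        for gt in genomes:
            for row in gt.genes.itertuples(index=False):
                fh.write(f"{gt.genome_id}\t{row.gene_id}\t{row.replicon}\t"
                         f"{row.start}\t{row.end}\t{row.strand}\n")


def read_profiles(path) -> pd.DataFrame:
    """Read a gene x genome 0/1 presence/absence profile matrix."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise FormatError(f"{path}: profile values must be 0/1")
    return df.astype(int)


def write_profiles(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_network(g: nx.Graph, sif_path, attrs_path=None) -> None:
    """Write a network as SIF (``a<TAB>pp<TAB>b``) plus an optional TSV sidecar
    with posterior odds and provenance, in canonical pair order."""
    edges = sorted(Pair(u, v) for u, v in g.edges)
    with open(sif_path, "w", encoding="utf-8") as fh:
        for pair in edges:
            fh.write(f"{pair.a}\tpp\t{pair.b}\n")
    if attrs_path is not None:
        with open(attrs_path, "w", encoding="utf-8") as fh:
            fh.write("# a\tb\tprovenance\tposterior_odds\n")
            for pair in edges:
                data = g.edges[pair.a, pair.b]
                prov = ",".join(sorted(data.get("provenance", {"predicted"})))
                odds = data.get("posterior_odds")
                odds_s = "-" if odds is None else f"{odds:.6g}"
                fh.write(f"{pair.a}\t{pair.b}\t{prov}\t{odds_s}\n")


def read_network(sif_path, attrs_path=None) -> nx.Graph:
    g = nx.Graph()
    for lineno, fields in _iter_rows(sif_path):
        if len(fields) != 3 or fields[1] != "pp":
            raise FormatError(f"{sif_path}:{lineno}: expected 'a<TAB>pp<TAB>b'")
        a, _, b = fields
        pair = canonical_pair(a, b)
        g.add_edge(pair.a, pair.b, provenance={"predicted"})
    if attrs_path is not None:
        for _, (a, b, prov, odds) in _iter_rows(attrs_path, n_cols=4):
            pair = canonical_pair(a, b)
            data = g.edges[pair.a, pair.b]
            data["provenance"] = set(prov.split(","))
            if odds != "-":
                data["posterior_odds"] = float(odds)
    return g


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]
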