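"""GO ontology parsing, term transfer to contigs, pedigree tracing and
tissue-unique term discovery.

Every GO term belongs to one namespace (biological_process, molecular_function
or cellular_component) whose apex term is its root; following only ``is_a``
edges always reaches the term's own namespace root, while ``part_of`` edges
can additionally carry a term into another namespace.  A term's "pedigree" is
the set of all simple paths from the term to a root under a chosen edge
semantics.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
ROOT_IDS = {"biological_process": "GO:0008150",
            "molecular_function": "GO:0003674",
            "cellular_component": "GO:0005575"}
DEFAULT_PATH_CAP = 10_000


@dataclass
class GoGraph:
    """Terms plus separate is_a / part_of parent adjacency."""

    terms: dict[str, dict]           # id -> {name, namespace}
    is_a: dict[str, list[str]]       # child -> parents
    part_of: dict[str, list[str]]
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def parents(self, term: str, semantics: str) -> list[str]:
        if semantics == "is_a":
            return self.is_a.get(term, [])
        if semantics == "is_a+part_of":
            return self.is_a.get(term, []) + self.part_of.get(term, [])
        raise ValueError("semantics must be 'is_a' or 'is_a+part_of'")

    def resolve(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms
                if not self.is_a.get(t) and t not in self.obsolete}


@dataclass
class Pedigree:
    term: str
    semantics: str
    paths: list[list[str]]          # each ends at a root term
    reachable_roots: set[str]
    top_level_ancestors: set[str]   # immediate children of roots on any path
    truncated: bool = False         # path cap reached


def parse_obo(source) -> GoGraph:
    """Parse OBO 1.2 text (string, path or handle) into a :class:`GoGraph`.

    Obsolete terms are recorded but carry no edges; alt_ids map to their
    primary id; a term stanza without a namespace is an error naming the term.
    Cycles over is_a+part_of are rejected outright.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    graph = obonet.read_obo(_io.StringIO(text))
    terms: dict[str, dict] = {}
    is_a: dict[str, list[str]] = {}
    part_of: dict[str, list[str]] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            raise ValueError(f"term {node} has no namespace")
        terms[node] = {"name": data.get("name", ""), "namespace": ns}
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            is_a.setdefault(child, []).append(parent)
        elif key == "part_of":
            part_of.setdefault(child, []).append(parent)
    # obonet drops obsolete stanzas; recover them from the raw text so they
    # stay addressable (but never traversable)
    obsolete = set()
    for stanza in re.split(r"\n\[", text):
        if "is_obsolete: true" in stanza:
            m = re.search(r"^id: (\S+)", stanza, flags=re.M)
            if m:
                tid = m.group(1)
                obsolete.add(tid)
                if tid not in terms:
                    name = re.search(r"^name: (.*)$", stanza, flags=re.M)
                    ns = re.search(r"^namespace: (\S+)", stanza, flags=re.M)
                    terms[tid] = {"name": name.group(1) if name else "",
                                  "namespace": ns.group(1) if ns else ""}
    combined = nx.DiGraph()
    combined.add_nodes_from(terms)
    for c, ps in is_a.items():
        combined.add_edges_from((c, p) for p in ps)
    for c, ps in part_of.items():
        combined.add_edges_from((c, p) for p in ps)
    if not nx.is_directed_acyclic_graph(combined):
        cycle = nx.find_cycle(combined)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return GoGraph(terms=terms, is_a=is_a, part_of=part_of,
                   obsolete=obsolete, alt_ids=alt_ids)


def pedigree(term: str, graph: GoGraph, semantics: str = "is_a",
             path_cap: int = DEFAULT_PATH_CAP) -> Pedigree:
    """All simple ancestor paths from ``term`` to a root.

    Roots are terms with no is_a parents (the three namespace apexes).  The
    enumeration is capped at ``path_cap`` paths with an explicit truncation
    flag, since deep DAGs can hold combinatorially many paths.
    """
    term = graph.resolve(term)
    if term in graph.obsolete:
        raise ValueError(f"term {term} is obsolete")
    if term not in graph.terms:
        raise KeyError(f"term {term} not in ontology")
    roots = graph.roots
    paths: list[list[str]] = []
    truncated = False

    stack: list[tuple[str, list[str]]] = [(term, [term])]
    while stack:
        node, path = stack.pop()
        if len(paths) >= path_cap:
            truncated = True
            break
        parents = [p for p in graph.parents(node, semantics)
                   if p not in graph.obsolete and p not in path]
        if node in roots:
            paths.append(path)
            # a root may itself have part_of parents in pathological files;
            # a path ends as soon as a root is reached
            continue
        if not parents:
            continue  # dead end that is not a root (e.g. pruned obsolete)
        for p in parents:
            stack.append((p, path + [p]))
    reachable = {p[-1] for p in paths}
    top_level = {p[-2] for p in paths if len(p) >= 2}
    return Pedigree(term=term, semantics=semantics, paths=paths,
                    reachable_roots=reachable, top_level_ancestors=top_level,
                    truncated=truncated)


def transfer_go(best_hits: dict[str, str], gene_go: dict[str, set[str]]
                ) -> tuple[dict[str, set[str]], float]:
    """Contig -> GO set via its best-hit gene; returns the annotated fraction.

    Contigs whose hit gene has no GO terms receive the empty set and count
    against the coverage statistic; several contigs may inherit from the same
    gene.
    """
    contig_go = {c: set(gene_go.get(g, set())) for c, g in best_hits.items()}
    if not contig_go:
        return contig_go, float("nan")
    annotated = sum(1 for s in contig_go.values() if s)
    return contig_go, annotated / len(contig_go)


def gene_go_from_frame(frame: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, go in zip(frame["gene_id"], frame["go_id"]):
        out.setdefault(gene, set()).add(go)
    return out


def tissue_unique_terms(contig_go: dict[str, set[str]],
                        tissue_specific_sets: dict[str, set[str]],
                        contig_tissues: dict[str, set[str]],
                        contig_tau: dict[str, float] | None = None
                        ) -> dict[str, dict[str, float | None]]:
    """Per-tissue GO terms attached only to that tissue's contigs.

    A term is unique to tissue t when it is attached to at least one
    tissue-specific(t) contig and to no contig expressed in any other tissue.
    The value stored per term is the maximum tau over its contigs (None when
    tau is unavailable).
    """
    term_tissues: dict[str, set[str]] = {}
    term_tau: dict[str, float | None] = {}
    for contig, terms in contig_go.items():
        tissues = contig_tissues.get(contig, set())
        for t in terms:
            term_tissues.setdefault(t, set()).update(tissues)
            tau = (contig_tau or {}).get(contig)
            if tau is not None:
                prev = term_tau.get(t)
                term_tau[t] = tau if prev is None else max(prev, tau)
            else:
                term_tau.setdefault(t, None)
    out: dict[str, dict[str, float | None]] = {t: {} for t in tissue_specific_sets}
    for tissue, contigs in tissue_specific_sets.items():
        for contig in contigs:
            for term in contig_go.get(contig, set()):
                if term_tissues.get(term, set()) <= {tissue}:
                    out[tissue][term] = term_tau.get(term)
    return out


def domain_summary(contig_go: dict[str, set[str]], graph: GoGraph) -> pd.DataFrame:
    """Per-namespace term-assignment counts across contigs."""
    rows = []
    for contig, terms in contig_go.items():
        counts = {ns: 0 for ns in NAMESPACES}
        for t in terms:
            t = graph.resolve(t)
            if t in graph.terms:
                counts[graph.terms[t]["namespace"]] += 1
        rows.append({"contig_id": contig, **counts,
                     "total_terms": sum(counts.values())})
    return pd.DataFrame(rows)
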