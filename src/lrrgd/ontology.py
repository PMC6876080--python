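"""Ontology DAGs, annotation corpora, information content, and MICA.

An ontology (Disease Ontology, Gene Ontology, or any OBO 1.2 file) is read
into an :class:`OntologyDAG`: a directed acyclic graph whose edges run from a
term to its parents.  Annotations attach entities (genes / proteins) to
terms; after up-propagating annotations to every ancestor, the information
content of a term is

    IC(t) = -ln( count(t) / N )

where ``count(t)`` is the number of distinct entities annotated at or below
``t`` and ``N`` the number of distinct annotated entities overall.  Roots
have IC 0 by definition.  The most informative common ancestor (MICA) of two
terms is the shared ancestor maximising IC; it is the core quantity of the
Resnik and Lin similarity measures.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

#: relations traversed when walking from a term to its ancestors.  Other OBO
#: relations (regulates, develops_from, ...) are preserved on the term but do
#: not contribute to ancestry, matching common GO practice.
ANCESTRY_RELATIONS = frozenset({"is_a", "part_of"})


class OboParseError(ValueError):
    """Raised for malformed OBO input; the message names the offending line."""


class OntologyStructureError(ValueError):
    """Raised when the parsed ontology is not a DAG."""


@dataclass
class OntologyTerm:
    term_id: str
    name: str = ""
    namespace: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)  # (parent_id, relation)
    obsolete: bool = False


class OntologyDAG:
    """Directed acyclic graph of ontology terms.

    Edges in :attr:`graph` run child -> parent and carry a ``relation``
    attribute; only :data:`ANCESTRY_RELATIONS` become edges.  Acyclicity is
    checked at construction.
    """

    def __init__(self, terms: dict[str, OntologyTerm]):
        self.terms = terms
        self.graph = nx.DiGraph()
        for t in terms.values():
            self.graph.add_node(t.term_id)
        for t in terms.values():
            for pid, rel in t.parents:
                if rel in ANCESTRY_RELATIONS and pid in terms:
                    self.graph.add_edge(t.term_id, pid, relation=rel)
        if not nx.is_directed_acyclic_graph(self.graph):
            member = nx.find_cycle(self.graph)[0][0]
            raise OntologyStructureError(
                f"ontology contains a cycle through term {member!r}"
            )
        self.roots: list[str] = sorted(
            n for n in self.graph.nodes if self.graph.out_degree(n) == 0
        )
        self._root_set = frozenset(self.roots)
        self._closure: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise KeyError(f"unknown ontology term {term_id!r}")

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure over parent links (includes the term)."""
        self._require(term_id)
        cached = self._closure.get(term_id)
        if cached is None:
            cached = frozenset({term_id}) | frozenset(
                nx.descendants(self.graph, term_id)
            )
            self._closure[term_id] = cached
        return cached

    def children_in(self, term_id: str, subset: frozenset[str]):
        """Yield (child_id, relation) for children of ``term_id`` within ``subset``."""
        for child, _, data in self.graph.in_edges(term_id, data=True):
            if child in subset:
                yield child, data["relation"]

    def is_root(self, term_id: str) -> bool:
        return term_id in self._root_set


def _finish_term(collected: dict | None, terms: dict[str, OntologyTerm], lineno: int):
    if collected is None:
        return
    tid = collected.get("id")
    if tid is None:
        raise OboParseError(f"line {lineno}: [Term] stanza without an id")
    if tid in terms:
        raise OboParseError(f"line {lineno}: duplicate term id {tid!r}")
    obsolete = collected.get("obsolete", False)
    terms[tid] = OntologyTerm(
        term_id=tid,
        name=collected.get("name", ""),
        namespace=collected.get("namespace", ""),
        parents=[] if obsolete else collected.get("parents", []),
        obsolete=obsolete,
    )


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDAG`.

    Obsolete terms are dropped (their parent links are not migrated), parent
    links to unknown terms are pruned, and acyclicity is verified.  Supported
    stanza fields: id, name, namespace, is_a, relationship, is_obsolete.
    """
    terms: dict[str, OntologyTerm] = {}
    collected: dict | None = None
    in_term = False
    lineno = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(
                        f"line {lineno}: malformed stanza header {line!r}"
                    )
                if in_term:
                    _finish_term(collected, terms, lineno)
                in_term = line == "[Term]"
                collected = {"parents": []} if in_term else None
                continue
            if ":" not in line:
                raise OboParseError(
                    f"line {lineno}: expected 'tag: value', got {line!r}"
                )
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.split("!", 1)[0].strip()
            if not in_term:
                continue
            assert collected is not None
            if tag == "id":
                if not value:
                    raise OboParseError(f"line {lineno}: empty term id")
                collected["id"] = value
            elif tag == "name":
                collected["name"] = value
            elif tag == "namespace":
                collected["namespace"] = value
            elif tag == "is_a":
                if not value:
                    raise OboParseError(f"line {lineno}: empty is_a target")
                collected["parents"].append((value, "is_a"))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise OboParseError(
                        f"line {lineno}: malformed relationship {value!r}"
                    )
                collected["parents"].append((parts[1], parts[0]))
            elif tag == "is_obsolete":
                collected["obsolete"] = value.lower() == "true"
    if in_term:
        _finish_term(collected, terms, lineno)

    live = {tid: t for tid, t in terms.items() if not t.obsolete}
    for t in live.values():
        t.parents = [(p, r) for (p, r) in t.parents if p in live]
    return OntologyDAG(live)


class AnnotationCorpus:
    """Deduplicated (term, entity) annotation pairs against a companion DAG."""

    def __init__(self, pairs: Iterable[tuple[str, str]], dag: OntologyDAG):
        self.pairs: frozenset[tuple[str, str]] = frozenset(pairs)
        for term_id, _ in self.pairs:
            if term_id not in dag:
                raise KeyError(
                    f"annotation references unknown term {term_id!r}"
                )
        self._by_entity: dict[str, set[str]] = defaultdict(set)
        self._by_term: dict[str, set[str]] = defaultdict(set)
        for term_id, entity_id in self.pairs:
            self._by_entity[entity_id].add(term_id)
            self._by_term[term_id].add(entity_id)
        self.entities: frozenset[str] = frozenset(self._by_entity)

    def __len__(self) -> int:
        return len(self.pairs)

    def terms_for(self, entity_id: str) -> frozenset[str]:
        return frozenset(self._by_entity.get(entity_id, ()))

    def entities_for(self, term_id: str) -> frozenset[str]:
        return frozenset(self._by_term.get(term_id, ()))


def load_annotations(path: str | Path, dag: OntologyDAG) -> AnnotationCorpus:
    """Read a GAF-like TSV (entity_id <TAB> term_id; '!' starts a comment)."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise OboParseError(
                    f"line {lineno}: expected at least 2 tab-separated columns"
                )
            entity_id, term_id = fields[0].strip(), fields[1].strip()
            pairs.append((term_id, entity_id))
    return AnnotationCorpus(pairs, dag)


@dataclass(eq=False)
class ICTable:
    """Per-term information content after annotation up-propagation.

    Terms with zero propagated count are absent; :meth:`get` treats them as
    IC 0 (they carry no information).
    """

    ic: dict[str, float]
    ic_max: float
    total_annotations: int

    def get(self, term_id: str) -> float:
        return self.ic.get(term_id, 0.0)


def information_content(dag: OntologyDAG, annotations: AnnotationCorpus) -> ICTable:
    """Up-propagate annotations and derive IC(t) = -ln(count(t)/N).

    Each entity is counted at most once per term regardless of how many of
    its annotated terms share an ancestor.  Root IC is pinned to 0.
    """
    if len(annotations) == 0:
        raise ValueError("annotation corpus is empty")
    propagated: dict[str, set[str]] = defaultdict(set)
    for term_id, entity_id in annotations.pairs:
        for anc in dag.ancestors(term_id):
            propagated[anc].add(entity_id)
    n_total = len(annotations.entities)
    ic: dict[str, float] = {}
    for term_id, entities in propagated.items():
        if dag.is_root(term_id):
            ic[term_id] = 0.0
        else:
            ic[term_id] = -math.log(len(entities) / n_total)
    ic_max = max(ic.values(), default=0.0)
    return ICTable(ic=ic, ic_max=ic_max, total_annotations=n_total)


def mica(
    dag: OntologyDAG, ic: ICTable, t1: str, t2: str
) -> tuple[str, float]:
    """Most informative common ancestor of two terms.

    Ancestry is reflexive, so ``mica(t, t) = (t, IC(t))``.  Ties on IC break
    to the lexicographically smallest term id; when no common ancestor
    carries positive IC the nearest common root is returned with IC 0.
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    if not common:
        raise ValueError(f"terms {t1!r} and {t2!r} share no ancestor")
    best_ic = max(ic.get(t) for t in common)
    if best_ic > 0.0:
        best = min(t for t in common if ic.get(t) == best_ic)
        return best, best_ic
    common_roots = sorted(t for t in common if dag.is_root(t))
    if common_roots:
        return common_roots[0], 0.0
    return min(common), 0.0
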