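"""Shared fixtures: tiny hand-built ontologies, the default synthetic
fixture bundle, and one full pipeline run reused by several test modules."""

from __future__ import annotations

import numpy as np
import pytest

from lrrgd import ontology as onto
from lrrgd import synthetic
from lrrgd.cli import RunConfig, run_pipeline

CHAIN_OBO = """format-version: 1.2

[Term]
id: T:0
name: root

[Term]
id: T:A
name: a
is_a: T:0

[Term]
id: T:B
name: b
is_a: T:A
"""

# root with child A; A has children B and C.  Annotated entities: e1 -> B,
# e2 -> C, e3 -> root, e4 -> root, giving propagated counts root=4, A=2,
# B=C=1, hence IC(A)=ln 2, IC(B)=IC(C)=ln 4 = ic_max.
IC_FIXTURE_OBO = """format-version: 1.2

[Term]
id: T:0
name: root

[Term]
id: T:A
name: a
is_a: T:0

[Term]
id: T:B
name: b
is_a: T:A

[Term]
id: T:C
name: c
is_a: T:A
"""

IC_FIXTURE_PAIRS = [("T:B", "e1"), ("T:C", "e2"), ("T:0", "e3"), ("T:0", "e4")]


def dag_from_text(tmp_path, text, name="test.obo"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return onto.parse_obo(p)


@pytest.fixture
def chain_dag(tmp_path):
    return dag_from_text(tmp_path, CHAIN_OBO)


@pytest.fixture
def ic_fixture(tmp_path):
    dag = dag_from_text(tmp_path, IC_FIXTURE_OBO)
    corpus = onto.AnnotationCorpus(IC_FIXTURE_PAIRS, dag)
    return dag, corpus, onto.information_content(dag, corpus)


def random_annotated_dag(seed: int, n_terms: int = 50, n_entities: int = 40):
    """A random DAG plus annotations, via the synthetic generator."""
    spec = synthetic.FixtureSpec(n_terms=n_terms, rng_seed=seed)
    rng = np.random.default_rng(seed)
    text = synthetic.generate_ontology(spec, rng, prefix="T", namespace="test")
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "r.obo"
        p.write_text(text, encoding="utf-8")
        dag = onto.parse_obo(p)
    terms = sorted(dag.terms)
    pairs = [
        (terms[int(rng.integers(0, len(terms)))], f"e{i}") for i in range(n_entities)
    ]
    corpus = onto.AnnotationCorpus(pairs, dag)
    return dag, corpus, onto.information_content(dag, corpus)


# ---------------------------------------------------------------------------
# independent brute-force oracles (never reuse the library's graph machinery)


def bfs_closure(dag: onto.OntologyDAG, term_id: str) -> frozenset:
    """Reflexive ancestor closure by explicit BFS over parent links."""
    seen = {term_id}
    frontier = [term_id]
    while frontier:
        nxt = []
        for t in frontier:
            for pid, rel in dag.terms[t].parents:
                if rel in onto.ANCESTRY_RELATIONS and pid in dag.terms and pid not in seen:
                    seen.add(pid)
                    nxt.append(pid)
        frontier = nxt
    return frozenset(seen)


def brute_mica(dag, ic, t1, t2):
    """Exhaustive enumeration of common ancestors maximising IC."""
    common = bfs_closure(dag, t1) & bfs_closure(dag, t2)
    best_ic = max(ic.get(t) for t in common)
    if best_ic > 0:
        return min(t for t in common if ic.get(t) == best_ic), best_ic
    roots = sorted(t for t in common if dag.is_root(t))
    return (roots[0] if roots else min(common)), 0.0


# ---------------------------------------------------------------------------
# default synthetic fixture and one full pipeline run (session-scoped: the
# same frozen run backs recovery, conservation and reporting tests)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    return synthetic.end_to_end_fixture(
        rng_seed=42, out_dir=tmp_path_factory.mktemp("fixture")
    )


@pytest.fixture(scope="session")
def pipeline_out(bundle, tmp_path_factory):
    out_dir = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(
        do_obo=bundle.do_obo,
        go_obo=bundle.go_obo,
        go_annotations=bundle.go_annotations,
        do_annotations=bundle.do_annotations,
        funnet=bundle.funnet,
        associations=bundle.associations,
        target=bundle.target_id,
        seed_proteins=bundle.seed_proteins_file,
        rng_seed=42,
        out_dir=out_dir,
    )
    return run_pipeline(cfg)
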