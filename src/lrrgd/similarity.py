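"""Disease-pair similarity: five ontology-based measures and their sum.

A disease is compared through its :class:`DiseaseProfile` (its own disease-
ontology term(s), its gene/protein set, and the GO terms annotating those
genes).  Five measures are computed per pair:

* **Resnik** — IC of the MICA, rescaled to [0, 4] by ``4 * IC / ic_max``.
* **Lin** — ``2 * IC(MICA) / (IC(t1) + IC(t2))`` in [0, 1].
* **Wang** — decayed semantic-contribution values summed over all shared
  ancestors, normalised by each term's total contribution; in (0, 1].
* **PSB** (surrogate) — best-match average of ``IC(MICA)/ic_max`` over the
  diseases' biological-process GO terms.
* **SemFunSim** (surrogate) — best-match average over gene sets, scoring a
  gene pair 1 for identity and otherwise by a functional-association weight.

PSB and SemFunSim are deliberate surrogates: the published algorithms they
stand in for are not re-implemented here, only their signature and [0, 1]
range are preserved (see docs/methods.md).

Term-pair measures are lifted to disease level by the best-match average
(:func:`bma`).  The five scores are summed into a total with theoretical
maximum 8 (four unit-range measures plus Resnik's 4), and totals are
normalised by 8 into regression labels.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .ontology import AnnotationCorpus, ICTable, OntologyDAG, mica

logger = logging.getLogger(__name__)

#: theoretical maximum of the combined (summed) similarity: 1+1+1+1+4.
MAX_COMBINED_SIMILARITY = 8.0

#: semantic-contribution decay per relation for Wang's measure.
DEFAULT_WANG_DECAY: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

BP_NAMESPACE = "biological_process"


@dataclass(frozen=True)
class DiseaseProfile:
    """The unit of comparison: a disease's genes, GO terms and DO term(s)."""

    disease_id: str
    genes: frozenset[str]
    terms: frozenset[str]  # GO terms annotating the disease's genes
    do_terms: frozenset[str]  # the disease's own DO term(s); singleton by default


def make_profile(
    disease_id: str,
    genes: Iterable[str],
    go_corpus: AnnotationCorpus | None = None,
    do_terms: Iterable[str] | None = None,
) -> DiseaseProfile:
    """Build a profile, deriving GO terms from the genes' annotations."""
    gene_set = frozenset(genes)
    terms: set[str] = set()
    if go_corpus is not None:
        for g in gene_set:
            terms |= go_corpus.terms_for(g)
    return DiseaseProfile(
        disease_id=disease_id,
        genes=gene_set,
        terms=frozenset(terms),
        do_terms=frozenset(do_terms) if do_terms is not None else frozenset({disease_id}),
    )


@dataclass(frozen=True)
class MethodScores:
    """The five per-method disease-pair scores and their sum."""

    semfunsim: float
    wang: float
    lin: float
    psb: float
    resnik: float
    total: float = field(default=0.0)

    def __post_init__(self):
        for name in ("semfunsim", "wang", "lin", "psb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} score {v} outside [0, 1]")
        if not 0.0 <= self.resnik <= 4.0 + 1e-12:
            raise ValueError(f"resnik score {self.resnik} outside [0, 4]")

    @classmethod
    def of(cls, semfunsim, wang, lin, psb, resnik) -> "MethodScores":
        total = semfunsim + wang + lin + psb + resnik
        return cls(semfunsim, wang, lin, psb, resnik, total)


def sim_resnik(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> float:
    """Resnik similarity rescaled to [0, 4]: ``4 * IC(MICA) / ic_max``."""
    if ic.ic_max == 0.0:
        return 0.0
    _, mica_ic = mica(dag, ic, t1, t2)
    return 4.0 * mica_ic / ic.ic_max


def sim_lin(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> float:
    """Lin similarity ``2 * IC(MICA) / (IC(t1) + IC(t2))``; 0 for zero denominator."""
    denom = ic.get(t1) + ic.get(t2)
    if denom == 0.0:
        return 0.0
    _, mica_ic = mica(dag, ic, t1, t2)
    return 2.0 * mica_ic / denom


def _svalues(dag: OntologyDAG, term: str, decay: Mapping[str, float]) -> dict[str, float]:
    """Wang semantic-contribution values of ``term``'s ancestors toward it.

    S_A(A) = 1; for an ancestor t, S_A(t) is the best decayed contribution
    over children of t lying on a path to A.
    """
    closure = dag.ancestors(term)
    svals: dict[str, float] = {term: 1.0}

    def s(t: str) -> float:
        v = svals.get(t)
        if v is not None:
            return v
        best = 0.0
        for child, rel in dag.children_in(t, closure):
            best = max(best, decay[rel] * s(child))
        svals[t] = best
        return best

    for t in closure:
        s(t)
    return svals


def sim_wang(
    dag: OntologyDAG,
    t1: str,
    t2: str,
    decay: Mapping[str, float] | None = None,
) -> float:
    """Wang similarity over all shared ancestors with decayed contributions."""
    if decay is None:
        decay = DEFAULT_WANG_DECAY
    for rel, d in decay.items():
        if not 0.0 < d < 1.0:
            raise ValueError(f"decay weight for {rel!r} must lie in (0, 1), got {d}")
    s1 = _svalues(dag, t1, decay)
    s2 = _svalues(dag, t2, decay)
    shared = set(s1) & set(s2)
    sv1 = sum(s1.values())
    sv2 = sum(s2.values())
    return sum(s1[t] + s2[t] for t in shared) / (sv1 + sv2)


def bma(
    pair_score: Callable[[str, str], float],
    set1: Iterable[str],
    set2: Iterable[str],
) -> float:
    """Best-match average: symmetrised mean of each element's best match."""
    a = sorted(set1)
    b = sorted(set2)
    if not a or not b:
        raise ValueError("bma requires two nonempty sets")
    fwd = statistics.fmean(max(pair_score(x, y) for y in b) for x in a)
    rev = statistics.fmean(max(pair_score(x, y) for x in a) for y in b)
    return 0.5 * (fwd + rev)


def sim_psb(
    p1: DiseaseProfile,
    p2: DiseaseProfile,
    dag_go: OntologyDAG,
    ic_go: ICTable,
    namespace: str = BP_NAMESPACE,
) -> float:
    """Surrogate process-similarity score over biological-process GO terms.

    BMA of ``IC(MICA)/ic_max`` restricted to the BP namespace; 0 (with a
    warning) when either disease has no BP term.
    """
    bp1 = {t for t in p1.terms if dag_go.terms[t].namespace == namespace}
    bp2 = {t for t in p2.terms if dag_go.terms[t].namespace == namespace}
    if not bp1 or not bp2:
        logger.warning(
            "PSB: empty biological-process term set for %s/%s; score 0",
            p1.disease_id,
            p2.disease_id,
        )
        return 0.0
    if ic_go.ic_max == 0.0:
        return 0.0

    def score(a: str, b: str) -> float:
        _, mica_ic = mica(dag_go, ic_go, a, b)
        return mica_ic / ic_go.ic_max

    return bma(score, bp1, bp2)


FunNet = Mapping[frozenset, float]


def load_funnet(path: str | Path) -> dict[frozenset, float]:
    """Read a gene-gene functional-association weight TSV (gene_a, gene_b, weight)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = {"gene_a", "gene_b", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"funnet table missing columns: {sorted(missing)}")
    net: dict[frozenset, float] = {}
    for a, b, w in df.itertuples(index=False):
        w = float(w)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"funnet weight {w} for ({a}, {b}) outside [0, 1]")
        net[frozenset((a, b))] = w
    return net


def sim_semfunsim(
    p1: DiseaseProfile, p2: DiseaseProfile, funnet: FunNet
) -> float:
    """Surrogate semantic/functional score: BMA over gene sets.

    A gene pair scores 1 on identity, otherwise the functional-association
    weight (0 when the pair is absent from the network).
    """
    if not p1.genes or not p2.genes:
        raise ValueError("sim_semfunsim requires nonempty gene sets")

    def score(a: str, b: str) -> float:
        if a == b:
            return 1.0
        w = funnet.get(frozenset((a, b)), 0.0)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"funnet weight {w} outside [0, 1]")
        return w

    return bma(score, p1.genes, p2.genes)


@dataclass(eq=False)
class SimilarityResources:
    """Bundle of ontologies, IC tables and the functional network.

    When a disease-ontology DAG plus IC table are present, Resnik/Lin/Wang
    are computed over the diseases' DO terms (the default route); otherwise
    they fall back to the GO-term profiles of the gene sets.
    """

    dag_go: OntologyDAG
    ic_go: ICTable
    dag_do: OntologyDAG | None = None
    ic_do: ICTable | None = None
    funnet: FunNet = field(default_factory=dict)
    wang_decay: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WANG_DECAY))
    bp_namespace: str = BP_NAMESPACE


def combined_similarity(
    target: DiseaseProfile,
    other: DiseaseProfile,
    resources: SimilarityResources,
) -> MethodScores:
    """All five scores for a disease pair plus their sum.

    Term-level measures are lifted to disease level with :func:`bma`.
    """
    if resources.dag_do is not None and resources.ic_do is not None:
        term_dag, term_ic = resources.dag_do, resources.ic_do
        set1, set2 = target.do_terms, other.do_terms
    else:
        term_dag, term_ic = resources.dag_go, resources.ic_go
        set1, set2 = target.terms, other.terms
    if not set1 or not set2:
        raise ValueError("disease entering similarity has an empty term set")

    resnik = bma(lambda a, b: sim_resnik(term_dag, term_ic, a, b), set1, set2)
    lin = bma(lambda a, b: sim_lin(term_dag, term_ic, a, b), set1, set2)
    wang = bma(
        lambda a, b: sim_wang(term_dag, a, b, resources.wang_decay), set1, set2
    )
    psb = sim_psb(
        target, other, resources.dag_go, resources.ic_go, resources.bp_namespace
    )
    semfunsim = sim_semfunsim(target, other, resources.funnet)
    return MethodScores.of(semfunsim, wang, lin, psb, resnik)


def normalize_similarity(total: float) -> float:
    """Map a combined total onto [0, 1] by dividing by the maximum, 8."""
    if not 0.0 <= total <= MAX_COMBINED_SIMILARITY:
        raise ValueError(f"combined similarity {total} outside [0, 8]")
    return total / MAX_COMBINED_SIMILARITY


def filter_by_threshold(
    scores: Iterable[tuple[str, float]],
    threshold: float = 3.5,
    inclusive: bool = True,
) -> list[str]:
    """Diseases whose combined total passes the similarity threshold.

    Returned sorted by total ascending, ties by disease id.  The default
    cutoff 3.5 retains only the small neighbourhood of closely related
    diseases.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if inclusive:
        kept = [(d, t) for d, t in scores if t >= threshold]
    else:
        kept = [(d, t) for d, t in scores if t > threshold]
    kept.sort(key=lambda dt: (dt[1], dt[0]))
    return [d for d, _ in kept]


SIMILARITY_COLUMNS = [
    "disease_id",
    "semfunsim",
    "wang",
    "lin",
    "psb",
    "resnik",
    "total",
    "normalized",
]


def similarity_frame(records: Mapping[str, MethodScores]) -> pd.DataFrame:
    """Tabulate per-disease scores (full precision) with normalised labels."""
    rows = []
    for disease_id, s in records.items():
        rows.append(
            {
                "disease_id": disease_id,
                "semfunsim": s.semfunsim,
                "wang": s.wang,
                "lin": s.lin,
                "psb": s.psb,
                "resnik": s.resnik,
                "total": s.total,
                "normalized": normalize_similarity(s.total),
            }
        )
    return pd.DataFrame(rows, columns=SIMILARITY_COLUMNS)


def write_similarity_table(path: str | Path, records: Mapping[str, MethodScores]) -> None:
    similarity_frame(records).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_similarity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"disease_id": str})
    missing = set(SIMILARITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"similarity table missing columns: {sorted(missing)}")
    return df
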