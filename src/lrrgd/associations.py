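"""Disease-protein association tables and the binary feature matrix.

The association table is the bipartite relation between diseases and their
curated proteins (what one would extract for human, reviewed entries from a
protein knowledgebase).  After excluding degenerate diseases (no proteins,
or catch-all diseases with thousands of them), each remaining disease
becomes one sample: a binary vector over the union of all proteins, labelled
with its normalised similarity to the target disease.  Heavy cross-disease
protein sharing ("redundancy") is the signal the whole method rests on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseProteinTable:
    """Deduplicated (disease, protein) rows with stable first-seen indices."""

    rows: tuple[tuple[str, str], ...]
    diseases: tuple[str, ...]
    proteins: tuple[str, ...]

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[tuple[str, str]],
        empty_diseases: Iterable[str] = (),
    ) -> "DiseaseProteinTable":
        """Build from raw rows, deduplicating while preserving input order.

        ``empty_diseases`` registers diseases known to have no associations
        (so the exclusion filter can report them).
        """
        seen: set[tuple[str, str]] = set()
        dedup: list[tuple[str, str]] = []
        diseases: dict[str, None] = {}
        proteins: dict[str, None] = {}
        for d in empty_diseases:
            diseases.setdefault(d, None)
        for d, p in rows:
            diseases.setdefault(d, None)
            key = (d, p)
            if key in seen:
                continue
            seen.add(key)
            dedup.append(key)
            proteins.setdefault(p, None)
        return cls(
            rows=tuple(dedup),
            diseases=tuple(diseases),
            proteins=tuple(proteins),
        )

    def proteins_of(self, disease_id: str) -> tuple[str, ...]:
        return tuple(p for d, p in self.rows if d == disease_id)

    def counts(self) -> dict[str, int]:
        """Association count per disease (0 for registered empty diseases)."""
        c = {d: 0 for d in self.diseases}
        for d, _ in self.rows:
            c[d] += 1
        return c


def load_associations(path: str | Path) -> DiseaseProteinTable:
    """Read a TSV with header ``disease_id, protein_accession``.

    A row with an empty protein cell registers the disease without any
    association (it will fall to the exclusion filter).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"disease_id", "protein_accession"} - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("association table is empty")
    rows = []
    empty: list[str] = []
    for d, p in zip(df["disease_id"], df["protein_accession"]):
        d, p = d.strip(), p.strip()
        if not p:
            empty.append(d)
        else:
            rows.append((d, p))
    return DiseaseProteinTable.from_rows(rows, empty_diseases=empty)


def exclude_diseases(
    table: DiseaseProteinTable,
    min_proteins: int = 1,
    max_proteins: int = 2000,
    drop_ids: Sequence[str] = (),
) -> DiseaseProteinTable:
    """Drop diseases with too few or too many associations, plus listed ids.

    The default cap of 2000 removes catch-all diseases (umbrella terms
    related to thousands of proteins) whose rows would swamp the feature
    space; the floor removes diseases with no curated protein at all.
    """
    counts = table.counts()
    dropset = set(drop_ids)
    removed = {
        d
        for d, c in counts.items()
        if c < min_proteins or c > max_proteins or d in dropset
    }
    if removed:
        logger.info("excluding %d disease(s): %s", len(removed), sorted(removed))
    kept_rows = [(d, p) for d, p in table.rows if d not in removed]
    result = DiseaseProteinTable.from_rows(kept_rows)
    if not result.diseases:
        logger.warning("exclusion filter removed every disease")
    return result


@dataclass(frozen=True)
class RedundancyStats:
    """How much of the pooled association list repeats across diseases."""

    total_associations: int
    unique_proteins: int

    def __post_init__(self):
        if self.total_associations < 1:
            raise ValueError("redundancy requires at least one association")
        if not 0 <= self.unique_proteins <= self.total_associations:
            raise ValueError("unique count outside [0, total]")

    @property
    def redundant_pct(self) -> float:
        return 100.0 * (self.total_associations - self.unique_proteins) / self.total_associations

    @property
    def display_pct(self) -> float:
        return round(self.redundant_pct, 1)


def redundancy_stats(
    table: DiseaseProteinTable | None = None,
    total: int | None = None,
    unique: int | None = None,
) -> RedundancyStats:
    """Redundancy from a table or from raw (total, unique) counts."""
    if table is not None:
        return RedundancyStats(len(table.rows), len(table.proteins))
    if total is None or unique is None:
        raise ValueError("provide either a table or both total and unique counts")
    return RedundancyStats(total, unique)


@dataclass(eq=False)
class FeatureMatrix:
    """Binary diseases x proteins matrix with normalised-similarity labels."""

    X: np.ndarray  # shape (n_diseases, n_proteins), dtype int8, entries {0,1}
    y: np.ndarray  # shape (n_diseases,), values in [0, 1]
    disease_index: tuple[str, ...]
    protein_index: tuple[str, ...]

    def row(self, disease_id: str) -> np.ndarray:
        return self.X[self.disease_index.index(disease_id)]


def build_feature_matrix(
    table: DiseaseProteinTable, labels: Mapping[str, float]
) -> FeatureMatrix:
    """Disease-major binary matrix; X[d, p] = 1 iff (d, p) is associated.

    Every disease must carry a label (its normalised similarity to the
    target).  Column order is first-seen protein order, frozen in
    ``protein_index`` so downstream ensembles are deterministic.
    """
    for d in table.diseases:
        if d not in labels:
            raise KeyError(f"disease {d!r} has no similarity label")
    disease_index = table.diseases
    protein_index = table.proteins
    dpos = {d: i for i, d in enumerate(disease_index)}
    ppos = {p: j for j, p in enumerate(protein_index)}
    X = np.zeros((len(disease_index), len(protein_index)), dtype=np.int8)
    for d, p in table.rows:
        X[dpos[d], ppos[p]] = 1
    empty_rows = [d for d in disease_index if X[dpos[d]].sum() == 0]
    if empty_rows:
        logger.warning("diseases with all-zero feature rows: %s", empty_rows)
    y = np.array([float(labels[d]) for d in disease_index])
    if ((y < 0) | (y > 1)).any():
        raise ValueError("labels must lie in [0, 1]")
    return FeatureMatrix(X=X, y=y, disease_index=disease_index, protein_index=protein_index)


def write_feature_matrix(path: str | Path, fm: FeatureMatrix) -> None:
    """Serialise as TSV: disease_id, label, then one column per protein."""
    df = pd.DataFrame(fm.X, columns=list(fm.protein_index))
    df.insert(0, "label", fm.y)
    df.insert(0, "disease_id", list(fm.disease_index))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"disease_id": str})
    if list(df.columns[:2]) != ["disease_id", "label"]:
        raise ValueError("feature matrix file must start with disease_id, label columns")
    proteins = tuple(df.columns[2:])
    X = df[list(proteins)].to_numpy(dtype=np.int8)
    return FeatureMatrix(
        X=X,
        y=df["label"].to_numpy(dtype=float),
        disease_index=tuple(df["disease_id"]),
        protein_index=proteins,
    )
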