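"""Readers and writers for all external artifacts.

File dialect: tab-separated UTF-8; lines starting with ``#`` are
comments.  The association edge list defines the canonical entity
ordering (first occurrence); every similarity matrix read with
``expected_ids`` is permuted to that ordering so all downstream matrices
share one indexing authority.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AssociationMatrix, ScoreMatrix, SimilarityMatrix
from .dag import DiseaseDAG


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending line."""


#: asymmetry beyond this triggers a warning before symmetrization
ASYMMETRY_WARN = 1e-8

_ASSOC_HEADER = ("disease_id", "mirna_id")


def _data_lines(path: str | Path) -> list[tuple[int, list[str]]]:
    """(1-based line number, tab-split fields) for non-comment, non-blank lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line.split("\t")))
    return out


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column (disease_id, mirna_id) edge list into a binary matrix.

    Ids are registered in first-occurrence order; duplicate edges collapse
    to a single 1.  An optional header row naming the two columns is
    skipped.
    """
    rows = _data_lines(path)
    if rows and [f.strip().lower() for f in rows[0][1]] == list(_ASSOC_HEADER):
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: no association records found")
    diseases: dict[str, int] = {}
    mirnas: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    for lineno, fields in rows:
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        d, m = (f.strip() for f in fields)
        if not d or not m:
            raise ParseError(f"{path}:{lineno}: blank identifier")
        pairs.append((diseases.setdefault(d, len(diseases)),
                      mirnas.setdefault(m, len(mirnas))))
    values = np.zeros((len(diseases), len(mirnas)))
    for i, j in pairs:
        values[i, j] = 1.0
    return AssociationMatrix(values, list(diseases), list(mirnas))


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the verified pairs back out as a two-column edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tmirna_id\n")
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.disease_ids[i]}\t{assoc.mirna_ids[j]}\n")


def read_similarity(
    path: str | Path,
    expected_ids: list[str] | None = None,
    view_name: str = "",
) -> SimilarityMatrix:
    """Read a square similarity table with row and column headers.

    The matrix is symmetrized as (M + M')/2, warning if the asymmetry
    exceeds 1e-8.  If ``expected_ids`` is given the rows/columns are
    permuted to that ordering; missing ids are an error (extra ids in
    the file are dropped).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if set(row_ids) != set(col_ids):
        raise ParseError(f"{path}: row and column headers do not match")
    df = df.loc[row_ids, row_ids]
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ParseError(f"{path}: non-finite similarity entries")
    if (values < 0).any():
        raise ParseError(f"{path}: negative similarity entries")
    asym = float(np.abs(values - values.T).max(initial=0.0))
    if asym > ASYMMETRY_WARN:
        warnings.warn(
            f"{path}: similarity matrix asymmetric by {asym:g}; symmetrizing",
            stacklevel=2,
        )
    values = (values + values.T) / 2.0
    sim = SimilarityMatrix(values, row_ids, view_name)
    if expected_ids is not None:
        missing = [i for i in expected_ids if i not in set(row_ids)]
        if missing:
            raise KeyError(f"{path}: ids missing from similarity matrix: {missing}")
        sim = sim.reordered(list(expected_ids))
    return sim


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_dag(term_path: str | Path, edge_path: str | Path) -> DiseaseDAG:
    """Read a term list and a child->parent edge list into a validated DAG."""
    terms: list[str] = []
    for lineno, fields in _data_lines(term_path):
        t = fields[0].strip()
        if not t:
            raise ParseError(f"{term_path}:{lineno}: blank term identifier")
        terms.append(t)
    if not terms:
        raise ParseError(f"{term_path}: no terms found")
    if terms and terms[0].lower() in ("term", "term_id"):
        terms = terms[1:]
    edges: list[tuple[str, str]] = []
    for lineno, fields in _data_lines(edge_path):
        if len(fields) != 2:
            raise ParseError(
                f"{edge_path}:{lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}"
            )
        c, p = (f.strip() for f in fields)
        if (c.lower(), p.lower()) == ("child_id", "parent_id"):
            continue
        edges.append((c, p))
    return DiseaseDAG(terms, edges)


def write_dag(dag: DiseaseDAG, term_path: str | Path, edge_path: str | Path) -> None:
    with open(term_path, "w", encoding="utf-8") as fh:
        fh.write("term_id\n")
        for t in dag.terms:
            fh.write(f"{t}\n")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("child_id\tparent_id\n")
        for c, p in dag.parent_edges:
            fh.write(f"{c}\t{p}\n")


def score_ranking(scores: ScoreMatrix, top_k: int | None = None) -> pd.DataFrame:
    """Per-disease ranking of miRNAs by descending score.

    Ties are broken by miRNA id order (the column ordering of the score
    matrix).  Returns a DataFrame with columns
    (disease_id, mirna_id, score, rank).
    """
    if not np.isfinite(scores.values).all():
        raise ValueError("scores contain non-finite values")
    records = []
    nm = len(scores.mirna_ids)
    for i, d in enumerate(scores.disease_ids):
        row = scores.values[i]
        # stable sort on column index after primary sort on -score
        order = np.lexsort((np.arange(nm), -row))
        if top_k is not None:
            order = order[:top_k]
        for rank, j in enumerate(order, start=1):
            records.append((d, scores.mirna_ids[j], row[j], rank))
    return pd.DataFrame(records, columns=["disease_id", "mirna_id", "score", "rank"])


def write_scores(
    scores: ScoreMatrix, path: str | Path, top_k: int | None = None
) -> None:
    """Write the per-disease ranked score table as TSV."""
    df = score_ranking(scores, top_k=top_k)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(
    path: str | Path,
    disease_ids: list[str] | None = None,
    mirna_ids: list[str] | None = None,
) -> ScoreMatrix:
    """Read a full ranked score table back into a matrix.

    The file must cover every (disease, miRNA) pair (i.e. written without
    ``top_k``).  If id orderings are not supplied, first occurrence in the
    file defines them.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if disease_ids is None:
        disease_ids = list(dict.fromkeys(df["disease_id"].astype(str)))
    if mirna_ids is None:
        mirna_ids = list(dict.fromkeys(df["mirna_id"].astype(str)))
    dpos = {d: i for i, d in enumerate(disease_ids)}
    mpos = {m: j for j, m in enumerate(mirna_ids)}
    values = np.full((len(disease_ids), len(mirna_ids)), np.nan)
    for d, m, s in zip(df["disease_id"].astype(str), df["mirna_id"].astype(str),
                       df["score"].astype(float)):
        values[dpos[d], mpos[m]] = s
    if np.isnan(values).any():
        raise ParseError(f"{path}: score table does not cover all pairs")
    return ScoreMatrix(values, disease_ids, mirna_ids)
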