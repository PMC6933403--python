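"""Readers and writers for the package's plain-text interchange formats.

Formats (all delimited text, tab canonical, comma auto-detected):

* association list — two columns ``mirna_id<TAB>disease_id``, optional
  header, duplicates collapsed;
* dense similarity matrix — header row of ids, first column of row ids;
* disease DAG edge list — three columns
  ``disease_id<TAB>child_term<TAB>parent_term``;
* ranked predictions — four columns
  ``disease_id<TAB>rank<TAB>mirna_id<TAB>score``.

Identifier matching is exact-string after whitespace trimming and
lowercasing; no fuzzy vocabulary reconciliation is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import AssociationMatrix, ScoreMatrix, SimilarityMatrix

__all__ = [
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "read_dags",
    "write_dags",
    "write_scores",
    "DagEdgeList",
]

logger = logging.getLogger(__name__)

#: per-disease edge lists: disease_id -> list of (child_term, parent_term)
DagEdgeList = dict[str, list[tuple[str, str]]]


def _norm_id(raw: str) -> str:
    return raw.strip().lower()


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_associations(
    path: str | Path, *, dialect: str | None = None, sort_labels: bool = False
) -> AssociationMatrix:
    """Read a two-column (miRNA id, disease id) association list.

    Duplicate rows collapse to a single association.  Label order is
    first-appearance order unless ``sort_labels`` is set, in which case
    labels are sorted lexicographically.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"association file {path} is empty")
    delim = dialect or _sniff_delimiter(path)

    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(delim)]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two fields (miRNA, disease), "
                    f"got {line!r}"
                )
            pairs.append((_norm_id(fields[0]), _norm_id(fields[1])))
    # tolerate a single header line such as "mirna_id  disease_id"
    if pairs and pairs[0] in {("mirna", "disease"), ("mirna_id", "disease_id")}:
        pairs = pairs[1:]
    if not pairs:
        raise ValueError(f"association file {path} contains no data rows")

    n_read = len(pairs)
    distinct = list(dict.fromkeys(pairs))
    mirna_ids = list(dict.fromkeys(m for m, _ in distinct))
    disease_ids = list(dict.fromkeys(d for _, d in distinct))
    if sort_labels:
        mirna_ids.sort()
        disease_ids.sort()
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in distinct:
        values[mi[m], di[d]] = 1.0
    logger.info(
        "read %d rows, %d distinct associations, %d miRNAs, %d diseases from %s",
        n_read, len(distinct), len(mirna_ids), len(disease_ids), path,
    )
    return AssociationMatrix(values, mirna_ids, disease_ids)


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the distinct association pairs as canonical two-column TSV."""
    with open(path, "w") as fh:
        for i, j in assoc.known_pairs():
            fh.write(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\n")


def read_similarity(
    path: str | Path,
    expected_ids: Sequence[str] | None = None,
    *,
    role: str = "miRNA_functional",
) -> SimilarityMatrix:
    """Read a dense similarity matrix (header row + first-column labels).

    If ``expected_ids`` is given the matrix is reindexed to that order;
    missing ids raise.  Asymmetry above 1e-8 raises; smaller asymmetry
    is silently averaged away.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, index_col=0)
    df.index = [_norm_id(str(i)) for i in df.index]
    df.columns = [_norm_id(str(c)) for c in df.columns]
    bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if list(df.index) != list(df.columns):
        raise ValueError(f"row and column labels differ in {path}")
    mat = SimilarityMatrix(df.to_numpy(dtype=float), list(df.index), role)
    if expected_ids is not None:
        expected = [_norm_id(str(i)) for i in expected_ids]
        missing = sorted(set(expected) - set(mat.ids))
        if missing:
            raise KeyError(
                f"ids missing from similarity file {path}: {missing[:10]}"
            )
        mat = mat.reindex(expected)
    return mat


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t")


def _check_dag(disease: str, edges: list[tuple[str, str]]) -> None:
    """Validate one disease DAG: acyclic, rooted at the disease term."""
    import networkx as nx

    g = nx.DiGraph(edges)
    if disease not in g:
        raise ValueError(
            f"disease term {disease!r} absent from its own DAG node set"
        )
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
        raise ValueError(f"cycle detected in DAG for disease {disease!r}: {path}")


def read_dags(path: str | Path) -> DagEdgeList:
    """Read a three-column (disease_id, child_term, parent_term) edge list."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    dags: DagEdgeList = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(delim)]
            if len(fields) < 3 or not all(fields[:3]):
                raise ValueError(
                    f"{path}:{lineno}: expected three fields "
                    f"(disease, child, parent), got {line!r}"
                )
            if fields[:3] == ["disease_id", "child_term", "parent_term"]:
                continue
            disease, child, parent = (_norm_id(f) for f in fields[:3])
            dags.setdefault(disease, []).append((child, parent))
    for disease, edges in dags.items():
        _check_dag(disease, edges)
    return dags


def write_dags(dags: DagEdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tchild_term\tparent_term\n")
        for disease, edges in dags.items():
            for child, parent in edges:
                fh.write(f"{disease}\t{child}\t{parent}\n")


def write_scores(
    scores: ScoreMatrix,
    path: str | Path,
    *,
    exclude_known: AssociationMatrix,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Write a ranked candidate table, one block of rows per disease.

    Only candidate pairs — pairs with a 0 in ``exclude_known`` — are
    emitted, sorted per disease by descending score with lexicographic
    miRNA-id tie-break.  Returns the table that was written.
    """
    if (
        scores.disease_ids != [d for d in exclude_known.disease_ids]
        or scores.mirna_ids != [m for m in exclude_known.mirna_ids]
    ):
        raise ValueError("score matrix and exclusion matrix labels differ")
    records = []
    for j, disease in enumerate(scores.disease_ids):
        cand = [
            (scores.mirna_ids[i], scores.values[j, i])
            for i in range(len(scores.mirna_ids))
            if exclude_known.values[i, j] == 0
        ]
        cand.sort(key=lambda t: (-t[1], t[0]))
        if top_k is not None:
            cand = cand[:top_k]
        for rank, (mirna, score) in enumerate(cand, start=1):
            records.append((disease, rank, mirna, score))
    df = pd.DataFrame(records, columns=["disease_id", "rank", "mirna_id", "score"])
    df.to_csv(path, sep="\t", index=False)
    return df
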