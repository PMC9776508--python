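"""Readers/writers for association tables, similarity matrices and disease DAG files.

All on-disk formats are plain text:

* association table — two tab-separated columns ``miRNA<TAB>disease``,
  optional header line;
* similarity matrix — dense TSV/CSV with row and column name headers;
* disease ontology — three tab-separated columns
  ``disease<TAB>child_node<TAB>parent_node``, one edge per line, where the
  record ``d<TAB>d<TAB>-`` declares a root-only DAG for disease ``d``;
* predictions — ``miRNA<TAB>disease<TAB>score`` sorted by score descending.

Entity indexing is 0-based throughout; rows are miRNAs, columns diseases.
Name matching is exact and case-sensitive after whitespace trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EntityCatalog",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseOntology",
    "UnknownEntityError",
    "read_association_table",
    "write_association_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_dag_file",
    "write_dag_file",
    "write_predictions",
]

#: asymmetries up to this size are silently symmetrized by averaging
SYMMETRY_TOL = 1e-6

SIMILARITY_KINDS = ("functional", "semantic", "gip", "integrated")


class UnknownEntityError(KeyError):
    """An entity name is absent from a fixed catalog or ontology."""


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered miRNA and disease name lists with bijective name->index maps."""

    mirna_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    mirna_index: dict[str, int] = field(init=False, repr=False)
    disease_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for axis, names in (("miRNA", self.mirna_names), ("disease", self.disease_names)):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {axis} names in catalog")
        object.__setattr__(self, "mirna_index", {n: i for i, n in enumerate(self.mirna_names)})
        object.__setattr__(self, "disease_index", {n: i for i, n in enumerate(self.disease_names)})

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease matrix A with its entity catalog.

    ``values[i, j] == 1`` iff miRNA i is known to be associated with
    disease j.
    """

    values: np.ndarray
    catalog: EntityCatalog

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.catalog.n_mirnas, self.catalog.n_diseases):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match catalog "
                f"({self.catalog.n_mirnas}, {self.catalog.n_diseases})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    @property
    def n_unknown(self) -> int:
        return self.values.size - self.n_positives


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] keyed by names.

    ``kind`` tags provenance: functional (miRNA functional similarity),
    semantic (disease ontology similarity), gip (Gaussian interaction-profile
    kernel) or integrated.  gip/integrated matrices must have unit diagonal.
    """

    values: np.ndarray
    names: tuple[str, ...]
    kind: str = "functional"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.names = tuple(self.names)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} does not match {n} names")
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance (max |S - S.T| = {asym:g})")
        # small asymmetries (e.g. text round-trip noise) are averaged away
        self.values = (self.values + self.values.T) / 2.0
        if self.values.size and (self.values.min() < -SYMMETRY_TOL or self.values.max() > 1 + SYMMETRY_TOL):
            raise ValueError("similarity entries must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)
        if self.kind in ("gip", "integrated") and n and not np.allclose(np.diag(self.values), 1.0):
            raise ValueError(f"{self.kind} similarity must have unit diagonal")

    @property
    def n(self) -> int:
        return len(self.names)


class DiseaseOntology:
    """Forest of per-disease DAGs with ancestor closures.

    Each disease owns a DAG ``(d, T(d), E(d))`` where ``T(d)`` is the node
    set (the disease plus all its ancestors) and ``E(d)`` the child->parent
    edges.  A registry of DAG memberships supports the frequency-based
    information-content similarity model.
    """

    def __init__(self, edges_per_disease: dict[str, list[tuple[str, str]]]):
        self._edges: dict[str, list[tuple[str, str]]] = {}
        self._nodes: dict[str, frozenset[str]] = {}
        for disease, edges in edges_per_disease.items():
            g = nx.DiGraph()
            g.add_node(disease)
            g.add_edges_from(edges)  # child -> parent direction
            if not nx.is_directed_acyclic_graph(g):
                raise ValueError(f"cycle detected in DAG of disease {disease!r}")
            if disease not in g:
                raise ValueError(f"disease {disease!r} missing from its own DAG")
            closure = frozenset(nx.descendants(g, disease)) | {disease}
            self._edges[disease] = [(c, p) for c, p in edges if c in closure and p in closure]
            self._nodes[disease] = closure
        # node -> number of disease DAGs whose closure contains it
        self._membership: dict[str, int] = {}
        for closure in self._nodes.values():
            for node in closure:
                self._membership[node] = self._membership.get(node, 0) + 1

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def n_diseases(self) -> int:
        return len(self._nodes)

    def __contains__(self, disease: str) -> bool:
        return disease in self._nodes

    def ancestors(self, disease: str) -> frozenset[str]:
        """T(d): the disease's own node plus all its ancestors."""
        try:
            return self._nodes[disease]
        except KeyError:
            raise UnknownEntityError(f"disease {disease!r} has no DAG") from None

    def edges(self, disease: str) -> list[tuple[str, str]]:
        """E(d) as (child, parent) pairs restricted to T(d)."""
        if disease not in self._nodes:
            raise UnknownEntityError(f"disease {disease!r} has no DAG")
        return list(self._edges[disease])

    def children_within(self, disease: str, node: str) -> list[str]:
        """Children of ``node`` inside DAG(d), per E(d)."""
        return [c for c, p in self.edges(disease) if p == node]

    def dag_count(self, node: str) -> int:
        """Number of disease DAGs whose node set contains ``node``."""
        try:
            return self._membership[node]
        except KeyError:
            raise UnknownEntityError(f"node {node!r} appears in no DAG") from None


def _clean_lines(path: str | Path) -> list[list[str]]:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([f.strip() for f in line.split("\t")])
    return rows


def read_association_table(
    path: str | Path, catalog: EntityCatalog | None = None
) -> AssociationMatrix:
    """Read a two-column (miRNA, disease) TSV into a binary matrix.

    Duplicate pairs collapse to a single 1.  With ``catalog=None`` the
    catalog is built from the file (names in order of first appearance);
    otherwise every name must already be in the given catalog.
    """
    rows = _clean_lines(path)
    if rows and rows[0][:2] in (["miRNA", "disease"], ["mirna", "disease"]):
        rows = rows[1:]
    pairs = []
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"malformed association row: {row!r}")
        pairs.append((row[0], row[1]))
    if catalog is None:
        if not pairs:
            raise ValueError(f"empty association table: {path}")
        mirnas = tuple(dict.fromkeys(m for m, _ in pairs))
        diseases = tuple(dict.fromkeys(d for _, d in pairs))
        catalog = EntityCatalog(mirnas, diseases)
    values = np.zeros((catalog.n_mirnas, catalog.n_diseases), dtype=np.int8)
    for m, d in pairs:
        if m not in catalog.mirna_index:
            raise UnknownEntityError(f"miRNA {m!r} not in catalog")
        if d not in catalog.disease_index:
            raise UnknownEntityError(f"disease {d!r} not in catalog")
        values[catalog.mirna_index[m], catalog.disease_index[d]] = 1
    return AssociationMatrix(values, catalog)


def write_association_table(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the known pairs of an association matrix as a 2-column TSV."""
    cat = assoc.catalog
    with open(path, "w") as fh:
        fh.write("miRNA\tdisease\n")
        for i, j in zip(*np.nonzero(assoc.values)):
            fh.write(f"{cat.mirna_names[i]}\t{cat.disease_names[j]}\n")


def read_similarity_matrix(path: str | Path, kind: str = "functional") -> SimilarityMatrix:
    """Read a dense named similarity matrix (TSV or CSV, sniffed by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {df.shape}")
    names = tuple(str(n).strip() for n in df.index)
    col_names = tuple(str(n).strip() for n in df.columns)
    if names != col_names:
        raise ValueError("row and column names of a similarity matrix must agree")
    return SimilarityMatrix(df.to_numpy(dtype=float), names, kind=kind)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a named similarity matrix as TSV at 10 significant digits."""
    df = pd.DataFrame(sim.values, index=list(sim.names), columns=list(sim.names))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_dag_file(path: str | Path) -> DiseaseOntology:
    """Read a 3-column DAG file (disease, child_node, parent_node)."""
    edges: dict[str, list[tuple[str, str]]] = {}
    for row in _clean_lines(path):
        if len(row) != 3:
            raise ValueError(f"malformed DAG row: {row!r}")
        disease, child, parent = row
        edges.setdefault(disease, [])
        if parent != "-":
            edges[disease].append((child, parent))
    if not edges:
        raise ValueError(f"empty DAG file: {path}")
    return DiseaseOntology(edges)


def write_dag_file(ont: DiseaseOntology, path: str | Path) -> None:
    with open(path, "w") as fh:
        for disease in ont.diseases:
            dag_edges = ont.edges(disease)
            if not dag_edges:
                fh.write(f"{disease}\t{disease}\t-\n")
            for child, parent in dag_edges:
                fh.write(f"{disease}\t{child}\t{parent}\n")


def write_predictions(
    rows: list[tuple[str, str, float]], path: str | Path
) -> None:
    """Write (miRNA, disease, score) rows as TSV sorted by score descending."""
    ordered = sorted(rows, key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("miRNA\tdisease\tscore\n")
        for m, d, s in ordered:
            fh.write(f"{m}\t{d}\t{s:.10g}\n")
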