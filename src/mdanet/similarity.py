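"""Similarity networks for miRNAs and diseases.

Disease semantic similarity follows the classic two-model MeSH-DAG scheme:

* model 1 — each ancestor node k of disease d contributes
  ``max(delta * contribution(child))`` with decay factor delta (default 0.5)
  and the disease's own node contributes 1;
* model 2 — each node contributes its information content
  ``-ln(#DAGs containing the node / #diseases)``, so rare ontology terms
  weigh more than ubiquitous ones.

For either model the pairwise similarity is the summed contribution of the
shared DAG nodes, from both sides, divided by the total semantic values; the
final semantic similarity is the arithmetic mean of the two models.

Gaussian interaction-profile (GIP) kernel similarity fills the gaps: a
radial-basis kernel on rows (or columns) of the binary association matrix,
with bandwidth normalized by the mean squared profile norm.  The integrated
similarity picks the primary (functional/semantic) value where one is
available and the GIP value otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import DiseaseOntology, SimilarityMatrix, UnknownEntityError

__all__ = [
    "GipConfig",
    "semantic_contributions",
    "semantic_value",
    "semantic_similarity_pair",
    "information_content",
    "disease_semantic_similarity",
    "gip_kernel",
    "integrate_similarity",
    "default_mask",
    "laplacian_normalize",
]


@dataclass(frozen=True)
class GipConfig:
    """Bandwidth hyperparameter of the GIP kernel (gamma' in the usual notation)."""

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")


def semantic_contributions(
    ont: DiseaseOntology, disease: str, model: str = "model1", delta: float = 0.5
) -> dict[str, float]:
    """Per-node semantic contribution map for one disease's DAG.

    Under model1 the disease's own node contributes 1 and each ancestor the
    delta-decayed maximum over its children within the DAG.  Under model2
    every node contributes its information content, independent of depth.
    """
    nodes = ont.ancestors(disease)
    if model == "model2":
        return {k: information_content(ont, k) for k in nodes}
    if model != "model1":
        raise ValueError(f"unknown semantic model {model!r}")
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    children: dict[str, list[str]] = {k: [] for k in nodes}
    for c, p in ont.edges(disease):
        children[p].append(c)

    contrib: dict[str, float] = {}

    def value(k: str) -> float:
        if k in contrib:
            return contrib[k]
        if k == disease:
            contrib[k] = 1.0
        else:
            contrib[k] = max(delta * value(c) for c in children[k])
        return contrib[k]

    for k in nodes:
        value(k)
    return contrib


def semantic_value(contribs: dict[str, float]) -> float:
    """DV(d): total semantic value, the sum of contributions over T(d)."""
    if not contribs:
        raise ValueError("empty contribution map")
    return float(sum(contribs.values()))


def information_content(ont: DiseaseOntology, node: str) -> float:
    """-ln(fraction of disease DAGs whose node set contains ``node``)."""
    return float(-np.log(ont.dag_count(node) / ont.n_diseases))


def semantic_similarity_pair(
    ont: DiseaseOntology,
    di: str,
    dj: str,
    model: str = "model1",
    delta: float = 0.5,
) -> float:
    """Shared-ancestor similarity between two diseases under one model."""
    ci = semantic_contributions(ont, di, model, delta)
    cj = semantic_contributions(ont, dj, model, delta)
    denom = semantic_value(ci) + semantic_value(cj)
    if denom == 0:
        raise ZeroDivisionError(
            f"degenerate ontology: DV({di}) + DV({dj}) = 0 (all-zero contributions)"
        )
    shared = set(ci) & set(cj)
    num = sum(ci[k] + cj[k] for k in shared)
    return float(num / denom)


def disease_semantic_similarity(
    ont: DiseaseOntology,
    names: list[str] | tuple[str, ...],
    delta: float = 0.5,
) -> SimilarityMatrix:
    """Full disease semantic similarity matrix: mean of model1 and model2.

    Diseases absent from the ontology get a zero row/column except for the
    unit diagonal; downstream the integration mask marks them as lacking
    semantic similarity so the GIP kernel fills in.
    """
    n = len(names)
    out = np.eye(n)
    for a in range(n):
        if names[a] not in ont:
            continue
        for b in range(a + 1, n):
            if names[b] not in ont:
                continue
            s1 = semantic_similarity_pair(ont, names[a], names[b], "model1", delta)
            s2 = semantic_similarity_pair(ont, names[a], names[b], "model2", delta)
            out[a, b] = out[b, a] = (s1 + s2) / 2.0
    return SimilarityMatrix(out, tuple(names), kind="semantic")


def gip_kernel(
    profiles: np.ndarray,
    names: list[str] | tuple[str, ...],
    cfg: GipConfig = GipConfig(),
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile rows.

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2) with
    gamma = gamma' / mean_i ||IP(i)||^2.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    mean_sq_norm = float((profiles**2).sum() / n)
    if mean_sq_norm == 0:
        raise ZeroDivisionError("all profiles are zero: GIP bandwidth undefined")
    gamma = cfg.gamma_prime / mean_sq_norm
    sq_norms = (profiles**2).sum(axis=1)
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    k = np.exp(-gamma * sq_dist)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(k, tuple(names), kind="gip")


def default_mask(primary: SimilarityMatrix) -> np.ndarray:
    """Availability mask: off-diagonal exact zeros mean "no similarity known".

    Functional/semantic similarity files conventionally encode missingness
    as 0; the diagonal is always considered available.
    """
    mask = primary.values != 0
    np.fill_diagonal(mask, True)
    return mask


def integrate_similarity(
    primary: SimilarityMatrix,
    gip: SimilarityMatrix,
    mask: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Element-wise selection: primary similarity where available, GIP otherwise."""
    if primary.names != gip.names:
        raise ValueError("primary and GIP matrices must share names")
    if mask is None:
        mask = default_mask(primary)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != primary.values.shape:
        raise ValueError("mask shape must match the similarity matrices")
    if not (mask == mask.T).all():
        raise ValueError("availability mask must be symmetric")
    merged = np.where(mask, primary.values, gip.values)
    return SimilarityMatrix(merged, primary.names, kind="integrated")


def laplacian_normalize(sim: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Symmetric normalization D^(-1/2) S D^(-1/2), D = diag(row sums).

    This is the propagation operator used by the graph-convolutional
    encoder/decoder layers; its spectrum lies in [-1, 1].
    """
    s = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    deg = s.sum(axis=1)
    if (deg <= 0).any():
        raise ZeroDivisionError("zero row sum: graph has an isolated all-zero node")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return s * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
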