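"""Self-contained synthetic fixtures with planted block structure.

The generator emulates the gross statistics of a curated miRNA-disease
catalog: a sparse binary association matrix whose density is concentrated in
matched miRNA/disease blocks (e.g. cancer-related miRNA families vs
neoplasm groups), together with similarity matrices that are high within a
block and low across blocks, plus truncated Gaussian noise.  A separate
helper builds small random disease ontologies (forests of rooted DAGs with
shared ancestors) for exercising the semantic-similarity code.

Everything is deterministic under a seed, so tests and experiments need no
downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import AssociationMatrix, DiseaseOntology, EntityCatalog, SimilarityMatrix

__all__ = [
    "PlantedConfig",
    "generate_planted_bundle",
    "generate_catalog_association",
    "generate_toy_ontology",
]


@dataclass
class PlantedConfig:
    """Sizes, block structure and noise levels of a planted bundle."""

    nm: int = 100
    nd: int = 80
    n_blocks: int = 4
    p_in: float = 0.3  # association probability within matched blocks
    p_out: float = 0.02  # background association probability
    sim_in: float = 0.7  # baseline similarity within a block
    sim_out: float = 0.1  # baseline similarity across blocks
    noise_sd: float = 0.05  # sd of the symmetric Gaussian similarity noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not (self.n_blocks >= 1 and self.nm >= self.n_blocks and self.nd >= self.n_blocks):
            raise ValueError("block count must not exceed either axis size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _blocks(n: int, b: int) -> np.ndarray:
    return (np.arange(n) * b) // n


def _noisy_block_similarity(
    blocks: np.ndarray, cfg: PlantedConfig, rng: np.random.Generator, kind: str, names
) -> SimilarityMatrix:
    n = len(blocks)
    base = np.where(blocks[:, None] == blocks[None, :], cfg.sim_in, cfg.sim_out).astype(float)
    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, size=(n, n))
        base += (noise + noise.T) / 2.0
    np.clip(base, 0.0, 1.0, out=base)
    np.fill_diagonal(base, 1.0)
    return SimilarityMatrix(base, names, kind=kind)


def generate_planted_bundle(
    cfg: PlantedConfig = PlantedConfig(),
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Association matrix plus consistent miRNA/disease similarity matrices.

    miRNA i and disease j associate with probability ``p_in`` when their
    block labels match and ``p_out`` otherwise; similarities reflect the
    same block labels, so association structure is recoverable from the
    similarity graphs — the property the embedding pipeline exploits.
    """
    rng = np.random.default_rng(cfg.seed)
    mb = _blocks(cfg.nm, cfg.n_blocks)
    db = _blocks(cfg.nd, cfg.n_blocks)
    prob = np.where(mb[:, None] == db[None, :], cfg.p_in, cfg.p_out)
    values = (rng.random((cfg.nm, cfg.nd)) < prob).astype(np.int8)
    catalog = EntityCatalog(
        tuple(f"mirna-{i:03d}" for i in range(cfg.nm)),
        tuple(f"disease-{j:03d}" for j in range(cfg.nd)),
    )
    assoc = AssociationMatrix(values, catalog)
    sm = _noisy_block_similarity(mb, cfg, rng, "functional", catalog.mirna_names)
    sd = _noisy_block_similarity(db, cfg, rng, "semantic", catalog.disease_names)
    return assoc, sm, sd


def generate_catalog_association(
    nm: int, nd: int, n_positives: int, seed: int = 0
) -> AssociationMatrix:
    """Association matrix with an exact number of uniformly placed positives."""
    if n_positives > nm * nd:
        raise ValueError("more positives than matrix cells")
    rng = np.random.default_rng(seed)
    flat = rng.choice(nm * nd, size=n_positives, replace=False)
    values = np.zeros(nm * nd, dtype=np.int8)
    values[flat] = 1
    catalog = EntityCatalog(
        tuple(f"mirna-{i:03d}" for i in range(nm)),
        tuple(f"disease-{j:03d}" for j in range(nd)),
    )
    return AssociationMatrix(values.reshape(nm, nd), catalog)


def generate_toy_ontology(n_diseases: int, depth: int, seed: int = 0) -> DiseaseOntology:
    """Random forest of rooted DAGs with shared ancestor chains.

    ``depth=1`` makes every disease a root-only DAG (no pairwise overlap).
    For ``depth >= 2`` each disease gets an ancestor chain of random length
    below ``depth`` drawn from a small shared pool, so some pairs overlap;
    the first two diseases always share a single parent, giving at least one
    guaranteed sibling pair.
    """
    if n_diseases < 2 or depth < 1:
        raise ValueError("need n_diseases >= 2 and depth >= 1")
    rng = np.random.default_rng(seed)
    edges: dict[str, list[tuple[str, str]]] = {}
    n_chains = max(2, n_diseases // 2)
    for idx in range(n_diseases):
        d = f"disease-{idx:03d}"
        if depth == 1:
            edges[d] = []
            continue
        if idx < 2:  # guaranteed sibling pair under ancestor chain 0
            chain_id, length = 0, 1
        else:
            chain_id = int(rng.integers(0, n_chains))
            length = int(rng.integers(0, depth))
        chain = [f"anc-{chain_id:02d}-{lvl}" for lvl in range(length)]
        dag = []
        prev = d
        for node in chain:
            dag.append((prev, node))
            prev = node
        edges[d] = dag
    return DiseaseOntology(edges)
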