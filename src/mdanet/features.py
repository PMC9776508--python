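"""Feature construction for entities and miRNA-disease pairs.

Two raw feature blocks exist per entity:

* F1, the association profile — a miRNA's row (or a disease's column) of the
  binary association matrix;
* F2, the similarity profile — the entity's row of its integrated similarity
  matrix.

The learned block Z^L comes from the stacked graph autoencoder.  The final
entity embedding is V = [Z^L | F1] (learned block first), giving widths
dim(Z^L) + nd for miRNAs and dim(Z^L) + nm for diseases; a pair feature is
the concatenation [Vm_i | Vd_j] (miRNA block first).  Ablation modes swap
which blocks enter V.
"""

from __future__ import annotations

import numpy as np

from .io_data import AssociationMatrix

__all__ = [
    "FEATURE_MODES",
    "association_block",
    "build_entity_embeddings",
    "build_pair_feature",
    "build_pair_matrix",
    "entity_features",
]

FEATURE_MODES = ("full", "only-pretrain", "non-pretrain", "only-association")


def association_block(assoc: AssociationMatrix, axis: str) -> np.ndarray:
    """F1: rows of A for miRNAs, columns of A (as rows) for diseases."""
    if axis == "miRNA":
        return assoc.values.astype(float)
    if axis == "disease":
        return assoc.values.T.astype(float)
    raise ValueError(f"unknown axis {axis!r}")


def build_entity_embeddings(z_final: np.ndarray, assoc: AssociationMatrix, axis: str) -> np.ndarray:
    """V = [Z^L | F1] for every entity on one axis."""
    f1 = association_block(assoc, axis)
    z_final = np.asarray(z_final, dtype=float)
    if z_final.shape[0] != f1.shape[0]:
        raise ValueError(
            f"Z has {z_final.shape[0]} rows but axis {axis!r} has {f1.shape[0]} entities"
        )
    return np.hstack([z_final, f1])


def entity_features(
    mode: str,
    z_final: np.ndarray | None,
    f2: np.ndarray,
    assoc: AssociationMatrix,
    axis: str,
) -> np.ndarray:
    """Entity embedding under a feature-ablation mode.

    full -> [Z^L | F1]; only-pretrain -> [Z^L]; non-pretrain -> [F2 | F1];
    only-association -> [F1].
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}; expected one of {FEATURE_MODES}")
    f1 = association_block(assoc, axis)
    if mode == "only-association":
        return f1
    if mode == "non-pretrain":
        return np.hstack([np.asarray(f2, dtype=float), f1])
    if z_final is None:
        raise ValueError(f"mode {mode!r} requires pretrained embeddings")
    if mode == "only-pretrain":
        return np.asarray(z_final, dtype=float)
    return build_entity_embeddings(z_final, assoc, axis)


def build_pair_feature(vm_i: np.ndarray, vd_j: np.ndarray) -> np.ndarray:
    """Pair vector [Vm_i | Vd_j]; width = width(Vm) + width(Vd)."""
    vm_i = np.asarray(vm_i, dtype=float)
    vd_j = np.asarray(vd_j, dtype=float)
    if not (np.isfinite(vm_i).all() and np.isfinite(vd_j).all()):
        raise FloatingPointError("non-finite entity embedding")
    return np.concatenate([vm_i, vd_j])


def build_pair_matrix(vm: np.ndarray, vd: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Stack pair features for an (n_pairs, 2) index array of (i, j) rows."""
    pairs = np.asarray(pairs)
    return np.hstack([vm[pairs[:, 0]], vd[pairs[:, 1]]])
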