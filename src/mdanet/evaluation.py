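"""Cross-validation harness, metrics, and the feature-ablation runner.

The evaluation protocol mirrors standard practice for bipartite link
prediction with balanced resampling: all known associations are positives,
an equal number of unknown pairs is sampled as negatives, the balanced set
is split into k stratified folds, and the whole procedure is repeated over
several negative resamplings.  Reported numbers are means and standard
deviations over all resampling x fold combinations.

Two leakage policies are available.  The default ("leakage-safe") rebuilds
the association-profile features and the GIP kernels from the training
folds only, with test-fold positives zeroed.  ``paper_mode=True`` uses the
full association matrix everywhere, the apparent protocol of most published
predictors in this family; both are explicit so results are comparable
either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import MlpConfig, build_labeled_pairs, mlp_forward, train_mlp
from .features import build_pair_matrix, entity_features
from .io_data import AssociationMatrix, SimilarityMatrix
from .sgae import SgaeConfig, train_sgae
from .similarity import GipConfig, gip_kernel, integrate_similarity, laplacian_normalize

__all__ = [
    "DataBundle",
    "EvalReport",
    "kfold_split",
    "confusion_and_metrics",
    "roc_auc",
    "pr_auc",
    "build_integrated_similarity",
    "run_cv",
]

METRIC_NAMES = ("auc", "aupr", "acc", "pre", "rec", "f1")


@dataclass
class DataBundle:
    """Inputs of one experiment: associations plus primary similarities.

    ``mirna_sim`` is the functional similarity matrix, ``disease_sim`` the
    semantic one; availability masks default to "exact off-diagonal zero
    means missing" (see :func:`mdanet.similarity.default_mask`).
    """

    assoc: AssociationMatrix
    mirna_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    mirna_mask: np.ndarray | None = None
    disease_mask: np.ndarray | None = None


@dataclass
class EvalReport:
    mode: str
    k: int
    seed: int
    n_resamplings: int
    paper_mode: bool
    fold_metrics: list[dict[str, Any]] = field(default_factory=list)

    def aggregate(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([fm[name] for fm in self.fold_metrics])
            out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "mode": self.mode,
            "k": self.k,
            "seed": self.seed,
            "n_resamplings": self.n_resamplings,
            "paper_mode": self.paper_mode,
            "aggregate": self.aggregate(),
            "folds": self.fold_metrics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def kfold_split(
    n_samples: int, k: int, seed: int, labels: np.ndarray | None = None
) -> np.ndarray:
    """Fold assignment array (values 0..k-1), stratified when labels given."""
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the {n_samples} available samples")
    if k < 2:
        raise ValueError("k must be at least 2")
    assign = np.empty(n_samples, dtype=int)
    if labels is not None and len(np.unique(labels)) > 1:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n_samples), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n_samples))
    for fold, (_, test_idx) in enumerate(split_iter):
        assign[test_idx] = fold
    return assign


def confusion_and_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, precision, recall and F1 at a fixed score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty score array")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / (tp + tn + fp + fn)
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return {"acc": acc, "pre": pre, "rec": rec, "f1": f1}


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (equals the Mann-Whitney pair statistic)."""
    _check_two_classes(np.asarray(labels))
    return float(_skm.roc_auc_score(labels, scores))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise integration."""
    _check_two_classes(np.asarray(labels))
    return float(_skm.average_precision_score(labels, scores))


def build_integrated_similarity(
    assoc: AssociationMatrix,
    bundle: DataBundle,
    gip_cfg: GipConfig = GipConfig(),
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated Sm and Sd: primary similarity where known, GIP elsewhere.

    GIP profiles are the rows/columns of ``assoc`` (which may be a
    training-fold-only matrix under the leakage-safe policy).
    """
    cat = assoc.catalog
    gm = gip_kernel(assoc.values, cat.mirna_names, gip_cfg)
    gd = gip_kernel(assoc.values.T, cat.disease_names, gip_cfg)
    sm = integrate_similarity(bundle.mirna_sim, gm, bundle.mirna_mask)
    sd = integrate_similarity(bundle.disease_sim, gd, bundle.disease_mask)
    return sm, sd


def _pretrain(
    assoc: AssociationMatrix,
    bundle: DataBundle,
    sgae_cfg: SgaeConfig,
    gip_cfg: GipConfig,
    seed: int,
    need_embeddings: bool,
):
    """Similarity integration + (optionally) SGAE pre-training for both axes."""
    sm, sd = build_integrated_similarity(assoc, bundle, gip_cfg)
    zm = zd = None
    if need_embeddings:
        cfg_m = SgaeConfig(
            dims=sgae_cfg.dims, n_layers=sgae_cfg.n_layers, final_dim=sgae_cfg.final_dim,
            hidden_factor=sgae_cfg.hidden_factor, epochs=sgae_cfg.epochs, lr=sgae_cfg.lr,
            weight_decay=sgae_cfg.weight_decay, seed=seed,
        )
        emb_m, _, _ = train_sgae(laplacian_normalize(sm), sm.values, cfg_m, axis="miRNA")
        cfg_d = SgaeConfig(
            dims=sgae_cfg.dims, n_layers=sgae_cfg.n_layers, final_dim=sgae_cfg.final_dim,
            hidden_factor=sgae_cfg.hidden_factor, epochs=sgae_cfg.epochs, lr=sgae_cfg.lr,
            weight_decay=sgae_cfg.weight_decay, seed=seed + 1,
        )
        emb_d, _, _ = train_sgae(laplacian_normalize(sd), sd.values, cfg_d, axis="disease")
        zm, zd = emb_m.final, emb_d.final
    return sm, sd, zm, zd


def run_cv(
    bundle: DataBundle,
    mode: str = "full",
    k: int = 5,
    seed: int = 0,
    n_resamplings: int = 10,
    sgae_cfg: SgaeConfig | None = None,
    mlp_cfg: MlpConfig | None = None,
    gip_cfg: GipConfig = GipConfig(),
    paper_mode: bool = False,
) -> EvalReport:
    """Balanced-resampling k-fold cross-validation of the full pipeline.

    For each resampling round r (seed ``seed + r``): draw negatives equal in
    number to the positives, split the balanced set into k stratified folds,
    and for each fold build features per the leakage policy, pre-train the
    stacked graph autoencoder (when the mode uses learned embeddings), train
    the MLP on the training folds and score the test fold.
    """
    sgae_cfg = sgae_cfg or SgaeConfig()
    mlp_cfg = mlp_cfg or MlpConfig()
    need_emb = mode in ("full", "only-pretrain")
    report = EvalReport(mode=mode, k=k, seed=seed, n_resamplings=n_resamplings,
                        paper_mode=paper_mode)
    assoc = bundle.assoc
    for r in range(n_resamplings):
        rs_seed = seed + r
        pair_set = build_labeled_pairs(assoc, rs_seed, round_id=r)
        folds = kfold_split(len(pair_set.labels), k, rs_seed, pair_set.labels)
        if paper_mode:
            shared = _pretrain(assoc, bundle, sgae_cfg, gip_cfg, rs_seed, need_emb)
        for fold in range(k):
            test = folds == fold
            if paper_mode:
                assoc_train = assoc
                sm, sd, zm, zd = shared
            else:
                masked = assoc.values.copy()
                tp = pair_set.pairs[test & (pair_set.labels == 1)]
                masked[tp[:, 0], tp[:, 1]] = 0
                assoc_train = AssociationMatrix(masked, assoc.catalog)
                sm, sd, zm, zd = _pretrain(
                    assoc_train, bundle, sgae_cfg, gip_cfg, rs_seed, need_emb
                )
            vm = entity_features(mode, zm, sm.values, assoc_train, "miRNA")
            vd = entity_features(mode, zd, sd.values, assoc_train, "disease")
            fold_mlp = MlpConfig(hidden=mlp_cfg.hidden, epochs=mlp_cfg.epochs,
                                 lr=mlp_cfg.lr, seed=rs_seed, threshold=mlp_cfg.threshold)
            x_train = build_pair_matrix(vm, vd, pair_set.pairs[~test])
            x_test = build_pair_matrix(vm, vd, pair_set.pairs[test])
            params, _ = train_mlp(x_train, pair_set.labels[~test], fold_mlp)
            scores = mlp_forward(x_test, params)
            y_test = pair_set.labels[test]
            fm = confusion_and_metrics(scores, y_test, fold_mlp.threshold)
            fm["auc"] = roc_auc(scores, y_test)
            fm["aupr"] = pr_auc(scores, y_test)
            fm["resampling"] = r
            fm["fold"] = fold
            report.fold_metrics.append(fm)
    return report
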