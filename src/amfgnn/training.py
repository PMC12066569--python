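"""Model assembly, training loop, cross-validation and metrics.

The model encodes three graphs with separate GAT stacks: the drug KNN
similarity graph, the disease KNN similarity graph, and the bipartite
association graph (nodes = drugs + diseases, edges = *training-fold*
positives only, so held-out pairs never enter message passing).  Initial
node features are learned linear projections of the similarity rows;
last-layer GAT outputs are mixed with residual transforms of these initial
features via learned scalars, the two views of each entity are fused, and
pairs are scored by the configured head.

Cross-validation follows the all-pairs protocol: every drug-disease pair
(positive or negative) is assigned to exactly one of the 10 test folds; the
association adjacency is rebuilt per fold from that fold's training
positives.  Metrics are AUROC (midrank ties), and recall / F1 at the 0.5
probability threshold, reported per fold with mean and standard deviation.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, recall_score, roc_auc_score

from ._tensor import Adam, Parameter, Tensor, stack_rows
from .config import TrainConfig
from .datasets import DatasetBundle, KnnGraph, build_knn_adjacency
from .fusion import AdaptiveScalar, ResidualTransform, fuse_views, residual_mix
from .gat import GatStack
from .kan import KanNetwork, MlpNetwork
from .objectives import contrastive_loss, cross_entropy, score_pairs, total_loss

__all__ = ["AmfgnnModel", "FoldSplit", "MetricReport", "MetricsError",
           "make_folds", "train_fold", "train_full", "compute_metrics",
           "run_cv", "top_candidates"]

log = logging.getLogger("amfgnn")


class MetricsError(ValueError):
    """Metrics are undefined (e.g. a single-class test fold)."""


# --------------------------------------------------------------------------
# fold construction
# --------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Flat pair-index sets (row-major over the association matrix)."""

    fold_id: int
    train_pairs: np.ndarray
    test_pairs: np.ndarray


def make_folds(n_drugs: int, n_diseases: int, n_folds: int = 10,
               seed: int = 0) -> list[FoldSplit]:
    """Seeded random partition of ALL pairs into near-equal test folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_pairs = n_drugs * n_diseases
    if n_folds > n_pairs:
        raise ValueError(f"n_folds={n_folds} exceeds {n_pairs} pairs")
    rng = np.random.default_rng([seed, 101])
    perm = rng.permutation(n_pairs)
    chunks = np.array_split(perm, n_folds)
    folds = []
    for fid, test in enumerate(chunks):
        test = np.sort(test)
        mask = np.ones(n_pairs, dtype=bool)
        mask[test] = False
        folds.append(FoldSplit(fid, np.flatnonzero(mask), test))
    return folds


def make_folds_disease_cold(n_drugs: int, n_diseases: int, n_folds: int = 10,
                            seed: int = 0) -> list[FoldSplit]:
    """Column-wise holdout: each fold tests all pairs of unseen diseases."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n_diseases:
        raise ValueError("more folds than diseases")
    rng = np.random.default_rng([seed, 103])
    cols = rng.permutation(n_diseases)
    folds = []
    for fid, test_cols in enumerate(np.array_split(cols, n_folds)):
        col_mask = np.zeros(n_diseases, dtype=bool)
        col_mask[test_cols] = True
        pair_mask = np.tile(col_mask, n_drugs)
        folds.append(
            FoldSplit(fid, np.flatnonzero(~pair_mask),
                      np.flatnonzero(pair_mask))
        )
    return folds


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class AmfgnnModel:
    """Twin similarity encoders + association encoder + fusion + head."""

    def __init__(self, n_drugs: int, n_diseases: int, cfg: TrainConfig,
                 rng: np.random.Generator):
        self.n_drugs, self.n_diseases = n_drugs, n_diseases
        self.cfg = cfg
        d = cfg.embed_dim

        def lin(n_in):
            limit = np.sqrt(6.0 / (n_in + d))
            return (Parameter(rng.uniform(-limit, limit, (n_in, d))),
                    Parameter(np.zeros(d)))

        self.proj_drug = lin(n_drugs)
        self.proj_dis = lin(n_diseases)
        kw = dict(negative_slope=cfg.negative_slope, dropout_rate=cfg.dropout)
        self.gat_drug = GatStack(d, d, cfg.gat_layers, cfg.heads, rng, **kw)
        self.gat_dis = GatStack(d, d, cfg.gat_layers, cfg.heads, rng, **kw)
        self.gat_assoc = GatStack(d, d, cfg.gat_layers, cfg.heads, rng, **kw)
        self.res_drug = ResidualTransform(d, rng)
        self.res_dis = ResidualTransform(d, rng)
        self.res_assoc = ResidualTransform(d, rng)
        self.eps = [AdaptiveScalar() for _ in range(3)]
        self.eta = [AdaptiveScalar() for _ in range(2)]
        fused = 3 * d
        in_width = fused if cfg.pair_features == "product" else 2 * fused
        if cfg.head_kind == "kan":
            # learnable activations on the pair features: summing phi_i of
            # M_i * D_j coordinates generalises the inner-product score
            self.head = KanNetwork([in_width, cfg.head_hidden, 1], rng)
        elif cfg.head_kind == "mlp":
            self.head = MlpNetwork([in_width, cfg.head_hidden, 1], rng)
        else:
            self.head = None

    def parameters(self) -> list:
        ps = [*self.proj_drug, *self.proj_dis]
        for stack in (self.gat_drug, self.gat_dis, self.gat_assoc):
            ps += stack.parameters()
        for res in (self.res_drug, self.res_dis, self.res_assoc):
            ps += res.parameters()
        for s in (*self.eps, *self.eta):
            ps += s.parameters()
        if self.head is not None:
            ps += self.head.parameters()
        return ps

    def forward(self, drug_graph: KnnGraph, dis_graph: KnnGraph,
                assoc_adj: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns fused embeddings (M, D) and the per-entity view pairs."""
        h_as0 = Tensor(drug_graph.features) @ self.proj_drug[0] \
            + self.proj_drug[1]
        h_ds0 = Tensor(dis_graph.features) @ self.proj_dis[0] \
            + self.proj_dis[1]
        h_asl = self.gat_drug.forward(drug_graph.adjacency, h_as0,
                                      training=training, rng=rng)
        h_dsl = self.gat_dis.forward(dis_graph.adjacency, h_ds0,
                                     training=training, rng=rng)
        h_ad0 = stack_rows(h_as0, h_ds0)
        h_adl = self.gat_assoc.forward(assoc_adj, h_ad0,
                                       training=training, rng=rng)
        r_a = self.res_drug.forward(h_as0)
        r_d = self.res_dis.forward(h_ds0)
        r_ad = self.res_assoc.forward(h_ad0)
        h_a1 = residual_mix(h_asl, r_a, self.eps[0].value)
        h_d1 = residual_mix(h_dsl, r_d, self.eps[1].value)
        h_ad = residual_mix(h_adl, r_ad, self.eps[2].value)
        h_a2 = h_ad[np.arange(self.n_drugs)]
        h_d2 = h_ad[self.n_drugs + np.arange(self.n_diseases)]
        m = fuse_views(h_a1, h_a2, self.eta[0].value)
        dd = fuse_views(h_d1, h_d2, self.eta[1].value)
        return m, dd, (h_a1, h_a2, h_d1, h_d2)

    def score(self, m: Tensor, d: Tensor,
              pairs: tuple[np.ndarray, np.ndarray]) -> Tensor:
        return score_pairs(m, d, pairs, head=self.head,
                           pair_features=self.cfg.pair_features)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _assoc_adjacency(n_drugs: int, n_diseases: int,
                     pos_pairs: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    n = n_drugs + n_diseases
    adj = np.zeros((n, n), dtype=np.int8)
    di, sj = pos_pairs
    adj[di, n_drugs + sj] = 1
    adj[n_drugs + sj, di] = 1
    np.fill_diagonal(adj, 1)
    return adj


def _build_graphs(bundle: DatasetBundle, cfg: TrainConfig):
    k = min(cfg.knn_k, bundle.drug_sim.n - 1)
    kd = min(cfg.knn_k, bundle.disease_sim.n - 1)
    return (build_knn_adjacency(bundle.drug_sim, k),
            build_knn_adjacency(bundle.disease_sim, kd))


def _train(bundle: DatasetBundle, train_pairs: np.ndarray, cfg: TrainConfig,
           stream: int):
    """Train on the given pair set; returns (model, assoc_adj, graphs)."""
    assoc = bundle.associations
    labels_flat = assoc.values.reshape(-1)
    y_train = labels_flat[train_pairs]
    pos = train_pairs[y_train == 1]
    neg = train_pairs[y_train == 0]
    if pos.size == 0:
        raise ValueError("degenerate fold: no training positives")
    drug_graph, dis_graph = _build_graphs(bundle, cfg)
    pos_ij = np.unravel_index(pos, assoc.values.shape)
    adj = _assoc_adjacency(assoc.n_drugs, assoc.n_diseases, pos_ij)
    rng_init = np.random.default_rng([cfg.seed, 11, stream])
    rng_neg = np.random.default_rng([cfg.seed, 17, stream])
    rng_drop = np.random.default_rng([cfg.seed, 13, stream])
    model = AmfgnnModel(assoc.n_drugs, assoc.n_diseases, cfg, rng_init)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n_neg = min(neg.size, int(round(cfg.neg_ratio * pos.size)))
    for epoch in range(cfg.epochs):
        batch = np.concatenate(
            [pos, rng_neg.choice(neg, size=n_neg, replace=False)]
        )
        bij = np.unravel_index(batch, assoc.values.shape)
        m, d, views = model.forward(drug_graph, dis_graph, adj,
                                    training=True, rng=rng_drop)
        scores = model.score(m, d, bij)
        ce = cross_entropy(scores, labels_flat[batch],
                           reduction=cfg.ce_reduction)
        if cfg.contrastive:
            lmc = contrastive_loss(views[0], views[1])
            ldc = contrastive_loss(views[2], views[3])
        else:
            lmc = ldc = Tensor(0.0)
        loss = total_loss(ce, lmc, ldc, cfg.loss_weights)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if epoch % 50 == 0 or epoch == cfg.epochs - 1:
            log.debug("stream %s epoch %d loss %.5f", stream, epoch,
                      loss.item())
    return model, adj, (drug_graph, dis_graph)


def train_fold(bundle: DatasetBundle, fold: FoldSplit,
               cfg: TrainConfig) -> tuple[AmfgnnModel, np.ndarray, np.ndarray]:
    """Train on a fold's training pairs; score its test pairs.

    No test pair (positive or negative) influences message passing or the
    loss.  Returns (model, test_scores, test_labels).
    """
    model, adj, (dg, sg) = _train(bundle, fold.train_pairs, cfg,
                                  stream=fold.fold_id)
    m, d, _ = model.forward(dg, sg, adj, training=False)
    tij = np.unravel_index(fold.test_pairs, bundle.associations.values.shape)
    scores = model.score(m, d, tij).data
    labels = bundle.associations.values.reshape(-1)[fold.test_pairs]
    return model, scores, labels.astype(int)


def train_full(bundle: DatasetBundle, cfg: TrainConfig) -> np.ndarray:
    """Train on all pairs and return the full score matrix (for ranking)."""
    assoc = bundle.associations
    all_pairs = np.arange(assoc.values.size)
    model, adj, (dg, sg) = _train(bundle, all_pairs, cfg, stream=999)
    m, d, _ = model.forward(dg, sg, adj, training=False)
    ij = np.unravel_index(all_pairs, assoc.values.shape)
    return model.score(m, d, ij).data.reshape(assoc.values.shape)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class MetricReport:
    auc: float
    recall: float
    f1: float
    auc_sd: float = 0.0
    recall_sd: float = 0.0
    f1_sd: float = 0.0
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "recall": self.recall, "f1": self.f1,
            "auc_sd": self.auc_sd, "recall_sd": self.recall_sd,
            "f1_sd": self.f1_sd, "per_fold": self.per_fold,
        }


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    fold_id: int | None = None) -> dict:
    """AUROC (midrank), recall and F1 at the 0.5 threshold."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise MetricsError(
            f"single-class test set"
            + (f" in fold {fold_id}" if fold_id is not None else "")
        )
    pred = (np.asarray(scores) >= 0.5).astype(int)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "recall": float(recall_score(labels, pred, zero_division=0)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
    }


def _aggregate(per_fold: list[dict]) -> MetricReport:
    arr = {k: np.array([f[k] for f in per_fold])
           for k in ("auc", "recall", "f1")}
    return MetricReport(
        auc=float(arr["auc"].mean()), recall=float(arr["recall"].mean()),
        f1=float(arr["f1"].mean()), auc_sd=float(arr["auc"].std()),
        recall_sd=float(arr["recall"].std()), f1_sd=float(arr["f1"].std()),
        per_fold=per_fold,
    )


# --------------------------------------------------------------------------
# cross-validation driver
# --------------------------------------------------------------------------

def run_cv(bundle: DatasetBundle, cfg: TrainConfig,
           out_dir: str | None = None) -> MetricReport:
    """Full k-fold protocol: split, train per fold, aggregate mean +- SD.

    With out_dir set, writes metrics.json, scores.tsv (every pair scored by
    the fold in which it was held out) and a config.yaml snapshot.
    """
    assoc = bundle.associations
    if cfg.split_mode == "disease-cold":
        folds = make_folds_disease_cold(assoc.n_drugs, assoc.n_diseases,
                                        cfg.n_folds, cfg.seed)
    else:
        folds = make_folds(assoc.n_drugs, assoc.n_diseases, cfg.n_folds,
                           cfg.seed)
    per_fold = []
    all_scores = np.full(assoc.values.size, np.nan)
    for fold in folds:
        log.info("fold %d/%d: %d train / %d test pairs", fold.fold_id + 1,
                 len(folds), fold.train_pairs.size, fold.test_pairs.size)
        _, scores, labels = train_fold(bundle, fold, cfg)
        stats = compute_metrics(scores, labels, fold_id=fold.fold_id)
        stats["fold"] = fold.fold_id
        per_fold.append(stats)
        all_scores[fold.test_pairs] = scores
        log.info("fold %d AUC %.4f", fold.fold_id, stats["auc"])
    report = _aggregate(per_fold)
    if out_dir is not None:
        _write_artifacts(bundle, cfg, report, all_scores, out_dir)
    return report


def _write_artifacts(bundle: DatasetBundle, cfg: TrainConfig,
                     report: MetricReport, all_scores: np.ndarray,
                     out_dir: str) -> None:
    from . import __version__
    from .config import save_config

    os.makedirs(out_dir, exist_ok=True)
    payload = {"version": __version__, "seed": cfg.seed,
               "split_mode": cfg.split_mode, **report.to_dict()}
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    save_config(cfg, os.path.join(out_dir, "config.yaml"))
    assoc = bundle.associations
    with open(os.path.join(out_dir, "scores.tsv"), "w") as fh:
        fh.write("drug_id\tdisease_id\tscore\n")
        mat = all_scores.reshape(assoc.values.shape)
        for i, did in enumerate(assoc.drug_ids):
            for j, sid in enumerate(assoc.disease_ids):
                fh.write(f"{did}\t{sid}\t{mat[i, j]:.10g}\n")


def evaluate_single_fold(bundle: DatasetBundle, cfg: TrainConfig,
                         fold_id: int = 0) -> dict:
    """Train/evaluate one fold of the configured split (fast ablation runs)."""
    assoc = bundle.associations
    fold = make_folds(assoc.n_drugs, assoc.n_diseases, cfg.n_folds,
                      cfg.seed)[fold_id]
    _, scores, labels = train_fold(bundle, fold, cfg)
    return compute_metrics(scores, labels, fold_id=fold_id)


def top_candidates(score_matrix: np.ndarray, drug_ids: list[str],
                   disease_index: int, k: int = 10) -> list[tuple[str, float]]:
    """Top-k drugs for one disease, score descending, ties by drug id."""
    col = score_matrix[:, disease_index]
    order = sorted(range(len(drug_ids)), key=lambda i: (-col[i], drug_ids[i]))
    return [(drug_ids[i], float(col[i])) for i in order[:k]]
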