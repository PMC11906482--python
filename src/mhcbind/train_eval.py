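"""5-fold cross-validated training, fold-averaged ensembling, metrics.

Training follows the published recipe: the data are split into five
folds; each member model trains on four folds and is checkpointed at its
minimum held-out-fold loss; the ensemble prediction is the arithmetic
mean of the five members' outputs.

Metrics: ROC-AUC (Mann-Whitney pairwise probability), PR-AUC (area
under the descending-score precision-recall step curve with ties
grouped), TOPk%-PPV (positive fraction among the top ceil(k*N)
predictions, ties broken by stable input order), and Pearson r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold

from .network import ModelConfig, PanMHCNet, _as_pairs


# ---------------------------------------------------------------------
# fold handling
# ---------------------------------------------------------------------

def kfold_split(records, k: int = 5, seed: int = 0, existing=None) -> np.ndarray:
    """Assign each record a fold id in [0, k).

    ``records`` may be a length or a sized collection.  Folds differ in
    size by at most one and are deterministic for a fixed seed.  If
    ``existing`` fold labels are supplied they are passed through
    verbatim.
    """
    n = records if isinstance(records, int) else len(records)
    if existing is not None:
        existing = np.asarray(existing, dtype=np.int64)
        if len(existing) != n:
            raise ValueError("existing fold labels length mismatch")
        return existing
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    assignment = np.empty(n, dtype=np.int64)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)))):
        assignment[test_idx] = fold
    return assignment


def train_fold(X, y, config: ModelConfig, pseudo_sequences: dict,
               validation=None) -> PanMHCNet:
    """Train one member model; returns the fitted estimator."""
    model = PanMHCNet(config=config, pseudo_sequences=pseudo_sequences)
    model.fit(X, y, validation=validation)
    return model


# ---------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------

def ensemble_predict(members, X) -> np.ndarray:
    """Arithmetic mean of the member models' predictions."""
    if not members:
        raise ValueError("empty ensemble")
    preds = np.stack([np.asarray(m.predict(X), dtype=np.float64) for m in members])
    return preds.mean(axis=0)


class FoldEnsemble(BaseEstimator):
    """K models trained on complementary folds; predicts the fold mean.

    Fitted attributes: ``members_`` (list of PanMHCNet),
    ``fold_assignment_`` (record -> fold id).
    """

    def __init__(self, config: ModelConfig = None, pseudo_sequences: dict = None,
                 n_folds: int = 5, seed: int = 0):
        self.config = config
        self.pseudo_sequences = pseudo_sequences
        self.n_folds = n_folds
        self.seed = seed

    @classmethod
    def from_members(cls, members) -> "FoldEnsemble":
        """Wrap pre-built member models (used for stubs and loading)."""
        ens = cls(n_folds=len(members))
        ens.members_ = list(members)
        ens.fold_assignment_ = None
        return ens

    def fit(self, X, y, folds=None):
        from dataclasses import replace

        from .encoding import encode_dataset

        y = np.asarray(y, dtype=np.float64)
        peptides, alleles = _as_pairs(X)
        # encode once; folds share the arrays
        onehot, blosum = encode_dataset(peptides, alleles,
                                        self.pseudo_sequences,
                                        self.config.max_pep_len)
        self.fold_assignment_ = kfold_split(len(y), k=self.n_folds,
                                            seed=self.seed, existing=folds)
        self.members_ = []
        for fold in range(self.n_folds):
            tr = self.fold_assignment_ != fold
            va = ~tr
            cfg = replace(self.config, seed=self.config.seed + fold)
            member = PanMHCNet(config=cfg,
                               pseudo_sequences=self.pseudo_sequences)
            member.fit_encoded(
                onehot[tr], blosum[tr], y[tr],
                validation=((onehot[va], blosum[va]), y[va]),
            )
            self.members_.append(member)
        return self

    def predict(self, X) -> np.ndarray:
        tasks = {m.config.task for m in self.members_
                 if getattr(m, "config", None) is not None}
        if len(tasks) > 1:
            raise ValueError(f"heterogeneous member tasks: {tasks}")
        if all(isinstance(m, PanMHCNet) for m in self.members_):
            m0 = self.members_[0]
            peptides, alleles = _as_pairs(X)
            from .encoding import encode_dataset

            onehot, blosum = encode_dataset(peptides, alleles,
                                            m0.pseudo_sequences,
                                            m0.config.max_pep_len)
            preds = np.stack([m._predict_encoded(onehot, blosum)
                              for m in self.members_])
            return preds.mean(axis=0)
        return ensemble_predict(self.members_, X)


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def _check_binary(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal shape")
    return labels, scores


def roc_auc(labels, scores) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie) over all pos/neg pairs."""
    labels, scores = _check_binary(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC is undefined with a single class")
    return float(roc_auc_score(labels, scores))

def pr_auc(labels, scores) -> float:
    """Area under the precision-recall step curve, descending scores,
    ties grouped (equals average precision)."""
    labels, scores = _check_binary(labels, scores)
    if labels.sum() == 0:
        raise ValueError("PR-AUC requires at least one positive")
    return float(average_precision_score(labels, scores))


def top_k_ppv(labels, scores, k: float = 0.20) -> float:
    """Positive fraction among the top ceil(k*N) scores.

    Ties are broken by stable input order.
    """
    labels, scores = _check_binary(labels, scores)
    if not 0 < k <= 1:
        raise ValueError("k must be in (0, 1]")
    n = len(labels)
    if n == 0:
        raise ValueError("empty input")
    top = int(np.ceil(k * n))
    order = np.argsort(-scores, kind="stable")
    return float(np.mean(labels[order[:top]]))


def pearson_r(x, y) -> float:
    """Product-moment correlation; rejects degenerate input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class EvalResult:
    pr_auc: float
    roc_auc: float
    top_k_ppv: float
    k: float
    n_pos: int
    n_neg: int
    pearson_r: float | None = None

    def to_dict(self) -> dict:
        return {
            "pr_auc": self.pr_auc,
            "roc_auc": self.roc_auc,
            "top_k_ppv": self.top_k_ppv,
            "k": self.k,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "pearson_r": self.pearson_r,
        }


def evaluate(labels, scores, k: float = 0.20, targets=None) -> EvalResult:
    """Compute the full classification metric panel; if continuous
    ``targets`` are supplied, also Pearson r of scores against them."""
    labels = np.asarray(labels)
    r = None
    if targets is not None:
        r = pearson_r(np.asarray(scores, dtype=np.float64), targets)
    return EvalResult(
        pr_auc=pr_auc(labels, scores),
        roc_auc=roc_auc(labels, scores),
        top_k_ppv=top_k_ppv(labels, scores, k=k),
        k=k,
        n_pos=int(np.sum(labels == 1)),
        n_neg=int(np.sum(labels == 0)),
        pearson_r=r,
    )
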