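"""Target-replication objective and the optimisation loop.

The loss for one patient with final probability ``p``, per-visit
probabilities ``p_1..p_T`` and outcome ``y`` is

    L = (1 - lambda) * bce(p, y) + (lambda / T) * sum_i bce(p_i, y)

with ``bce`` the binary cross-entropy and ``lambda`` in [0, 1] the
replication factor.  At lambda = 0 the intermediate (per-visit) terms vanish
and L is the ordinary final-step cross-entropy; at lambda = 1 only the
replicated visit losses drive learning.  Architectures without replication
heads are trained on the final-step term alone.

Optimisation is mini-batch Adam with gradient clipping; after each epoch the
tuning-fold AUROC is computed and the best-epoch parameters are retained
(early stopping on patience).  Embeddings stay frozen throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cohort import Document
from .embeddings import EmbeddingModel
from .metrics import PredictionSet, auroc
from .networks import (DocumentBatch, ModelConfig, RiskModel, build_model,
                       make_batches, predict_proba)

__all__ = ["target_replication_loss", "TrainConfig", "train", "tune_grid",
           "TrainState"]

_EPS = 1e-7


def _bce(p, y):
    """Binary cross-entropy, numpy or Tensor; probabilities clipped away
    from {0,1} for numerical safety."""
    if isinstance(p, Tensor):
        pc = p * (1.0 - 2.0 * _EPS) + _EPS
        yt = Tensor(np.asarray(y, dtype=float))
        return -(yt * ad.log(pc) + (1.0 - yt) * ad.log(1.0 - pc))
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=float)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def target_replication_loss(final_prob, visit_probs, label, lambda_rep,
                            visit_mask=None):
    """Replicated binary cross-entropy for one patient or a batch.

    Accepts plain arrays (returns a float) or autodiff Tensors (returns a
    scalar Tensor for backpropagation).  ``visit_mask`` marks real visits in
    a padded ``visit_probs`` array; when omitted all entries count.
    """
    lam = float(lambda_rep)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda_rep must be in [0, 1], got {lambda_rep}")
    symbolic = isinstance(final_prob, Tensor)
    final_term = _bce(final_prob, label).mean()
    if visit_probs is None or lam == 0.0:
        return final_term if symbolic else float(final_term)

    y = np.asarray(label, dtype=float)
    v_ndim = visit_probs.ndim
    y_v = y[..., None] if (v_ndim == 2 and y.ndim == 1) else y
    vloss = _bce(visit_probs, y_v)
    if visit_mask is None:
        rep_term = vloss.mean()
    else:
        mask = np.asarray(visit_mask, dtype=float)
        w = mask / np.maximum(mask.sum(axis=-1, keepdims=True), 1.0)
        weighted = vloss * (Tensor(w) if symbolic else w)
        rep_term = weighted.sum(axis=-1).mean()
    total = (1.0 - lam) * final_term + lam * rep_term
    return total if symbolic else float(total)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    clip_norm: float = 5.0


@dataclass
class TrainState:
    epoch: int = 0
    lr: float = 1e-3
    best_tune_auroc: float = -np.inf
    early_stop_counter: int = 0
    seed: int = 0
    history: list[dict] = field(default_factory=list)


def _struct_scaler(docs: Sequence[Document]) -> tuple[np.ndarray, np.ndarray]:
    mat = np.stack([d.structured.as_vector() for d in docs])
    return mat.mean(axis=0), mat.std(axis=0)


def train(model: RiskModel, train_docs: Sequence[Document],
          tune_docs: Sequence[Document], embedding: EmbeddingModel,
          hyperparams: TrainConfig | None = None, seed: int = 0
          ) -> tuple[RiskModel, list[dict]]:
    """Fit ``model`` on the training fold with tuning-fold model selection.

    Returns the model (parameters set to the best tuning epoch) and a
    per-epoch history of train loss and tuning AUROC.  Fully reproducible
    given ``seed``; the embedding matrix is never modified.
    """
    if not train_docs or not tune_docs:
        raise ValueError("training and tuning folds must be non-empty")
    hp = hyperparams or TrainConfig()
    if model.uses_structured:
        model.set_struct_scaler(*_struct_scaler(train_docs))
    state = TrainState(lr=hp.lr, seed=seed)
    if hp.max_epochs == 0:
        return model, state.history

    model.init_output_bias(float(np.mean([d.label for d in train_docs])))
    rng = np.random.default_rng(seed)
    emb_before = embedding.matrix.copy()
    batches = make_batches(list(train_docs), embedding,
                           batch_size=hp.batch_size,
                           include_structured=model.uses_structured)
    opt = ad.Adam(model.params, lr=hp.lr)
    lam = model.config.lambda_rep if model.target_replication else 0.0
    best_state = model.get_state()

    for epoch in range(1, hp.max_epochs + 1):
        order = rng.permutation(len(batches))
        losses = []
        for bi in order:
            batch = batches[bi]
            out = model.forward(batch, training=True)
            loss = target_replication_loss(out.final_prob, out.visit_probs,
                                           batch.labels, lam, out.visit_mask)
            opt.zero_grad()
            loss.backward()
            ad.clip_global_norm(model.params, hp.clip_norm)
            opt.step()
            losses.append(float(loss.data))
        tune_probs = predict_proba(model, list(tune_docs), embedding)
        tune_labels = np.array([d.label for d in tune_docs])
        score = auroc(PredictionSet(
            patient_ids=[d.patient_id for d in tune_docs],
            labels=tune_labels, probabilities=tune_probs))
        state.epoch = epoch
        state.history.append({"epoch": epoch,
                              "train_loss": float(np.mean(losses)),
                              "tune_auroc": float(score)})
        if score > state.best_tune_auroc:
            state.best_tune_auroc = score
            best_state = model.get_state()
            state.early_stop_counter = 0
        else:
            state.early_stop_counter += 1
            if state.early_stop_counter >= hp.patience:
                break
    model.set_state(best_state)
    assert np.array_equal(embedding.matrix, emb_before), \
        "embeddings must stay frozen during model training"
    return model, state.history


def tune_grid(model_kind: str, grid: Sequence[dict],
              train_docs: Sequence[Document], tune_docs: Sequence[Document],
              embedding: EmbeddingModel, seed: int = 0,
              train_config: TrainConfig | None = None) -> dict:
    """Exhaustive hyperparameter search on the tuning fold.

    Each grid point is a dict of ModelConfig overrides.  Ties on tuning
    AUROC break toward smaller ``lambda_rep``, then smaller ``word_hidden``.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    results = []
    for point in grid:
        cfg = ModelConfig(kind=model_kind,
                          embed_dim=embedding.dim, seed=seed, **point)
        model = build_model(cfg)
        model, history = train(model, train_docs, tune_docs, embedding,
                               hyperparams=train_config, seed=seed)
        best = max((h["tune_auroc"] for h in history), default=0.0)
        results.append((best, point))
    results.sort(key=lambda r: (-r[0],
                                r[1].get("lambda_rep", 0.5),
                                r[1].get("word_hidden", 50)))
    return results[0][1]
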