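"""Hierarchical attention networks and ablation architectures.

Six architectures share one interface:

``han_text``
    Word-level BiLSTM + attention produces one vector per visit ("sentence");
    a sentence-level BiLSTM + attention produces the patient vector; a linear
    + sigmoid head yields the lung-cancer probability.  A shared affine +
    sigmoid head on the sentence-level recurrent states yields one
    probability per visit for target replication.
``han_combined``
    As ``han_text``, with a ReLU hidden layer on the structured predictors
    (age, sex, windowed ICPC counts) fused to the patient vector by
    concatenation just before the output layer (late fusion).
``hn``
    The hierarchy without attention: both attention layers replaced by mean
    pooling over unmasked states.
``lstm``
    A flat model: a word-level BiLSTM represents each visit by its final
    states, the patient vector is the unweighted mean of visit vectors;
    target replication over visits is kept.
``psgnn``
    Sliding 3-word phrase embeddings -> ReLU hidden layer -> mean over
    phrases -> logistic output.  No hierarchy, no attention, no replication.
``cnn``
    Two ReLU convolution layers (width 3) over the words of each visit with
    max pooling to a visit vector, per-visit replication heads, and max
    pooling over visits to the patient vector.

Word embeddings enter as frozen constants: gradients never reach the
embedding matrix.  All computations are masked so that padding words or
sentences never change any output probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cohort import Document
from .embeddings import EmbeddingModel

__all__ = ["ModelConfig", "DocumentBatch", "ForwardOutput", "build_model",
           "build_ablation", "make_batches", "predict", "predict_proba",
           "feature_matrix", "MODEL_KINDS", "save_checkpoint",
           "load_checkpoint"]

MODEL_KINDS = ("han_text", "han_combined", "hn", "lstm", "psgnn", "cnn")


@dataclass
class ModelConfig:
    kind: str = "han_text"
    embed_dim: int = 100
    word_hidden: int = 50       # per direction
    sent_hidden: int = 50       # per direction
    attn_dim: int = 100
    struct_hidden: int = 16
    n_structured: int = 13
    lambda_rep: float = 0.5
    dropout: float = 0.0
    seed: int = 0
    cnn_channels: int = 32
    psgnn_hidden: int = 32
    kernel: int = 3

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not 0.0 <= self.lambda_rep <= 1.0:
            raise ValueError("lambda_rep must lie in [0, 1]")
        for name in ("embed_dim", "word_hidden", "sent_hidden", "attn_dim",
                     "struct_hidden", "cnn_channels", "psgnn_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DocumentBatch:
    patient_ids: list[str]
    word_vecs: np.ndarray        # B x S x T x D (frozen embeddings)
    word_mask: np.ndarray        # B x S x T
    sent_mask: np.ndarray        # B x S
    flat_vecs: np.ndarray        # B x L x D (sentences concatenated)
    flat_mask: np.ndarray        # B x L
    structured: np.ndarray | None  # B x p
    labels: np.ndarray           # B


@dataclass
class ForwardOutput:
    final_prob: Tensor           # B
    visit_probs: Tensor | None   # B x S (masked positions meaningless)
    visit_mask: np.ndarray | None
    word_attention: np.ndarray | None = None   # B x S x T
    sentence_attention: np.ndarray | None = None  # B x S


# ----------------------------------------------------------------- batching
def make_batches(documents: Sequence[Document], embedding: EmbeddingModel,
                 batch_size: int = 32,
                 include_structured: bool = False) -> list[DocumentBatch]:
    """Embed documents and group them into padded batches.

    Tokens absent from the training vocabulary receive the zero UNK vector;
    padding positions also embed to zero and are excluded by masks.
    """
    aug = np.vstack([np.zeros((1, embedding.dim)), embedding.matrix])
    batches = []
    for start in range(0, len(documents), batch_size):
        chunk = documents[start:start + batch_size]
        batches.append(_embed_chunk(chunk, embedding, aug, include_structured))
    return batches


def _embed_chunk(chunk: Sequence[Document], embedding: EmbeddingModel,
                 aug: np.ndarray, include_structured: bool) -> DocumentBatch:
    B = len(chunk)
    S = max(len(d.sentences) for d in chunk)
    T = max(5, max(len(s) for d in chunk for s in d.sentences))
    L = max(3, max(d.word_count for d in chunk))
    idx = np.zeros((B, S, T), dtype=np.int64)
    wmask = np.zeros((B, S, T))
    smask = np.zeros((B, S))
    fidx = np.zeros((B, L), dtype=np.int64)
    fmask = np.zeros((B, L))
    for b, d in enumerate(chunk):
        pos = 0
        for s, sent in enumerate(d.sentences):
            smask[b, s] = 1.0
            for t, tok in enumerate(sent):
                idx[b, s, t] = embedding.vocab.get(tok, -1) + 1
                wmask[b, s, t] = 1.0
            fidx[b, pos:pos + len(sent)] = idx[b, s, :len(sent)]
            fmask[b, pos:pos + len(sent)] = 1.0
            pos += len(sent)
    struct = None
    if include_structured:
        struct = np.stack([d.structured.as_vector() for d in chunk])
    return DocumentBatch(
        patient_ids=[d.patient_id for d in chunk],
        word_vecs=aug[idx], word_mask=wmask, sent_mask=smask,
        flat_vecs=aug[fidx], flat_mask=fmask,
        structured=struct,
        labels=np.array([d.label for d in chunk], dtype=float),
    )


# ------------------------------------------------------------------- layers
def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape or (fan_in, fan_out))


def _lstm_params(rng, prefix: str, d_in: int, hidden: int) -> dict[str, Tensor]:
    p = {}
    for direction in ("f", "b"):
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0   # forget-gate bias
        p[f"{prefix}_{direction}_Wx"] = Tensor(
            _glorot(rng, d_in, 4 * hidden), requires_grad=True)
        p[f"{prefix}_{direction}_Wh"] = Tensor(
            _glorot(rng, hidden, 4 * hidden), requires_grad=True)
        p[f"{prefix}_{direction}_b"] = Tensor(b, requires_grad=True)
    return p


def _attn_params(rng, prefix: str, d_in: int, attn: int) -> dict[str, Tensor]:
    return {
        f"{prefix}_Wa": Tensor(_glorot(rng, d_in, attn), requires_grad=True),
        f"{prefix}_ba": Tensor(np.zeros(attn), requires_grad=True),
        f"{prefix}_ctx": Tensor(_glorot(rng, attn, 1), requires_grad=True),
    }


def _linear_params(rng, prefix: str, d_in: int, d_out: int) -> dict[str, Tensor]:
    return {
        f"{prefix}_W": Tensor(_glorot(rng, d_in, d_out), requires_grad=True),
        f"{prefix}_b": Tensor(np.zeros(d_out), requires_grad=True),
    }


def _lstm_direction(x: Tensor, mask: np.ndarray, Wx: Tensor, Wh: Tensor,
                    b: Tensor, hidden: int, reverse: bool) -> list[Tensor]:
    """One LSTM direction over x [N,T,D]; masked steps carry state through."""
    N, T = mask.shape
    h = Tensor(np.zeros((N, hidden)))
    c = Tensor(np.zeros((N, hidden)))
    order = range(T - 1, -1, -1) if reverse else range(T)
    states: dict[int, Tensor] = {}
    for t in order:
        xt = x[:, t, :]
        z = xt @ Wx + h @ Wh + b
        i = ad.sigmoid(z[:, 0 * hidden:1 * hidden])
        f = ad.sigmoid(z[:, 1 * hidden:2 * hidden])
        g = ad.tanh(z[:, 2 * hidden:3 * hidden])
        o = ad.sigmoid(z[:, 3 * hidden:4 * hidden])
        c_new = f * c + i * g
        h_new = o * ad.tanh(c_new)
        m = Tensor(mask[:, t:t + 1])
        inv = Tensor(1.0 - mask[:, t:t + 1])
        c = m * c_new + inv * c
        h = m * h_new + inv * h
        states[t] = h
    return [states[t] for t in range(T)]


def _bilstm(params: dict, prefix: str, x: Tensor, mask: np.ndarray,
            hidden: int) -> tuple[Tensor, Tensor]:
    """Returns (states [N,T,2H] fwd||bwd, final [N,2H])."""
    fwd = _lstm_direction(x, mask, params[f"{prefix}_f_Wx"],
                          params[f"{prefix}_f_Wh"], params[f"{prefix}_f_b"],
                          hidden, reverse=False)
    bwd = _lstm_direction(x, mask, params[f"{prefix}_b_Wx"],
                          params[f"{prefix}_b_Wh"], params[f"{prefix}_b_b"],
                          hidden, reverse=True)
    states = ad.concat([ad.stack(fwd, axis=1), ad.stack(bwd, axis=1)], axis=-1)
    final = ad.concat([fwd[-1], bwd[0]], axis=-1)
    return states, final


def _attend(params: dict, prefix: str, states: Tensor,
            mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Projection + tanh + context-vector dot + masked softmax."""
    u = ad.tanh(states @ params[f"{prefix}_Wa"] + params[f"{prefix}_ba"])
    scores = (u @ params[f"{prefix}_ctx"]).reshape(states.shape[0],
                                                   states.shape[1])
    alpha = ad.masked_softmax(scores, mask, axis=1)
    vec = (alpha.reshape(*alpha.shape, 1) * states).sum(axis=1)
    return vec, alpha


def _masked_mean(states: Tensor, mask: np.ndarray) -> Tensor:
    denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
    w = Tensor((mask / denom)[..., None])
    return (w * states).sum(axis=1)


# -------------------------------------------------------------------- model
class RiskModel:
    """Shared interface: params dict + masked forward pass."""

    hierarchical = False
    attention = False
    target_replication = False
    uses_structured = False

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        self.struct_mean = np.zeros(config.n_structured)
        self.struct_std = np.ones(config.n_structured)
        self._build(self.rng)

    def _build(self, rng) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def init_output_bias(self, prevalence: float) -> None:
        """Start output (and visit) heads at the outcome log-odds.

        With a rare outcome the first phase of optimisation is otherwise
        spent moving the bias to the base rate before any discriminative
        learning happens; starting at the training-fold log-odds removes
        that plateau.
        """
        p = float(np.clip(prevalence, 1e-6, 1 - 1e-6))
        logit = float(np.log(p / (1.0 - p)))
        for name in ("out_b", "visit_head_b"):
            if name in self.params:
                self.params[name].data[:] = logit

    def set_struct_scaler(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.struct_mean = np.asarray(mean, dtype=float)
        self.struct_std = np.where(np.asarray(std, dtype=float) > 0, std, 1.0)

    def _check_structured(self, batch: DocumentBatch) -> None:
        if self.uses_structured and batch.structured is None:
            raise ValueError(f"{self.config.kind} requires structured predictors")
        if not self.uses_structured and batch.structured is not None:
            raise ValueError(
                f"structured predictors supplied to text-only model "
                f"{self.config.kind!r}")

    def forward(self, batch: DocumentBatch,
                training: bool = False) -> ForwardOutput:
        raise NotImplementedError

    # --------------------------------------------------------- housekeeping
    def parameter_names(self) -> list[str]:
        return sorted(self.params)

    def get_state(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.params.items()}
        state["__struct_mean__"] = self.struct_mean.copy()
        state["__struct_std__"] = self.struct_std.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()
        if "__struct_mean__" in state:
            self.struct_mean = state["__struct_mean__"].copy()
            self.struct_std = state["__struct_std__"].copy()

    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0:
            return x
        keep = (self.rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)


class HANModel(RiskModel):
    """Hierarchical BiLSTM + attention; ``combined`` adds late fusion."""

    hierarchical = True
    attention = True
    target_replication = True

    def __init__(self, config: ModelConfig):
        self.uses_structured = config.kind == "han_combined"
        super().__init__(config)

    def _build(self, rng) -> None:
        c = self.config
        p = {}
        p.update(_lstm_params(rng, "word", c.embed_dim, c.word_hidden))
        p.update(_attn_params(rng, "word_attn", 2 * c.word_hidden, c.attn_dim))
        p.update(_lstm_params(rng, "sent", 2 * c.word_hidden, c.sent_hidden))
        p.update(_attn_params(rng, "sent_attn", 2 * c.sent_hidden, c.attn_dim))
        p.update(_linear_params(rng, "visit_head", 2 * c.sent_hidden, 1))
        out_in = 2 * c.sent_hidden
        if self.uses_structured:
            p.update(_linear_params(rng, "struct", c.n_structured,
                                    c.struct_hidden))
            out_in += c.struct_hidden
        p.update(_linear_params(rng, "out", out_in, 1))
        self.params = p

    # exposed building blocks -------------------------------------------------
    def encode_sentence(self, word_vectors: np.ndarray,
                        mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Encode one sentence [T,D] -> (sentence vector, word attention)."""
        mask = np.asarray(mask, dtype=float)
        if mask.sum() < 1:
            raise ValueError("cannot encode a fully masked sentence")
        x = Tensor(np.asarray(word_vectors, dtype=float)[None])
        states, _ = _bilstm(self.params, "word", x, mask[None],
                            self.config.word_hidden)
        vec, alpha = _attend(self.params, "word_attn", states, mask[None])
        return vec.data[0], alpha.data[0]

    def encode_document(self, sentence_vectors: np.ndarray,
                        mask: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Encode sentence vectors [S,2Hw] -> (doc vector, visit states,
        sentence attention)."""
        mask = np.asarray(mask, dtype=float)
        if mask.sum() < 1:
            raise ValueError("cannot encode a fully masked document")
        x = Tensor(np.asarray(sentence_vectors, dtype=float)[None])
        states, _ = _bilstm(self.params, "sent", x, mask[None],
                            self.config.sent_hidden)
        vec, alpha = _attend(self.params, "sent_attn", states, mask[None])
        return vec.data[0], states.data[0], alpha.data[0]

    def forward(self, batch: DocumentBatch,
                training: bool = False) -> ForwardOutput:
        self._check_structured(batch)
        c = self.config
        B, S, T, D = batch.word_vecs.shape
        x = Tensor(batch.word_vecs.reshape(B * S, T, D))
        wmask = batch.word_mask.reshape(B * S, T)
        wstates, _ = _bilstm(self.params, "word", x, wmask, c.word_hidden)
        svecs, walpha = _attend(self.params, "word_attn", wstates, wmask)
        svecs = svecs.reshape(B, S, 2 * c.word_hidden)
        sstates, _ = _bilstm(self.params, "sent", svecs, batch.sent_mask,
                             c.sent_hidden)
        doc_vec, salpha = _attend(self.params, "sent_attn", sstates,
                                  batch.sent_mask)
        visit_logit = sstates @ self.params["visit_head_W"] \
            + self.params["visit_head_b"]
        visit_probs = ad.sigmoid(visit_logit.reshape(B, S))
        doc_vec = self._dropout(doc_vec, training)
        if self.uses_structured:
            z = (batch.structured - self.struct_mean) / self.struct_std
            sfeat = ad.relu(Tensor(z) @ self.params["struct_W"]
                            + self.params["struct_b"])
            doc_vec = ad.concat([doc_vec, sfeat], axis=-1)
        logit = doc_vec @ self.params["out_W"] + self.params["out_b"]
        return ForwardOutput(
            final_prob=ad.sigmoid(logit.reshape(B)),
            visit_probs=visit_probs, visit_mask=batch.sent_mask,
            word_attention=walpha.data.reshape(B, S, T),
            sentence_attention=salpha.data,
        )


class HNModel(RiskModel):
    """The hierarchy with attention removed: mean pooling at both levels."""

    hierarchical = True
    attention = False
    target_replication = True

    def _build(self, rng) -> None:
        c = self.config
        p = {}
        p.update(_lstm_params(rng, "word", c.embed_dim, c.word_hidden))
        p.update(_lstm_params(rng, "sent", 2 * c.word_hidden, c.sent_hidden))
        p.update(_linear_params(rng, "visit_head", 2 * c.sent_hidden, 1))
        p.update(_linear_params(rng, "out", 2 * c.sent_hidden, 1))
        self.params = p

    def forward(self, batch: DocumentBatch,
                training: bool = False) -> ForwardOutput:
        self._check_structured(batch)
        c = self.config
        B, S, T, D = batch.word_vecs.shape
        x = Tensor(batch.word_vecs.reshape(B * S, T, D))
        wmask = batch.word_mask.reshape(B * S, T)
        wstates, _ = _bilstm(self.params, "word", x, wmask, c.word_hidden)
        svecs = _masked_mean(wstates, wmask).reshape(B, S, 2 * c.word_hidden)
        sstates, _ = _bilstm(self.params, "sent", svecs, batch.sent_mask,
                             c.sent_hidden)
        doc_vec = _masked_mean(sstates, batch.sent_mask)
        visit_logit = sstates @ self.params["visit_head_W"] \
            + self.params["visit_head_b"]
        doc_vec = self._dropout(doc_vec, training)
        logit = doc_vec @ self.params["out_W"] + self.params["out_b"]
        return ForwardOutput(
            final_prob=ad.sigmoid(logit.reshape(B)),
            visit_probs=ad.sigmoid(visit_logit.reshape(B, S)),
            visit_mask=batch.sent_mask,
        )


class FlatLSTMModel(RiskModel):
    """Visit BiLSTM final states; patient vector = mean of visit vectors."""

    hierarchical = False
    attention = False
    target_replication = True

    def _build(self, rng) -> None:
        c = self.config
        p = {}
        p.update(_lstm_params(rng, "word", c.embed_dim, c.word_hidden))
        p.update(_linear_params(rng, "visit_head", 2 * c.word_hidden, 1))
        p.update(_linear_params(rng, "out", 2 * c.word_hidden, 1))
        self.params = p

    def forward(self, batch: DocumentBatch,
                training: bool = False) -> ForwardOutput:
        self._check_structured(batch)
        c = self.config
        B, S, T, D = batch.word_vecs.shape
        x = Tensor(batch.word_vecs.reshape(B * S, T, D))
        wmask = batch.word_mask.reshape(B * S, T)
        _, final = _bilstm(self.params, "word", x, wmask, c.word_hidden)
        # zero out padding sentences: their "final" state is the zero initial
        # state anyway (mask carries), but be explicit for safety
        svecs = (Tensor(batch.sent_mask.reshape(B * S, 1))
                 * final).reshape(B, S, 2 * c.word_hidden)
        doc_vec = _masked_mean(svecs, batch.sent_mask)
        visit_logit = svecs @ self.params["visit_head_W"] \
            + self.params["visit_head_b"]
        doc_vec = self._dropout(doc_vec, training)
        logit = doc_vec @ self.params["out_W"] + self.params["out_b"]
        return ForwardOutput(
            final_prob=ad.sigmoid(logit.reshape(B)),
            visit_probs=ad.sigmoid(visit_logit.reshape(B, S)),
            visit_mask=batch.sent_mask,
        )


def _windows(x: Tensor, length: int, k: int) -> Tensor:
    """Sliding windows of width k along axis 1, concatenated on features."""
    return ad.concat([x[:, i:length - k + 1 + i, :] for i in range(k)],
                     axis=-1)


def _window_mask(mask: np.ndarray, k: int) -> np.ndarray:
    L = mask.shape[-1]
    out = mask[..., :L - k + 1].copy()
    for i in range(1, k):
        out = out * mask[..., i:L - k + 1 + i]
    return out


class PSGNNModel(RiskModel):
    """Phrase-skip-gram-style network: 3-word phrases -> hidden -> logistic."""

    hierarchical = False
    attention = False
    target_replication = False

    def _build(self, rng) -> None:
        c = self.config
        p = {}
        p.update(_linear_params(rng, "phrase", c.kernel * c.embed_dim,
                                c.psgnn_hidden))
        p.update(_linear_params(rng, "out", c.psgnn_hidden, 1))
        self.params = p

    def phrase_count(self, n_words: int) -> int:
        return max(0, n_words - self.config.kernel + 1)

    def forward(self, batch: DocumentBatch,
                training: bool = False) -> ForwardOutput:
        self._check_structured(batch)
        c = self.config
        B, L, D = batch.flat_vecs.shape
        x = Tensor(batch.flat_vecs)
        w = _windows(x, L, c.kernel)
        h = ad.relu(w @ self.params["phrase_W"] + self.params["phrase_b"])
        pmask = _window_mask(batch.flat_mask, c.kernel)
        pooled = _masked_mean(h, pmask)
        pooled = self._dropout(pooled, training)
        logit = pooled @ self.params["out_W"] + self.params["out_b"]
        return ForwardOutput(final_prob=ad.sigmoid(logit.reshape(B)),
                             visit_probs=None, visit_mask=None)


class CNNModel(RiskModel):
    """Two-layer convolution per visit, max pooling, per-visit replication."""

    hierarchical = True
    attention = False
    target_replication = True

    def _build(self, rng) -> None:
        c = self.config
        p = {}
        p.update(_linear_params(rng, "conv1", c.kernel * c.embed_dim,
                                c.cnn_channels))
        p.update(_linear_params(rng, "conv2", c.kernel * c.cnn_channels,
                                c.cnn_channels))
        p.update(_linear_params(rng, "visit_head", c.cnn_channels, 1))
        p.update(_linear_params(rng, "out", c.cnn_channels, 1))
        self.params = p

    def forward(self, batch: DocumentBatch,
                training: bool = False) -> ForwardOutput:
        self._check_structured(batch)
        c = self.config
        B, S, T, D = batch.word_vecs.shape
        x = Tensor(batch.word_vecs.reshape(B * S, T, D))
        wmask = batch.word_mask.reshape(B * S, T)
        h1 = ad.relu(_windows(x, T, c.kernel) @ self.params["conv1_W"]
                     + self.params["conv1_b"])
        m1 = _window_mask(wmask, c.kernel)
        h2 = ad.relu(_windows(h1, m1.shape[-1], c.kernel)
                     @ self.params["conv2_W"] + self.params["conv2_b"])
        m2 = _window_mask(m1, c.kernel)
        has_any = (m2.sum(axis=-1) > 0).astype(float)[:, None]
        neg = Tensor(((m2 - 1.0) * 1e9)[..., None])
        visit_vec = ad.maxpool(h2 + neg, axis=1) * Tensor(has_any)
        svecs = visit_vec.reshape(B, S, c.cnn_channels)
        visit_logit = svecs @ self.params["visit_head_W"] \
            + self.params["visit_head_b"]
        sneg = Tensor(((batch.sent_mask - 1.0) * 1e9)[..., None])
        doc_vec = ad.maxpool(svecs + sneg, axis=1)
        doc_vec = self._dropout(doc_vec, training)
        logit = doc_vec @ self.params["out_W"] + self.params["out_b"]
        return ForwardOutput(
            final_prob=ad.sigmoid(logit.reshape(B)),
            visit_probs=ad.sigmoid(visit_logit.reshape(B, S)),
            visit_mask=batch.sent_mask,
        )


# ------------------------------------------------------------------ factory
_CLASSES = {
    "han_text": HANModel,
    "han_combined": HANModel,
    "hn": HNModel,
    "lstm": FlatLSTMModel,
    "psgnn": PSGNNModel,
    "cnn": CNNModel,
}


def build_model(config: ModelConfig) -> RiskModel:
    return _CLASSES[config.kind](config)


def build_ablation(kind: str, config: ModelConfig | None = None) -> RiskModel:
    """Construct one of the compared architectures by name."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if config is None:
        config = ModelConfig(kind=kind)
    elif config.kind != kind:
        config = ModelConfig(**{**asdict(config), "kind": kind})
    return build_model(config)


def feature_matrix() -> dict[str, dict[str, bool]]:
    """Architecture capabilities by introspection of the model classes."""
    out = {}
    for kind in MODEL_KINDS:
        cls = _CLASSES[kind]
        attention = cls.attention
        if kind == "hn":
            attention = False
        out[kind] = {
            "hierarchical": cls.hierarchical,
            "attention": attention,
            "target_replication": cls.target_replication,
        }
    return out


def predict(model: RiskModel, batch: DocumentBatch) -> ForwardOutput:
    """Forward pass in evaluation mode."""
    return model.forward(batch, training=False)


def predict_proba(model: RiskModel, documents: Sequence[Document],
                  embedding: EmbeddingModel,
                  batch_size: int = 64) -> np.ndarray:
    """Final probabilities for a document list, in input order."""
    probs = []
    batches = make_batches(documents, embedding, batch_size=batch_size,
                           include_structured=model.uses_structured)
    for batch in batches:
        probs.append(predict(model, batch).final_prob.data)
    return np.concatenate(probs) if probs else np.array([])


# --------------------------------------------------------------- checkpoint
def save_checkpoint(model: RiskModel, path: str | Path) -> None:
    """Parameter dictionary as .npz plus a JSON ModelConfig sidecar."""
    path = Path(path)
    np.savez(path, **model.get_state())
    sidecar = path.with_suffix(".config.json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path) -> RiskModel:
    path = Path(path)
    cfg = ModelConfig(**json.loads(
        path.with_suffix(".config.json").read_text()))
    model = build_model(cfg)
    with np.load(path if path.suffix == ".npz"
                 else path.with_suffix(".npz")) as data:
        model.set_state({k: data[k] for k in data.files})
    return model
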