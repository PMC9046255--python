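"""Protein language-model embedders.

Defines the embedder contract used by the hybrid models, the attribution
code, the zero-shot variant scorer and the contact probe:

* per-residue embeddings ``L x h`` (special tokens stripped),
* a pooled [CLS] representation for sequence-only heads,
* amino-acid probability distributions at masked positions (all requested
  positions masked simultaneously in a single forward pass),
* row-stochastic self-attention maps per (layer, head).

:class:`StubProteinLM` is a deterministic, seed-initialised 2-layer,
2-head transformer that satisfies the full contract on CPU in milliseconds,
so every downstream component is testable without multi-gigabyte pretrained
weights. :class:`PretrainedLMAdapter` exposes the same contract over a
HuggingFace ``transformers`` masked LM when that optional dependency is
installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import (Linear, LayerNorm, Module, Parameter, Tensor, concat,
                       log_softmax, matmul, no_grad, softmax, take_rows, tanh)
from .structure_io import AA_ALPHABET, AA_TO_INDEX

CLS, SEP, MASK = "[CLS]", "[SEP]", "[MASK]"
VOCAB = list(AA_ALPHABET) + [CLS, SEP, MASK]
TOKEN_TO_ID = {t: i for i, t in enumerate(VOCAB)}


@dataclass
class EmbeddingMatrix:
    """L x h per-residue embeddings with provenance."""

    values: np.ndarray
    source: str = "stub"        # "stub" | "pretrained"
    layer_index: int = -1       # hidden layer the embeddings were read from

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embeddings must be a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite embeddings")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class TokenDistribution:
    """Amino-acid probability vectors at masked positions (1-based)."""

    positions: list[int]
    probs: np.ndarray           # (m, 21), rows sum to 1
    alphabet: str = AA_ALPHABET

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(self.positions), len(self.alphabet)):
            raise ValueError("probability table shape mismatch")
        if np.any(self.probs <= 0) or np.any(
                np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("rows must be strictly positive and sum to 1")

    def prob_of(self, position: int, aa: str) -> float:
        i = self.positions.index(position)
        return float(self.probs[i, self.alphabet.index(aa)])


@dataclass
class AttentionMaps:
    """Per (layer, head) L x L row-stochastic attention, specials stripped."""

    maps: np.ndarray            # (n_layers, n_heads, L, L)
    source: str = "stub"

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 4:
            raise ValueError("expected (layers, heads, L, L)")
        rows = self.maps.sum(axis=-1)
        if np.any(np.abs(rows - 1.0) > 1e-4):
            raise ValueError("attention rows must sum to 1 after stripping")

    @property
    def n_layers(self):
        return self.maps.shape[0]

    @property
    def n_heads(self):
        return self.maps.shape[1]

    @property
    def length(self):
        return self.maps.shape[2]


def validate_sequence(aa: str) -> None:
    if len(aa) < 1:
        raise ValueError("empty sequence")
    for i, ch in enumerate(aa):
        if ch not in AA_TO_INDEX:
            raise ValueError(f"invalid amino-acid character {ch!r} at position {i + 1}")


def _sinusoidal_positions(n: int, h: int) -> np.ndarray:
    pos = np.arange(n, dtype=np.float64)[:, None]
    m = np.arange(h // 2, dtype=np.float64)
    freqs = 1.0 / (10000.0 ** (2.0 * m / h))
    args = pos * freqs
    out = np.zeros((n, h))
    out[:, 0::2] = np.sin(args)
    out[:, 1::2] = np.cos(args)
    return out


class _TransformerLayer(Module):
    def __init__(self, h: int, n_heads: int, rng: np.random.Generator):
        if h % n_heads:
            raise ValueError("hidden width must divide the head count")
        self.h, self.n_heads, self.d_head = h, n_heads, h // n_heads
        self.Wq = Linear(h, h, rng)
        self.Wk = Linear(h, h, rng)
        self.Wv = Linear(h, h, rng)
        self.Wo = Linear(h, h, rng)
        self.ff1 = Linear(h, 2 * h, rng)
        self.ff2 = Linear(2 * h, h, rng)
        self.norm1 = LayerNorm(h)
        self.norm2 = LayerNorm(h)

    def __call__(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        T = x.shape[0]
        q, k, v = self.Wq(x), self.Wk(x), self.Wv(x)
        heads, attn_rows = [], []
        scale = 1.0 / np.sqrt(self.d_head)
        for head in range(self.n_heads):
            sl = slice(head * self.d_head, (head + 1) * self.d_head)
            qs, ks, vs = q[:, sl], k[:, sl], v[:, sl]
            scores = ad.mul(matmul(qs, ks.T), scale)
            attn = softmax(scores, axis=-1)
            attn_rows.append(attn.data.copy())
            heads.append(matmul(attn, vs))
        merged = concat(heads, axis=-1)
        x = self.norm1(ad.add(x, self.Wo(merged)))
        x = self.norm2(ad.add(x, self.ff2(ad.relu(self.ff1(x)))))
        return x, np.stack(attn_rows)  # (n_heads, T, T)


class StubProteinLM(Module):
    """Deterministic mini-transformer satisfying the embedder contract.

    Random but seed-fixed weights; no pretraining. The token-embedding table
    is permanently excluded from gradient flow (fine-tuning touches only the
    transformer layers and heads), matching how the hybrid models fine-tune
    a pretrained LM.
    """

    def __init__(self, h: int = 16, n_layers: int = 2, n_heads: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.h, self.n_layers, self.n_heads = h, n_layers, n_heads
        self.seed = seed
        self.token_embedding = Parameter(rng.normal(0.0, 1.0, size=(len(VOCAB), h)))
        self.token_embedding.requires_grad = False  # never fine-tuned
        self.layers = [_TransformerLayer(h, n_heads, rng) for _ in range(n_layers)]
        self.pooler = Linear(h, h, rng)
        self.mlm_head = Linear(h, len(AA_ALPHABET), rng)

    # ------------------------------------------------------------- plumbing
    def tokenize(self, aa: str, masked_positions: set[int] | None = None) -> np.ndarray:
        validate_sequence(aa)
        masked = masked_positions or set()
        ids = [TOKEN_TO_ID[CLS]]
        for i, ch in enumerate(aa, start=1):
            ids.append(TOKEN_TO_ID[MASK] if i in masked else TOKEN_TO_ID[ch])
        ids.append(TOKEN_TO_ID[SEP])
        return np.asarray(ids, dtype=np.intp)

    def forward_tokens(self, token_ids: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Hidden states (T, h) and stacked attention (layers, heads, T, T).

        Builds an autodiff graph; wrap in ``no_grad()`` for inference.
        """
        x = ad.add(take_rows(self.token_embedding, token_ids),
                   Tensor(_sinusoidal_positions(len(token_ids), self.h)))
        maps = []
        for layer in self.layers:
            x, attn = layer(x)
            maps.append(attn)
        return x, np.stack(maps)

    def set_transformer_trainable(self, trainable: bool) -> None:
        """Freeze/unfreeze the transformer layers (embedding table stays frozen)."""
        for layer in self.layers:
            for p in layer.parameters():
                p.requires_grad = trainable
        for p in self.pooler.parameters() + self.mlm_head.parameters():
            p.requires_grad = trainable

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    # ------------------------------------------------------------- contract
    def embed_tensor(self, aa: str) -> Tensor:
        """Per-residue hidden states as a graph-attached Tensor (L, h)."""
        hidden, _ = self.forward_tokens(self.tokenize(aa))
        return hidden[1:len(aa) + 1]

    def embed(self, aa: str) -> EmbeddingMatrix:
        with no_grad():
            values = self.embed_tensor(aa).data
        return EmbeddingMatrix(values=values, source="stub",
                               layer_index=self.n_layers - 1)

    def pooled_cls_tensor(self, aa: str) -> Tensor:
        hidden, _ = self.forward_tokens(self.tokenize(aa))
        cls_row = hidden[0:1]  # keep 2-D for the linear map
        return ad.reshape(tanh(self.pooler(cls_row)), (self.h,))

    def pooled_cls(self, aa: str) -> np.ndarray:
        with no_grad():
            return self.pooled_cls_tensor(aa).data

    def masked_logprobs(self, aa: str, masked_positions) -> TokenDistribution:
        positions = sorted(set(int(p) for p in masked_positions))
        if not positions:
            raise ValueError("empty masked-position set")
        validate_sequence(aa)
        for p in positions:
            if not 1 <= p <= len(aa):
                raise ValueError(f"masked position {p} outside [1, {len(aa)}]")
        ids = self.tokenize(aa, masked_positions=set(positions))
        with no_grad():
            hidden, _ = self.forward_tokens(ids)
            logits = self.mlm_head(hidden)
            logp = log_softmax(logits, axis=-1).data
        probs = np.exp(logp[[p for p in positions], :])  # token row p == residue p
        return TokenDistribution(positions=positions, probs=probs)

    def attention_maps(self, aa: str) -> AttentionMaps:
        """Self-attention over residues; special-token rows/columns stripped
        and rows renormalised."""
        ids = self.tokenize(aa)
        with no_grad():
            _, maps = self.forward_tokens(ids)
        inner = maps[:, :, 1:len(aa) + 1, 1:len(aa) + 1]
        inner = inner / inner.sum(axis=-1, keepdims=True)
        return AttentionMaps(maps=inner, source="stub")


class PretrainedLMAdapter:
    """Same contract over a HuggingFace masked protein LM (optional).

    Requires the ``transformers`` package and local model weights; the
    deterministic stub is the reference implementation for offline use, and
    both are exercised by one shared conformance suite.
    """

    def __init__(self, model_name_or_path: str, layer_index: int = -1):
        try:
            import torch  # noqa: F401
            from transformers import AutoModelForMaskedLM, AutoTokenizer
        except ImportError as err:  # pragma: no cover - optional dependency
            raise ImportError(
                "PretrainedLMAdapter requires the optional 'transformers' and "
                "'torch' packages (pip install geoprot[lm])") from err
        self._torch = __import__("torch")
        self.tokenizer = AutoTokenizer.from_pretrained(model_name_or_path)
        self.model = AutoModelForMaskedLM.from_pretrained(
            model_name_or_path, output_hidden_states=True,
            output_attentions=True)
        self.model.eval()
        self.layer_index = layer_index

    def _forward(self, aa: str, masked_positions: set[int] | None = None):
        tokens = " ".join(
            MASK if masked_positions and i in masked_positions else ch
            for i, ch in enumerate(aa, start=1))
        enc = self.tokenizer(tokens, return_tensors="pt")
        with self._torch.no_grad():
            return enc, self.model(**enc)

    def embed(self, aa: str) -> EmbeddingMatrix:
        validate_sequence(aa)
        _, out = self._forward(aa)
        hidden = out.hidden_states[self.layer_index][0, 1:len(aa) + 1]
        return EmbeddingMatrix(values=hidden.numpy().astype(np.float64),
                               source="pretrained", layer_index=self.layer_index)

    def masked_logprobs(self, aa: str, masked_positions) -> TokenDistribution:
        positions = sorted(set(int(p) for p in masked_positions))
        if not positions:
            raise ValueError("empty masked-position set")
        _, out = self._forward(aa, set(positions))
        logits = out.logits[0]
        rows = []
        for p in positions:
            token_logits = logits[p]
            aa_ids = [self.tokenizer.convert_tokens_to_ids(c) for c in AA_ALPHABET]
            row = self._torch.softmax(token_logits[aa_ids], dim=-1).numpy()
            rows.append(row / row.sum())
        return TokenDistribution(positions=positions, probs=np.array(rows))

    def attention_maps(self, aa: str) -> AttentionMaps:
        validate_sequence(aa)
        _, out = self._forward(aa)
        maps = np.stack([a[0].numpy() for a in out.attentions])
        inner = maps[:, :, 1:len(aa) + 1, 1:len(aa) + 1].astype(np.float64)
        inner = inner / inner.sum(axis=-1, keepdims=True)
        return AttentionMaps(maps=inner, source="pretrained")


# ----------------------------------------------------------- op-style façade
def embed_sequence(aa: str, model) -> EmbeddingMatrix:
    """Per-residue embeddings from any embedder satisfying the contract."""
    return model.embed(aa)


def pooled_cls(aa: str, model) -> np.ndarray:
    """Pooled [CLS] representation for sequence-only heads."""
    return model.pooled_cls(aa)


def masked_logprobs(aa: str, masked_positions, model) -> TokenDistribution:
    """Distributions at masked positions, all masked in one forward pass."""
    return model.masked_logprobs(aa, masked_positions)
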