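"""A compact NumPy encoder–decoder transformer for reaction prediction.

This module defines the predictor contract every interpretation method in
the toolkit consumes, and a desk-scale reference implementation of it: a
pre-layer-norm transformer with sinusoidal positions, trained by
teacher-forced cross-entropy with Adam.  It is small enough to train on a
single CPU in minutes on the synthetic regioselectivity corpora, while
exposing exactly the quantities the interpretation methods need:

* ``embed`` — the token-embedding matrix of a source sequence (the ``x`` of
  the attribution path integral; positions are added inside the forward
  pass so that the baseline input passes through the same code path);
* ``encoder_states`` — final encoder states, one row per source token;
* ``sequence_probability`` — the teacher-forced product of per-token
  conditional probabilities of a target sequence (end-of-sequence
  included), a differentiable function of the source embeddings;
* ``gradient`` — the gradient of that probability with respect to the
  source embedding matrix.

The output projection is zero-initialized, so an untrained model assigns
the uniform distribution over the vocabulary at every step.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from rdkit import Chem

from .autodiff import Tensor, gather_rows, layer_norm, softmax, take_along_last
from .reaction_io import ReactionRecord, TokenizedInput, tokenize_smiles

__all__ = [
    "Vocabulary",
    "ReferenceModelConfig",
    "PredictorContract",
    "TransformerPredictor",
    "DecodeResult",
    "train_reference_model",
    "sequence_probability",
    "greedy_decode",
    "exact_match_accuracy",
    "augment_records",
    "VocabularyError",
]

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"


class VocabularyError(KeyError):
    """A token that is not in the model's vocabulary."""


@dataclass(frozen=True)
class Vocabulary:
    """Token <-> index map with ``<pad>``/``<bos>``/``<eos>`` specials."""

    tokens: tuple[str, ...]

    @classmethod
    def build(cls, sequences) -> "Vocabulary":
        seen = sorted({t for seq in sequences for t in seq})
        return cls(tokens=(PAD, BOS, EOS, *seen))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def encode(self, seq: Sequence[str]) -> np.ndarray:
        idx = self.index
        try:
            return np.array([idx[t] for t in seq], dtype=np.int64)
        except KeyError as exc:
            raise VocabularyError(f"token {exc.args[0]!r} not in vocabulary") from exc

    def decode(self, ids) -> list[str]:
        return [self.tokens[int(i)] for i in ids]


@dataclass
class ReferenceModelConfig:
    """Hyper-parameters of the reference model.

    ``d_model`` defaults to 256 to match the latent width the retrieval
    module assumes, but any positive width works; the desk-scale presets
    used in the tests shrink it for speed.
    """

    d_model: int = 256
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 512
    seed: int = 0
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    max_decode_len: int = 120
    max_len: int = 512
    dtype: str = "float64"  # "float32" halves training time at toy scale

    def __post_init__(self) -> None:
        for name in ("d_model", "n_layers", "n_heads", "d_ff", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@runtime_checkable
class PredictorContract(Protocol):
    """What every interpretation method needs from a predictor."""

    vocabulary: Vocabulary

    def embed(self, tokens: Sequence[str]) -> np.ndarray: ...

    def encoder_states(self, src_embedding: np.ndarray) -> np.ndarray: ...

    def sequence_probability(self, source, target: Sequence[str]) -> float: ...

    def gradient(self, src_embedding: np.ndarray, target: Sequence[str]) -> np.ndarray: ...


@dataclass
class DecodeResult:
    tokens: list[str]
    complete: bool  # False when the length cap was hit before <eos>

    @property
    def smiles(self) -> str:
        return "".join(self.tokens)


def _positional_encoding(max_len: int, d: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.zeros((max_len, d))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


def _init(rng: np.random.Generator, *shape, dtype=np.float64) -> Tensor:
    scale = 1.0 / math.sqrt(shape[0])
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(dtype), requires_grad=True)


def _zeros(*shape, dtype=np.float64) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def _ones(*shape, dtype=np.float64) -> Tensor:
    return Tensor(np.ones(shape, dtype=dtype), requires_grad=True)


class _AttentionBlock:
    def __init__(self, rng, d, dtype):
        self.wq, self.wk, self.wv, self.wo = (_init(rng, d, d, dtype=dtype) for _ in range(4))

    def params(self):
        return [self.wq, self.wk, self.wv, self.wo]


class _FeedForward:
    def __init__(self, rng, d, d_ff, dtype):
        self.w1, self.b1 = _init(rng, d, d_ff, dtype=dtype), _zeros(d_ff, dtype=dtype)
        self.w2, self.b2 = _init(rng, d_ff, d, dtype=dtype), _zeros(d, dtype=dtype)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.w1 + self.b1).relu() @ self.w2 + self.b2


class _Norm:
    def __init__(self, d, dtype):
        self.g, self.b = _ones(d, dtype=dtype), _zeros(d, dtype=dtype)

    def params(self):
        return [self.g, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.g, self.b)


def _attend(block: _AttentionBlock, q_in: Tensor, kv_in: Tensor, n_heads: int,
            mask: np.ndarray | None) -> Tensor:
    """Multi-head scaled dot-product attention.  ``mask`` is additive."""
    *lead, tq, d = q_in.shape
    tk = kv_in.shape[-2]
    dh = d // n_heads
    b = lead[0] if lead else 1

    def split(x: Tensor, t: int) -> Tensor:
        return x.reshape(b, t, n_heads, dh).transpose(0, 2, 1, 3)

    q3 = q_in.reshape(b, tq, d)
    k3 = kv_in.reshape(b, tk, d)
    q = split(q3 @ block.wq, tq)
    k = split(k3 @ block.wk, tk)
    v = split(k3 @ block.wv, tk)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
    if mask is not None:
        scores = scores + mask
    att = softmax(scores, axis=-1)
    ctx = (att @ v).transpose(0, 2, 1, 3).reshape(b, tq, d)
    out = ctx @ block.wo
    return out if lead else out.reshape(tq, d)


class _EncoderLayer:
    def __init__(self, rng, d, d_ff, dtype):
        self.attn = _AttentionBlock(rng, d, dtype)
        self.ff = _FeedForward(rng, d, d_ff, dtype)
        self.n1, self.n2 = _Norm(d, dtype), _Norm(d, dtype)

    def params(self):
        return self.attn.params() + self.ff.params() + self.n1.params() + self.n2.params()

    def __call__(self, x, n_heads, mask):
        h = self.n1(x)
        x = x + _attend(self.attn, h, h, n_heads, mask)
        return x + self.ff(self.n2(x))


class _DecoderLayer:
    def __init__(self, rng, d, d_ff, dtype):
        self.self_attn = _AttentionBlock(rng, d, dtype)
        self.cross_attn = _AttentionBlock(rng, d, dtype)
        self.ff = _FeedForward(rng, d, d_ff, dtype)
        self.n1, self.n2, self.n3 = _Norm(d, dtype), _Norm(d, dtype), _Norm(d, dtype)

    def params(self):
        return (self.self_attn.params() + self.cross_attn.params() + self.ff.params()
                + self.n1.params() + self.n2.params() + self.n3.params())

    def __call__(self, x, memory, n_heads, causal_mask, mem_mask):
        h = self.n1(x)
        x = x + _attend(self.self_attn, h, h, n_heads, causal_mask)
        x = x + _attend(self.cross_attn, self.n2(x), memory, n_heads, mem_mask)
        return x + self.ff(self.n3(x))


_NEG = -1e9


class TransformerPredictor:
    """The reference predictor.  Satisfies :class:`PredictorContract`."""

    def __init__(self, config: ReferenceModelConfig, vocabulary: Vocabulary):
        self.config = config
        self.vocabulary = vocabulary
        rng = np.random.default_rng(config.seed)
        d, v = config.d_model, len(vocabulary)
        dt = np.dtype(config.dtype).type
        self._dtype = dt
        self.src_embed = _init(rng, v, d, dtype=dt)
        self.tgt_embed = _init(rng, v, d, dtype=dt)
        # zero-initialized output head: the untrained model is uniform
        self.w_out = _zeros(d, v, dtype=dt)
        self.b_out = _zeros(v, dtype=dt)
        self.enc_layers = [_EncoderLayer(rng, d, config.d_ff, dt)
                           for _ in range(config.n_layers)]
        self.dec_layers = [_DecoderLayer(rng, d, config.d_ff, dt)
                           for _ in range(config.n_layers)]
        self.enc_norm, self.dec_norm = _Norm(d, dt), _Norm(d, dt)
        self._pos = _positional_encoding(config.max_len, d).astype(dt)
        self._scale = float(math.sqrt(d))

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = [self.src_embed, self.tgt_embed, self.w_out, self.b_out]
        for layer in self.enc_layers + self.dec_layers:
            ps += layer.params()
        ps += self.enc_norm.params() + self.dec_norm.params()
        return ps

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        h.update("\x00".join(self.vocabulary.tokens).encode())
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()[:16]

    # -- contract --------------------------------------------------------
    @staticmethod
    def _tokens(source) -> list[str]:
        if isinstance(source, TokenizedInput):
            return list(source.tokens)
        return list(source)

    def embed(self, tokens) -> np.ndarray:
        """Token-embedding matrix (N x d), positions not yet added."""
        ids = self.vocabulary.encode(self._tokens(tokens))
        return self.src_embed.data[ids].copy()

    def baseline_embedding(self, n: int, token: str = ".") -> np.ndarray:
        """The embedding of ``token`` repeated ``n`` times (N x d)."""
        i = self.vocabulary.encode([token])[0]
        return np.tile(self.src_embed.data[i], (n, 1))

    def _encode_from(self, src_emb: Tensor, mask=None) -> Tensor:
        t = src_emb.shape[-2]
        x = src_emb * self._scale + self._pos[:t]
        for layer in self.enc_layers:
            x = layer(x, self.config.n_heads, mask)
        return self.enc_norm(x)

    def encoder_states(self, src_embedding) -> np.ndarray:
        """Final encoder states (N x d) for a source embedding matrix or
        a token sequence / :class:`TokenizedInput`."""
        if isinstance(src_embedding, np.ndarray):
            emb = Tensor(src_embedding)
        else:
            emb = Tensor(self.embed(src_embedding))
        return self._encode_from(emb).data

    def _decode_logits(self, memory: Tensor, tgt_in_ids: np.ndarray,
                       mem_mask=None) -> Tensor:
        t = len(tgt_in_ids)
        x = gather_rows(self.tgt_embed, tgt_in_ids) * self._scale + self._pos[:t]
        causal = np.triu(np.full((t, t), _NEG, dtype=self._dtype), k=1)
        for layer in self.dec_layers:
            x = layer(x, memory, self.config.n_heads, causal, mem_mask)
        return self.dec_norm(x) @ self.w_out + self.b_out

    def _step_log_probs(self, logits: Tensor, label_ids: np.ndarray) -> Tensor:
        shift = logits - logits.data.max(axis=-1, keepdims=True)
        log_z = shift.exp().sum(axis=-1).log()
        return take_along_last(shift, label_ids) - log_z

    def seq_log_prob_tensor(self, src_emb: Tensor, target) -> Tensor:
        """Differentiable log of the teacher-forced sequence probability."""
        vocab = self.vocabulary
        tgt_ids = vocab.encode(self._tokens(target))
        bos, eos = vocab.encode([BOS])[0], vocab.encode([EOS])[0]
        tgt_in = np.concatenate([[bos], tgt_ids]).astype(np.int64)
        labels = np.concatenate([tgt_ids, [eos]]).astype(np.int64)
        memory = self._encode_from(src_emb)
        logits = self._decode_logits(memory, tgt_in)
        return self._step_log_probs(logits, labels).sum()

    def seq_prob_tensor(self, src_emb: Tensor, target) -> Tensor:
        return self.seq_log_prob_tensor(src_emb, target).exp()

    def sequence_probability(self, source, target) -> float:
        """Teacher-forced product of conditional probabilities, in [0, 1]."""
        emb = Tensor(self.embed(source))
        return float(self.seq_prob_tensor(emb, target).data)

    def gradient(self, src_embedding: np.ndarray, target) -> np.ndarray:
        """d sequence_probability / d source embedding (same shape as input)."""
        emb = Tensor(src_embedding, requires_grad=True)
        self.seq_prob_tensor(emb, target).backward()
        return emb.grad

    # -- decoding --------------------------------------------------------
    def next_token_distribution(self, source, prefix) -> np.ndarray:
        """P(next token | source, prefix) over the vocabulary; sums to 1."""
        vocab = self.vocabulary
        emb = Tensor(self.embed(source))
        memory = self._encode_from(emb)
        bos = vocab.encode([BOS])[0]
        tgt_in = np.concatenate([[bos], vocab.encode(self._tokens(prefix))]).astype(np.int64)
        logits = self._decode_logits(memory, tgt_in).data[-1]
        e = np.exp(logits - logits.max())
        return e / e.sum()

    def greedy_decode(self, source) -> DecodeResult:
        vocab = self.vocabulary
        emb = Tensor(self.embed(source))
        memory = self._encode_from(emb)
        bos, eos = vocab.encode([BOS])[0], vocab.encode([EOS])[0]
        ids = [int(bos)]
        for _ in range(self.config.max_decode_len):
            logits = self._decode_logits(memory, np.array(ids, dtype=np.int64)).data[-1]
            nxt = int(np.argmax(logits))
            if nxt == eos:
                return DecodeResult(tokens=vocab.decode(ids[1:]), complete=True)
            ids.append(nxt)
        return DecodeResult(tokens=vocab.decode(ids[1:]), complete=False)

    def greedy_decode_batch(self, sources) -> list[DecodeResult]:
        """Greedy-decode many sources at once (same result as per-sequence
        :meth:`greedy_decode`, batched for speed)."""
        vocab = self.vocabulary
        seqs = [vocab.encode(self._tokens(s)) for s in sources]
        b = len(seqs)
        ts = max(len(s) for s in seqs)
        src = _pad_batch(seqs, ts)
        src_mask = np.where(src == 0, _NEG, 0.0).astype(self._dtype)[:, None, None, :]
        x = gather_rows(self.src_embed, src) * self._scale + self._pos[:ts]
        for layer in self.enc_layers:
            x = layer(x, self.config.n_heads, src_mask)
        memory = self.enc_norm(x)

        bos, eos = vocab.encode([BOS])[0], vocab.encode([EOS])[0]
        ids = np.full((b, 1), bos, dtype=np.int64)
        done = np.zeros(b, dtype=bool)
        for _ in range(self.config.max_decode_len):
            t = ids.shape[1]
            y = gather_rows(self.tgt_embed, ids) * self._scale + self._pos[:t]
            causal = np.triu(np.full((t, t), _NEG, dtype=self._dtype), k=1)[None, None]
            tgt_pad = np.where(ids == 0, _NEG, 0.0).astype(self._dtype)[:, None, None, :]
            h = y
            for layer in self.dec_layers:
                h = layer(h, memory, self.config.n_heads, causal + tgt_pad, src_mask)
            logits = (self.dec_norm(h) @ self.w_out + self.b_out).data[:, -1]
            nxt = logits.argmax(axis=-1)
            nxt[done] = 0  # finished rows emit pad, hidden from attention
            newly = (~done) & (nxt == eos)
            done |= newly
            nxt[newly] = 0
            ids = np.concatenate([ids, nxt[:, None]], axis=1)
            if done.all():
                break
        out = []
        for i in range(b):
            toks = [int(t) for t in ids[i, 1:] if t != 0]
            out.append(DecodeResult(tokens=vocab.decode(toks), complete=bool(done[i])))
        return out

    # -- batched training forward ---------------------------------------
    def _batch_loss(self, src: np.ndarray, tgt_in: np.ndarray,
                    labels: np.ndarray, label_mask: np.ndarray) -> Tensor:
        """Mean cross-entropy over non-pad label positions of a batch."""
        b, ts = src.shape
        tt = tgt_in.shape[1]
        src_mask = np.where(src == 0, _NEG, 0.0).astype(self._dtype)[:, None, None, :]
        x = gather_rows(self.src_embed, src) * self._scale + self._pos[:ts]
        for layer in self.enc_layers:
            x = layer(x, self.config.n_heads, src_mask)
        memory = self.enc_norm(x)

        y = gather_rows(self.tgt_embed, tgt_in) * self._scale + self._pos[:tt]
        causal = np.triu(np.full((tt, tt), _NEG, dtype=self._dtype), k=1)[None, None]
        tgt_pad = np.where(tgt_in == 0, _NEG, 0.0).astype(self._dtype)[:, None, None, :]
        for layer in self.dec_layers:
            y = layer(y, memory, self.config.n_heads, causal + tgt_pad, src_mask)
        logits = self.dec_norm(y) @ self.w_out + self.b_out
        lp = self._step_log_probs(logits, labels)
        masked = lp * label_mask
        return -(masked.sum() / label_mask.sum())

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sidecar = {
            "config": asdict(self.config),
            "vocabulary": list(self.vocabulary.tokens),
            "fingerprint": self.fingerprint(),
        }
        (directory / "config.json").write_text(json.dumps(sidecar, indent=1))
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "TransformerPredictor":
        directory = Path(directory)
        sidecar = json.loads((directory / "config.json").read_text())
        config = ReferenceModelConfig(**sidecar["config"])
        model = cls(config, Vocabulary(tokens=tuple(sidecar["vocabulary"])))
        with np.load(directory / "weights.npz") as npz:
            for i, p in enumerate(model.parameters()):
                p.data = npz[f"p{i}"].astype(model._dtype)
        if model.fingerprint() != sidecar["fingerprint"]:
            raise ValueError("checkpoint fingerprint mismatch after load")
        return model


# -- module-level convenience wrappers (the spec's operation surface) ----

def sequence_probability(model: PredictorContract, source, target) -> float:
    return model.sequence_probability(source, target)


def greedy_decode(model: TransformerPredictor, source) -> DecodeResult:
    return model.greedy_decode(source)


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _pad_batch(seqs: list[np.ndarray], width: int) -> np.ndarray:
    out = np.zeros((len(seqs), width), dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def train_reference_model(pairs, config: ReferenceModelConfig,
                          vocabulary: Vocabulary | None = None,
                          epoch_callback=None) -> TransformerPredictor:
    """Train the reference model on ``pairs`` of (source, target) token lists.

    Fully deterministic given ``config.seed``: initialization, shuffling and
    every update are driven by one generator.  ``epoch_callback(epoch, model)``
    is invoked after each epoch (used by the bias experiment to record
    prediction proportions over training).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training corpus")
    if vocabulary is None:
        vocabulary = Vocabulary.build([s for s, _ in pairs] + [t for _, t in pairs])
    model = TransformerPredictor(config, vocabulary)
    rng = np.random.default_rng(config.seed + 1)
    bos, eos = vocabulary.encode([BOS])[0], vocabulary.encode([EOS])[0]

    enc = []
    for s, t in pairs:
        sid = vocabulary.encode(s)
        tid = vocabulary.encode(t)
        enc.append((sid, np.concatenate([[bos], tid]), np.concatenate([tid, [eos]])))

    opt = _Adam(model.parameters(), config.learning_rate)
    n = len(enc)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = [enc[i] for i in order[start : start + config.batch_size]]
            ws = max(len(b[0]) for b in batch)
            wt = max(len(b[1]) for b in batch)
            src = _pad_batch([b[0] for b in batch], ws)
            tgt_in = _pad_batch([b[1] for b in batch], wt)
            labels = _pad_batch([b[2] for b in batch], wt)
            label_mask = (labels != 0).astype(model._dtype)
            opt.zero_grad()
            loss = model._batch_loss(src, tgt_in, labels, label_mask)
            loss.backward()
            opt.step()
        opt.lr *= config.lr_decay
        if epoch_callback is not None:
            epoch_callback(epoch + 1, model)
    return model


def exact_match_accuracy(model: TransformerPredictor, pairs) -> float:
    """Top-1 exact-match rate of greedy decodes against reference targets."""
    pairs = list(pairs)
    hits = 0
    for s, t in pairs:
        out = model.greedy_decode(s)
        hits += out.complete and out.tokens == list(t)
    return hits / len(pairs)


def augment_records(records: list[ReactionRecord], seed: int) -> list[ReactionRecord]:
    """Double a corpus with random-equivalent SMILES spellings of each side."""
    out = list(records)
    for i, r in enumerate(records):
        def rand(smiles_list):
            res = []
            for j, s in enumerate(smiles_list):
                mol = Chem.MolFromSmiles(s)
                v = Chem.MolToRandomSmilesVect(mol, 1, randomSeed=seed + 7919 * i + j)
                res.append(v[0])
            return res
        out.append(
            ReactionRecord(
                id=f"{r.id}-aug",
                reactants=rand(r.reactants),
                reagents=rand(r.reagents),
                products=rand(r.products),
                metadata=dict(r.metadata),
            )
        )
    return out
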