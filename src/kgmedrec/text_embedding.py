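"""Skip-gram word embeddings and a GRU sentence encoder for symptom text.

The word model is the classic skip-gram with a *full softmax* objective:
for a center word w_I the probability of observing word j at a context
position is

    p(w_j | w_I) = exp(u_j) / sum_{j'} exp(u_{j'}),   u = W_out^T W_in[w_I]

and the loss of an observed context is its negative log-likelihood
    -sum_c u_{j*_c} + |context| * log sum_j exp(u_j).

Vocabularies here are tiny by construction, so the exact softmax is
affordable and there is no need for negative sampling.

Document vectors use a single-layer GRU encoder in the Skip-Thought style:
the final hidden state after reading the token vectors is the sentence
vector.  An optional pretraining mode attaches two GRU decoders that
predict the previous and next sentence of a document stream; a mean-pooling
fallback is also provided and flagged in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, Adam
from .errors import DivergenceError, VocabularyError

__all__ = [
    "Vocabulary", "SkipGramModel", "TextConfig", "GRUEncoder",
    "build_vocab", "context_prob", "skipgram_loss", "train_skipgram",
    "encode_sentence", "encode_documents", "train_skipthought",
]


def tokenize(text: str) -> list[str]:
    return text.lower().split()


@dataclass
class Vocabulary:
    index: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.index)

    def __getitem__(self, token: str) -> int:
        try:
            return self.index[token]
        except KeyError:
            raise VocabularyError(f"unknown token {token!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.index


@dataclass
class TextConfig:
    dim: int = 16            # word-vector dimension
    window: int = 2          # context radius C
    min_count: int = 1
    hidden: int = 16         # GRU sentence dimension
    lr: float = 0.05
    epochs: int = 10
    batch_size: int = 256
    seed: int = 0


@dataclass
class SkipGramModel:
    vocab: Vocabulary
    w_in: np.ndarray          # (V, d) input embeddings
    w_out: np.ndarray         # (d, V) output weights
    window: int = 2

    def scores(self, token: str) -> np.ndarray:
        """The V output scores u for a center token."""
        return self.w_in[self.vocab[token]] @ self.w_out

    def vector(self, token: str) -> np.ndarray:
        return self.w_in[self.vocab[token]]

    @staticmethod
    def init_random(vocab: Vocabulary, config: TextConfig) -> "SkipGramModel":
        rng = np.random.default_rng(config.seed)
        V, d = vocab.size, config.dim
        return SkipGramModel(vocab,
                             rng.uniform(-0.5 / d, 0.5 / d, (V, d)),
                             rng.uniform(-0.5 / d, 0.5 / d, (d, V)),
                             window=config.window)


def build_vocab(corpus, min_count: int = 1) -> Vocabulary:
    """Frequency-then-lexicographic deterministic vocabulary."""
    texts = [corpus] if isinstance(corpus, str) else list(corpus)
    freq: dict[str, int] = {}
    for text in texts:
        for tok in tokenize(text):
            freq[tok] = freq.get(tok, 0) + 1
    kept = sorted((t for t, c in freq.items() if c >= min_count),
                  key=lambda t: (-freq[t], t))
    if not kept:
        raise ValueError("vocabulary is empty after min_count filtering")
    return Vocabulary({t: i for i, t in enumerate(kept)})


def context_prob(model: SkipGramModel, input_word: str, target_word: str) -> float:
    """Softmax probability of `target_word` in the context of `input_word`."""
    u = model.scores(input_word)
    u = u - u.max()
    p = np.exp(u) / np.exp(u).sum()
    return float(p[model.vocab[target_word]])


def skipgram_loss(model: SkipGramModel, center_word: str,
                  context_words: list[str]) -> float:
    """Negative log-likelihood of the observed context (full softmax)."""
    u = model.scores(center_word)
    m = u.max()
    lse = m + np.log(np.exp(u - m).sum())
    targets = [model.vocab[w] for w in context_words]
    return float(len(targets) * lse - sum(u[j] for j in targets))


def _pairs(texts: list[str], vocab: Vocabulary, window: int) -> np.ndarray:
    out = []
    for text in texts:
        toks = [vocab.index[t] for t in tokenize(text) if t in vocab]
        for i, c in enumerate(toks):
            for j in range(max(0, i - window), min(len(toks), i + window + 1)):
                if j != i:
                    out.append((c, toks[j]))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def train_skipgram(corpus, config: TextConfig | None = None,
                   ) -> tuple[SkipGramModel, list[float]]:
    """Full-softmax skip-gram training; returns model and per-epoch mean NLL."""
    config = config or TextConfig()
    texts = [corpus] if isinstance(corpus, str) else list(corpus)
    vocab = build_vocab(texts, config.min_count)
    model = SkipGramModel.init_random(vocab, config)
    pairs = _pairs(texts, vocab, config.window)
    if pairs.size == 0:
        raise ValueError("corpus has no skip-gram pairs at this window size")

    Win = Tensor.param(model.w_in, "w_in")
    Wout = Tensor.param(model.w_out, "w_out")
    opt = Adam([Win, Wout], lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        total, count = 0.0, 0
        for start in range(0, len(pairs), config.batch_size):
            sel = pairs[order[start:start + config.batch_size]]
            centers, targets = sel[:, 0], sel[:, 1]
            opt.zero_grad()
            u = Win.gather(centers) @ Wout            # (B, V)
            lse = u.logsumexp(axis=-1)                # (B,)
            picked = (u * Tensor(np.eye(vocab.size)[targets])).sum(axis=-1)
            loss = (lse - picked).mean()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sel)
            count += len(sel)
        mean = total / count
        if not np.isfinite(mean):
            raise DivergenceError(epoch, mean)
        trace.append(mean)
    model.w_in, model.w_out = Win.data, Wout.data
    return model, trace


# ---------------------------------------------------------------------------
# GRU sentence encoder (Skip-Thought style)
# ---------------------------------------------------------------------------

@dataclass
class GRUEncoder:
    """Single-layer GRU; the final hidden state is the sentence vector."""

    w_z: np.ndarray; u_z: np.ndarray; b_z: np.ndarray
    w_r: np.ndarray; u_r: np.ndarray; b_r: np.ndarray
    w_h: np.ndarray; u_h: np.ndarray; b_h: np.ndarray

    @property
    def hidden(self) -> int:
        return self.b_z.size

    @staticmethod
    def init_random(dim_in: int, hidden: int, seed: int = 0) -> "GRUEncoder":
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(hidden)

        def w():
            return rng.uniform(-s, s, (dim_in, hidden))

        def u():
            return rng.uniform(-s, s, (hidden, hidden))

        return GRUEncoder(w(), u(), np.zeros(hidden),
                          w(), u(), np.zeros(hidden),
                          w(), u(), np.zeros(hidden))

    def params(self) -> list[np.ndarray]:
        return [self.w_z, self.u_z, self.b_z, self.w_r, self.u_r, self.b_r,
                self.w_h, self.u_h, self.b_h]

    def step(self, x: np.ndarray, h: np.ndarray) -> np.ndarray:
        z = _sig(x @ self.w_z + h @ self.u_z + self.b_z)
        r = _sig(x @ self.w_r + h @ self.u_r + self.b_r)
        h_tilde = np.tanh(x @ self.w_h + (r * h) @ self.u_h + self.b_h)
        return (1.0 - z) * h + z * h_tilde

    def encode(self, vectors: np.ndarray) -> np.ndarray:
        """Run the GRU over (T, d) token vectors; return final hidden state."""
        h = np.zeros(self.hidden)
        for x in vectors:
            h = self.step(x, h)
        return h


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def encode_sentence(document: str, word_model: SkipGramModel,
                    encoder: GRUEncoder | None = None,
                    mode: str = "gru") -> np.ndarray:
    """Document -> vector via GRU final state, or mean pooling (`mode="mean"`)."""
    toks = [t for t in tokenize(document) if t in word_model.vocab]
    if not toks:
        raise ValueError("cannot encode an empty document")
    vecs = np.stack([word_model.vector(t) for t in toks])
    if mode == "mean":
        return vecs.mean(axis=0)
    if mode != "gru":
        raise ValueError(f"unknown mode {mode!r}")
    if encoder is None:
        raise ValueError("GRU mode requires an encoder")
    return encoder.encode(vecs)


def encode_documents(documents: dict[str, str], word_model: SkipGramModel,
                     encoder: GRUEncoder | None = None, mode: str = "gru",
                     ) -> tuple[dict[str, np.ndarray], dict]:
    """Encode every document; the metadata header records the mode used."""
    vectors = {eid: encode_sentence(text, word_model, encoder, mode)
               for eid, text in documents.items()}
    dim = next(iter(vectors.values())).size if vectors else 0
    return vectors, {"mode": mode, "dim": dim}


def train_skipthought(sentences: list[str], word_model: SkipGramModel,
                      hidden: int = 16, lr: float = 0.05, epochs: int = 5,
                      seed: int = 0) -> tuple[GRUEncoder, list[float]]:
    """Optional Skip-Thought pretraining of the GRU encoder.

    Two GRU decoders, seeded with the encoder's final state, predict the
    tokens of the previous and the next sentence of the stream (teacher
    forcing over frozen word vectors, full-softmax output layer).  Returns
    the trained encoder and the per-epoch mean decoder NLL.
    """
    d = word_model.w_in.shape[1]
    V = word_model.vocab.size
    enc = GRUEncoder.init_random(d, hidden, seed)
    dec_prev = GRUEncoder.init_random(d, hidden, seed + 1)
    dec_next = GRUEncoder.init_random(d, hidden, seed + 2)
    rng = np.random.default_rng(seed + 3)
    s = 1.0 / np.sqrt(hidden)
    proj = rng.uniform(-s, s, (hidden, V))  # shared decoder output layer

    tensors = {}

    def lift(arrs, tag):
        out = []
        for i, a in enumerate(arrs):
            t = Tensor.param(a, f"{tag}{i}")
            out.append(t)
            tensors[f"{tag}{i}"] = t
        return out

    enc_p = lift(enc.params(), "e")
    prev_p = lift(dec_prev.params(), "p")
    next_p = lift(dec_next.params(), "n")
    proj_t = Tensor.param(proj, "proj")
    opt = Adam(list(tensors.values()) + [proj_t], lr=lr)

    def gru_step(ps, x, h):
        wz, uz, bz, wr, ur, br, wh, uh, bh = ps
        z = (x @ wz + h @ uz + bz).sigmoid()
        r = (x @ wr + h @ ur + br).sigmoid()
        ht = (x @ wh + (r * h) @ uh + bh).tanh()
        return (1.0 - z) * h + z * ht

    def run(ps, vecs, h0):
        h = h0
        states = []
        for x in vecs:
            h = gru_step(ps, Tensor(x), h)
            states.append(h)
        return h, states

    sent_vecs = []
    sent_ids = []
    for s_ in sentences:
        toks = [t for t in tokenize(s_) if t in word_model.vocab]
        if toks:
            sent_vecs.append(np.stack([word_model.vector(t) for t in toks]))
            sent_ids.append(np.array([word_model.vocab[t] for t in toks]))
    if len(sent_vecs) < 3:
        raise ValueError("skip-thought pretraining needs >= 3 encodable sentences")

    trace: list[float] = []
    for epoch in range(epochs):
        total, count = 0.0, 0
        for i in range(1, len(sent_vecs) - 1):
            opt.zero_grad()
            h_enc, _ = run(enc_p, sent_vecs[i], Tensor(np.zeros(hidden)))
            loss_terms = []
            for ps, j in ((prev_p, i - 1), (next_p, i + 1)):
                # decoder reads gold token vectors, predicts each next token
                h = h_enc
                inputs = [np.zeros(d)] + list(sent_vecs[j][:-1])
                _, states = run(ps, inputs, h)
                for st, target in zip(states, sent_ids[j]):
                    u = st @ proj_t
                    loss_terms.append(u.logsumexp(axis=-1)
                                      - (u * Tensor(np.eye(V)[target])).sum())
            loss = loss_terms[0]
            for lt in loss_terms[1:]:
                loss = loss + lt
            loss = loss * (1.0 / len(loss_terms))
            loss.backward()
            opt.step()
            total += float(loss.data)
            count += 1
        mean = total / count
        if not np.isfinite(mean):
            raise DivergenceError(epoch, mean)
        trace.append(mean)

    for arr, t in zip(enc.params(), enc_p):
        arr[...] = t.data
    return enc, trace
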