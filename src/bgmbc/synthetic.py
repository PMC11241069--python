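"""Synthetic study data: class-conditional report text, a stub encoder, encoded datasets.

The real corpus behind this method — two-column patient tables of free-text
histopathology reports labelled metastatic / non-metastatic — is private
clinical data.  This module generates stand-ins with the statistical
structure the pipeline relies on:

* two classes whose reports differ in vocabulary (metastasis-flavoured
  marker phrases at elevated rates in class 1) and in length, so that both
  the pooled-embedding features and the attention-derived node scores carry
  class signal;
* a deterministic *stub encoder* — a transformer-shaped function with
  fixed pseudo-random parameters and softmax-normalised attentions — so the
  whole pipeline runs with no model download; and
* directly generated encoded datasets (Gaussian features with class-shifted
  informative dimensions, class-conditional attention scores) that bypass
  text entirely for fast tests.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .encoder import (
    CLS_ID,
    PAD_ID,
    EncoderOutput,
    ReportRecord,
    TokenisedReport,
)

__all__ = [
    "SyntheticConfig",
    "StubEncoder",
    "stub_encoder",
    "generate_reports",
    "generate_encoded_dataset",
]

# Neutral histology vocabulary shared by both classes.
_NEUTRAL_TERMS = (
    "specimen received formalin fixed paraffin embedded sections show breast "
    "tissue with ducts and lobules stroma fibrous adipose unremarkable "
    "margins inked grossly measuring cm aggregate fragments core biopsy "
    "microscopy reveals epithelium myoepithelial layer preserved benign "
    "ductal hyperplasia usual type scattered microcalcifications present "
    "immunohistochemistry performed receptor status oestrogen progesterone "
    "her2 ki67 index nuclear grade tubule formation mitotic count scored"
).split()

# Marker phrases enriched in metastatic (class 1) reports.
_CLASS1_PHRASES = (
    "metastatic carcinoma deposits identified",
    "lymphovascular invasion present",
    "axillary lymph node involved by tumour",
    "extranodal extension noted",
    "perineural invasion seen",
    "poorly differentiated invasive carcinoma infiltrating",
)

# Benign phrases enriched in non-metastatic (class 0) reports.
_CLASS0_PHRASES = (
    "no evidence of malignancy",
    "reactive follicular hyperplasia only",
    "fibroadenoma with intracanalicular pattern",
    "clear resection margins free of tumour",
    "benign breast parenchyma",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic corpus and encoded-dataset generators.

    Defaults mirror the study conditions the pipeline targets: 1000
    patient nodes, balanced classes, 767-wide embedding features with a
    handful of informative dimensions, and class-separated report lengths
    that straddle the tokeniser's 512-token window.
    """

    n_records: int = 1000
    class_balance: float = 0.5  # fraction of class-1 (metastatic) records
    length_range_class0: tuple[int, int] = (20, 140)  # words per report
    length_range_class1: tuple[int, int] = (180, 520)
    phrase_rate_class1: float = 0.08  # marker phrases per word position
    phrase_rate_class0: float = 0.04
    n_features: int = 767
    n_informative: int = 5
    effect_size: float = 3.0  # class mean shift on informative dims, in sd units
    noise_scale: float = 1.0
    score_loc: tuple[float, float] = (150.0, 450.0)  # class-conditional score means
    score_scale: tuple[float, float] = (40.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 2:
            raise ValueError("need at least two records")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


def generate_reports(cfg: SyntheticConfig) -> tuple[list[ReportRecord], np.ndarray]:
    """Generate a labelled synthetic report corpus.

    Class-1 reports are longer and contain metastasis-flavoured marker
    phrases at an elevated rate; class-0 reports are shorter with benign
    phrasing.  Returns the records plus an int array of labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([101, cfg.seed]))
    n1 = int(round(cfg.class_balance * cfg.n_records))
    labels = np.zeros(cfg.n_records, dtype=np.int64)
    labels[:n1] = 1
    rng.shuffle(labels)
    records: list[ReportRecord] = []
    for i, y in enumerate(labels):
        lo, hi = cfg.length_range_class1 if y == 1 else cfg.length_range_class0
        n_words = int(rng.integers(lo, hi + 1))
        rate = cfg.phrase_rate_class1 if y == 1 else cfg.phrase_rate_class0
        phrases = _CLASS1_PHRASES if y == 1 else _CLASS0_PHRASES
        words: list[str] = []
        while len(words) < n_words:
            if rng.random() < rate:
                words.extend(rng.choice(phrases).split())
            else:
                words.append(rng.choice(_NEUTRAL_TERMS))
        records.append(
            ReportRecord(record_id=f"MR{i:05d}", text=" ".join(words[:n_words]))
        )
    return records, labels


class StubEncoder:
    """Deterministic transformer-shaped encoder with fixed random parameters.

    Token embeddings plus sinusoidal positions pass through ``n_layers`` of
    multi-head scaled-dot-product self-attention with residual updates.
    Attention rows for non-pad queries are softmax-normalised over the real
    (non-pad) keys; pad queries receive a uniform distribution over real
    keys so every row of the returned stack sums to one.  All parameters
    are drawn once from the seed, so the same input is encoded bit-identically
    on every call.
    """

    def __init__(
        self,
        hidden_size: int = 768,
        n_layers: int = 2,
        n_heads: int = 2,
        seed: int = 0,
        vocab_size: int = 8192,
        head_dim: int | None = None,
    ) -> None:
        if hidden_size < 1:
            raise ValueError("hidden size must be >= 1")
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.seed = seed
        self.vocab_size = vocab_size
        self.head_dim = head_dim or max(1, min(32, hidden_size // n_heads))
        rng = np.random.default_rng(np.random.SeedSequence([7, seed]))
        scale = 1.0 / np.sqrt(hidden_size)
        self._emb = rng.standard_normal((vocab_size, hidden_size)).astype(np.float32)
        self._emb *= scale
        dk = self.head_dim
        self._wq = rng.standard_normal((n_layers, n_heads, hidden_size, dk)).astype(np.float32) * scale
        self._wk = rng.standard_normal((n_layers, n_heads, hidden_size, dk)).astype(np.float32) * scale
        self._wv = rng.standard_normal((n_layers, n_heads, hidden_size, dk)).astype(np.float32) * scale
        self._wo = rng.standard_normal((n_layers, n_heads * dk, hidden_size)).astype(np.float32) * scale

    @staticmethod
    def _positions(n: int, d: int) -> np.ndarray:
        pos = np.arange(n, dtype=np.float32)[:, None]
        dim = np.arange(d, dtype=np.float32)[None, :]
        angle = pos / np.power(10000.0, (2 * (dim // 2)) / d)
        enc = np.where(dim % 2 == 0, np.sin(angle), np.cos(angle))
        return enc.astype(np.float32) / np.sqrt(d)

    def encode(self, tok: TokenisedReport) -> EncoderOutput:
        """Encode one tokenised report; see :class:`bgmbc.encoder.EncoderOutput`."""
        mask = tok.pad_mask
        n = int(mask.sum())
        if n == 0:
            raise ValueError("cannot encode a fully padded report")
        max_len = tok.token_ids.shape[0]
        # Work on the real-token prefix only; pads are purely structural.
        ids = tok.token_ids[:n]
        x = self._emb[ids] + self._positions(n, self.hidden_size)
        stack = np.zeros(
            (self.n_layers, self.n_heads, max_len, max_len), dtype=np.float64
        )
        dk = self.head_dim
        for layer in range(self.n_layers):
            head_outs = []
            for h in range(self.n_heads):
                q = x @ self._wq[layer, h]
                k = x @ self._wk[layer, h]
                v = x @ self._wv[layer, h]
                logits = (q @ k.T) / np.sqrt(dk)
                logits -= logits.max(axis=1, keepdims=True)
                a = np.exp(logits)
                a /= a.sum(axis=1, keepdims=True)
                stack[layer, h, :n, :n] = a
                # pad queries: uniform over real keys, keeping every row normalised
                if n < max_len:
                    stack[layer, h, n:, :n] = 1.0 / n
                head_outs.append(a.astype(np.float32) @ v)
            update = np.concatenate(head_outs, axis=1) @ self._wo[layer]
            x = x + update
            # RMS-normalise per token to keep activations on a stable scale
            x = x / np.sqrt(np.mean(np.square(x), axis=1, keepdims=True) + 1e-6)
        emb = np.zeros((max_len, self.hidden_size), dtype=np.float64)
        emb[:n] = x
        return EncoderOutput(token_embeddings=emb, attention_stack=stack)


@lru_cache(maxsize=8)
def stub_encoder(
    hidden_size: int = 768,
    n_layers: int = 2,
    n_heads: int = 2,
    seed: int = 0,
    vocab_size: int = 8192,
) -> StubEncoder:
    """Build (and cache) a deterministic stub encoder for the given geometry."""
    return StubEncoder(
        hidden_size=hidden_size,
        n_layers=n_layers,
        n_heads=n_heads,
        seed=seed,
        vocab_size=vocab_size,
    )


def generate_encoded_dataset(cfg: SyntheticConfig):
    """Generate an already-encoded dataset, bypassing text and encoder.

    Features are Gaussian noise with class-shifted means on
    ``n_informative`` randomly chosen dimensions (shift = ``effect_size``
    standard deviations); attention scores are drawn from class-conditional
    normals with configurable overlap, floored at zero.

    Returns ``(table, scores, informative_dims)`` where ``table`` is a
    :class:`bgmbc.selection.FeatureTable` (which carries the labels).
    """
    from .selection import FeatureTable

    rng = np.random.default_rng(np.random.SeedSequence([202, cfg.seed]))
    n, p = cfg.n_records, cfg.n_features
    n1 = int(round(cfg.class_balance * n))
    y = np.zeros(n, dtype=np.int64)
    y[:n1] = 1
    rng.shuffle(y)
    x = rng.standard_normal((n, p)) * cfg.noise_scale
    dims = np.sort(rng.choice(p, size=cfg.n_informative, replace=False))
    if dims.size:
        x[y == 1][:, dims]  # no-op guard for empty class
        x[np.ix_(y == 1, dims)] += cfg.effect_size * cfg.noise_scale
    loc0, loc1 = cfg.score_loc
    sc0, sc1 = cfg.score_scale
    scores = np.where(
        y == 1,
        rng.normal(loc1, sc1, size=n),
        rng.normal(loc0, sc0, size=n),
    )
    scores = np.maximum(scores, 0.0)
    table = FeatureTable(
        X=x,
        y=y,
        column_ids=[f"f{j}" for j in range(p)],
        record_ids=[f"MR{i:05d}" for i in range(n)],
    )
    return table, scores, dims
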