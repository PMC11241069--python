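"""Report encoding: tokenisation, transformer outputs, pooled features, attention scores.

Each free-text histopathology report is tokenised to a fixed-width id
sequence, pushed through a transformer-shaped encoder, and reduced to

* one fixed-width feature vector — the mean of the last-hidden-state token
  embeddings over real (non-pad) tokens, truncated to ``feature_width``
  components (default 767); and
* one scalar *node attention score* — by default the masked sum of the
  layer- and head-averaged token-to-token attention matrix.  Because every
  non-pad query row of that matrix is softmax-normalised, the sum sits on
  the scale of the report's token count, which is the scale on which the
  graph builder's score-gap threshold (default 200) is meaningful.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReportRecord",
    "TokenisedReport",
    "EncoderOutput",
    "ReportFeatures",
    "NodeAttentionScore",
    "EncoderConfig",
    "BlankReportError",
    "EncoderConfigError",
    "tokenise_report",
    "encode_report",
    "mean_embedding",
    "extract_report_features",
    "head_mean_attention",
    "node_attention_score",
]

PAD_ID, CLS_ID, SEP_ID, UNK_ID = 0, 1, 2, 3
N_SPECIAL = 4

_WORD_RE = re.compile(r"[a-z0-9]+")


class BlankReportError(ValueError):
    """Raised when a report is empty after normalisation."""


class EncoderConfigError(ValueError):
    """Raised for invalid or unloadable encoder configurations."""


@dataclass(frozen=True)
class ReportRecord:
    """One patient: an opaque medical-record identifier plus raw report text."""

    record_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")


@dataclass(frozen=True)
class TokenisedReport:
    """Fixed-width token id sequence with a pad mask (True = real token)."""

    token_ids: np.ndarray
    pad_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.token_ids.shape != self.pad_mask.shape:
            raise ValueError("token_ids and pad_mask must share a shape")

    @property
    def length(self) -> int:
        """Number of real (non-pad) tokens N."""
        return int(self.pad_mask.sum())


@dataclass(frozen=True)
class EncoderOutput:
    """Last-hidden-state embeddings plus the full attention stack.

    ``token_embeddings`` is (max_len, d); ``attention_stack`` is
    (layers, heads, max_len, max_len) with softmax-normalised rows for
    every non-pad query.
    """

    token_embeddings: np.ndarray
    attention_stack: np.ndarray

    def __post_init__(self) -> None:
        if self.token_embeddings.ndim != 2 or self.attention_stack.ndim != 4:
            raise ValueError("bad encoder output shapes")
        n = self.token_embeddings.shape[0]
        if self.attention_stack.shape[2:] != (n, n):
            raise ValueError("attention stack does not match sequence length")


@dataclass(frozen=True)
class ReportFeatures:
    """One report reduced to a fixed-width feature vector."""

    values: np.ndarray
    record_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("report features must be finite")


@dataclass(frozen=True)
class NodeAttentionScore:
    """Scalar attention score for one report/node (unitless, >= 0 by default)."""

    score: float
    record_id: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("attention score must be finite")


@dataclass(frozen=True)
class EncoderConfig:
    """Which encoder to run and how to reduce its outputs.

    ``name=None`` selects the deterministic stub encoder parameterised by
    ``stub_seed``; a non-None name refers to a pretrained transformer, for
    which no backend ships with this package.
    """

    name: str | None = None
    stub_seed: int = 0
    hidden_size: int = 768
    n_layers: int = 2
    n_heads: int = 2
    max_len: int = 512
    feature_width: int = 767
    vocab_size: int = 8192
    score_mode: str = "sum"  # sum | mean | cls_row_sum

    def __post_init__(self) -> None:
        if self.feature_width > self.hidden_size:
            raise EncoderConfigError(
                f"feature_width {self.feature_width} exceeds hidden size {self.hidden_size}"
            )
        if self.score_mode not in ("sum", "mean", "cls_row_sum"):
            raise EncoderConfigError(f"unknown score_mode {self.score_mode!r}")


def _word_pieces(word: str, piece_len: int = 4, head_len: int = 8) -> list[str]:
    """Split a long word into subword pieces of at most ``piece_len`` chars."""
    if len(word) <= head_len:
        return [word]
    head, rest = word[:head_len], word[head_len:]
    return [head] + ["##" + rest[i : i + piece_len] for i in range(0, len(rest), piece_len)]


def _piece_id(piece: str, vocab_size: int) -> int:
    return N_SPECIAL + zlib.crc32(piece.encode("utf-8")) % (vocab_size - N_SPECIAL)


def tokenise_report(
    text: str,
    max_len: int = 512,
    *,
    vocab_size: int = 8192,
    keep_blank: bool = False,
) -> TokenisedReport:
    """Tokenise one report into a padded/truncated fixed-width id sequence.

    Lowercases, splits on non-alphanumerics, breaks long words into subword
    pieces, hashes each piece into a fixed vocabulary, and brackets the
    sequence with start/separator tokens.  Deterministic: the same text
    always yields the same ids.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2 (room for special tokens)")
    words = _WORD_RE.findall(text.lower())
    if not words and not keep_blank:
        raise BlankReportError("blank report: no tokens after normalisation")
    ids = [CLS_ID]
    for w in words:
        for piece in _word_pieces(w):
            ids.append(_piece_id(piece, vocab_size))
        if len(ids) >= max_len - 1:
            break
    ids = ids[: max_len - 1]
    ids.append(SEP_ID)
    n = len(ids)
    token_ids = np.full(max_len, PAD_ID, dtype=np.int64)
    token_ids[:n] = ids
    pad_mask = np.zeros(max_len, dtype=bool)
    pad_mask[:n] = True
    return TokenisedReport(token_ids=token_ids, pad_mask=pad_mask)


def encode_report(tok: TokenisedReport, encoder: "EncoderConfig") -> EncoderOutput:
    """Run the configured encoder over one tokenised report.

    Only the deterministic stub backend is available; naming a pretrained
    encoder raises :class:`EncoderConfigError`.
    """
    if encoder.name is not None:
        raise EncoderConfigError(
            f"cannot load encoder {encoder.name!r}: no pretrained-transformer backend "
            "is available; use the stub encoder (name=None)"
        )
    from .synthetic import stub_encoder

    enc = stub_encoder(
        hidden_size=encoder.hidden_size,
        n_layers=encoder.n_layers,
        n_heads=encoder.n_heads,
        seed=encoder.stub_seed,
        vocab_size=encoder.vocab_size,
    )
    return enc.encode(tok)


def mean_embedding(token_embeddings: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
    """Mean-pool token embeddings over the N real (non-pad) tokens."""
    mask = np.asarray(pad_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise BlankReportError("empty report: no non-pad tokens to pool")
    return np.asarray(token_embeddings)[mask].sum(axis=0) / n


def extract_report_features(
    rec: ReportRecord,
    encoder: EncoderConfig,
    feature_width: int | None = None,
) -> ReportFeatures:
    """Encode one report and reduce it to a fixed-width feature vector.

    The vector is the mean-pooled last hidden state truncated to its first
    ``feature_width`` components (default from the config: 767 of the
    768-wide hidden state).
    """
    width = encoder.feature_width if feature_width is None else feature_width
    if width > encoder.hidden_size:
        raise EncoderConfigError(
            f"feature_width {width} exceeds hidden size {encoder.hidden_size}"
        )
    tok = tokenise_report(rec.text, encoder.max_len, vocab_size=encoder.vocab_size)
    out = encode_report(tok, encoder)
    pooled = mean_embedding(out.token_embeddings, tok.pad_mask)
    return ReportFeatures(values=pooled[:width].copy(), record_id=rec.record_id)


def head_mean_attention(layer_attn: np.ndarray) -> np.ndarray:
    """Average an (H, n, n) per-head attention block over its H heads."""
    a = np.asarray(layer_attn)
    if a.ndim != 3:
        raise ValueError("expected an (H, n, n) attention block")
    if a.shape[0] < 1:
        raise ValueError("need at least one head")
    return a.mean(axis=0)


def node_attention_score(
    out: EncoderOutput,
    pad_mask: np.ndarray,
    *,
    record_id: str = "",
    mode: str = "sum",
) -> NodeAttentionScore:
    """Reduce a report's attention stack to one scalar node score.

    The stack is averaged over layers and heads, pad rows and columns are
    masked out, and the surviving entries are reduced by ``mode``:

    ``sum`` (default)
        total masked attention mass; equals the non-pad token count when no
        key masking is applied, so scores live on the token-count scale.
    ``mean``
        masked mean (softmax scale, <= 1).
    ``cls_row_sum``
        masked sum of the start-token query row only.
    """
    mask = np.asarray(pad_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise BlankReportError("empty report: no non-pad tokens")
    avg = out.attention_stack.mean(axis=(0, 1))  # heads then layers: flat mean
    sub = avg[np.ix_(mask, mask)]
    if mode == "sum":
        score = float(sub.sum())
    elif mode == "mean":
        score = float(sub.mean())
    elif mode == "cls_row_sum":
        score = float(sub[0].sum())
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return NodeAttentionScore(score=score, record_id=record_id)
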