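"""Text cleaning, TF-IDF vocabulary truncation, splitting and encoding.

The pipeline brings raw multi-label text into :class:`~curribatch.corpus.LabeledCorpus`
form and then into integer-encoded arrays:

1. lowercase, strip punctuation, split on whitespace, drop digit-only tokens
   and stopwords;
2. rank tokens by a corpus-level TF-IDF score and keep the top-k (10,000 by
   default) as the vocabulary;
3. shuffle-split into train/val/test at 7:1:2;
4. encode documents as token-id sequences (unknown id 0) and label sets as
   multi-hot vectors over the corpus label catalog.
"""

from __future__ import annotations

import importlib.resources
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import LabeledCorpus

UNK_ID = 0

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def default_stopwords() -> frozenset[str]:
    """The packaged English stopword list (overridable in every caller)."""
    text = (
        importlib.resources.files("curribatch")
        .joinpath("data/stopwords.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_stopwords(path: str | Path) -> frozenset[str]:
    text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


def clean_and_tokenize(
    raw_text: str, stopword_list: Iterable[str] | None = None
) -> list[str]:
    """Lowercase, remove punctuation/numbers/stopwords, split on whitespace.

    "Numbers removed" means tokens consisting solely of digits once
    punctuation has been stripped.
    """
    stopwords = (
        default_stopwords() if stopword_list is None else set(stopword_list)
    )
    tokens = raw_text.lower().translate(_PUNCT_TABLE).split()
    return [t for t in tokens if not t.isdigit() and t not in stopwords]


@dataclass
class Vocabulary:
    """The kept tokens after TF-IDF truncation; id 0 is reserved for unknowns."""

    tokens: tuple[str, ...]
    token_to_id: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.tokens = tuple(self.tokens)
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary contains duplicate tokens")
        self.token_to_id = {t: i + 1 for i, t in enumerate(self.tokens)}

    @property
    def retained_size(self) -> int:
        return len(self.tokens)

    @property
    def n_ids(self) -> int:
        """Number of integer ids including the unknown id."""
        return len(self.tokens) + 1

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for tok, i in self.token_to_id.items():
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        pairs = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    tok, i = line.rstrip("\n").split("\t")
                    pairs.append((int(i), tok))
        pairs.sort()
        return cls(tuple(tok for _, tok in pairs))


def tfidf_scores(corpus: LabeledCorpus) -> dict[str, tuple[float, int]]:
    """Corpus-level TF-IDF per token: (total term frequency) × ln(N/df).

    Returns token → (score, total term frequency). Natural log, no smoothing:
    a token present in every document scores exactly 0.
    """
    n_docs = len(corpus)
    tf: dict[str, int] = {}
    df: dict[str, int] = {}
    for ex in corpus.examples:
        seen = set()
        for tok in ex.tokens:
            tf[tok] = tf.get(tok, 0) + 1
            if tok not in seen:
                seen.add(tok)
                df[tok] = df.get(tok, 0) + 1
    return {
        tok: (tf[tok] * math.log(n_docs / df[tok]), tf[tok]) for tok in tf
    }


def build_vocabulary(corpus: LabeledCorpus, top_k: int = 10_000) -> Vocabulary:
    """Rank tokens by corpus-level TF-IDF and keep the top-k.

    Ties broken by total term frequency (higher first), then lexicographic.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    scores = tfidf_scores(corpus)
    ranked = sorted(scores, key=lambda t: (-scores[t][0], -scores[t][1], t))
    return Vocabulary(tuple(ranked[:top_k]))


@dataclass
class SplitSpec:
    """Train/val/test shuffle-split ratios (default 7:1:2) and seed."""

    train: float = 0.7
    val: float = 0.1
    test: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("ratios must be non-negative")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


def split_corpus(
    corpus: LabeledCorpus, spec: SplitSpec
) -> tuple[LabeledCorpus, LabeledCorpus, LabeledCorpus]:
    """Seeded shuffle-split; val and test get the floored shares, train the rest."""
    n = len(corpus)
    if n < 3:
        raise ValueError("need at least 3 examples to split")
    n_val = int(spec.val * n)
    n_test = int(spec.test * n)
    n_train = n - n_val - n_test
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    ids = [corpus.examples[i].doc_id for i in perm]
    return (
        corpus.subset(ids[:n_train]),
        corpus.subset(ids[n_train : n_train + n_val]),
        corpus.subset(ids[n_train + n_val :]),
    )


@dataclass
class EncodedCorpus:
    """Integer-encoded corpus: token-id sequences + multi-hot label matrix."""

    doc_ids: tuple[str, ...]
    token_ids: list[np.ndarray]
    label_matrix: np.ndarray  # (n_examples, |catalog|) in {0,1}
    label_catalog: tuple[str, ...]
    vocab: Vocabulary

    def __len__(self) -> int:
        return len(self.doc_ids)

    @property
    def n_labels(self) -> int:
        return len(self.label_catalog)

    @property
    def doc_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.doc_ids)}

    def label_frequencies(self) -> np.ndarray:
        """Number of examples carrying each label (for long-tail thresholds)."""
        return self.label_matrix.sum(axis=0)


def encode(corpus: LabeledCorpus, vocab: Vocabulary) -> EncodedCorpus:
    """Map tokens to ids (OOV → unknown id 0) and label sets to multi-hot rows."""
    catalog = corpus.label_catalog
    index = corpus.label_index
    token_ids = []
    labels = np.zeros((len(corpus), len(catalog)), dtype=np.int8)
    for i, ex in enumerate(corpus.examples):
        if not ex.labels:  # unreachable via Example, but encode owns the contract
            raise ValueError(f"example {ex.doc_id!r} has an empty label set")
        token_ids.append(
            np.fromiter((vocab.id_of(t) for t in ex.tokens), dtype=np.int64)
        )
        for lab in ex.labels:
            labels[i, index[lab]] = 1
    return EncodedCorpus(
        tuple(ex.doc_id for ex in corpus.examples),
        token_ids,
        labels,
        catalog,
        vocab,
    )
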