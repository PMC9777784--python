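"""Synthetic long-tailed multi-label corpus generator.

Emulates the statistical shape of a large coded clinical-note collection:
thousands of labels with a power-law (Zipf) frequency distribution, a
handful-to-dozens of labels per document, and documents of bounded length
over a fixed vocabulary. Documents carry a learnable signal: with
probability ``signal_strength`` a token is drawn from a label-specific
token block, otherwise from a shared background distribution, so that small
classifiers can actually learn the label↔token mapping.

This generator is a stand-in for real coded clinical text; it makes no
attempt at realistic language, only at the label/token statistics that the
batching strategy interacts with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .batching import LabelDistribution
from .corpus import Example, LabeledCorpus


def label_name(i: int) -> str:
    return f"C{i:04d}"


def token_name(i: int) -> str:
    return f"tok{i}"


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults give a desk-scale long-tailed corpus."""

    n_examples: int = 2000
    n_labels: int = 200
    zipf_exponent: float = 1.2
    mean_labels_per_example: float = 3.0
    max_labels_per_example: int = 10
    min_labels_per_example: int = 1
    vocab_size: int = 2000
    doc_length_range: tuple[int, int] = (100, 300)
    signal_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labels < 1:
            raise ValueError("need at least one label")
        if self.zipf_exponent < 0:
            raise ValueError("zipf exponent must be ≥ 0")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.min_labels_per_example < 1:
            raise ValueError("min labels per example must be ≥ 1")
        if not (
            self.min_labels_per_example
            <= self.mean_labels_per_example
            <= self.max_labels_per_example
        ):
            raise ValueError("need min ≤ mean ≤ max labels per example")
        lo, hi = self.doc_length_range
        if lo < 1 or hi < lo:
            raise ValueError("doc_length_range must satisfy 1 ≤ min ≤ max")
        if self.vocab_size < 2:
            raise ValueError("vocabulary must have at least 2 tokens")


@dataclass
class CorpusStats:
    """Summary counts mirroring a dataset-description table."""

    n_examples: int
    n_unique_labels: int
    avg_words: float
    max_words: int
    min_words: int
    avg_labels: float
    max_labels: int
    min_labels: int

    def to_tsv(self) -> str:
        header = (
            "n_examples\tunique_labels\tavg_words\tmax_words\tmin_words"
            "\tavg_labels\tmax_labels\tmin_labels"
        )
        row = (
            f"{self.n_examples}\t{self.n_unique_labels}\t{self.avg_words:.4g}"
            f"\t{self.max_words}\t{self.min_words}\t{self.avg_labels:.4g}"
            f"\t{self.max_labels}\t{self.min_labels}"
        )
        return header + "\n" + row + "\n"


def sample_label_frequencies(
    n_labels: int, zipf_exponent: float, seed: int = 0
) -> LabelDistribution:
    """Zipf label-frequency distribution: P(rank r) ∝ r^(−s), exponent 0 → uniform.

    The distribution is deterministic given (n_labels, exponent); the seed
    is accepted for interface symmetry with the samplers.
    """
    if n_labels < 1:
        raise ValueError("need at least one label")
    ranks = np.arange(1, n_labels + 1, dtype=float)
    weights = ranks ** (-float(zipf_exponent))
    probs = weights / weights.sum()
    return LabelDistribution(tuple(label_name(i) for i in range(n_labels)), probs)


def _label_token_blocks(cfg: SynthConfig) -> tuple[np.ndarray, list[np.ndarray]]:
    """Background token ids plus one token block per label.

    The first half of the vocabulary is shared background; the second half is
    divided into per-label blocks (cyclically when there are more labels than
    blocks, so blocks are disjoint whenever the vocabulary is large enough).
    """
    n_bg = max(1, cfg.vocab_size // 2)
    background = np.arange(n_bg)
    n_sig = cfg.vocab_size - n_bg
    block = max(1, n_sig // cfg.n_labels)
    blocks = []
    for i in range(cfg.n_labels):
        start = (i * block) % n_sig
        ids = (start + np.arange(block)) % n_sig + n_bg
        blocks.append(ids)
    return background, blocks


def generate_corpus(config: SynthConfig) -> LabeledCorpus:
    """Draw a fully reproducible synthetic corpus under ``config``.

    Per example: the label count is Poisson(mean) clipped to [min, max];
    labels are drawn without replacement with probability proportional to the
    Zipf label frequencies; each token comes from a uniformly chosen own-label
    block with probability ``signal_strength``, else from the background.
    """
    cfg = config
    catalog = tuple(label_name(i) for i in range(cfg.n_labels))
    vocabulary = tuple(token_name(i) for i in range(cfg.vocab_size))
    if cfg.n_examples == 0:
        warnings.warn("generating an empty corpus (n_examples=0)", stacklevel=2)
        return LabeledCorpus([], catalog, vocabulary)

    rng = np.random.default_rng(cfg.seed)
    freqs = sample_label_frequencies(cfg.n_labels, cfg.zipf_exponent).probs
    background, blocks = _label_token_blocks(cfg)
    lo, hi = cfg.doc_length_range
    kmax = min(cfg.max_labels_per_example, cfg.n_labels)

    examples = []
    for i in range(cfg.n_examples):
        k = int(np.clip(rng.poisson(cfg.mean_labels_per_example),
                        cfg.min_labels_per_example, kmax))
        label_ids = rng.choice(cfg.n_labels, size=k, replace=False, p=freqs)
        length = int(rng.integers(lo, hi + 1))
        is_signal = rng.random(length) < cfg.signal_strength
        token_ids = np.empty(length, dtype=np.int64)
        n_bgtok = int((~is_signal).sum())
        token_ids[~is_signal] = rng.choice(background, size=n_bgtok)
        n_sigtok = length - n_bgtok
        if n_sigtok:
            which = label_ids[rng.integers(0, k, size=n_sigtok)]
            sig = np.array(
                [blocks[l][rng.integers(len(blocks[l]))] for l in which],
                dtype=np.int64,
            )
            token_ids[is_signal] = sig
        examples.append(
            Example(
                f"doc{i:06d}",
                tuple(vocabulary[t] for t in token_ids),
                frozenset(catalog[l] for l in label_ids),
            )
        )
    return LabeledCorpus(examples, catalog, vocabulary)


def corpus_stats(corpus: LabeledCorpus) -> CorpusStats:
    """Exact summary counts over a corpus; all-zero for an empty corpus."""
    if len(corpus) == 0:
        return CorpusStats(0, 0, 0.0, 0, 0, 0.0, 0, 0)
    words = np.array([len(ex.tokens) for ex in corpus.examples])
    labels = np.array([len(ex.labels) for ex in corpus.examples])
    unique = {lab for ex in corpus.examples for lab in ex.labels}
    return CorpusStats(
        n_examples=len(corpus),
        n_unique_labels=len(unique),
        avg_words=float(words.mean()),
        max_words=int(words.max()),
        min_words=int(words.min()),
        avg_labels=float(labels.mean()),
        max_labels=int(labels.max()),
        min_labels=int(labels.min()),
    )
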