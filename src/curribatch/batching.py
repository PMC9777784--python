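"""Batch-set construction: the curriculum batching samplers.

Three samplers turn a training corpus into a batch set whose pooled label
distribution is, respectively:

* **UDD** (uniform) — stratified sampling with replacement (SSR): each batch
  draws M labels uniformly from the set of training labels, then one example
  uniformly (with replacement) from each drawn label's stratum.
* **SDD** (shuffled) — the ordinary shuffle: a seeded permutation of the
  corpus chunked into ⌈|D|/M⌉ windows.
* **IDD** (imbalanced/original) — probability sampling with replacement
  (PSR): labels are drawn i.i.d. from the empirical label distribution of
  the corpus, then one example uniformly from each drawn label's stratum.

A curriculum schedule sequences the three kinds from easy to hard
(UDD → SDD → IDD by default, 50 epochs each).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Example, LabeledCorpus


class BatchKind(str, Enum):
    UDD = "UDD"
    SDD = "SDD"
    IDD = "IDD"

    @classmethod
    def parse(cls, s: "str | BatchKind") -> "BatchKind":
        if isinstance(s, BatchKind):
            return s
        return cls(s.upper())


# spawn keys for deterministic, independent per-sampler streams
_KIND_STREAM = {BatchKind.UDD: 0, BatchKind.SDD: 1, BatchKind.IDD: 2}


def _rng_for(kind: BatchKind, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_KIND_STREAM[kind],))
    )


@dataclass(frozen=True)
class Batch:
    """An ordered list of example references; duplicates allowed for UDD/IDD."""

    doc_ids: tuple[str, ...]
    drawn_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.doc_ids:
            raise ValueError("a batch must contain at least one example")

    def __len__(self) -> int:
        return len(self.doc_ids)


@dataclass
class BatchSet:
    """An ordered list of batches with a kind tag and the seed that built it."""

    kind: BatchKind
    batches: list[Batch]
    seed: int
    source_corpus_id: str = ""

    def __len__(self) -> int:
        return len(self.batches)

    def pooled_doc_ids(self) -> list[str]:
        """All example references across batches, with multiplicity."""
        return [d for b in self.batches for d in b.doc_ids]

    def pooled_examples(self, corpus: LabeledCorpus) -> list[Example]:
        idx = corpus.doc_index
        return [corpus.examples[idx[d]] for d in self.pooled_doc_ids()]

    def drawn_label_counts(self) -> dict[str, int] | None:
        """Counts of the raw label draws (UDD/IDD only; None for SDD)."""
        if any(b.drawn_labels is None for b in self.batches):
            return None
        counts: dict[str, int] = {}
        for b in self.batches:
            for lab in b.drawn_labels:  # type: ignore[union-attr]
                counts[lab] = counts.get(lab, 0) + 1
        return counts

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for i, b in enumerate(self.batches):
                rec = {
                    "kind": self.kind.value,
                    "index": i,
                    "doc_ids": list(b.doc_ids),
                }
                if b.drawn_labels is not None:
                    rec["drawn_labels"] = list(b.drawn_labels)
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path, seed: int = -1) -> "BatchSet":
        batches: list[Batch] = []
        kind: BatchKind | None = None
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                kind = BatchKind.parse(rec["kind"])
                drawn = rec.get("drawn_labels")
                batches.append(
                    Batch(tuple(rec["doc_ids"]), tuple(drawn) if drawn else None)
                )
        if kind is None:
            raise ValueError(f"empty batch-set file: {path}")
        return cls(kind, batches, seed)


@dataclass
class LabelDistribution:
    """A probability vector over an ordered label catalog."""

    labels: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.labels),):
            raise ValueError("probability vector length must match catalog size")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")

    def __getitem__(self, label: str) -> float:
        return float(self.probs[self.labels.index(label)])


def label_distribution(
    examples: Iterable[Example],
    label_catalog: Sequence[str] | None = None,
) -> LabelDistribution:
    """Empirical label distribution: each example contributes each of its labels once.

    P(l) = (number of example-label incidences of l) / (total incidences).
    """
    examples = list(examples)
    if label_catalog is None:
        label_catalog = sorted({lab for ex in examples for lab in ex.labels})
    catalog = tuple(label_catalog)
    index = {lab: i for i, lab in enumerate(catalog)}
    counts = np.zeros(len(catalog), dtype=float)
    for ex in examples:
        for lab in ex.labels:
            counts[index[lab]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no label incidences: cannot form a label distribution")
    return LabelDistribution(catalog, counts / total)


def _strata(corpus: LabeledCorpus) -> dict[str, np.ndarray]:
    """Map each label with ≥1 training example to the indices of its examples."""
    strata: dict[str, list[int]] = {}
    for i, ex in enumerate(corpus.examples):
        for lab in ex.labels:
            strata.setdefault(lab, []).append(i)
    return {lab: np.asarray(ix, dtype=np.int64) for lab, ix in strata.items()}


def default_n_batches(n_examples: int, batch_size: int) -> int:
    """K = N = N' = ⌈|D|/M⌉ — one convention for all three batch sets."""
    return math.ceil(n_examples / batch_size)


def shuffle_batchset(
    train_corpus: LabeledCorpus, batch_size: int, seed: int
) -> BatchSet:
    """SDD: a seeded permutation chunked into ⌈|D|/M⌉ sliding windows.

    Every example appears exactly once; the last batch may be short.
    """
    if batch_size < 1:
        raise ValueError("batch size must be ≥ 1")
    n = len(train_corpus)
    if n == 0:
        raise ValueError("cannot batch an empty corpus")
    if batch_size > n:
        warnings.warn(
            f"batch size {batch_size} exceeds corpus size {n}; "
            "producing a single batch",
            stacklevel=2,
        )
    rng = _rng_for(BatchKind.SDD, seed)
    perm = rng.permutation(n)
    ids = [train_corpus.examples[i].doc_id for i in perm]
    batches = [
        Batch(tuple(ids[i : i + batch_size])) for i in range(0, n, batch_size)
    ]
    return BatchSet(BatchKind.SDD, batches, seed)


def _sampled_batchset(
    kind: BatchKind,
    train_corpus: LabeledCorpus,
    batch_size: int,
    n_batches: int | None,
    seed: int,
    label_probs: np.ndarray | None,
    labels: tuple[str, ...],
    strata: dict[str, np.ndarray],
) -> BatchSet:
    rng = _rng_for(kind, seed)
    if n_batches is None:
        n_batches = default_n_batches(len(train_corpus), batch_size)
    batches = []
    label_arr = np.arange(len(labels))
    for _ in range(n_batches):
        drawn = rng.choice(label_arr, size=batch_size, replace=True, p=label_probs)
        doc_ids = []
        for li in drawn:
            stratum = strata[labels[li]]
            doc_ids.append(
                train_corpus.examples[stratum[rng.integers(len(stratum))]].doc_id
            )
        batches.append(Batch(tuple(doc_ids), tuple(labels[li] for li in drawn)))
    return BatchSet(kind, batches, seed)


def ssr_batchset(
    train_corpus: LabeledCorpus,
    batch_size: int,
    n_batches: int | None = None,
    seed: int = 0,
) -> BatchSet:
    """UDD via stratified sampling with replacement.

    Per batch: M labels drawn uniformly (with replacement) from the set of
    distinct training labels; for each, one example drawn uniformly with
    replacement from that label's stratum. N = ⌈|D|/M⌉ batches by default.
    """
    if batch_size < 1 or (n_batches is not None and n_batches < 1):
        raise ValueError("batch size and batch count must be ≥ 1")
    strata = _strata(train_corpus)
    if not strata:
        raise ValueError("training corpus has no labels")
    labels = tuple(sorted(strata))
    return _sampled_batchset(
        BatchKind.UDD, train_corpus, batch_size, n_batches, seed, None, labels, strata
    )


def psr_batchset(
    train_corpus: LabeledCorpus,
    batch_size: int,
    n_batches: int | None = None,
    seed: int = 0,
) -> BatchSet:
    """IDD via probability sampling with replacement.

    Per batch: M labels drawn i.i.d. from the empirical label distribution of
    the corpus; one example drawn uniformly with replacement from each drawn
    label's stratum. N' = ⌈|D|/M⌉ batches by default.
    """
    if batch_size < 1 or (n_batches is not None and n_batches < 1):
        raise ValueError("batch size and batch count must be ≥ 1")
    strata = _strata(train_corpus)
    if not strata:
        raise ValueError("training corpus has no labels")
    labels = tuple(sorted(strata))
    dist = label_distribution(train_corpus.examples, labels)
    return _sampled_batchset(
        BatchKind.IDD,
        train_corpus,
        batch_size,
        n_batches,
        seed,
        dist.probs,
        labels,
        strata,
    )


def build_batchsets(
    train_corpus: LabeledCorpus, batch_size: int, seed: int
) -> dict[BatchKind, BatchSet]:
    """All three batch sets, built offline from one root seed."""
    return {
        BatchKind.UDD: ssr_batchset(train_corpus, batch_size, seed=seed),
        BatchKind.SDD: shuffle_batchset(train_corpus, batch_size, seed),
        BatchKind.IDD: psr_batchset(train_corpus, batch_size, seed=seed),
    }


@dataclass
class CurriculumSchedule:
    """Ordered (batch-set kind, epoch count) phases."""

    phases: list[tuple[BatchKind, int]]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a schedule needs at least one phase")
        self.phases = [(BatchKind.parse(k), int(e)) for k, e in self.phases]
        if any(e < 1 for _, e in self.phases):
            raise ValueError("every phase must run for at least one epoch")

    @property
    def total_epochs(self) -> int:
        return sum(e for _, e in self.phases)

    @property
    def phase_starts(self) -> list[int]:
        """First epoch of each phase after the first (the switch points)."""
        starts, cum = [], 0
        for _, e in self.phases[:-1]:
            cum += e
            starts.append(cum)
        return starts

    def kind_for_epoch(self, epoch: int) -> BatchKind:
        if not 0 <= epoch < self.total_epochs:
            raise ValueError(
                f"epoch {epoch} outside schedule of {self.total_epochs} epochs"
            )
        cum = 0
        for kind, e in self.phases:
            cum += e
            if epoch < cum:
                return kind
        raise AssertionError("unreachable")

    def kinds(self) -> set[BatchKind]:
        return {k for k, _ in self.phases}

    @classmethod
    def parse(cls, spec: str) -> "CurriculumSchedule":
        """Parse schedule strings like ``"udd:50,sdd:50,idd:50"``."""
        phases = []
        for part in spec.split(","):
            part = part.strip()
            if not part:
                continue
            kind, _, count = part.partition(":")
            phases.append((BatchKind.parse(kind), int(count)))
        return cls(phases)

    def __str__(self) -> str:
        return ",".join(f"{k.value.lower()}:{e}" for k, e in self.phases)


def build_schedule(
    phase_spec: Sequence[tuple[str | BatchKind, int]] | None = None,
) -> CurriculumSchedule:
    """The curriculum: UDD→SDD→IDD, 50 epochs each, unless overridden."""
    if phase_spec is None:
        phase_spec = [(BatchKind.UDD, 50), (BatchKind.SDD, 50), (BatchKind.IDD, 50)]
    return CurriculumSchedule(list(phase_spec))


def batchset_for_epoch(schedule: CurriculumSchedule, epoch: int) -> BatchKind:
    return schedule.kind_for_epoch(epoch)
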