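"""Core containers for labeled multi-label text corpora.

A corpus is a list of examples, each pairing a token sequence (a clinical
note, in the motivating application) with a non-empty set of code labels,
plus an ordered label catalog and vocabulary. Corpora are serialized as
JSON-lines: one example per line with keys ``doc_id``, ``tokens``,
``labels``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True)
class Example:
    """One document: a token sequence and its non-empty label set."""

    doc_id: str
    tokens: tuple[str, ...]
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError(f"example {self.doc_id!r} has an empty label set")
        if not self.tokens:
            raise ValueError(f"example {self.doc_id!r} has no tokens")
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass
class LabeledCorpus:
    """Examples plus an ordered label catalog and an ordered vocabulary.

    The catalog may be a superset of the labels actually used (train/val/test
    splits of one corpus share the parent catalog so that multi-hot label
    vectors align across splits).
    """

    examples: list[Example]
    label_catalog: tuple[str, ...]
    vocabulary: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.label_catalog = tuple(self.label_catalog)
        self.vocabulary = tuple(self.vocabulary)
        catalog = set(self.label_catalog)
        if len(catalog) != len(self.label_catalog):
            raise ValueError("label catalog contains duplicates")
        seen: set[str] = set()
        for ex in self.examples:
            if ex.doc_id in seen:
                raise ValueError(f"duplicate doc_id {ex.doc_id!r}")
            seen.add(ex.doc_id)
            missing = ex.labels - catalog
            if missing:
                raise ValueError(
                    f"example {ex.doc_id!r} uses labels outside the catalog: "
                    f"{sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self) -> Iterator[Example]:
        return iter(self.examples)

    @property
    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.label_catalog)}

    @property
    def doc_index(self) -> dict[str, int]:
        return {ex.doc_id: i for i, ex in enumerate(self.examples)}

    @classmethod
    def from_examples(
        cls,
        examples: Iterable[Example],
        label_catalog: Sequence[str] | None = None,
        vocabulary: Sequence[str] | None = None,
    ) -> "LabeledCorpus":
        """Build a corpus, deriving catalog/vocabulary from the examples if absent."""
        examples = list(examples)
        if label_catalog is None:
            label_catalog = sorted({lab for ex in examples for lab in ex.labels})
        if vocabulary is None:
            vocabulary = sorted({tok for ex in examples for tok in ex.tokens})
        return cls(examples, tuple(label_catalog), tuple(vocabulary))

    def subset(self, doc_ids: Sequence[str]) -> "LabeledCorpus":
        """A new corpus with the given examples, sharing catalog and vocabulary."""
        idx = self.doc_index
        chosen = [self.examples[idx[d]] for d in doc_ids]
        return LabeledCorpus(chosen, self.label_catalog, self.vocabulary)

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for ex in self.examples:
                fh.write(
                    json.dumps(
                        {
                            "doc_id": ex.doc_id,
                            "tokens": list(ex.tokens),
                            "labels": sorted(ex.labels),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(
        cls,
        path: str | Path,
        label_catalog: Sequence[str] | None = None,
        vocabulary: Sequence[str] | None = None,
    ) -> "LabeledCorpus":
        examples = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                examples.append(
                    Example(rec["doc_id"], tuple(rec["tokens"]), frozenset(rec["labels"]))
                )
        return cls.from_examples(examples, label_catalog, vocabulary)
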