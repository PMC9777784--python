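"""Batch-set difficulty diagnostics: KL divergence and Jensen–Shannon distance.

Both measures compare a batch set's label distribution with the global
training label distribution. The default report averages the divergence of
each batch's label distribution from the corpus distribution: a shuffle
partition pooled over all its batches reproduces the corpus distribution
exactly, so only the batch-level view distinguishes the shuffle regime from
the distribution-matched sampler. Pooled aggregation is available for
completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import rel_entr

from .batching import BatchKind, BatchSet, LabelDistribution, label_distribution
from .corpus import LabeledCorpus

DEFAULT_EPSILON = 1e-10


def _smooth(p: np.ndarray, epsilon: float) -> np.ndarray:
    if epsilon < 0:
        raise ValueError("epsilon must be ≥ 0")
    if epsilon == 0:
        return p
    q = p + epsilon
    return q / q.sum()


def _as_probs(p: "LabelDistribution | np.ndarray") -> np.ndarray:
    return p.probs if isinstance(p, LabelDistribution) else np.asarray(p, dtype=float)


def kl_divergence(
    p: "LabelDistribution | np.ndarray",
    q: "LabelDistribution | np.ndarray",
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """KL(p‖q) = Σ p ln(p/q) in nats, after epsilon-smoothing both arguments.

    With epsilon = 0 and q(l) = 0 < p(l) the divergence is +inf (returned,
    not raised).
    """
    pv, qv = _as_probs(p), _as_probs(q)
    if pv.shape != qv.shape:
        raise ValueError("distributions must share one label catalog")
    if isinstance(p, LabelDistribution) and isinstance(q, LabelDistribution):
        if p.labels != q.labels:
            raise ValueError("distributions must share one label catalog")
    pv, qv = _smooth(pv, epsilon), _smooth(qv, epsilon)
    return float(rel_entr(pv, qv).sum())


def js_distance(
    p: "LabelDistribution | np.ndarray", q: "LabelDistribution | np.ndarray"
) -> float:
    """Jensen–Shannon distance: sqrt(½ KL(p‖m) + ½ KL(q‖m)), m = (p+q)/2.

    Natural log; symmetric; bounded by sqrt(ln 2). No smoothing is needed
    because m is positive wherever p or q is.
    """
    pv, qv = _as_probs(p), _as_probs(q)
    if pv.shape != qv.shape:
        raise ValueError("distributions must share one label catalog")
    m = 0.5 * (pv + qv)
    jsd = 0.5 * rel_entr(pv, m).sum() + 0.5 * rel_entr(qv, m).sum()
    return float(np.sqrt(max(jsd, 0.0)))


@dataclass
class DifficultyReport:
    """KLD/JSD per batch-set kind against the global training distribution."""

    rows: dict[BatchKind, dict[str, float]]
    epsilon: float
    aggregate: str
    reference_corpus_id: str = ""

    def kld(self, kind: "BatchKind | str") -> float:
        return self.rows[BatchKind.parse(kind)]["kld"]

    def jsd(self, kind: "BatchKind | str") -> float:
        return self.rows[BatchKind.parse(kind)]["jsd"]

    def to_tsv(self) -> str:
        kinds = list(self.rows)
        lines = ["method\t" + "\t".join(k.value for k in kinds)]
        for measure in ("kld", "jsd"):
            lines.append(
                measure.upper()
                + "\t"
                + "\t".join(f"{self.rows[k][measure]:.6g}" for k in kinds)
            )
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv(), encoding="utf-8")


def difficulty_report(
    batchsets: Sequence[BatchSet],
    train_corpus: LabeledCorpus,
    epsilon: float = DEFAULT_EPSILON,
    aggregate: str = "per_batch",
    direction: str = "batch_to_corpus",
) -> DifficultyReport:
    """Compare each batch set's label distribution with the corpus distribution.

    aggregate="per_batch" (default): mean over batches of the divergence of
    the batch label distribution from the corpus distribution.
    aggregate="pooled": one divergence of the pooled (all batches, with
    multiplicity) distribution from the corpus distribution.

    direction="batch_to_corpus" computes KL(batch set ‖ corpus); "reverse"
    swaps the arguments (JSD is symmetric either way).
    """
    if aggregate not in ("per_batch", "pooled"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    if direction not in ("batch_to_corpus", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    catalog = train_corpus.label_catalog
    global_dist = label_distribution(train_corpus.examples, catalog)

    def one(p: LabelDistribution) -> tuple[float, float]:
        a, b = (p, global_dist) if direction == "batch_to_corpus" else (global_dist, p)
        return kl_divergence(a, b, epsilon), js_distance(a, b)

    idx = train_corpus.doc_index
    rows: dict[BatchKind, dict[str, float]] = {}
    for bs in batchsets:
        for batch in bs.batches:
            for d in batch.doc_ids:
                if d not in idx:
                    raise ValueError(
                        f"batch set {bs.kind.value} references {d!r}, "
                        "absent from the training corpus"
                    )
        if aggregate == "pooled":
            kld, jsd = one(label_distribution(bs.pooled_examples(train_corpus), catalog))
        else:
            vals = []
            for batch in bs.batches:
                exs = [train_corpus.examples[idx[d]] for d in batch.doc_ids]
                vals.append(one(label_distribution(exs, catalog)))
            kld = float(np.mean([v[0] for v in vals]))
            jsd = float(np.mean([v[1] for v in vals]))
        rows[bs.kind] = {"kld": kld, "jsd": jsd}
    return DifficultyReport(rows, epsilon, aggregate)
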