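"""Reference desk-scale studies: the package's scaled-down experimental protocol.

These functions bundle the full pipeline into the three reproducible studies
the package is validated with:

* :func:`sampler_law_study` — empirical label-draw frequencies of the
  stratified (uniform) and probability (distribution-matched) samplers,
  summarized as total-variation distances with Monte-Carlo multinomial null
  bounds;
* :func:`difficulty_study` — per-kind KLD/JSD difficulty report replicated
  over seeds, with the fraction of replicates showing the easy-to-hard
  ordering UDD > SDD > IDD;
* :func:`training_study` — the curriculum-vs-baseline comparison: a small
  convolutional classifier trained under UDD→SDD→IDD versus shuffle-only at
  equal total epochs, compared on micro/macro F1 and long-tailed recall.

Problem sizes are chosen so each study runs in minutes on one CPU; the
module docstrings and the methods note state them explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import metrics as mx
from . import model_train as mt
from . import preprocess as pp
from .batching import BatchKind, CurriculumSchedule, build_batchsets
from .divergence import difficulty_report
from .synth_corpus import SynthConfig, generate_corpus

#: Corpus for the sampler-law and difficulty studies (long-tailed, 200 labels).
DIAGNOSTIC_SYNTH = SynthConfig()  # n=2000, L=200, zipf 1.2

#: Corpus for the training study: fewer labels and short documents so that
#: six 30-epoch trainings stay within a few CPU-minutes.
TRAINING_SYNTH = SynthConfig(
    n_examples=2000, n_labels=50, vocab_size=1000, doc_length_range=(60, 120)
)

BATCH_SIZE = 100
CURRICULUM = "udd:10,sdd:10,idd:10"
BASELINE = "sdd:30"


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def mc_tv_bound(
    target: np.ndarray, n_draws: int, seed: int, reps: int = 300
) -> float:
    """3σ Monte-Carlo bound on the TV distance of multinomial frequencies.

    Simulates ``reps`` multinomial samples of size ``n_draws`` from
    ``target`` and returns mean + 3·std of their TV distances from it.
    """
    rng = np.random.default_rng(seed)
    tvs = [
        total_variation(rng.multinomial(n_draws, target) / n_draws, target)
        for _ in range(reps)
    ]
    return float(np.mean(tvs) + 3 * np.std(tvs))


def _draw_frequencies(batchset, labels: tuple[str, ...]) -> np.ndarray:
    counts = batchset.drawn_label_counts()
    vec = np.array([counts.get(lab, 0) for lab in labels], dtype=float)
    return vec / vec.sum()


def sampler_law_study(seed: int, config: SynthConfig | None = None) -> dict:
    """TV distances of SSR/PSR label draws vs their targets, with null bounds."""
    cfg = config or DIAGNOSTIC_SYNTH
    corpus = generate_corpus(dataclasses.replace(cfg, seed=seed))
    from .batching import label_distribution, psr_batchset, ssr_batchset

    udd = ssr_batchset(corpus, BATCH_SIZE, seed=seed + 1)
    idd = psr_batchset(corpus, BATCH_SIZE, seed=seed + 1)
    sdd_from = build_batchsets(corpus, BATCH_SIZE, seed + 1)[BatchKind.SDD]
    dist = label_distribution(corpus.examples, corpus.label_catalog)
    present = dist.probs > 0
    labels = tuple(np.asarray(corpus.label_catalog)[present])
    uniform = np.full(len(labels), 1.0 / len(labels))
    corpus_probs = dist.probs[present]
    n_draws = len(udd) * BATCH_SIZE
    ssr_tv = total_variation(_draw_frequencies(udd, labels), uniform)
    psr_tv = total_variation(_draw_frequencies(idd, labels), corpus_probs)
    return {
        "n_draws": n_draws,
        "ssr_tv": ssr_tv,
        "ssr_bound": mc_tv_bound(uniform, n_draws, seed + 2),
        "psr_tv": psr_tv,
        "psr_bound": mc_tv_bound(corpus_probs, n_draws, seed + 3),
        "sdd_n_batches": len(sdd_from),
        "sdd_expected_batches": -(-len(corpus) // BATCH_SIZE),
        "sdd_is_partition": sorted(sdd_from.pooled_doc_ids())
        == sorted(ex.doc_id for ex in corpus.examples),
    }


def difficulty_study(
    seed: int, n_seeds: int = 10, config: SynthConfig | None = None
) -> dict:
    """Replicated KLD/JSD difficulty reports and the UDD > SDD > IDD ordering rate."""
    cfg = config or DIAGNOSTIC_SYNTH
    corpus = generate_corpus(dataclasses.replace(cfg, seed=seed))
    klds, jsds = [], []
    kld_wins = jsd_wins = 0
    for s in range(n_seeds):
        bsets = build_batchsets(corpus, BATCH_SIZE, seed + 100 + s)
        rep = difficulty_report(list(bsets.values()), corpus)
        k = [rep.kld(x) for x in ("UDD", "SDD", "IDD")]
        j = [rep.jsd(x) for x in ("UDD", "SDD", "IDD")]
        klds.append(k)
        jsds.append(j)
        kld_wins += k[0] > k[1] > k[2]
        jsd_wins += j[0] > j[1] > j[2]
    kld_mean = np.mean(klds, axis=0)
    jsd_mean = np.mean(jsds, axis=0)
    return {
        "n_seeds": n_seeds,
        "kld": dict(zip(("UDD", "SDD", "IDD"), map(float, kld_mean))),
        "jsd": dict(zip(("UDD", "SDD", "IDD"), map(float, jsd_mean))),
        "kld_ordering_fraction": kld_wins / n_seeds,
        "jsd_ordering_fraction": jsd_wins / n_seeds,
    }


@dataclass
class TrainingRunResult:
    """Test-set metrics and training trace of one schedule at one seed."""

    schedule: str
    seed: int
    report: mx.MicroMacroReport
    longtail: mx.LongTailResult
    loss_history: list[float]
    phase_switch_epochs: list[int]


def run_schedule(
    seed: int,
    schedule: str,
    config: SynthConfig | None = None,
    batch_size: int = BATCH_SIZE,
) -> TrainingRunResult:
    """One end-to-end training run: simulate, split 7:1:2, batch, train, test."""
    cfg = config or TRAINING_SYNTH
    corpus = generate_corpus(dataclasses.replace(cfg, seed=seed))
    train_c, val_c, test_c = pp.split_corpus(corpus, pp.SplitSpec(seed=seed + 1))
    vocab = pp.build_vocabulary(corpus, 10_000)
    enc_train = pp.encode(train_c, vocab)
    enc_val = pp.encode(val_c, vocab)
    enc_test = pp.encode(test_c, vocab)
    bsets = build_batchsets(train_c, batch_size, seed + 2)
    spec = mt.ModelSpec(vocab_size=vocab.n_ids, n_labels=len(corpus.label_catalog))
    tcfg = mt.TrainConfig(
        batch_size=batch_size,
        schedule=CurriculumSchedule.parse(schedule),
        seed=seed + 3,
    )
    state = mt.train(enc_train, bsets, spec, tcfg, enc_val)
    pm = mt.predict(state, enc_test)
    report = mx.micro_macro_report(
        pm.decisions, enc_test.label_matrix, corpus.label_catalog
    )
    freqs = enc_train.label_frequencies()
    gamma = float(np.median(freqs))  # scaled long-tail threshold
    lt = mx.longtail_metrics(pm.decisions, enc_test.label_matrix, freqs, gamma)
    return TrainingRunResult(
        schedule, seed, report, lt, state.loss_history, state.phase_switch_epochs
    )


def training_study(seed: int, n_seeds: int = 3) -> dict:
    """Curriculum vs shuffle-only at equal total epochs, averaged over seeds.

    Returns mean test metrics per schedule, the per-seed runs, and the
    loss-rise record at each curriculum phase switch.
    """
    runs: dict[str, list[TrainingRunResult]] = {CURRICULUM: [], BASELINE: []}
    for i in range(n_seeds):
        s = seed + 10 * i
        for sched in (CURRICULUM, BASELINE):
            runs[sched].append(run_schedule(s, sched))

    def mean(sched: str, attr: str) -> float:
        return float(np.mean([getattr(r.report, attr) for r in runs[sched]]))

    spikes = []
    for r in runs[CURRICULUM]:
        for sw in r.phase_switch_epochs:
            spikes.append(bool(r.loss_history[sw] > r.loss_history[sw - 1]))
    return {
        "n_seeds": n_seeds,
        "curriculum": {
            "f1_macro": mean(CURRICULUM, "f1_macro"),
            "f1_micro": mean(CURRICULUM, "f1_micro"),
            "longtail_recall": float(
                np.mean([r.longtail.recall for r in runs[CURRICULUM]])
            ),
        },
        "baseline": {
            "f1_macro": mean(BASELINE, "f1_macro"),
            "f1_micro": mean(BASELINE, "f1_micro"),
            "longtail_recall": float(
                np.mean([r.longtail.recall for r in runs[BASELINE]])
            ),
        },
        "loss_spikes": spikes,
        "runs": runs,
    }
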