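"""Sampler laws, schedule arithmetic and reproducibility of batch sets."""

import numpy as np
import pytest

from curribatch.batching import (
    BatchKind,
    BatchSet,
    CurriculumSchedule,
    batchset_for_epoch,
    build_schedule,
    default_n_batches,
    label_distribution,
    psr_batchset,
    shuffle_batchset,
    ssr_batchset,
)
from curribatch.corpus import Example, LabeledCorpus


def single_label_corpus(counts: dict[str, int]) -> LabeledCorpus:
    """counts[label] examples, each carrying exactly that one label."""
    examples = [
        Example(f"{lab}{i}", ("t",), frozenset({lab}))
        for lab, n in counts.items()
        for i in range(n)
    ]
    return LabeledCorpus.from_examples(examples)


class TestLabelDistribution:
    def test_incidence_counting(self):
        corpus = LabeledCorpus.from_examples(
            [
                Example("x", ("t",), frozenset({"a"})),
                Example("y", ("t",), frozenset({"a", "b"})),
            ]
        )
        d = label_distribution(corpus.examples)
        assert d["a"] == pytest.approx(2 / 3)
        assert d["b"] == pytest.approx(1 / 3)

    def test_degenerate_single_label(self):
        corpus = single_label_corpus({"only": 5})
        d = label_distribution(corpus.examples)
        np.testing.assert_allclose(d.probs, [1.0])

    def test_no_labels_rejected(self):
        with pytest.raises(ValueError):
            label_distribution([], label_catalog=("a",))


class TestShuffleBatchset:
    def test_ceiling_chunking(self, tiny_corpus):
        bs = shuffle_batchset(tiny_corpus, 3, seed=0)
        assert [len(b) for b in bs.batches] == [3, 3, 3, 1]

    def test_multiset_union_is_corpus(self, small_synth):
        bs = shuffle_batchset(small_synth, 32, seed=5)
        assert sorted(bs.pooled_doc_ids()) == sorted(
            ex.doc_id for ex in small_synth.examples
        )

    def test_batch_count_rule_at_reference_scale(self):
        # 70% share of 55,177 examples at batch size 1000 → 39 batches
        n_train = 55_177 - int(0.1 * 55_177) - int(0.2 * 55_177)
        assert default_n_batches(n_train, 1000) == 39

    def test_oversized_batch_warns_single_batch(self, tiny_corpus):
        with pytest.warns(UserWarning):
            bs = shuffle_batchset(tiny_corpus, 50, seed=0)
        assert len(bs) == 1 and len(bs.batches[0]) == 10


class TestSSR:
    def test_single_stratum_draws_whole_corpus(self):
        corpus = single_label_corpus({"a": 8})
        bs = ssr_batchset(corpus, 4, seed=1)
        assert len(bs) == 2  # ceil(8/4)
        for b in bs.batches:
            assert len(b) == 4
            assert set(b.drawn_labels) == {"a"}

    def test_uniform_label_draws_within_3_sigma(self):
        # 4 equal-frequency labels; 100 batches of 100 → 10,000 draws
        corpus = single_label_corpus({"a": 10, "b": 10, "c": 10, "d": 10})
        bs = ssr_batchset(corpus, 100, n_batches=100, seed=2)
        counts = bs.drawn_label_counts()
        sigma = np.sqrt(0.25 * 0.75 / 10_000)
        for lab in "abcd":
            assert abs(counts[lab] / 10_000 - 0.25) < 3 * sigma

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            ssr_batchset(
                LabeledCorpus([], ("a",)), 4, seed=0
            )


class TestPSR:
    def test_draws_follow_empirical_distribution_binomial_bound(self):
        # P = (0.9, 0.1); one batch of 1000 draws: expect 900 ± 3σ of label a
        corpus = single_label_corpus({"a": 90, "b": 10})
        bs = psr_batchset(corpus, 1000, n_batches=1, seed=3)
        counts = bs.drawn_label_counts()
        sigma = np.sqrt(1000 * 0.9 * 0.1)
        assert abs(counts["a"] - 900) < 3 * sigma

    def test_examples_resolve_to_drawn_label_stratum(self):
        corpus = single_label_corpus({"a": 5, "b": 5})
        bs = psr_batchset(corpus, 10, n_batches=3, seed=4)
        for b in bs.batches:
            for doc, lab in zip(b.doc_ids, b.drawn_labels):
                assert doc.startswith(lab)


class TestReproducibilityAndSerialization:
    @pytest.mark.parametrize("builder", [
        lambda c, s: shuffle_batchset(c, 16, s),
        lambda c, s: ssr_batchset(c, 16, seed=s),
        lambda c, s: psr_batchset(c, 16, seed=s),
    ])
    def test_same_seed_identical_batchset(self, small_synth, builder):
        a, b = builder(small_synth, 11), builder(small_synth, 11)
        assert [x.doc_ids for x in a.batches] == [x.doc_ids for x in b.batches]

    def test_samplers_use_independent_streams(self, small_synth):
        udd = ssr_batchset(small_synth, 16, seed=11)
        idd = psr_batchset(small_synth, 16, seed=11)
        assert [x.doc_ids for x in udd.batches] != [x.doc_ids for x in idd.batches]

    def test_jsonl_round_trip(self, tmp_path, small_synth):
        bs = ssr_batchset(small_synth, 16, seed=1)
        bs.to_jsonl(tmp_path / "bs.jsonl")
        back = BatchSet.from_jsonl(tmp_path / "bs.jsonl")
        assert back.kind is BatchKind.UDD
        assert [x.doc_ids for x in back.batches] == [x.doc_ids for x in bs.batches]
        assert [x.drawn_labels for x in back.batches] == [
            x.drawn_labels for x in bs.batches
        ]


class TestSchedule:
    def test_default_curriculum(self):
        s = build_schedule()
        assert s.total_epochs == 150
        assert s.phase_starts == [50, 100]
        assert batchset_for_epoch(s, 0) is BatchKind.UDD
        assert batchset_for_epoch(s, 49) is BatchKind.UDD
        assert batchset_for_epoch(s, 50) is BatchKind.SDD
        assert batchset_for_epoch(s, 100) is BatchKind.IDD
        assert batchset_for_epoch(s, 149) is BatchKind.IDD

    def test_baseline_regime(self):
        s = build_schedule([("sdd", 150)])
        assert s.total_epochs == 150
        assert {batchset_for_epoch(s, e) for e in (0, 75, 149)} == {BatchKind.SDD}

    def test_empty_or_zero_phase_rejected(self):
        with pytest.raises(ValueError):
            build_schedule([])
        with pytest.raises(ValueError):
            build_schedule([("udd", 0)])

    def test_epoch_out_of_range(self):
        s = build_schedule()
        with pytest.raises(ValueError):
            batchset_for_epoch(s, 150)
        with pytest.raises(ValueError):
            batchset_for_epoch(s, -1)

    def test_parse_round_trip(self):
        s = CurriculumSchedule.parse("udd:10,sdd:5,idd:2")
        assert s.phases == [(BatchKind.UDD, 10), (BatchKind.SDD, 5), (BatchKind.IDD, 2)]
        assert CurriculumSchedule.parse(str(s)).phases == s.phases
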