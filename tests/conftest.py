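import pytest

from curribatch.corpus import Example, LabeledCorpus
from curribatch.synth_corpus import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus() -> LabeledCorpus:
    """Ten hand-built examples over three labels (split and batching fodder)."""
    examples = [
        Example(f"d{i}", (f"w{i}", "shared"), frozenset({"a"} if i < 6 else {"a", "b"} if i < 9 else {"c"}))
        for i in range(10)
    ]
    return LabeledCorpus.from_examples(examples, label_catalog=("a", "b", "c"))


@pytest.fixture(scope="session")
def small_synth() -> LabeledCorpus:
    """A quick long-tailed synthetic corpus for integration-style checks."""
    return generate_corpus(
        SynthConfig(
            n_examples=300,
            n_labels=30,
            vocab_size=300,
            doc_length_range=(20, 40),
            seed=7,
        )
    )
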