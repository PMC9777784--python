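"""End-to-end experiment runs: simulate → preprocess → batch → diagnose → train → evaluate.

A run is driven by one :class:`RunConfig` (loadable from YAML), writes every
artifact into a run directory and records a manifest with the parameters and
content digests of all text artifacts, so identical configs reproduce
identical manifests bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batching, divergence, metrics, model_train, preprocess, synth_corpus
from .batching import BatchKind, CurriculumSchedule
from .synth_corpus import SynthConfig


@dataclass
class RunConfig:
    """All stage parameters of one experiment, under a single root seed."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    top_k: int = 10_000
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    batch_size: int = 100
    schedule: str = "udd:50,sdd:50,idd:50"
    learning_rate: float = 0.008
    embedding_dim: int = 16
    n_filters: int = 8
    prediction_threshold: float = 0.5
    gamma: float | None = None  # None → median training-label frequency
    seed: int = 0

    def __post_init__(self) -> None:
        CurriculumSchedule.parse(self.schedule)  # validate early

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        if "ratios" in raw:
            raw["ratios"] = tuple(raw["ratios"])
        if "doc_length_range" in raw:
            raw["doc_length_range"] = tuple(raw["doc_length_range"])
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["doc_length_range"] = list(self.synth.doc_length_range)
        d["ratios"] = list(self.ratios)
        return d


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _params_digest(params: model_train.Params) -> str:
    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k]).tobytes())
    return h.hexdigest()


def run_experiment(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage and write artifacts plus a manifest into ``outdir``.

    On failure a ``FAILED_<stage>`` marker file names the stage that broke.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        # seeds are forked deterministically from the root seed per stage
        root = config.seed
        synth_cfg = dataclasses.replace(config.synth, seed=root)
        corpus = synth_corpus.generate_corpus(synth_cfg)
        corpus.to_jsonl(out / "corpus.jsonl")
        (out / "corpus_stats.tsv").write_text(
            synth_corpus.corpus_stats(corpus).to_tsv(), encoding="utf-8"
        )

        stage = "preprocess"
        vocab = preprocess.build_vocabulary(corpus, config.top_k)
        vocab.to_tsv(out / "vocabulary.tsv")
        spec = preprocess.SplitSpec(*config.ratios, seed=root + 1)
        train_c, val_c, test_c = preprocess.split_corpus(corpus, spec)
        for name, part in (("train", train_c), ("val", val_c), ("test", test_c)):
            part.to_jsonl(out / f"{name}.jsonl")
        enc_train = preprocess.encode(train_c, vocab)
        enc_val = preprocess.encode(val_c, vocab)
        enc_test = preprocess.encode(test_c, vocab)

        stage = "make-batches"
        batchsets = batching.build_batchsets(train_c, config.batch_size, root + 2)
        for kind, bs in batchsets.items():
            bs.to_jsonl(out / f"batchset_{kind.value.lower()}.jsonl")

        stage = "diagnose"
        report = divergence.difficulty_report(list(batchsets.values()), train_c)
        report.write_tsv(out / "difficulty.tsv")

        stage = "train"
        schedule = CurriculumSchedule.parse(config.schedule)
        model_spec = model_train.ModelSpec(
            vocab_size=vocab.n_ids,
            n_labels=len(corpus.label_catalog),
            embedding_dim=config.embedding_dim,
            n_filters=config.n_filters,
        )
        tcfg = model_train.TrainConfig(
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            schedule=schedule,
            seed=root + 3,
            prediction_threshold=config.prediction_threshold,
        )
        state = model_train.train(enc_train, batchsets, model_spec, tcfg, enc_val)
        (out / "loss_history.tsv").write_text(
            state.loss_history_tsv(), encoding="utf-8"
        )
        np.savez(out / "model_params.npz", **state.selected_params())

        stage = "evaluate"
        pm = model_train.predict(state, enc_test, config.prediction_threshold)
        report_mm = metrics.micro_macro_report(
            pm.decisions, enc_test.label_matrix, corpus.label_catalog
        )
        freqs = enc_train.label_frequencies()
        gamma = (
            float(np.median(freqs)) if config.gamma is None else float(config.gamma)
        )
        lt = metrics.longtail_metrics(pm.decisions, enc_test.label_matrix, freqs, gamma)
        row = report_mm.to_row()
        row.update(
            {
                "LT_precision": lt.precision,
                "LT_recall": lt.recall,
                "LT_n_labels": lt.n_longtail_labels,
                "gamma": gamma,
            }
        )
        pd.DataFrame([row]).to_csv(out / "metrics.tsv", sep="\t", index=False)

        stage = "manifest"
        artifacts = sorted(
            p.name
            for p in out.iterdir()
            if p.suffix in (".jsonl", ".tsv") and not p.name.startswith("FAILED")
        )
        manifest = {
            "config": config.to_dict(),
            "stage_seeds": {
                "simulate": root,
                "split": root + 1,
                "batches": root + 2,
                "train": root + 3,
            },
            "artifact_sha256": {a: _sha256_file(out / a) for a in artifacts},
            "model_params_digest": _params_digest(state.selected_params()),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    except Exception as err:
        (out / f"FAILED_{stage}").write_text(f"{stage}: {err}\n", encoding="utf-8")
        raise
    return out


def compare_runs(run_dirs: "list[str | Path]") -> pd.DataFrame:
    """Side-by-side metric table for ≥ 2 completed runs on the same corpus."""
    if len(run_dirs) < 2:
        raise ValueError("need at least two runs to compare")
    rows = []
    corpus_hash = None
    for rd in run_dirs:
        rd = Path(rd)
        manifest = json.loads((rd / "manifest.json").read_text(encoding="utf-8"))
        ch = manifest["artifact_sha256"].get("corpus.jsonl")
        if corpus_hash is None:
            corpus_hash = ch
        elif ch != corpus_hash:
            raise ValueError(f"run {rd} was executed on a different corpus")
        row = pd.read_csv(rd / "metrics.tsv", sep="\t").iloc[0].to_dict()
        row = {"run": rd.name, "schedule": manifest["config"]["schedule"], **row}
        rows.append(row)
    return pd.DataFrame(rows)


def average_runs(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each numeric metric grouped by schedule (multi-seed sweeps)."""
    num = table.select_dtypes("number").columns
    return table.groupby("schedule", as_index=False)[list(num)].mean()
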