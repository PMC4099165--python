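"""End-to-end authentication pipeline and preprocessing-arm comparison.

Stage order follows the usual chemometric workflow for origin
authentication: trim the uninformative high-wavenumber region, remove
aberrant spectra per class with the Stahel-Donoho diagnosis on the raw
(untransformed) spectra, apply exactly one pretreatment, split per class
with Kennard-Stone, choose the PLSDA latent-variable count by MCCV on the
training set, fit the final model and score the prediction set. Every
source of randomness (projection directions, MCCV splits, the generator)
flows from named seeds in the config; reports contain no timestamps, so
identical configs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import NEG, POS, SpectralDataset, read_spectra_csv, trim_wavenumbers
from .outliers import OutlyingnessResult, flag_and_remove
from .plsda import ConfusionCounts, MCCVResult, PLSDAClassifier, evaluate, mccv_select_lv
from .preprocessing import Method, PreprocessConfig, apply_preprocessing
from .simulate import GeneratorConfig, simulate_dataset
from .splitting import SplitResult, split_per_class

logger = logging.getLogger("nirauth")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run.

    ``input_csv`` takes precedence; otherwise a synthetic cohort is
    generated from ``generator``. The default split fraction 0.696 puts
    ~70% of each class in the training set (e.g. 300/431 and 80/115).
    """

    input_csv: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    trim_low: float = 4000.0
    trim_high: float = 9000.0
    outlier_cutoff: float = 3.0
    outlier_n_random: int = 500
    outlier_seed: int = 0
    outlier_per_class: bool = True
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split_fraction: float | None = 0.696
    split_counts: dict[str, int] | None = None
    split_on_preprocessed: bool = True
    max_lv: int = 20
    mccv_T: int = 20
    mccv_fraction: float = 0.5
    mccv_seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build from a YAML file with sections input/trim/outliers/
        preprocess/split/plsda/mccv/output."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        sec = raw.get("input", {})
        cfg.input_csv = sec.get("csv")
        if "generator" in sec:
            cfg.generator = GeneratorConfig(**sec["generator"])
        sec = raw.get("trim", {})
        cfg.trim_low = sec.get("low", cfg.trim_low)
        cfg.trim_high = sec.get("high", cfg.trim_high)
        sec = raw.get("outliers", {})
        cfg.outlier_cutoff = sec.get("cutoff", cfg.outlier_cutoff)
        cfg.outlier_n_random = sec.get("n_random", cfg.outlier_n_random)
        cfg.outlier_seed = sec.get("seed", cfg.outlier_seed)
        cfg.outlier_per_class = sec.get("per_class", cfg.outlier_per_class)
        sec = raw.get("preprocess", {})
        if sec:
            cfg.preprocess = PreprocessConfig(
                method=Method(sec.get("method", "raw")),
                sg_window=sec.get("sg_window", 11),
                sg_polyorder=sec.get("sg_polyorder"),
            )
        sec = raw.get("split", {})
        if "train_counts" in sec:
            cfg.split_counts, cfg.split_fraction = dict(sec["train_counts"]), None
        elif "train_fraction" in sec:
            cfg.split_fraction = sec["train_fraction"]
        cfg.split_on_preprocessed = sec.get("on_preprocessed", cfg.split_on_preprocessed)
        sec = raw.get("plsda", {})
        cfg.max_lv = sec.get("max_lv", cfg.max_lv)
        sec = raw.get("mccv", {})
        cfg.mccv_T = sec.get("T", cfg.mccv_T)
        cfg.mccv_fraction = sec.get("fraction", cfg.mccv_fraction)
        cfg.mccv_seed = sec.get("seed", cfg.mccv_seed)
        sec = raw.get("output", {})
        cfg.output_dir = sec.get("dir")
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"]["method"] = Method(self.preprocess.method).value
        return d


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    n_input: int
    n_removed: dict[str, int]
    n_retained: int
    per_class_split: dict[str, tuple[int, int]]
    chosen_lv: int
    mr_by_lv: list[float]
    confusion: dict[str, int]
    sensitivity: float
    specificity: float
    seeds: dict[str, int]
    version: str = __version__

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.n_removed.values()) != self.n_input:
            raise ValueError("removed + retained must equal input count")
        n_split = sum(a + b for a, b in self.per_class_split.values())
        if n_split != self.n_retained:
            raise ValueError("train + test must equal retained count")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return out
        return wrapped
    return deco


@_stage("input")
def _load(config: PipelineConfig) -> SpectralDataset:
    if config.input_csv:
        return read_spectra_csv(config.input_csv)
    dataset, _ = simulate_dataset(config.generator)
    return dataset


def run_pipeline(
    config: PipelineConfig, dataset: SpectralDataset | None = None
) -> RunReport:
    """Execute the full pipeline; optionally on an in-memory dataset.

    Writes the JSON report and per-stage CSV artifacts to
    ``config.output_dir`` when set (all files written only after every
    stage succeeded, so a failed run leaves nothing behind).
    """
    if dataset is None:
        dataset = _load(config)
    n_input = dataset.n
    logger.info("input: n=%d p=%d", dataset.n, dataset.p)

    trimmed = _stage("trim")(trim_wavenumbers)(dataset, config.trim_low, config.trim_high)
    logger.info("trim [%g, %g]: p=%d", config.trim_low, config.trim_high, trimmed.p)

    cleaned, out_results = _stage("outliers")(flag_and_remove)(
        trimmed, cutoff=config.outlier_cutoff, n_random=config.outlier_n_random,
        seed=config.outlier_seed, per_class=config.outlier_per_class,
    )
    n_removed = {k: int(v.mask.sum()) for k, v in out_results.items()}
    logger.info("outliers removed: %s -> n=%d", n_removed, cleaned.n)

    pre = _stage("preprocess")(apply_preprocessing)(cleaned, config.preprocess)

    split_basis = pre if config.split_on_preprocessed else cleaned
    split = _stage("split")(split_per_class)(
        split_basis, train_fraction=config.split_fraction, train_counts=config.split_counts,
    )
    logger.info("split: %s", split.per_class_counts)

    X_train = pre.absorbance[split.train_indices]
    y_train = pre.labels[split.train_indices]
    X_test = pre.absorbance[split.test_indices]
    y_test = pre.labels[split.test_indices]

    mccv = _stage("mccv")(mccv_select_lv)(
        X_train, y_train, max_lv=config.max_lv, T=config.mccv_T,
        fraction=config.mccv_fraction, seed=config.mccv_seed,
    )
    logger.info("mccv: chosen_lv=%d min MR=%.2f%%", mccv.chosen_lv, mccv.mr_by_lv.min())

    model = _stage("fit")(
        lambda: PLSDAClassifier(n_components=mccv.chosen_lv).fit(X_train, y_train)
    )()
    predicted = _stage("predict")(model.predict)(X_test)
    counts, sens, spec = _stage("evaluate")(evaluate)(y_test, predicted)
    logger.info("prediction set: sens=%.3f spec=%.3f", sens, spec)

    report = RunReport(
        config=config.echo(),
        n_input=n_input,
        n_removed=n_removed,
        n_retained=cleaned.n,
        per_class_split={k: tuple(v) for k, v in split.per_class_counts.items()},
        chosen_lv=mccv.chosen_lv,
        mr_by_lv=[round(float(v), 6) for v in mccv.mr_by_lv],
        confusion=dict(tp=counts.tp, fn=counts.fn, tn=counts.tn, fp=counts.fp),
        sensitivity=round(sens, 3),
        specificity=round(spec, 3),
        seeds=dict(outliers=config.outlier_seed, mccv=config.mccv_seed,
                   generator=config.generator.seed),
    )

    if config.output_dir:
        _write_artifacts(config, trimmed, out_results, pre, split, mccv, model,
                         y_test, predicted, report)
    return report


def _write_artifacts(config, trimmed, out_results, pre, split, mccv, model,
                     y_test, predicted, report) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for group, res in out_results.items():
        idx = trimmed.class_indices(group) if group in (POS, NEG) else np.arange(trimmed.n)
        for k, i in enumerate(idx):
            rows.append(dict(sample_id=trimmed.sample_ids[i], label=trimmed.labels[i],
                             outlyingness=res.values[k], flagged=bool(res.mask[k])))
    pd.DataFrame(rows).to_csv(outdir / "outliers.csv", index=False)

    subset = np.empty(pre.n, dtype=object)
    subset[split.train_indices] = "train"
    subset[split.test_indices] = "test"
    pd.DataFrame(dict(sample_id=pre.sample_ids, label=pre.labels, subset=subset)
                 ).to_csv(outdir / "split.csv", index=False)

    pd.DataFrame(dict(n_lv=np.arange(1, len(mccv.mr_by_lv) + 1),
                      mr_percent=mccv.mr_by_lv)).to_csv(outdir / "mr_by_lv.csv", index=False)

    resp = model.predict_responses(pre.absorbance[split.test_indices])
    pd.DataFrame(dict(sample_id=pre.sample_ids[split.test_indices], true=y_test,
                      response1=resp[:, 0], predicted=predicted)
                 ).to_csv(outdir / "predictions.csv", index=False)

    (outdir / "report.json").write_text(report.to_json() + "\n")


def compare_arms(
    config: PipelineConfig,
    arms: list[PreprocessConfig] | None = None,
    dataset: SpectralDataset | None = None,
) -> pd.DataFrame:
    """One pipeline run per pretreatment arm, sharing trim and outlier
    removal (and the split itself when ``split_on_preprocessed`` is off).

    Returns a table with one row per arm: method, chosen latent-variable
    count, sensitivity, specificity (3 decimals) and confusion fractions.
    """
    if arms is None:
        arms = [PreprocessConfig(method=m) for m in (Method.RAW, Method.SNV,
                                                     Method.D2, Method.SMOOTH)]
    if not arms:
        raise ValueError("need at least one arm")
    if dataset is None:
        dataset = _load(config)
    trimmed = _stage("trim")(trim_wavenumbers)(dataset, config.trim_low, config.trim_high)
    cleaned, _ = _stage("outliers")(flag_and_remove)(
        trimmed, cutoff=config.outlier_cutoff, n_random=config.outlier_n_random,
        seed=config.outlier_seed, per_class=config.outlier_per_class,
    )
    shared_split = None
    if not config.split_on_preprocessed:
        shared_split = split_per_class(cleaned, train_fraction=config.split_fraction,
                                       train_counts=config.split_counts)
    rows = []
    for arm in arms:
        pre = apply_preprocessing(cleaned, arm)
        split = shared_split or split_per_class(
            pre, train_fraction=config.split_fraction, train_counts=config.split_counts)
        X_tr, y_tr = pre.absorbance[split.train_indices], pre.labels[split.train_indices]
        X_te, y_te = pre.absorbance[split.test_indices], pre.labels[split.test_indices]
        mccv = mccv_select_lv(X_tr, y_tr, max_lv=config.max_lv, T=config.mccv_T,
                              fraction=config.mccv_fraction, seed=config.mccv_seed)
        model = PLSDAClassifier(n_components=mccv.chosen_lv).fit(X_tr, y_tr)
        counts, sens, spec = evaluate(y_te, model.predict(X_te))
        rows.append(dict(
            method=Method(arm.method).value, n_lv=mccv.chosen_lv,
            sensitivity=round(sens, 3), specificity=round(spec, 3),
            sens_fraction=f"{counts.tp}/{counts.tp + counts.fn}",
            spec_fraction=f"{counts.tn}/{counts.tn + counts.fp}",
        ))
    return pd.DataFrame(rows, columns=["method", "n_lv", "sensitivity", "specificity",
                                       "sens_fraction", "spec_fraction"])
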