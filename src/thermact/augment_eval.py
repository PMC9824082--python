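"""Pairwise-interpolation augmentation and the evaluation harness.

The harness reproduces the study protocols end to end on any dataset tensor:
repeated stratified 75/25 splits with every trainable component (denoiser,
subspace extractor, classifier) fitted on the training portion only; a
matched-splits A/B comparison of the pipeline with and without periodic
noise removal; cross-layout transfer (train on one sensor distance, test on
the other, or pool both); and sensor-subset comparison with per-sensor
feature concatenation.

Augmentation averages pairs of spatiotemporal maps of the *same subject and
activity*: for each group of exactly 10 repeats, the pairs
(1,2), (2,3), ..., (9,10), (2,4) generate 10 new maps, doubling the sample
count (450 -> 900 for a 15-class, 3-subject design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import classify, denoise, features
from .classify import ClassifierSpec
from .io_frames import ActivityRecord
from .preprocess import DatasetTensor, build_dataset

#: the stated pairing for 10 repeats (0-based): consecutive pairs plus (2,4)
AUGMENT_PAIRS = tuple((i, i + 1) for i in range(9)) + ((1, 3),)


@dataclass
class PipelineConfig:
    """One end-to-end configuration: extractor + classifier (+ denoiser)."""

    extractor: str = "svd"
    extractor_params: dict = field(default_factory=dict)
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("lr"))
    denoise: bool = False
    #: parameter-search settings passed to fit_noise_params; the harness
    #: default is a reduced desk-scale profile (see docs/methods.md)
    denoise_fit: dict = field(
        default_factory=lambda: {
            "K": 3,
            "i1_grid": range(-2, 9, 2),
            "num_cand_h": (1, 2, 3, 4, 6, 8, 12, 16),
            "num_cand_v": (1, 2, 3, 4, 6, 8, 12, 16),
        }
    )

    def fingerprint(self) -> dict:
        return {
            "extractor": self.extractor,
            "extractor_params": dict(self.extractor_params),
            "classifier": self.classifier.describe(),
            "denoise": self.denoise,
        }


@dataclass
class ExperimentResult:
    """Per-repeat accuracies plus aggregates and the summed confusion matrix."""

    train_accs: np.ndarray
    test_accs: np.ndarray
    confusion: pd.DataFrame
    config: dict
    seeds: tuple[int, ...] = ()
    noise_params: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.test_accs))

    @property
    def std(self) -> float:
        """Sample standard deviation of the per-repeat test accuracies."""
        return float(np.std(self.test_accs, ddof=1)) if len(self.test_accs) > 1 else 0.0

    def summary(self) -> str:
        return f"{100 * self.mean:.2f}% +/- {100 * self.std:.2f}% over {len(self.test_accs)} repeats"


def augment_pairwise(data: DatasetTensor) -> DatasetTensor:
    """Double a dataset by averaging same-subject, same-activity map pairs.

    Every (subject, activity) group must contain exactly 10 repeats in
    tensor order; each group contributes 10 averaged maps appended after the
    originals.
    """
    if data.subjects is None:
        raise ValueError("augmentation needs per-map subject metadata")
    groups: dict[tuple, list[int]] = {}
    for i, (subj, lab) in enumerate(zip(data.subjects, data.labels)):
        groups.setdefault((subj, lab), []).append(i)
    new_maps, new_labels, new_subjects, new_layouts = [], [], [], []
    for (subj, lab), idx in groups.items():
        if len(idx) != 10:
            raise ValueError(
                f"group (subject={subj!r}, activity={lab!r}) has {len(idx)} repeats; "
                "the pairing scheme is defined for exactly 10"
            )
        for a, b in AUGMENT_PAIRS:
            new_maps.append(0.5 * (data.maps[idx[a]] + data.maps[idx[b]]))
            new_labels.append(lab)
            new_subjects.append(subj)
            if data.layouts is not None:
                new_layouts.append(data.layouts[idx[a]])
    maps = np.concatenate([data.maps, np.stack(new_maps)])
    labels = np.concatenate([data.labels, np.array(new_labels)])
    subjects = np.concatenate([data.subjects, np.array(new_subjects)])
    layouts = None
    if data.layouts is not None:
        layouts = np.concatenate([data.layouts, np.array(new_layouts)])
    return DatasetTensor(maps, labels, subjects, layouts)


def _fit_and_score(
    train: DatasetTensor,
    test: DatasetTensor,
    config: PipelineConfig,
    seed: int,
) -> tuple[float, float, pd.DataFrame, denoise.NoiseParams | None]:
    """Fit the full pipeline on ``train`` only and score both portions."""
    params = None
    if config.denoise:
        params, _ = denoise.fit_noise_params(train, seed=seed, **config.denoise_fit)
        train = denoise.denoise_dataset(train, params)
        test = denoise.denoise_dataset(test, params)
    kw = dict(config.extractor_params)
    if config.extractor == "svd":
        kw.setdefault("k", min(45, len(train) - 1))
    model = features.fit_extractor(train, config.extractor, **kw)
    ftr = features.extract_features(train, config.extractor, model)
    fte = features.extract_features(test, config.extractor, model)
    spec = ClassifierSpec(config.classifier.family, config.classifier.params, seed=seed)
    clf = classify.train(spec, ftr)
    return (
        classify.accuracy(clf, ftr),
        classify.accuracy(clf, fte),
        classify.confusion(clf, fte),
        params,
    )


def run_experiment(
    data: DatasetTensor,
    config: PipelineConfig,
    repeats: int = 10,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> ExperimentResult:
    """Repeated stratified holdout evaluation of one pipeline configuration."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    if len(np.unique(data.labels)) < 2:
        raise ValueError("need at least 2 classes")
    tr_accs, te_accs, confs, fitted = [], [], [], []
    rep_seeds = tuple(seed + r for r in range(repeats))
    for rs in rep_seeds:
        idx_tr, idx_te = train_test_split(
            np.arange(len(data)), test_size=test_fraction,
            stratify=data.labels, random_state=rs,
        )
        tr_acc, te_acc, cm, params = _fit_and_score(
            data.subset(idx_tr), data.subset(idx_te), config, rs
        )
        tr_accs.append(tr_acc)
        te_accs.append(te_acc)
        confs.append(cm)
        fitted.append(params)
    total = confs[0]
    for cm in confs[1:]:
        total = total.add(cm, fill_value=0)
    return ExperimentResult(
        np.array(tr_accs), np.array(te_accs), total.astype(int),
        config.fingerprint(), rep_seeds, fitted,
    )


def ab_noise_test(
    data: DatasetTensor,
    config: PipelineConfig,
    repeats: int = 10,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[ExperimentResult, ExperimentResult]:
    """Matched A/B comparison: denoising off vs on with identical splits.

    Returns (off, on); both arms share repeat seeds, hence splits.
    """
    cfg_off = PipelineConfig(
        config.extractor, dict(config.extractor_params), config.classifier,
        denoise=False, denoise_fit=dict(config.denoise_fit),
    )
    cfg_on = PipelineConfig(
        config.extractor, dict(config.extractor_params), config.classifier,
        denoise=True, denoise_fit=dict(config.denoise_fit),
    )
    off = run_experiment(data, cfg_off, repeats, test_fraction, seed)
    on = run_experiment(data, cfg_on, repeats, test_fraction, seed)
    return off, on


def activity_key(label: str) -> str:
    """Layout-independent activity identity: AS3 and AL3 both map to A3."""
    if label.startswith(("AS", "AL")):
        return "A" + label[2:]
    return label


def _with_activity_keys(data: DatasetTensor) -> DatasetTensor:
    labels = np.array([activity_key(l) for l in data.labels])
    return DatasetTensor(data.maps, labels, data.subjects, data.layouts)


def cross_layout_test(
    train_data: DatasetTensor,
    test_data: DatasetTensor,
    config: PipelineConfig,
    seed: int = 0,
) -> ExperimentResult:
    """Train entirely on one layout's data and score on the other's.

    Labels are first reduced to layout-independent activity keys; a
    vocabulary mismatch raises an error.
    """
    tr = _with_activity_keys(train_data)
    te = _with_activity_keys(test_data)
    vtr, vte = set(tr.labels), set(te.labels)
    if vtr != vte:
        raise ValueError(f"label vocabularies differ: {sorted(vtr ^ vte)}")
    tr_acc, te_acc, cm, params = _fit_and_score(tr, te, config, seed)
    return ExperimentResult(
        np.array([tr_acc]), np.array([te_acc]), cm,
        {**config.fingerprint(), "protocol": "cross-layout"}, (seed,), [params],
    )


def mixed_layout_test(
    data_a: DatasetTensor,
    data_b: DatasetTensor,
    config: PipelineConfig,
    repeats: int = 10,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> ExperimentResult:
    """Pool both layouts and run the repeated-holdout protocol."""
    a, b = _with_activity_keys(data_a), _with_activity_keys(data_b)
    pooled = DatasetTensor(
        np.concatenate([a.maps, b.maps]),
        np.concatenate([a.labels, b.labels]),
        None if a.subjects is None or b.subjects is None
        else np.concatenate([a.subjects, b.subjects]),
        None if a.layouts is None or b.layouts is None
        else np.concatenate([a.layouts, b.layouts]),
    )
    return run_experiment(pooled, config, repeats, test_fraction, seed)


def sensor_subset_test(
    records: Sequence[ActivityRecord],
    subsets: Sequence[Sequence[str]],
    config: PipelineConfig,
    repeats: int = 5,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> dict[tuple[str, ...], ExperimentResult]:
    """Compare pipelines built on different sensor subsets.

    Features are extracted per sensor (extractor fitted per sensor on the
    training portion) and concatenated for multi-sensor subsets.  Splits are
    shared across subsets so results are directly comparable.
    """
    all_sensors = sorted({s for subset in subsets for s in subset})
    tensors = {}
    for sid in all_sensors:
        tensors[sid] = build_dataset(records, sid)  # raises if a sensor is missing
    labels = tensors[all_sensors[0]].labels
    Z = len(labels)
    results: dict[tuple[str, ...], ExperimentResult] = {}
    split_seeds = tuple(seed + r for r in range(repeats))
    for subset in subsets:
        key = tuple(subset)
        tr_accs, te_accs, confs = [], [], []
        for rs in split_seeds:
            idx_tr, idx_te = train_test_split(
                np.arange(Z), test_size=test_fraction, stratify=labels, random_state=rs
            )
            Xtr_parts, Xte_parts = [], []
            for sid in subset:
                dtr = tensors[sid].subset(idx_tr)
                dte = tensors[sid].subset(idx_te)
                kw = dict(config.extractor_params)
                if config.extractor == "svd":
                    kw.setdefault("k", min(45, len(dtr) - 1))
                model = features.fit_extractor(dtr, config.extractor, **kw)
                Xtr_parts.append(features.extract_features(dtr, config.extractor, model).X)
                Xte_parts.append(features.extract_features(dte, config.extractor, model).X)
            ftr = features.FeatureMatrix(
                np.hstack(Xtr_parts), labels[idx_tr], config.extractor, {"sensors": key}
            )
            fte = features.FeatureMatrix(
                np.hstack(Xte_parts), labels[idx_te], config.extractor, {"sensors": key}
            )
            spec = ClassifierSpec(config.classifier.family, config.classifier.params, seed=rs)
            clf = classify.train(spec, ftr)
            tr_accs.append(classify.accuracy(clf, ftr))
            te_accs.append(classify.accuracy(clf, fte))
            confs.append(classify.confusion(clf, fte))
        total = confs[0]
        for cm in confs[1:]:
            total = total.add(cm, fill_value=0)
        results[key] = ExperimentResult(
            np.array(tr_accs), np.array(te_accs), total.astype(int),
            {**config.fingerprint(), "sensors": key, "n_features": int(ftr.X.shape[1])},
            split_seeds,
        )
    return results
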