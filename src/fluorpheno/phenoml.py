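"""Fisher-criterion sequential forward selection and cross-validated
two-class stress classification.

The feature table holds 105 named fluorescence parameters per sample with
labels 1 (control) and 2 (drought-stressed). SFS greedily grows a subset
under a two-class Fisher separability criterion; classification is a
linear maximum-margin classifier on z-scored selected features with
stratified 10-fold cross-validation, reported as per-class and overall
accuracies per day.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import fluorparams, fluorsim, imaging
from .protocol import ProtocolDefinition, default_quenching_protocol

__all__ = [
    "FeatureTable",
    "SelectionResult",
    "CvReport",
    "fisher_ratio",
    "sfs_select",
    "cv_classify",
    "sample_features",
    "cohort_feature_table",
    "run_pipeline",
]


@dataclass
class FeatureTable:
    """Samples x parameters matrix with class labels (1=control, 2=drought)."""

    features: pd.DataFrame          # numeric, indexed by sample id
    labels: pd.Series               # aligned with features.index
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        self.labels = self.labels.loc[self.features.index]
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


@dataclass
class SelectionResult:
    selected: list[str]
    criterion_trajectory: list[float]
    k: int

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"selected": self.selected, "criterion": self.criterion_trajectory, "k": self.k},
                indent=2,
            )
        )


@dataclass
class CvReport:
    control_accuracy_pct: float
    drought_accuracy_pct: float
    overall_accuracy_pct: float
    fold_assignments: np.ndarray
    seed: int
    day: int | None = None
    genotype: str | None = None
    n_samples: int = 0


def fisher_ratio(feature_values, labels) -> float:
    """Two-class Fisher criterion J = (mu1 - mu2)^2 / (s1^2 + s2^2) with
    unbiased class variances. Returns +inf (with a warning) when both
    classes are degenerate but separated."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    a, b = x[y == classes[0]], x[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    denom = a.var(ddof=1) + b.var(ddof=1)
    num = (a.mean() - b.mean()) ** 2
    if denom == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero within-class variance: Fisher ratio is infinite", stacklevel=2)
        return float("inf")
    return float(num / denom)


def _subset_criterion(X: np.ndarray, y: np.ndarray) -> float:
    """Multiclass-free subset score: squared between-class mean difference
    whitened by the summed within-class covariance, d' Sw^-1 d. For a
    single feature this reduces exactly to :func:`fisher_ratio`."""
    classes = np.unique(y)
    a, b = X[y == classes[0]], X[y == classes[1]]
    d = a.mean(axis=0) - b.mean(axis=0)
    sw = np.cov(a, rowvar=False, ddof=1) + np.cov(b, rowvar=False, ddof=1)
    sw = np.atleast_2d(sw)
    ridge = 1e-12 * max(np.trace(sw) / sw.shape[0], 1.0)
    sw = sw + ridge * np.eye(sw.shape[0])
    try:
        return float(d @ np.linalg.solve(sw, d))
    except np.linalg.LinAlgError:
        return float(d @ np.linalg.pinv(sw) @ d)


def sfs_select(table: FeatureTable, k: int = 9) -> SelectionResult:
    """Greedy sequential forward selection under the subset Fisher
    criterion; deterministic (candidate ties broken by column order),
    stopping at exactly ``k`` features."""
    names = table.feature_names
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} available features")
    y = table.labels.to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("feature table must contain exactly two classes")
    X = table.features.to_numpy(dtype=float)
    selected: list[int] = []
    trajectory: list[float] = []
    remaining = list(range(len(names)))
    for _ in range(k):
        best_j, best_score = None, -np.inf
        for j in remaining:
            score = _subset_criterion(X[:, selected + [j]], y)
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
        trajectory.append(best_score)
    return SelectionResult(
        selected=[names[j] for j in selected], criterion_trajectory=trajectory, k=k
    )


def cv_classify(
    table: FeatureTable,
    features: SelectionResult | list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    day: int | None = None,
    genotype: str | None = None,
) -> CvReport:
    """Stratified k-fold cross-validation of a linear maximum-margin
    classifier on the selected features.

    Features are z-scored with the scaler fit on the training fold only.
    Reports control-class, drought-class and overall accuracy in percent,
    aggregated over all held-out folds.
    """
    names = (
        features.selected
        if isinstance(features, SelectionResult)
        else (list(features) if features is not None else table.feature_names)
    )
    X = table.features[names].to_numpy(dtype=float)
    y = table.labels.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("classification requires both classes present")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        warnings.warn(
            f"fewer than {folds} samples in a class {counts}; "
            f"reducing to {min(counts.values())} folds",
            stacklevel=2,
        )
        folds = min(counts.values())
    if folds < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
        fold_of[te] = f
    correct = pred == y
    ctrl = y == 1
    drt = y == 2
    return CvReport(
        control_accuracy_pct=100.0 * correct[ctrl].mean() if ctrl.any() else float("nan"),
        drought_accuracy_pct=100.0 * correct[drt].mean() if drt.any() else float("nan"),
        overall_accuracy_pct=100.0 * correct.mean(),
        fold_assignments=fold_of,
        seed=seed,
        day=day,
        genotype=genotype,
        n_samples=len(y),
    )


# ---------------------------------------------------------------------------
# feature assembly from simulated (or loaded) stacks

def sample_features(
    sample: fluorsim.CohortSample,
    protocol: ProtocolDefinition | None = None,
    seg_cfg: imaging.SegmentationConfig | None = None,
) -> dict[str, float]:
    """Run the extraction pipeline on one sample: segment on the Fm flash
    frame, extract the canopy trace, locate base signals, and compute the
    89 + 16 = 105 parameters."""
    protocol = protocol or default_quenching_protocol()
    ref = imaging.reference_frame(sample.stack, protocol)
    mask = imaging.segment_plant(ref, seg_cfg)
    trace = imaging.extract_trace(sample.stack, mask)
    signals = fluorparams.extract_basic_signals(trace, protocol)
    chl = fluorparams.compute_catalogue(signals)
    mc = fluorparams.multicolor_parameters(
        fluorparams.extract_multicolor_signals(sample.multicolor, mask)
    )
    return {**chl.values, **mc.values}


def cohort_feature_table(
    samples: list[fluorsim.CohortSample],
    protocol: ProtocolDefinition | None = None,
    seg_cfg: imaging.SegmentationConfig | None = None,
    day: int | None = None,
    genotype: str | None = None,
) -> FeatureTable:
    """Assemble the samples x 105 feature table for a simulated cohort."""
    protocol = protocol or default_quenching_protocol()
    rows, labels, meta = {}, {}, []
    for s in samples:
        rows[s.plant_id] = sample_features(s, protocol, seg_cfg)
        labels[s.plant_id] = s.label
        meta.append(
            {"plant_id": s.plant_id, "label": s.label, "preset": s.preset_name,
             "seed": s.seed, "day": day, "genotype": genotype}
        )
    features = pd.DataFrame.from_dict(rows, orient="index")
    return FeatureTable(
        features=features,
        labels=pd.Series(labels, name="label"),
        metadata=pd.DataFrame(meta).set_index("plant_id"),
    )


def run_pipeline(config: dict, out_dir=None) -> dict:
    """End-to-end run: simulate -> segment -> extract -> catalogue ->
    select -> classify for each configured day.

    ``config`` keys: ``days`` (list of day presets, e.g. ["day1", "day3"]),
    ``n_control``/``n_drought``, ``seed``, ``k`` (features to select),
    ``folds``, and optionally ``genotype``. Writes a classification report
    CSV shaped like a per-day accuracy table plus selection lists,
    significance tables and the trait correlation network when ``out_dir``
    is given.
    """
    days = config.get("days", ["day1", "day3", "day5", "day7", "day8"])
    n_control = int(config.get("n_control", 54))
    n_drought = int(config.get("n_drought", 54))
    seed = int(config.get("seed", 0))
    k = int(config.get("k", 9))
    folds = int(config.get("folds", 10))
    genotype = config.get("genotype", "WT")
    if n_control <= 0 or n_drought <= 0:
        raise RuntimeError("pipeline failed at stage 'simulate': empty cohort")

    report_rows = []
    bundle: dict = {"selections": {}, "reports": {}, "significance": {}, "seed": seed}
    for i, preset_name in enumerate(days):
        preset = fluorsim.get_preset(preset_name)
        try:
            cohort = fluorsim.simulate_cohort(
                n_control, n_drought, preset, seed=seed + 1000 * i
            )
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed at stage 'simulate' ({preset_name}): {e}")
        try:
            table = cohort_feature_table(cohort, day=preset.day, genotype=genotype)
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed at stage 'extract' ({preset_name}): {e}")
        sel = sfs_select(table, k=k)
        rep = cv_classify(table, sel, folds=folds, seed=seed, day=preset.day, genotype=genotype)
        bundle["selections"][preset_name] = sel
        bundle["reports"][preset_name] = rep
        sig = [
            compare_row
            for compare_row in _significance_rows(table, preset.day, genotype)
        ]
        bundle["significance"][preset_name] = pd.DataFrame(sig)
        report_rows.append(
            {
                "day": preset.day,
                "genotype": genotype,
                "control_pct": round(rep.control_accuracy_pct, 1),
                "drought_pct": round(rep.drought_accuracy_pct, 1),
                "overall_pct": round(rep.overall_accuracy_pct, 1),
            }
        )
    report = pd.DataFrame(report_rows)
    bundle["table"] = report
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "classification_report.csv", index=False)
        for name, sel in bundle["selections"].items():
            sel.to_json(out / f"selection_{name}.json")
        for name, df in bundle["significance"].items():
            df.to_csv(out / f"significance_{name}.csv", index=False)
    return bundle


def _significance_rows(table: FeatureTable, day, genotype):
    from .stats import compare_treatments

    merged = table.features.copy()
    merged["label"] = table.labels
    for param in ("Fv/Fm", "NPQ_Lss", "PhiPSII_Lss", "Rfd_L3", "BF", "GF", "RF", "IrF"):
        if param not in table.features.columns:
            continue
        res = compare_treatments(merged, param, day=None)
        yield {
            "parameter": param,
            "day": day,
            "genotype": genotype,
            "p_value": res.p_value,
            "stars": res.stars,
        }
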