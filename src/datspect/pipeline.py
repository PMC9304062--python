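"""End-to-end orchestration of the two-cohort synthetic experiment.

``run_experiment`` reproduces the full analysis protocol on phantoms:

1. simulate a training-like cohort (default 137 subjects) and a test-like
   cohort (default 102 subjects) with distinct class mixes and age models;
2. standardize every volume to the 70x70 frame; build the group striatal
   mask from the flip-augmented, max-normalized training images; produce
   background-normalized images for learning;
3. compute ROI indices (SBR, asymmetry index, putamen:caudate ratio);
4. cross-validate the three classifier families on the training cohort for
   each visual feature, then train final classifiers on the full augmented
   training set and score the test cohort;
5. build the three diagnosis models on the training cohort and compare
   their ROC curves on the test cohort (Youden thresholds, DeLong tests).

All randomness derives from a single seed; two runs with the same
configuration produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import diagnosis, feature_ml, phantom, preprocess, roi_quant
from .phantom import DiagnosisRule, PhantomParams
from .types import FeatureLabelSet, StandardImage, SubjectRecord

__all__ = ["PipelineConfig", "ExperimentResult", "simulate_cohorts",
           "run_experiment", "write_outputs", "preprocess_cohort"]

FEATURES = ("low", "asymmetric", "dot", "abnormal")
FAMILY = {"low": "low", "asymmetric": "asym", "dot": "dot", "abnormal": "abnormal"}


@dataclass
class PipelineConfig:
    """Resolved settings of one experiment run."""

    seed: int = 1
    n_train: int = 137
    n_test: int = 102
    phantom: PhantomParams = field(default_factory=PhantomParams)
    rule: DiagnosisRule = field(default_factory=DiagnosisRule)
    mask_cutoff: float = 0.30
    mask_mode: str = "robust"
    background_target: float = 0.15
    stepwise_epsilon: float = 0.005
    stepwise_criterion: str = "cv"
    # "test_insample": the logistic layers of Models 1 and 3 are fit and
    # assessed on the test cohort (the feature classifiers remain trained on
    # the training cohort); "two_cohort": logistic layers are fit on the
    # training cohort and only scored on the test cohort.
    model_protocol: str = "test_insample"
    methods: tuple[str, ...] = ("lr", "knn", "gbt")
    gbt_n_estimators: int = 200

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = dataclasses.asdict(self.phantom)
        d["rule"] = dataclasses.asdict(self.rule)
        d["methods"] = list(self.methods)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "phantom" in d:
            pp = d.pop("phantom")
            for k in ("image_size", "brain_axes", "putamen_axes"):
                if k in pp:
                    pp[k] = tuple(pp[k])
            d["phantom"] = PhantomParams(**pp)
        if "rule" in d:
            d["rule"] = DiagnosisRule(**d.pop("rule"))
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    def spec_for(self, method: str, seed: int) -> feature_ml.ClassifierSpec:
        hp = {}
        if method == "gbt":
            hp["n_estimators"] = self.gbt_n_estimators
        return feature_ml.ClassifierSpec(method=method, hyperparameters=hp, seed=seed)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_cohorts(config: PipelineConfig) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Training-like and test-like cohorts from the config seed."""
    s_train, s_test = _child_seeds(config.seed, 2)
    train = phantom.generate_cohort(config.n_train, phantom.TRAINING_MIX,
                                    phantom.AGE_TRAINING, config.rule,
                                    seed=s_train, params=config.phantom, prefix="TR")
    test = phantom.generate_cohort(config.n_test, phantom.TEST_MIX,
                                   phantom.AGE_TEST, config.rule,
                                   seed=s_test, params=config.phantom, prefix="TE")
    return train, test


def preprocess_cohort(records: Sequence[SubjectRecord]) -> list[tuple[np.ndarray, dict]]:
    return [preprocess.preprocess_volume(r.volume, r.subject_id) for r in records]


@dataclass
class ExperimentResult:
    config: PipelineConfig
    manifest_train: pd.DataFrame
    manifest_test: pd.DataFrame
    roi_train: pd.DataFrame
    roi_test: pd.DataFrame
    feature_metrics: pd.DataFrame
    train_probabilities: pd.DataFrame   # out-of-fold, per subject x feature x method
    test_probabilities: pd.DataFrame    # final classifiers applied to the test cohort
    model1: diagnosis.DiagnosisModel
    model3: diagnosis.DiagnosisModel
    stepwise_trace: list[dict]
    best_abnormal_method: str
    roc_model1: diagnosis.RocResult
    roc_model2: diagnosis.RocResult
    roc_model3: diagnosis.RocResult
    comparisons: pd.DataFrame
    model_summary: pd.DataFrame


def _roi_table(records, images, base_template) -> pd.DataFrame:
    rows = []
    for rec, img in zip(records, images):
        idx = roi_quant.compute_indices(img, base_template, subject_id=rec.subject_id)
        rows.append(idx.as_dict())
    return pd.DataFrame(rows)


def run_experiment(config: PipelineConfig | None = None,
                   cohorts: tuple[list[SubjectRecord], list[SubjectRecord]] | None = None
                   ) -> ExperimentResult:
    config = config or PipelineConfig()
    if cohorts is None:
        cohorts = simulate_cohorts(config)
    train, test = cohorts
    seeds = _child_seeds(config.seed + 1, 8)

    # --- standardization -------------------------------------------------
    prep_train = preprocess_cohort(train)
    prep_test = preprocess_cohort(test)
    max_train = [preprocess.normalize_max(f, p) for f, p in prep_train]
    mask = preprocess.build_group_striatal_mask(
        preprocess.augment_flip(max_train), cutoff=config.mask_cutoff,
        mode=config.mask_mode)
    bg_train = [preprocess.normalize_background(f, mask, config.background_target,
                                                provenance=p)
                for f, p in prep_train]
    bg_test = [preprocess.normalize_background(f, mask, config.background_target,
                                               provenance=p)
               for f, p in prep_test]

    # --- ROI indices ------------------------------------------------------
    base_tpl = roi_quant.default_template(config.phantom)
    roi_train = _roi_table(train, bg_train, base_tpl)
    roi_test = _roi_table(test, bg_test, base_tpl)

    # --- feature classification ------------------------------------------
    y_train = {f: np.array([getattr(r.labels, f) for r in train], dtype=int)
               for f in FEATURES}
    y_test = {f: np.array([getattr(r.labels, f) for r in test], dtype=int)
              for f in FEATURES}
    metrics_rows = []
    oof_cols, test_cols = {}, {}
    cv_auc: dict[tuple[str, str], float] = {}
    for fi, feat in enumerate(FEATURES):
        for mi, method in enumerate(config.methods):
            spec = config.spec_for(method, seeds[0])
            report, oof = feature_ml.crossvalidate_fourfold(
                bg_train, y_train[feat], spec, seed=seeds[1])
            cv_auc[(feat, method)] = report.auc
            metrics_rows.append({"feature": feat, "method": method,
                                 "auc": report.auc, "recall": report.recall,
                                 "precision": report.precision,
                                 "f1_score": report.f1_score,
                                 "accuracy": report.accuracy,
                                 "p_value": report.p_value})
            col = f"p_{FAMILY[feat]}_{method}"
            oof_cols[col] = oof
            final = feature_ml.train_classifier(
                *preprocess.augment_flip(bg_train, y_train[feat]), spec)
            test_cols[col] = final.predict_proba(bg_test)
    # ROI indices as classical comparators in the same table
    roi_scores = {"low": -roi_train["sbr_mean"].to_numpy(),
                  "asymmetric": roi_train["asymmetry_index"].to_numpy(),
                  "dot": -roi_train["pc_min"].to_numpy()}
    roi_names = {"low": "sbr_mean", "asymmetric": "asymmetry_index", "dot": "pc_min"}
    for feat, score in roi_scores.items():
        rep = feature_ml.compute_metrics(
            (score - score.min()) / np.ptp(score), y_train[feat])
        metrics_rows.append({"feature": feat, "method": f"roi:{roi_names[feat]}",
                             "auc": rep.auc, "recall": rep.recall,
                             "precision": rep.precision, "f1_score": rep.f1_score,
                             "accuracy": rep.accuracy, "p_value": rep.p_value})
    feature_metrics = pd.DataFrame(metrics_rows)

    train_probs = pd.DataFrame(oof_cols, index=[r.subject_id for r in train])
    train_probs.insert(0, "age", [r.age for r in train])
    test_probs = pd.DataFrame(test_cols, index=[r.subject_id for r in test])
    test_probs.insert(0, "age", [r.age for r in test])

    dx_train = np.array([r.diagnosis for r in train], dtype=int)
    dx_test = np.array([r.diagnosis for r in test], dtype=int)

    if config.model_protocol not in ("test_insample", "two_cohort"):
        raise ValueError(f"unknown model protocol {config.model_protocol!r}")
    insample = config.model_protocol == "test_insample"

    # --- Model 1: ROI logistic -------------------------------------------
    model1 = diagnosis.build_model1(roi_test if insample else roi_train,
                                    dx_test if insample else dx_train)
    p1_test = diagnosis.predict_probability(model1, roi_test)
    roc1 = diagnosis.roc_with_youden(p1_test, dx_test)

    # --- Model 2: best ML abnormality probability ------------------------
    best_abn = max(config.methods, key=lambda m: cv_auc[("abnormal", m)])
    p2_test = np.asarray(test_cols[f"p_abnormal_{best_abn}"], dtype=float)
    roc2 = diagnosis.build_model2(p2_test, dx_test)

    # --- Model 3: stepwise on F1-F3 probabilities + age ------------------
    cand_cols = ["age"] + [f"p_{fam}_{m}" for fam in ("low", "asym", "dot")
                           for m in config.methods]
    step_table = test_probs if insample else train_probs
    step_dx = dx_test if insample else dx_train
    model3, trace = diagnosis.forward_stepwise(
        step_table[cand_cols], step_dx, criterion=config.stepwise_criterion,
        epsilon=config.stepwise_epsilon, seed=seeds[2])
    p3_test = diagnosis.predict_probability(model3, test_probs)
    roc3 = diagnosis.roc_with_youden(p3_test, dx_test)

    comp_rows = []
    for (na, sa), (nb, sb) in (
        (("model3", p3_test), ("model1", p1_test)),
        (("model3", p3_test), ("model2", p2_test)),
        (("model2", p2_test), ("model1", p1_test)),
    ):
        c = diagnosis.compare_auc(sa, sb, dx_test)
        comp_rows.append({"model_a": na, "model_b": nb, **c})
    comparisons = pd.DataFrame(comp_rows)

    summary = pd.DataFrame([
        {"model": "model1", "variables": "+".join(model1.variables),
         "auc": roc1.auc, "auc_se": roc1.auc_se,
         "sensitivity": roc1.sens_at_youden, "specificity": roc1.spec_at_youden,
         "youden_threshold": roc1.youden_threshold,
         "p_vs_chance": roc1.p_value_vs_chance},
        {"model": "model2", "variables": f"p_abnormal_{best_abn}",
         "auc": roc2.auc, "auc_se": roc2.auc_se,
         "sensitivity": roc2.sens_at_youden, "specificity": roc2.spec_at_youden,
         "youden_threshold": roc2.youden_threshold,
         "p_vs_chance": roc2.p_value_vs_chance},
        {"model": "model3", "variables": "+".join(model3.variables),
         "auc": roc3.auc, "auc_se": roc3.auc_se,
         "sensitivity": roc3.sens_at_youden, "specificity": roc3.spec_at_youden,
         "youden_threshold": roc3.youden_threshold,
         "p_vs_chance": roc3.p_value_vs_chance},
    ])

    return ExperimentResult(
        config=config,
        manifest_train=phantom.cohort_manifest(train),
        manifest_test=phantom.cohort_manifest(test),
        roi_train=roi_train, roi_test=roi_test,
        feature_metrics=feature_metrics,
        train_probabilities=train_probs, test_probabilities=test_probs,
        model1=model1, model3=model3, stepwise_trace=trace,
        best_abnormal_method=best_abn,
        roc_model1=roc1, roc_model2=roc2, roc_model3=roc3,
        comparisons=comparisons, model_summary=summary,
    )


def write_outputs(result: ExperimentResult, outdir: str | Path,
                  plots: bool = False) -> dict[str, Path]:
    """Write the result bundle as CSV/JSON (+ optional ROC plot)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _csv(name: str, df: pd.DataFrame, index=False):
        p = outdir / name
        df.to_csv(p, index=index, float_format="%.10g")
        paths[name] = p

    result.config.to_yaml(outdir / "config.yaml")
    paths["config.yaml"] = outdir / "config.yaml"
    _csv("manifest_train.csv", result.manifest_train)
    _csv("manifest_test.csv", result.manifest_test)
    _csv("roi_train.csv", result.roi_train)
    _csv("roi_test.csv", result.roi_test)
    _csv("feature_metrics.csv", result.feature_metrics)
    _csv("train_probabilities.csv", result.train_probabilities, index=True)
    _csv("test_probabilities.csv", result.test_probabilities, index=True)
    _csv("model_comparisons.csv", result.comparisons)
    _csv("model_summary.csv", result.model_summary)
    models = {
        "model1": result.model1.as_dict(),
        "model2": {"name": "model2", "method": result.best_abnormal_method},
        "model3": result.model3.as_dict(),
        "stepwise_trace": result.stepwise_trace,
    }
    mp = outdir / "models.json"
    mp.write_text(json.dumps(models, indent=2, sort_keys=True))
    paths["models.json"] = mp
    if plots:
        paths["roc_curves.png"] = plot_roc(result, outdir / "roc_curves.png")
    return paths


def plot_roc(result: ExperimentResult, path: str | Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in (("Model 1 (ROI)", result.roc_model1),
                      ("Model 2 (ML abnormality)", result.roc_model2),
                      ("Model 3 (features + age)", result.roc_model3)):
        ax.plot(1 - roc.specificities, roc.sensitivities,
                label=f"{name}: AUC {roc.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
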