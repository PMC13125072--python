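"""Repeated stratified train/test benchmark of the classifier suite.

Splits are made at the patient level (every record of a patient lands on one
side of the split) with exact stratified 70/30 counts per class, so that
within-patient correlation cannot leak between train and test. Per repeat,
each classifier is fitted on the training records, each test patient is
scored by the mean of their record-level positive-class probabilities, the
operating threshold is chosen by Youden's index on the training patients,
and the full metric suite is computed on the test patients. Results are
reported as mean +/- sample SD over repeats, together with a McNemar
comparison of a designated classifier pair on the matched per-patient test
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .cohort import CHANNELS, LABEL_NORMAL, LABEL_RISK, PreprocessParams, Preprocessor
from .estimators import (
    BinnedMultinomialNB,
    DecisionTableClassifier,
    GaussianNB,
    RidgeLogisticRegression,
    SMOClassifier,
)

__all__ = ["default_models", "stratified_patient_split", "run_benchmark", "BenchmarkReport"]

METRIC_NAMES = (
    "accuracy",
    "tp_rate",
    "fp_rate",
    "precision",
    "recall",
    "f1",
    "mcc",
    "roc_auc",
    "pr_auc",
)


def default_models() -> dict:
    """The five benchmark classifiers with their default hyperparameters."""
    return {
        "gaussian_nb": GaussianNB(),
        "multinomial_nb": BinnedMultinomialNB(),
        "decision_table": DecisionTableClassifier(),
        "logistic": RidgeLogisticRegression(),
        "smo": SMOClassifier(),
    }


def stratified_patient_split(
    patient_labels: pd.Series, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-count stratified split of patient ids into train/test sets."""
    train_ids, test_ids = [], []
    for label, ids in patient_labels.groupby(patient_labels).groups.items():
        ids = np.asarray(list(ids))
        perm = rng.permutation(ids)
        n_train = int(round(train_fraction * ids.size))
        train_ids.append(perm[:n_train])
        test_ids.append(perm[n_train:])
    return np.sort(np.concatenate(train_ids)), np.sort(np.concatenate(test_ids))


@dataclass
class BenchmarkReport:
    """Mean +/- SD metrics per classifier plus a McNemar model comparison."""

    per_repeat: dict = field(default_factory=dict)  # model -> list of metric dicts
    mean: dict = field(default_factory=dict)  # model -> metric -> mean
    sd: dict = field(default_factory=dict)  # model -> metric -> sample SD (or None)
    youden_thresholds: dict = field(default_factory=dict)  # model -> list per repeat
    mcnemar_pair: tuple[str, str] | None = None
    mcnemar_per_repeat: list = field(default_factory=list)  # (b, c, stat, p)
    n_repeats: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "youden_thresholds": self.youden_thresholds,
            "per_repeat": self.per_repeat,
            "mcnemar_pair": list(self.mcnemar_pair) if self.mcnemar_pair else None,
            "mcnemar_per_repeat": [
                {"b": b, "c": c, "statistic": s, "p_value": p}
                for (b, c, s, p) in self.mcnemar_per_repeat
            ],
        }

    def to_markdown(self) -> str:
        """Benchmark table (one classifier per row, metric columns)."""
        cols = ["TP-rate", "FP-rate", "Precision", "Recall", "F-measure", "MCC", "ROC", "PRC"]
        keys = ["tp_rate", "fp_rate", "precision", "recall", "f1", "mcc", "roc_auc", "pr_auc"]
        lines = ["| Algorithm | " + " | ".join(cols) + " |",
                 "|---" * (len(cols) + 1) + "|"]
        for model, m in self.mean.items():
            cells = []
            for k in keys:
                if self.sd.get(model, {}).get(k) is not None:
                    cells.append(f"{m[k]:.3f} ± {self.sd[model][k]:.3f}")
                else:
                    cells.append(f"{m[k]:.3f}")
            lines.append(f"| {model} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def run_benchmark(
    cohort: pd.DataFrame,
    models: dict | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.70,
    preprocess_params: PreprocessParams | None = None,
    mcnemar_pair: tuple[str, str] = ("logistic", "gaussian_nb"),
    aggregate: str = "mean",
) -> BenchmarkReport:
    """Run the repeated stratified split benchmark on a raw cohort table.

    ``cohort`` is a record table as produced by
    :func:`sarsmon.cohort.generate_cohort` (missing cells allowed; the
    preprocessing pipeline is re-fitted on the training side of every split).
    ``aggregate`` selects per-patient score pooling: ``'mean'`` (default) or
    ``'max'``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    if models is None:
        models = default_models()
    for name in mcnemar_pair:
        if name not in models:
            raise ValueError(f"McNemar pair member {name!r} not among models")

    feature_cols = [c for c in CHANNELS if c in cohort.columns]
    patient_labels = cohort.groupby("patient_id")["label"].first()
    if patient_labels.nunique() < 2:
        raise ValueError("benchmark requires both classes in the cohort")

    report = BenchmarkReport(
        per_repeat={m: [] for m in models},
        youden_thresholds={m: [] for m in models},
        mcnemar_pair=mcnemar_pair,
        n_repeats=n_repeats,
        seed=seed,
    )
    streams = np.random.SeedSequence(seed).spawn(n_repeats)
    for r in range(n_repeats):
        rng = np.random.default_rng(streams[r])
        train_ids, test_ids = stratified_patient_split(
            patient_labels, train_fraction, rng
        )
        assert not set(train_ids) & set(test_ids)
        train_raw = cohort[cohort["patient_id"].isin(train_ids)]
        test_raw = cohort[cohort["patient_id"].isin(test_ids)]
        pre = Preprocessor(preprocess_params).fit(train_raw)
        train = pre.transform(train_raw)
        test = pre.transform(test_raw)
        Xtr = train[feature_cols].to_numpy()
        ytr = train["label"].to_numpy()

        pair_pred = {}
        test_patient_labels = patient_labels.loc[test_ids]
        for name, proto in models.items():
            model = type(proto)(**proto.get_params())
            model.fit(Xtr, ytr)
            train_scores = _agg_scores(model, train, feature_cols, aggregate)
            test_scores = _agg_scores(model, test, feature_cols, aggregate)
            train_patient_labels = patient_labels.loc[train_scores.index]
            thr = M.youden_threshold(
                train_scores.to_numpy(),
                train_patient_labels.to_numpy(),
                positive=LABEL_RISK,
            )
            pred = np.where(test_scores.to_numpy() >= thr, LABEL_RISK, LABEL_NORMAL)
            counts = M.confusion_counts(
                test_patient_labels.to_numpy(), pred, positive=LABEL_RISK
            )
            row = M.confusion_metrics(counts)
            row["roc_auc"] = M.roc_auc(
                test_scores.to_numpy(), test_patient_labels.to_numpy(), positive=LABEL_RISK
            )
            row["pr_auc"] = M.pr_auc(
                test_scores.to_numpy(), test_patient_labels.to_numpy(), positive=LABEL_RISK
            )
            report.per_repeat[name].append(row)
            report.youden_thresholds[name].append(thr)
            if name in mcnemar_pair:
                pair_pred[name] = pred

        truth = test_patient_labels.to_numpy()
        a_ok = pair_pred[mcnemar_pair[0]] == truth
        b_ok = pair_pred[mcnemar_pair[1]] == truth
        b_count = int(np.sum(a_ok & ~b_ok))
        c_count = int(np.sum(~a_ok & b_ok))
        stat, p = M.mcnemar_test(b_count, c_count)
        report.mcnemar_per_repeat.append((b_count, c_count, stat, p))

    for name in models:
        rows = report.per_repeat[name]
        report.mean[name] = {
            k: float(np.mean([row[k] for row in rows])) for k in METRIC_NAMES
        }
        if n_repeats >= 2:
            report.sd[name] = {
                k: float(np.std([row[k] for row in rows], ddof=1))
                for k in METRIC_NAMES
            }
        else:
            report.sd[name] = {k: None for k in METRIC_NAMES}
    return report


def _agg_scores(model, df, feature_cols, aggregate):
    proba = model.predict_proba(df[feature_cols].to_numpy())
    pos_col = int(np.argmax(model.classes_ == LABEL_RISK))
    grouped = pd.Series(proba[:, pos_col], index=df.index).groupby(
        df["patient_id"].to_numpy()
    )
    return grouped.mean() if aggregate == "mean" else grouped.max()
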