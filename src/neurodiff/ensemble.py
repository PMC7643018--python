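"""Subject-level cross-validation, the 10-network ensemble vote, metrics,
and cross-experiment comparison.

Fold assignment is by subject (all scans of one subject stay together) and
stratified by diagnosis.  Within each outer fold the training subjects are
split into ``k_inner`` subsets; each of the 10 networks uses a different
subset for validation/early stopping, and their test-time probability
vectors are averaged and softmaxed before the argmax decision.  The
normative model and (for GAN runs) the range normalizer are refit per outer
fold on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from neurodiff._nn import softmax
from neurodiff.datamodel import (
    Diagnosis,
    FeatureTable,
    SubjectRecord,
    align_records,
)
from neurodiff.gan import GanConfig, RangeNormalizer, train_gan
from neurodiff.mmdnn import TrainConfig, train_mmdnn
from neurodiff.wscore import DEFAULT_COVARIATES, compute_wscore, fit_normative

logger = logging.getLogger(__name__)


# -- fold planning ---------------------------------------------------------


@dataclass
class OuterFold:
    test_subjects: tuple
    inner_splits: list  # list of (train_subjects tuple, val_subjects tuple)


@dataclass
class FoldPlan:
    folds: list
    k_outer: int
    k_inner: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi, fold in enumerate(self.folds):
            rows.extend({"subject_id": s, "fold": fi} for s in fold.test_subjects)
        return pd.DataFrame(rows)


def make_fold_plan(
    records: Sequence[SubjectRecord],
    k_outer: int = 10,
    k_inner: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Stratified subject-level outer folds with inner train/val splits."""
    diagnosis_of: dict[str, Diagnosis] = {}
    for r in records:
        prev = diagnosis_of.setdefault(r.subject_id, r.diagnosis)
        if prev is not r.diagnosis:
            raise ValueError(
                f"subject {r.subject_id} has inconsistent diagnoses; "
                "run validate_cohort and exclude converters first"
            )
    subjects = np.array(sorted(diagnosis_of))
    strata = np.array([diagnosis_of[s].value for s in subjects])
    counts = pd.Series(strata).value_counts()
    too_few = counts[counts < k_outer]
    if len(too_few):
        raise ValueError(
            f"classes with fewer than {k_outer} subjects: {dict(too_few)}"
        )
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    folds = []
    for fi, (train_idx, test_idx) in enumerate(outer.split(subjects, strata)):
        train_subjects = subjects[train_idx]
        inner = KFold(n_splits=k_inner, shuffle=True, random_state=seed + 7919 * (fi + 1))
        splits = [
            (tuple(train_subjects[tr]), tuple(train_subjects[va]))
            for tr, va in inner.split(train_subjects)
        ]
        folds.append(OuterFold(tuple(subjects[test_idx]), splits))
    return FoldPlan(folds, k_outer, k_inner, seed)


# -- metrics ---------------------------------------------------------------


@dataclass
class Metrics:
    accuracy: float
    sensitivity: np.ndarray  # per-class recall
    confusion: np.ndarray  # rows = truth, cols = predicted
    n: int


def compute_metrics(truth, predicted, n_classes: int = 3) -> Metrics:
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != predicted.shape:
        raise ValueError("truth/predicted length mismatch")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (truth, predicted), 1)
    totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        sensitivity = np.where(totals > 0, np.diag(confusion) / totals, np.nan)
    accuracy = float(np.trace(confusion) / truth.size)
    return Metrics(accuracy, sensitivity, confusion, int(truth.size))


# -- ensemble fold ---------------------------------------------------------


@dataclass
class EnsembleResult:
    fold_index: int
    test_row_index: np.ndarray
    truth: np.ndarray
    per_network_probs: np.ndarray  # (n_networks, n_test, 3)
    mean_probs: np.ndarray
    final_probs: np.ndarray  # softmax of the mean
    predicted: np.ndarray
    metrics: Metrics
    per_network_accuracy: np.ndarray


def ensemble_vote(per_network_probs: np.ndarray):
    """Average the per-network probability vectors, softmax, argmax.

    Softmax after averaging is order-preserving, so the decision equals the
    argmax of the mean; both vectors are reported anyway, as printed.
    """
    per_network_probs = np.asarray(per_network_probs, dtype=float)
    mean_probs = per_network_probs.mean(axis=0)
    final_probs = softmax(mean_probs)
    return mean_probs, final_probs, final_probs.argmax(axis=1)


def _network_seed(base_seed: int, fold_index: int, network_index: int) -> int:
    ss = np.random.SeedSequence([base_seed, fold_index, network_index])
    return int(ss.generate_state(1)[0])


def run_ensemble_fold(
    plan: FoldPlan,
    fold_index: int,
    table: FeatureTable,
    records: Sequence[SubjectRecord],
    cfg: TrainConfig,
    *,
    use_gan: bool = False,
    gan_cfg: GanConfig | None = None,
    n_networks: int | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> EnsembleResult:
    """Train the per-fold ensemble and vote on the fold's test rows.

    Features must be raw: the normative model is fitted on this fold's
    training NC rows only, then all rows are w-scored (and, for GAN runs,
    range-normalized with training-fold ranges).
    """
    if table.kind != "raw":
        raise ValueError("run_ensemble_fold expects raw features (w-scoring is per fold)")
    aligned = align_records(records, table)
    fold = plan.folds[fold_index]
    test_set = set(fold.test_subjects)
    row_subjects = np.array([r.subject_id for r in aligned])
    labels = np.array([r.label for r in aligned])
    test_mask = np.isin(row_subjects, list(test_set))
    train_rows = np.flatnonzero(~test_mask)
    test_rows = np.flatnonzero(test_mask)

    # leakage guard: normative fit sees training-fold NC rows only
    nc_train = np.array(
        [i for i in train_rows if aligned[i].diagnosis is Diagnosis.NC]
    )
    assert not set(row_subjects[nc_train]) & test_set
    model_norm = fit_normative(
        table.subset(nc_train),
        [aligned[i] for i in nc_train],
        covariates=covariates,
    )
    wtable = compute_wscore(model_norm, table, aligned)
    values = wtable.values
    if use_gan:
        normalizer = RangeNormalizer().fit(values[train_rows])
        values = normalizer.transform(values)

    n_networks = n_networks if n_networks is not None else plan.k_inner
    if not 1 <= n_networks <= len(fold.inner_splits):
        raise ValueError(f"n_networks must be in [1, {len(fold.inner_splits)}]")
    probs_per_net = []
    acc_per_net = []
    for ni in range(n_networks):
        tr_subj, va_subj = fold.inner_splits[ni]
        net_rows = np.flatnonzero(np.isin(row_subjects, tr_subj + va_subj))
        assert not set(row_subjects[net_rows]) & test_set
        val_local = np.flatnonzero(np.isin(row_subjects[net_rows], va_subj))
        net_cfg = cfg.with_seed(_network_seed(cfg.seed, fold_index, ni))
        x_net, y_net = values[net_rows], labels[net_rows]
        if use_gan:
            _, net, _ = train_gan(
                x_net, y_net, net_cfg, gan_cfg or GanConfig(),
                specs=table.specs, val_idx=val_local,
            )
            p_test = net.predict_proba_real(values[test_rows])
        else:
            net, _ = train_mmdnn(
                x_net, y_net, net_cfg, specs=table.specs, val_idx=val_local
            )
            p_test = net.predict_proba(values[test_rows])
        probs_per_net.append(p_test)
        acc_per_net.append(float((p_test.argmax(axis=1) == labels[test_rows]).mean()))

    per_network_probs = np.stack(probs_per_net)
    mean_probs, final_probs, predicted = ensemble_vote(per_network_probs)
    metrics = compute_metrics(labels[test_rows], predicted)
    return EnsembleResult(
        fold_index=fold_index,
        test_row_index=test_rows,
        truth=labels[test_rows],
        per_network_probs=per_network_probs,
        mean_probs=mean_probs,
        final_probs=final_probs,
        predicted=predicted,
        metrics=metrics,
        per_network_accuracy=np.array(acc_per_net),
    )


@dataclass
class CrossvalResult:
    fold_results: list
    overall: Metrics
    fold_accuracies: np.ndarray
    plan: FoldPlan

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall.accuracy,
            "overall_sensitivity": [float(s) for s in self.overall.sensitivity],
            "confusion": self.overall.confusion.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "per_fold": [
                {
                    "fold": r.fold_index,
                    "accuracy": r.metrics.accuracy,
                    "sensitivity": [float(s) for s in r.metrics.sensitivity],
                    "confusion": r.metrics.confusion.tolist(),
                    "per_network_accuracy": r.per_network_accuracy.tolist(),
                }
                for r in self.fold_results
            ],
        }


def run_crossval(
    table: FeatureTable,
    records: Sequence[SubjectRecord],
    cfg: TrainConfig,
    *,
    k_outer: int = 10,
    k_inner: int = 10,
    n_networks: int | None = None,
    use_gan: bool = False,
    gan_cfg: GanConfig | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    plan: FoldPlan | None = None,
    seed: int | None = None,
) -> CrossvalResult:
    """Full nested cross-validation over all outer folds."""
    plan = plan or make_fold_plan(
        records, k_outer=k_outer, k_inner=k_inner,
        seed=cfg.seed if seed is None else seed,
    )
    results = []
    truth_all, pred_all = [], []
    for fi in range(len(plan.folds)):
        res = run_ensemble_fold(
            plan, fi, table, records, cfg,
            use_gan=use_gan, gan_cfg=gan_cfg,
            n_networks=n_networks, covariates=covariates,
        )
        logger.info("fold %d: accuracy %.3f", fi, res.metrics.accuracy)
        results.append(res)
        truth_all.append(res.truth)
        pred_all.append(res.predicted)
    overall = compute_metrics(np.concatenate(truth_all), np.concatenate(pred_all))
    return CrossvalResult(
        results, overall, np.array([r.metrics.accuracy for r in results]), plan
    )


# -- run comparison --------------------------------------------------------


def paired_one_tailed_t(baseline, improved):
    """Paired t-test that ``improved`` > ``baseline`` (fold-paired).

    Returns (t, p, zero_variance).  Zero-variance differences use the
    convention p = 1 if the mean difference <= 0 else p = 0.5, flagged.
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(improved, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold-accuracy vectors must have equal length")
    diff = b - a
    if np.allclose(diff.std(ddof=1) if diff.size > 1 else 0.0, 0.0):
        p = 1.0 if diff.mean() <= 0 else 0.5
        return 0.0, p, True
    t, p = stats.ttest_rel(b, a, alternative="greater")
    return float(t), float(p), False


def compare_runs(comparisons: dict, q: float = 0.05) -> pd.DataFrame:
    """BH-corrected paired one-tailed comparisons.

    ``comparisons`` maps a name to (baseline_accuracies, improved_accuracies),
    paired by fold.  Returns a frame with t, p, zero_variance and the FDR
    rejection decision across the supplied family.
    """
    rows = {}
    for name, (a, b) in comparisons.items():
        t, p, zero_var = paired_one_tailed_t(a, b)
        rows[name] = {"t": t, "p": p, "zero_variance": zero_var}
    df = pd.DataFrame(rows).T
    reject, _, _, _ = multipletests(df["p"].to_numpy(float), alpha=q, method="fdr_bh")
    df["reject"] = reject
    return df
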