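"""Feature fusion, SVM classification, and the repeated-split protocol.

Each subject is summarized by a processed record (embedding vector,
similarity ratio S, measured CLR ratio when a reflex was photographed).
One screening experiment then:

1. samples 15 + 15 training subjects per class without replacement (the
   remaining 15 + 15 are the test set);
2. fits PCA (k = 5) on the training embeddings only;
3. imputes missing training CLR ratios from the training labels, derives
   the similarity-ratio criterion from the training S values, and imputes
   missing test CLR ratios label-free via that criterion;
4. assembles 7-d fused vectors (pca1..pca5, S, clr), standardizes them
   with training statistics, trains a linear SVM (C = 1), and scores the
   test set.

No quantity fitted on data — PCA, imputation criterion, standardization,
SVM — ever sees a test subject.  The evaluation repeats this over many
seeded splits (5,000 in the reference protocol) and reports mean accuracy,
sensitivity (strabismic images flagged) and specificity (normal images
cleared) with normal-approximation 95% confidence intervals.  Experiment i
draws its random stream from ``SeedSequence(base_seed, spawn_key=(i,))``,
so any single experiment can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import position_features as pf
from .embedding_pca import DEFAULT_N_COMPONENTS, PCAModel, fit_pca, project
from .synthetic_eye import NORMAL, STRABISMUS

DEFAULT_TRAIN_PER_CLASS = 15
DEFAULT_N_EXPERIMENTS = 5_000


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject processed features entering the protocol."""

    subject_id: str
    label: str
    embedding: np.ndarray
    S: float
    clr_ratio: float | None      # measured value, None when no reflex
    clr_provenance: str = pf.MEASURED

    def __post_init__(self) -> None:
        if self.label not in (NORMAL, STRABISMUS):
            raise ProtocolError(f"unknown label {self.label!r}")
        if not np.isfinite(self.S) or self.S < 1.0 - 1e-9:
            raise ProtocolError(f"invalid similarity ratio {self.S}")


def assemble(pca_components: np.ndarray, S: float, clr: float) -> np.ndarray:
    """Fused feature vector in the fixed order (pca1..pcak, S, clr)."""
    p = np.asarray(pca_components, dtype=float).ravel()
    vec = np.concatenate([p, [S, clr]])
    if not np.all(np.isfinite(vec)):
        raise ProtocolError("non-finite entry in fused feature vector")
    if S < 1.0 - 1e-9 or clr < 0:
        raise ProtocolError("S must be >= 1 and clr >= 0")
    return vec


@dataclass(frozen=True)
class StandardizationState:
    mean: np.ndarray
    sd: np.ndarray


def fit_standardizer(train: np.ndarray) -> StandardizationState:
    """Per-dimension mean/sd from training vectors (population sd, so the
    transformed training set has sd exactly 1)."""
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ProtocolError("need at least 2 training vectors")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # a column of identical values can have sd ~ 1e-17 from the mean
    # round-off; treat it as zero-variance all the same
    zero = np.nonzero((sd == 0) | (np.ptp(X, axis=0) == 0))[0]
    if zero.size:
        raise ProtocolError(
            f"zero-variance feature dimension(s) {zero.tolist()}; cannot standardize")
    return StandardizationState(mean=mean, sd=sd)


def apply_standardizer(state: StandardizationState, vectors: np.ndarray) -> np.ndarray:
    return (np.asarray(vectors, dtype=float) - state.mean) / state.sd


@dataclass
class ScreeningSVM:
    """Linear-kernel SVM wrapper with a sensitivity-favoring tie rule.

    Prediction is the sign of the decision function; a score of exactly 0
    is classified strabismic.  Deterministic for fixed input and
    hyperparameters.
    """

    C: float = 1.0
    kernel: str = "linear"
    _svc: SVC = field(init=False, repr=False, default=None)  # type: ignore[assignment]

    def fit(self, X: np.ndarray, labels: Sequence[str]) -> "ScreeningSVM":
        y = np.array([1 if lab == STRABISMUS else 0 for lab in labels])
        if len(set(y.tolist())) < 2:
            raise ProtocolError("training set must contain both classes")
        self._svc = SVC(C=self.C, kernel=self.kernel)
        self._svc.fit(np.asarray(X, dtype=float), y)
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> list[str]:
        # classes_ = [0, 1]; positive score = class 1 = strabismus
        return [STRABISMUS if s >= 0 else NORMAL for s in self.decision(X)]


@dataclass(frozen=True)
class ExperimentResult:
    seed_key: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    tp: int  # strabismic classified strabismic
    tn: int  # normal classified normal
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class ExperimentArtifacts:
    """Everything fitted during one experiment's training phase; useful for
    diagnostics and for asserting that no test information leaks into
    training."""

    pca: PCAModel
    criterion: float
    standardizer: StandardizationState
    classifier: ScreeningSVM
    train_matrix: np.ndarray


def _experiment_rng(seed: int | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def _clr_for_training(rec: SubjectRecord) -> float:
    if rec.clr_ratio is not None:
        return rec.clr_ratio
    return pf.impute_clr_train(rec.label)


def _clr_for_test(rec: SubjectRecord, criterion: float) -> float:
    if rec.clr_ratio is not None:
        return rec.clr_ratio
    return pf.impute_clr_test(rec.S, criterion)


def run_experiment(
    cohort: Sequence[SubjectRecord],
    seed: int | np.random.SeedSequence,
    *,
    n_train_per_class: int = DEFAULT_TRAIN_PER_CLASS,
    k: int = DEFAULT_N_COMPONENTS,
    C: float = 1.0,
    kernel: str = "linear",
    with_artifacts: bool = False,
) -> ExperimentResult | tuple[ExperimentResult, ExperimentArtifacts]:
    """One seeded train/test split scored end to end (see module docstring)."""
    normal = [r for r in cohort if r.label == NORMAL]
    strab = [r for r in cohort if r.label == STRABISMUS]
    if len(normal) <= n_train_per_class - 1 or len(strab) <= n_train_per_class - 1:
        raise ProtocolError(
            f"need at least {n_train_per_class} subjects per class, got "
            f"{len(normal)} normal / {len(strab)} strabismic")
    if len(normal) == n_train_per_class or len(strab) == n_train_per_class:
        raise ProtocolError("a class would have an empty test set")

    rng = _experiment_rng(seed)
    train: list[SubjectRecord] = []
    test: list[SubjectRecord] = []
    for group in (normal, strab):
        idx = rng.permutation(len(group))
        train += [group[i] for i in idx[:n_train_per_class]]
        test += [group[i] for i in idx[n_train_per_class:]]

    pca: PCAModel = fit_pca(np.stack([r.embedding for r in train]), k=k)
    criterion = pf.clr_criterion(
        [r.S for r in train if r.label == NORMAL],
        [r.S for r in train if r.label == STRABISMUS],
    )

    X_train = np.stack([
        assemble(project(pca, r.embedding), r.S, _clr_for_training(r)) for r in train
    ])
    X_test = np.stack([
        assemble(project(pca, r.embedding), r.S, _clr_for_test(r, criterion))
        for r in test
    ])
    std = fit_standardizer(X_train)
    clf = ScreeningSVM(C=C, kernel=kernel).fit(
        apply_standardizer(std, X_train), [r.label for r in train])
    predictions = clf.predict(apply_standardizer(std, X_test))

    tp = tn = fp = fn = 0
    for rec, pred in zip(test, predictions):
        if rec.label == STRABISMUS:
            tp, fn = (tp + 1, fn) if pred == STRABISMUS else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred == NORMAL else (tn, fp + 1)
    seed_key = seed.entropy if isinstance(seed, np.random.SeedSequence) else int(seed)
    result = ExperimentResult(
        seed_key=int(seed_key) if np.isscalar(seed_key) else -1,
        train_ids=tuple(sorted(r.subject_id for r in train)),
        test_ids=tuple(sorted(r.subject_id for r in test)),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )
    if with_artifacts:
        return result, ExperimentArtifacts(
            pca=pca, criterion=criterion, standardizer=std, classifier=clf,
            train_matrix=X_train)
    return result


@dataclass(frozen=True)
class EvaluationReport:
    n_experiments: int
    accuracy_mean: float
    sensitivity_mean: float
    specificity_mean: float
    accuracy_ci95: tuple[float, float]
    sensitivity_ci95: tuple[float, float]
    specificity_ci95: tuple[float, float]
    records: pd.DataFrame = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "n_experiments": self.n_experiments,
            "accuracy": {"mean": self.accuracy_mean, "ci95": list(self.accuracy_ci95)},
            "sensitivity": {"mean": self.sensitivity_mean,
                            "ci95": list(self.sensitivity_ci95)},
            "specificity": {"mean": self.specificity_mean,
                            "ci95": list(self.specificity_ci95)},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _mean_ci(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(values.mean())
    if values.size < 2:
        return m, (m, m)  # single experiment: zero-width interval
    half = 1.96 * float(values.std(ddof=1)) / np.sqrt(values.size)
    return m, (m - half, m + half)


def evaluate(
    cohort: Sequence[SubjectRecord],
    n_experiments: int = DEFAULT_N_EXPERIMENTS,
    base_seed: int = 0,
    **experiment_kwargs,
) -> EvaluationReport:
    """Repeat ``run_experiment`` over seeded splits and aggregate."""
    if n_experiments < 1:
        raise ProtocolError("n_experiments must be at least 1")
    results = []
    for i in range(n_experiments):
        ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(i,))
        results.append(run_experiment(cohort, ss, **experiment_kwargs))

    records = pd.DataFrame({
        "experiment": np.arange(n_experiments),
        "tp": [r.tp for r in results], "tn": [r.tn for r in results],
        "fp": [r.fp for r in results], "fn": [r.fn for r in results],
        "accuracy": [r.accuracy for r in results],
        "sensitivity": [r.sensitivity for r in results],
        "specificity": [r.specificity for r in results],
        "train_ids": ["|".join(r.train_ids) for r in results],
    })
    acc_m, acc_ci = _mean_ci(records["accuracy"].to_numpy())
    sen_m, sen_ci = _mean_ci(records["sensitivity"].to_numpy())
    spe_m, spe_ci = _mean_ci(records["specificity"].to_numpy())
    return EvaluationReport(
        n_experiments=n_experiments,
        accuracy_mean=acc_m, sensitivity_mean=sen_m, specificity_mean=spe_m,
        accuracy_ci95=acc_ci, sensitivity_ci95=sen_ci, specificity_ci95=spe_ci,
        records=records,
    )
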