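"""Decision-support system: per-channel PCA+SVM, fusion, LOPO, baselines.

Each emission channel has its own pipeline — per-feature standardization,
PCA truncated at the smallest component count reaching the configured
cumulative explained-variance threshold (0.99 by default), and a multi-class
support-vector machine assigning a group label to every image.  A patient's
per-channel label is the majority over their z-stack, and the two channel
decisions are fused by weighted voting, the weight of each channel being its
training-set patient-level accuracy estimated by an inner 3-fold split over
training patients (so no test information leaks into the weights).

Evaluation is leave-one-person-out (LOPO): every fold holds out all images
of exactly one patient and refits the standardizer, PCA, SVMs and fusion
weights on the rest.  Performance is accumulated into a 3x3 confusion matrix
(rows = predicted, columns = true) from which accuracy and per-class
precision / recall / F1 are computed.

Two scalar Bayesian baselines mirror the clinical comparators: a Gaussian
class-conditional maximum-posterior classifier over a single scalar per
patient, applied to HbA1c and to the patient-mean GP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, DegenerateInputError, ParameterError
from .gp_imaging import BLUE_BAND, GREEN_BAND
from .synthetic_cohort import GROUPS

log = logging.getLogger(__name__)

META_COLUMNS = ("patient", "group", "z", "channel")


@dataclass(frozen=True)
class DSSConfig:
    variance_threshold: float = 0.99
    kernel: str = "linear"
    C: float = 1.0
    inner_folds: int = 3
    random_state: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ConfigurationError("variance_threshold must lie in (0, 1]")
        if self.C <= 0 or self.inner_folds < 2:
            raise ConfigurationError("C must be > 0 and inner_folds >= 2")


@dataclass(frozen=True)
class PCAModel:
    """Truncated principal-component model fitted on training rows only."""

    center: np.ndarray
    loadings: np.ndarray  # (k, p), orthonormal rows
    explained_variance_ratio: np.ndarray  # full spectrum
    k: int

    @classmethod
    def fit(cls, x: np.ndarray, variance_threshold: float = 0.99) -> "PCAModel":
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 2:
            raise DegenerateInputError("PCA needs at least 2 training rows")
        pca = PCA(svd_solver="full")
        pca.fit(x)
        evr = pca.explained_variance_ratio_
        cum = np.cumsum(evr)
        reach = np.nonzero(cum >= variance_threshold - 1e-12)[0]
        k = int(reach[0]) + 1 if reach.size else int(evr.size)
        return cls(
            center=pca.mean_,
            loadings=pca.components_[:k],
            explained_variance_ratio=evr,
            k=k,
        )

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.center) @ self.loadings.T


def fit_pca(x: np.ndarray, variance_threshold: float = 0.99) -> PCAModel:
    """Principal components of the training matrix, truncated at the smallest
    count whose cumulative explained variance reaches the threshold."""
    return PCAModel.fit(x, variance_threshold)


@dataclass
class ChannelPipeline:
    """standardize -> project -> classify, fitted on training rows only."""

    scaler: StandardScaler
    pca: PCAModel
    svm: SVC
    classes: tuple[str, ...] = GROUPS

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.pca.transform(self.scaler.transform(x)))

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Per-class one-vs-rest scores, columns ordered as ``self.classes``."""
        scores = self.svm.decision_function(self.pca.transform(self.scaler.transform(x)))
        if scores.ndim == 1:  # binary training set: expand to two columns
            scores = np.column_stack([-scores, scores])
        present = list(self.svm.classes_)
        # classes absent from training get a large negative finite score so
        # weighted sums stay well-defined even with zero channel weights
        full = np.full((scores.shape[0], len(self.classes)), -1e12)
        for col, cls in enumerate(present):
            full[:, self.classes.index(cls)] = scores[:, col]
        return full


def fit_channel_pipeline(
    features: np.ndarray, labels: np.ndarray, config: DSSConfig = DSSConfig()
) -> ChannelPipeline:
    """Fit one channel's standardizer, PCA and SVM on training images."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ConfigurationError("training labels contain a single class")
    scaler = StandardScaler().fit(features)
    z = scaler.transform(features)
    pca = PCAModel.fit(z, config.variance_threshold)
    svm = SVC(
        kernel=config.kernel,
        C=config.C,
        decision_function_shape="ovr",
        random_state=config.random_state,
    )
    svm.fit(pca.transform(z), labels)
    return ChannelPipeline(scaler=scaler, pca=pca, svm=svm)


@dataclass
class TrainedDSS:
    blue_pipeline: ChannelPipeline
    green_pipeline: ChannelPipeline
    channel_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        wb, wg = self.channel_weights
        if wb < 0 or wg < 0 or (wb == 0 and wg == 0):
            raise ParameterError("channel weights must be >= 0 and not both 0")


def _stack_vote(
    pipeline: ChannelPipeline, stack_features: np.ndarray
) -> tuple[str, bool, np.ndarray]:
    """Majority class over a stack.

    Returns (label, tie_flag, mean per-class decision scores).  A tie is
    provisionally broken by the channel's own summed decision score, then by
    lower class index, but the flag lets the fusion stage resolve it with
    both channels instead.
    """
    labels = pipeline.predict(stack_features)
    counts = np.array([np.sum(labels == g) for g in GROUPS])
    mean_scores = pipeline.decision_scores(stack_features).mean(axis=0)
    top = counts.max()
    tied = np.nonzero(counts == top)[0]
    if tied.size == 1:
        return GROUPS[tied[0]], False, mean_scores
    best = tied[np.argmax(mean_scores[tied])]  # first max: lower class index
    return GROUPS[best], True, mean_scores


def _majority_label(
    pipeline: ChannelPipeline, stack_features: np.ndarray
) -> tuple[str, np.ndarray]:
    """Single-channel stack majority (ties by score, then lower index)."""
    label, _, _ = _stack_vote(pipeline, stack_features)
    return label, pipeline.predict(stack_features)


def classify_patient(
    dss: TrainedDSS, blue_features: np.ndarray, green_features: np.ndarray
) -> str:
    """Weighted-voting fusion of the two per-channel patient labels.

    Each channel's patient label is the stack majority; the final label is
    the weighted vote of the two channel decisions.  A tied stack majority
    in either channel is resolved by the weighted sum of both channels'
    mean decision scores (a split stack must not outvote a decisive one);
    between two decisive channels, ties go to the channel with the larger
    weight (= higher training-fold accuracy), then to the lower class index.
    """
    blue_features = np.atleast_2d(np.asarray(blue_features, dtype=np.float64))
    green_features = np.atleast_2d(np.asarray(green_features, dtype=np.float64))
    if blue_features.shape[0] == 0 or green_features.shape[0] == 0:
        raise DegenerateInputError("empty image stack")
    label_b, tie_b, scores_b = _stack_vote(dss.blue_pipeline, blue_features)
    label_g, tie_g, scores_g = _stack_vote(dss.green_pipeline, green_features)
    wb, wg = dss.channel_weights
    if tie_b or tie_g:
        fused = wb * scores_b + wg * scores_g
        return GROUPS[int(np.argmax(fused))]
    if label_b == label_g:
        return label_b
    if wb > wg:
        return label_b
    if wg > wb:
        return label_g
    return min(label_b, label_g, key=GROUPS.index)


# --------------------------------------------------------------------------
# LOPO protocol
# --------------------------------------------------------------------------

@dataclass
class FoldRecord:
    """Audit record of one LOPO fold (used to assert fold isolation)."""

    test_patient: str
    train_patients: tuple[str, ...]
    predicted: str
    true: str
    channel_weights: tuple[float, float]
    k_per_channel: dict[str, int]
    scaler_mean: dict[str, np.ndarray]


@dataclass
class LOPOResult:
    report: "MetricsReport"
    folds: list[FoldRecord]

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient": f.test_patient,
                    "true": f.true,
                    "predicted": f.predicted,
                    "weight_blue": f.channel_weights[0],
                    "weight_green": f.channel_weights[1],
                }
                for f in self.folds
            ]
        )


def _split_table(table: pd.DataFrame):
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    per_patient: dict[str, dict] = {}
    for pid, sub in table.groupby("patient", sort=True):
        groups = sub["group"].unique()
        if groups.size != 1:
            raise ConfigurationError(f"patient {pid} carries multiple group labels")
        blue = sub[sub["channel"] == BLUE_BAND].sort_values("z")
        green = sub[sub["channel"] == GREEN_BAND].sort_values("z")
        if len(blue) == 0 or len(green) == 0:
            raise DegenerateInputError(f"patient {pid} is missing a channel")
        per_patient[pid] = {
            "group": groups[0],
            BLUE_BAND: blue[feature_cols].to_numpy(dtype=np.float64),
            GREEN_BAND: green[feature_cols].to_numpy(dtype=np.float64),
        }
    return per_patient, feature_cols


def _stacked(per_patient: dict, pids: list[str], channel: str):
    x = np.vstack([per_patient[p][channel] for p in pids])
    y = np.concatenate(
        [[per_patient[p]["group"]] * len(per_patient[p][channel]) for p in pids]
    )
    return x, y


def _inner_weight(
    per_patient: dict, train_pids: list[str], channel: str, config: DSSConfig
) -> float:
    """Patient-level accuracy of one channel under an inner k-fold split of
    the *training* patients (class-stratified round-robin)."""
    by_class: dict[str, list[str]] = {g: [] for g in GROUPS}
    for p in train_pids:
        by_class[per_patient[p]["group"]].append(p)
    folds: list[list[str]] = [[] for _ in range(config.inner_folds)]
    slot = 0
    for g in GROUPS:
        for p in sorted(by_class[g]):
            folds[slot % config.inner_folds].append(p)
            slot += 1
    correct = total = 0
    for i in range(config.inner_folds):
        val = folds[i]
        fit_pids = [p for j, f in enumerate(folds) if j != i for p in f]
        if not val or not fit_pids:
            continue
        x, y = _stacked(per_patient, fit_pids, channel)
        if np.unique(y).size < 2:
            continue
        pipe = fit_channel_pipeline(x, y, config)
        for p in val:
            pred, _ = _majority_label(pipe, per_patient[p][channel])
            correct += pred == per_patient[p]["group"]
            total += 1
    return correct / total if total else 0.5


def fit_dss(
    per_patient: dict, train_pids: list[str], config: DSSConfig
) -> TrainedDSS:
    """Fit both channel pipelines and the fusion weights on training patients."""
    weights = tuple(
        _inner_weight(per_patient, train_pids, ch, config)
        for ch in (BLUE_BAND, GREEN_BAND)
    )
    if weights[0] == 0 and weights[1] == 0:
        weights = (0.5, 0.5)
    pipes = {}
    for ch in (BLUE_BAND, GREEN_BAND):
        x, y = _stacked(per_patient, train_pids, ch)
        pipes[ch] = fit_channel_pipeline(x, y, config)
    return TrainedDSS(
        blue_pipeline=pipes[BLUE_BAND],
        green_pipeline=pipes[GREEN_BAND],
        channel_weights=weights,
    )


def lopo_evaluate(table: pd.DataFrame, config: DSSConfig = DSSConfig()) -> LOPOResult:
    """Leave-one-person-out evaluation of the full DSS.

    Every fold refits standardizer, PCA, SVMs and fusion weights on all
    other patients, then predicts the held-out patient.  The confusion
    matrix (rows = predicted, columns = true) accumulates one entry per
    patient.
    """
    per_patient, _ = _split_table(table)
    pids = sorted(per_patient)
    class_counts = {g: sum(per_patient[p]["group"] == g for p in pids) for g in GROUPS}
    present = {g: n for g, n in class_counts.items() if n > 0}
    if len(present) < 2 or any(n < 2 for n in present.values()):
        raise ConfigurationError(
            f"LOPO needs >= 2 patients in >= 2 classes, got {class_counts}"
        )
    confusion = np.zeros((3, 3), dtype=np.int64)
    folds: list[FoldRecord] = []
    for pid in pids:
        train_pids = [p for p in pids if p != pid]
        dss = fit_dss(per_patient, train_pids, config)
        pred = classify_patient(
            dss, per_patient[pid][BLUE_BAND], per_patient[pid][GREEN_BAND]
        )
        true = per_patient[pid]["group"]
        confusion[GROUPS.index(pred), GROUPS.index(true)] += 1
        folds.append(
            FoldRecord(
                test_patient=pid,
                train_patients=tuple(train_pids),
                predicted=pred,
                true=true,
                channel_weights=dss.channel_weights,
                k_per_channel={
                    BLUE_BAND: dss.blue_pipeline.pca.k,
                    GREEN_BAND: dss.green_pipeline.pca.k,
                },
                scaler_mean={
                    BLUE_BAND: dss.blue_pipeline.scaler.mean_.copy(),
                    GREEN_BAND: dss.green_pipeline.scaler.mean_.copy(),
                },
            )
        )
    return LOPOResult(report=compute_metrics(confusion), folds=folds)


# --------------------------------------------------------------------------
# Scalar Bayesian baselines
# --------------------------------------------------------------------------

@dataclass
class BayesScalarClassifier:
    """Gaussian class-conditional maximum-posterior classifier on one scalar.

    Per-class sample mean and sample SD (floored at 1e-6 so single-member or
    constant classes stay usable), priors equal to training class
    frequencies.  Ties go to the lower class index.
    """

    classes: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    priors: np.ndarray

    SD_FLOOR = 1e-6

    @classmethod
    def fit(cls, values: np.ndarray, labels: np.ndarray) -> "BayesScalarClassifier":
        values = np.asarray(values, dtype=np.float64)
        labels = np.asarray(labels)
        classes = tuple(g for g in GROUPS if np.any(labels == g))
        if len(classes) < 2:
            raise ConfigurationError("scalar baseline needs >= 2 classes")
        means, sds, priors = [], [], []
        for g in classes:
            v = values[labels == g]
            means.append(v.mean())
            sd = v.std(ddof=1) if v.size > 1 else 0.0
            if not np.isfinite(sd) or sd < cls.SD_FLOOR:
                log.info("class %s has degenerate spread; flooring SD", g)
                sd = cls.SD_FLOOR
            sds.append(sd)
            priors.append(v.size / values.size)
        return cls(classes, np.array(means), np.array(sds), np.array(priors))

    def log_posterior(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        return norm.logpdf(x[:, None], self.means[None, :], self.sds[None, :]) + np.log(
            self.priors
        )[None, :]

    def predict(self, x) -> np.ndarray:
        lp = self.log_posterior(x)
        return np.array([self.classes[i] for i in np.argmax(lp, axis=1)])


def fit_bayes_scalar(values, labels) -> BayesScalarClassifier:
    return BayesScalarClassifier.fit(np.asarray(values), np.asarray(labels))


def lopo_bayes_scalar(values, labels) -> LOPOResult:
    """LOPO evaluation of the scalar Bayesian baseline."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ParameterError("values and labels lengths differ")
    confusion = np.zeros((3, 3), dtype=np.int64)
    folds: list[FoldRecord] = []
    for i in range(values.size):
        keep = np.arange(values.size) != i
        clf = BayesScalarClassifier.fit(values[keep], labels[keep])
        pred = str(clf.predict(values[i])[0])
        confusion[GROUPS.index(pred), GROUPS.index(labels[i])] += 1
        folds.append(
            FoldRecord(
                test_patient=str(i),
                train_patients=tuple(map(str, np.nonzero(keep)[0])),
                predicted=pred,
                true=str(labels[i]),
                channel_weights=(1.0, 0.0),
                k_per_channel={},
                scaler_mean={},
            )
        )
    return LOPOResult(report=compute_metrics(confusion), folds=folds)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """3-class confusion matrix (rows = predicted, columns = true) and the
    derived accuracy / per-class precision / recall / F1."""

    confusion: np.ndarray
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion).tolist(),
            "accuracy": self.accuracy,
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "f1": dict(self.f1),
            "undefined": list(self.undefined),
        }


def compute_metrics(confusion: np.ndarray) -> MetricsReport:
    """Accuracy = trace/total; precision_c = M[c,c]/row_c; recall_c =
    M[c,c]/col_c; F1 the harmonic mean.  Zero-denominator ratios are
    reported as 0 and flagged."""
    m = np.asarray(confusion)
    if m.shape != (3, 3):
        raise ParameterError("confusion matrix must be 3x3")
    if np.any(m < 0) or not np.issubdtype(m.dtype, np.number):
        raise ParameterError("confusion matrix must be non-negative")
    total = m.sum()
    if total == 0:
        raise DegenerateInputError("confusion matrix is all zero")
    accuracy = float(np.trace(m) / total)
    precision, recall, f1 = {}, {}, {}
    undefined = []
    for i, g in enumerate(GROUPS):
        row, col = m[i, :].sum(), m[:, i].sum()
        if row == 0:
            precision[g] = 0.0
            undefined.append(f"precision_{g}")
        else:
            precision[g] = float(m[i, i] / row)
        if col == 0:
            recall[g] = 0.0
            undefined.append(f"recall_{g}")
        else:
            recall[g] = float(m[i, i] / col)
        if precision[g] + recall[g] == 0:
            f1[g] = 0.0
            undefined.append(f"f1_{g}")
        else:
            f1[g] = float(2 * precision[g] * recall[g] / (precision[g] + recall[g]))
    return MetricsReport(
        confusion=m.copy(),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        undefined=tuple(undefined),
    )
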