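"""Maximum-likelihood diagnostic classification of feature sequences.

Training (per class): estimate mixed moments, build the canonical
decomposition, extract the class's own training coefficients at the
decision positions, and fit one Parzen density per decision coefficient.
Classification: a test realization is standardized with the shared pooled
transform, decomposed *separately under each class's model* (the densities
are class-conditional, so the coefficients must be too), and assigned to
the class maximizing the sum of log densities of its decision coefficients
— the product decision rule.  Three criteria are supported, differing only
in the monomial dictionary:

* ``linear`` — first powers only (classical canonical expansion);
* ``polynomial`` — single-time powers ``1..N_p`` (default 3);
* ``nonlinear`` — the full cross-time dictionary of order ``N`` (default 4).

An optional low-likelihood threshold flags realizations resembling no
trained class (``"unknown"`` — the novel-disease flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canonical import (
    CanonicalModel,
    DictionaryOrder,
    build_canonical_model,
    build_dictionary,
    extract_coefficients,
)
from .density import KernelDensity, fit_parzen
from .errors import InvalidInputError, TrainingError
from .moments import MomentTable, Standardization, TrainingSet, standardize
from .synthetic import BenchmarkConfig, make_benchmark

__all__ = [
    "Criterion",
    "ClassModel",
    "DiagnosticClassifier",
    "ClassificationResult",
    "train_classifier",
    "classify",
    "evaluate_accuracy",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "unknown"


@dataclass(frozen=True)
class Criterion:
    """A decision-rule family plus its order parameters."""

    kind: str  # linear | polynomial | nonlinear
    order: int = 4  # N for nonlinear, N_p for polynomial; ignored for linear
    degree_bound: int | None = None  # nonlinear only; default N - 1

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "nonlinear"):
            raise InvalidInputError(f"unknown criterion kind {self.kind!r}")
        if self.kind == "polynomial" and self.order < 1:
            raise InvalidInputError("polynomial criterion needs order >= 1")
        if self.kind == "nonlinear" and self.order < 2:
            raise InvalidInputError("nonlinear criterion needs order N >= 2")

    @staticmethod
    def linear() -> "Criterion":
        return Criterion("linear", order=1)

    @staticmethod
    def polynomial(order: int = 3) -> "Criterion":
        return Criterion("polynomial", order=order)

    @staticmethod
    def nonlinear(order: int = 4, degree_bound: int | None = None) -> "Criterion":
        return Criterion("nonlinear", order=order, degree_bound=degree_bound)

    def dictionary(self, I: int) -> DictionaryOrder:
        if self.kind == "linear":
            return build_dictionary(I, N=2, B=1, cross=False)
        if self.kind == "polynomial":
            return build_dictionary(I, N=self.order + 1, B=self.order, cross=False)
        return build_dictionary(I, N=self.order, B=self.degree_bound, cross=True)


@dataclass
class ClassModel:
    """One class: its canonical model and decision-coefficient densities."""

    label: str
    model: CanonicalModel
    densities: dict[int, KernelDensity]  # block i -> Parzen density
    n_train: int


@dataclass
class DiagnosticClassifier:
    criterion: Criterion
    transform: Standardization
    classes: list[ClassModel]
    usable_blocks: tuple[int, ...]
    unknown_threshold: float | None = None

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classes]

    @property
    def I(self) -> int:
        return self.classes[0].model.order.I

    def log_likelihoods(self, realizations: np.ndarray) -> np.ndarray:
        """Per-class sums of decision-coefficient log densities, shape (n, K)."""
        X = np.atleast_2d(np.asarray(realizations, dtype=float))
        if X.shape[1] != self.I:
            raise InvalidInputError(
                f"realizations have length {X.shape[1]}, classifier expects {self.I}"
            )
        Z = self.transform.apply(X)
        out = np.zeros((X.shape[0], len(self.classes)))
        for k, cm in enumerate(self.classes):
            P = extract_coefficients(cm.model, Z)
            for nu in self.usable_blocks:
                idx = cm.model.decision_indices[nu]
                out[:, k] += cm.densities[nu].logpdf(P[:, idx])
        return out


@dataclass
class ClassificationResult:
    label: str
    log_likelihoods: dict[str, float]
    decision_values: dict[str, np.ndarray]

    @property
    def is_unknown(self) -> bool:
        return self.label == UNKNOWN_LABEL


def train_classifier(
    training: list[TrainingSet],
    criterion: Criterion = Criterion.nonlinear(),
    var_tol: float = 1e-10,
    bandwidth="silverman",
    kernel: str = "gaussian",
    unknown_quantile: float | None = None,
) -> DiagnosticClassifier:
    """Fit per-class canonical models and decision-coefficient densities.

    Standardization is pooled across classes; the decision rule only uses
    blocks whose decision coefficient is non-degenerate in *every* class
    (skipped blocks are logged).  ``unknown_quantile`` (e.g. ``0.01``)
    optionally arms the low-likelihood novelty flag at that quantile of the
    per-class training log-likelihoods; it is off by default.
    """
    if not training:
        raise InvalidInputError("train_classifier: no training sets")
    labels = [ts.label for ts in training]
    if len(set(labels)) != len(labels):
        raise InvalidInputError(f"duplicate class labels: {labels}")
    widths = {ts.n_features for ts in training}
    if len(widths) != 1:
        raise InvalidInputError(f"inconsistent I across classes: {widths}")
    I = widths.pop()
    training = sorted(training, key=lambda ts: ts.label)

    transform, std_sets = standardize(training)
    order = criterion.dictionary(I)
    logger.info(
        "training %s criterion: K=%d classes, I=%d, dictionary size %d",
        criterion.kind,
        len(training),
        I,
        order.size,
    )

    class_models: list[ClassModel] = []
    models: list[CanonicalModel] = []
    for ts in std_sets:
        model = build_canonical_model(MomentTable(ts), order, var_tol=var_tol)
        if model.active.size == 0:
            raise TrainingError(
                f"class {ts.label!r}: every monomial is degenerate "
                "(zero-variance training data?)"
            )
        dead = [nu for nu, idx in model.decision_indices.items() if idx is None]
        if dead:
            logger.warning(
                "class %r: blocks %s fully degenerate under %s criterion",
                ts.label,
                dead,
                criterion.kind,
            )
        models.append(model)

    usable = [
        nu
        for nu in range(1, I + 1)
        if all(m.decision_indices[nu] is not None for m in models)
    ]
    if not usable:
        dead_by_class = {
            ts.label: [nu for nu, i in m.decision_indices.items() if i is None]
            for ts, m in zip(std_sets, models)
        }
        raise TrainingError(
            f"no block has a usable decision coefficient in every class; "
            f"fully degenerate blocks per class: {dead_by_class}"
        )

    for ts, model in zip(std_sets, models):
        P = extract_coefficients(model, ts.values)
        densities = {
            nu: fit_parzen(P[:, model.decision_indices[nu]], bandwidth, kernel=kernel)
            for nu in usable
        }
        class_models.append(
            ClassModel(label=ts.label, model=model, densities=densities,
                       n_train=ts.n_realizations)
        )

    clf = DiagnosticClassifier(
        criterion=criterion,
        transform=transform,
        classes=class_models,
        usable_blocks=tuple(usable),
    )
    if unknown_quantile is not None:
        thresholds = []
        for ts, cm in zip(training, clf.classes):
            ll = clf.log_likelihoods(ts.values)[:, clf.labels.index(cm.label)]
            thresholds.append(float(np.quantile(ll, unknown_quantile)))
        clf.unknown_threshold = min(thresholds)
    return clf


def classify(
    clf: DiagnosticClassifier, realization
) -> ClassificationResult | list[ClassificationResult]:
    """Apply the product decision rule; ties break to the smallest label.

    Accepts one realization (1-D) or a stack (2-D); if the classifier's
    ``unknown_threshold`` is set and the best log-likelihood falls below
    it, the realization is labelled ``"unknown"``.
    """
    X = np.asarray(realization, dtype=float)
    single = X.ndim == 1
    ll = clf.log_likelihoods(X)
    best = np.argmax(ll, axis=1)  # classes sorted by label -> first max wins ties
    results = []
    X2 = np.atleast_2d(X)
    Z = clf.transform.apply(X2)
    decision_vals = {
        cm.label: extract_coefficients(cm.model, Z)[
            :, [cm.model.decision_indices[nu] for nu in clf.usable_blocks]
        ]
        for cm in clf.classes
    }
    for row in range(ll.shape[0]):
        label = clf.labels[best[row]]
        if clf.unknown_threshold is not None and ll[row, best[row]] < clf.unknown_threshold:
            label = UNKNOWN_LABEL
        results.append(
            ClassificationResult(
                label=label,
                log_likelihoods=dict(zip(clf.labels, ll[row])),
                decision_values={k: v[row] for k, v in decision_vals.items()},
            )
        )
    return results[0] if single else results


def evaluate_accuracy(
    clf: DiagnosticClassifier, test_sets: list[TrainingSet]
) -> dict[str, float]:
    """Per-class and overall percent-correct on labelled test sets."""
    known = set(clf.labels)
    for ts in test_sets:
        if ts.label not in known:
            raise InvalidInputError(
                f"test label {ts.label!r} unseen by classifier {sorted(known)}"
            )
    out: dict[str, float] = {}
    total = correct = 0
    for ts in test_sets:
        ll = clf.log_likelihoods(ts.values)
        pred = np.argmax(ll, axis=1)
        hits = int(np.sum(pred == clf.labels.index(ts.label)))
        out[ts.label] = 100.0 * hits / ts.n_realizations
        total += ts.n_realizations
        correct += hits
    out["overall"] = 100.0 * correct / total
    return out


def run_benchmark(
    cfg: BenchmarkConfig,
    criteria: tuple[Criterion, ...] = (
        Criterion.linear(),
        Criterion.polynomial(3),
        Criterion.nonlinear(4),
    ),
    var_tol: float = 1e-10,
) -> pd.DataFrame:
    """Train and score every criterion on one benchmark draw.

    Returns a criteria-by-classes table of percent-correct values (plus an
    ``overall`` column) — the comparative layout of the method study.
    """
    train, test = make_benchmark(cfg)
    rows = {}
    for crit in criteria:
        clf = train_classifier(train, criterion=crit, var_tol=var_tol)
        rows[crit.kind] = evaluate_accuracy(clf, test)
    df = pd.DataFrame(rows).T
    df.index.name = "criterion"
    return df
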