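"""Sample mixed-moment estimation for discrete feature sequences.

A subject's electrocardiogram is summarised by a short sequence of real
features ``c(1..I)`` (PQRST amplitudes and intervals by default, ``I = 14``).
Everything downstream — the canonical decomposition, its coordinate
functions and coefficient variances — is a function of mixed moments

    E[ C^{xi_g}(i - r_{g-1}) ... C^{xi_1}(i) ]

estimated from a class's training realizations.  This module owns that
estimation: pooled standardization of the features (numerical conditioning
for the high-order products), a :class:`MomentSpec` naming one moment, and a
:class:`MomentTable` that caches sample averages of the corresponding
products.

Conventions
-----------
* All sample moments use the maximum-likelihood denominator ``L`` (not
  ``L - 1``), so the empirical Gram matrix of monomials is exactly positive
  semidefinite.
* Feature indices are 1-based throughout, matching ``c(1)..c(I)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "TrainingSet",
    "MomentSpec",
    "Standardization",
    "standardize",
    "MomentTable",
]


@dataclass(frozen=True)
class TrainingSet:
    """A labelled set of feature-vector realizations for one class.

    ``values`` has shape ``(L, I)``: row ``l`` is the realization
    ``c_l(1..I)`` of subject ``l``.
    """

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(
                f"training set {self.label!r}: expected a 2-D (L, I) array, "
                f"got ndim={arr.ndim}"
            )
        if arr.shape[0] < 2:
            raise InvalidInputError(
                f"training set {self.label!r}: needs at least 2 realizations, "
                f"got {arr.shape[0]}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(
                f"training set {self.label!r}: non-finite feature values"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n_realizations(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def validate_realization(values, I: int) -> np.ndarray:
    """Check a single feature vector against the configured length ``I``."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size != I:
        raise InvalidInputError(f"realization has length {arr.size}, expected {I}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("realization contains non-finite values")
    return arr


@dataclass(frozen=True)
class MomentSpec:
    """Names one mixed moment: ``E[prod_j C(t_j) ** p_j]``.

    ``time_points`` are unique 1-based feature indices; ``powers`` is the
    parallel tuple of positive integer exponents.  The canonical (sorted)
    form is used as the cache key, which makes the estimate symmetric under
    permutation of the ``(time, power)`` pairs.
    """

    time_points: tuple[int, ...]
    powers: tuple[int, ...]

    def __post_init__(self) -> None:
        tp = tuple(int(t) for t in self.time_points)
        pw = tuple(int(p) for p in self.powers)
        if len(tp) != len(pw):
            raise InvalidInputError("time_points and powers must be parallel")
        if len(set(tp)) != len(tp):
            raise InvalidInputError(f"time points must be unique, got {tp}")
        if any(t < 1 for t in tp):
            raise InvalidInputError(f"time points are 1-based, got {tp}")
        if any(p < 1 for p in pw):
            raise InvalidInputError(f"powers must be >= 1, got {pw}")
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(self, "powers", pw)

    @property
    def degree(self) -> int:
        return sum(self.powers)

    def canonical(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(zip(self.time_points, self.powers)))

    def combine(self, other: "MomentSpec") -> "MomentSpec":
        """Spec of the product of the two named monomials (powers add)."""
        acc: dict[int, int] = {}
        for t, p in zip(self.time_points, self.powers):
            acc[t] = acc.get(t, 0) + p
        for t, p in zip(other.time_points, other.powers):
            acc[t] = acc.get(t, 0) + p
        items = sorted(acc.items())
        return MomentSpec(tuple(t for t, _ in items), tuple(p for _, p in items))


@dataclass(frozen=True)
class Standardization:
    """Per-feature affine transform ``(x - offset) / scale``.

    Degenerate (zero-variance) features keep ``scale = 1`` and are flagged.
    The same transform object is applied to training and test realizations;
    a fixed invertible per-feature affine map leaves the per-class argmax of
    the decision rule unchanged, so standardizing only improves the
    conditioning of the high-order moments.
    """

    offset: np.ndarray
    scale: np.ndarray
    degenerate: np.ndarray  # bool mask of zero-variance features

    def apply(self, values: np.ndarray) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("cannot standardize non-finite values")
        return (arr - self.offset) / self.scale

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scale + self.offset


def standardize(
    training: list[TrainingSet] | TrainingSet,
) -> tuple[Standardization, list[TrainingSet]]:
    """Pooled per-feature standardization across all supplied classes.

    Offsets are pooled means, scales pooled standard deviations with the
    maximum-likelihood denominator ``L`` (total row count).  Returns the
    transform and the transformed sets; reapplying to the output yields
    offsets 0 and scales 1.
    """
    sets = [training] if isinstance(training, TrainingSet) else list(training)
    if not sets:
        raise InvalidInputError("standardize: no training sets supplied")
    widths = {ts.n_features for ts in sets}
    if len(widths) != 1:
        raise InvalidInputError(f"inconsistent feature counts across classes: {widths}")
    pooled = np.vstack([ts.values for ts in sets])
    offset = pooled.mean(axis=0)
    scale = pooled.std(axis=0)  # denominator L
    degen = scale <= 0.0
    scale = np.where(degen, 1.0, scale)
    transform = Standardization(offset=offset, scale=scale, degenerate=degen)
    out = [TrainingSet(ts.label, transform.apply(ts.values)) for ts in sets]
    return transform, out


class MomentTable:
    """Cached sample mixed moments of one class's (standardized) realizations.

    ``data`` is the ``(L, I)`` matrix the averages run over.  Power columns
    ``c(i)**p`` and product columns are cached, so repeated queries during
    the decomposition recursions are cheap and bit-identical.
    """

    def __init__(self, data: np.ndarray | TrainingSet):
        if isinstance(data, TrainingSet):
            data = data.values
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.ndim != 2 or arr.size == 0:
            raise InvalidInputError("MomentTable expects a non-empty (L, I) array")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("MomentTable: non-finite values")
        self._data = arr
        self._pow: dict[tuple[int, int], np.ndarray] = {}
        self._val: dict[tuple[tuple[int, int], ...], np.ndarray] = {}
        self._mom: dict[tuple[tuple[int, int], ...], float] = {}

    @property
    def n_realizations(self) -> int:
        return self._data.shape[0]

    @property
    def n_features(self) -> int:
        return self._data.shape[1]

    def _power_column(self, t: int, p: int) -> np.ndarray:
        if not 1 <= t <= self.n_features:
            raise IndexError(
                f"time point {t} outside 1..{self.n_features}"
            )
        key = (t, p)
        col = self._pow.get(key)
        if col is None:
            col = self._data[:, t - 1] ** p
            self._pow[key] = col
        return col

    def values(self, spec: MomentSpec) -> np.ndarray:
        """Per-realization values of the monomial named by ``spec``."""
        key = spec.canonical()
        col = self._val.get(key)
        if col is None:
            if not key:
                col = np.ones(self.n_realizations)
            else:
                col = self._power_column(*key[0]).copy()
                for t, p in key[1:]:
                    col *= self._power_column(t, p)
            self._val[key] = col
        return col

    def estimate_moment(self, spec: MomentSpec) -> float:
        """Sample average of the product; the empty spec has moment 1."""
        key = spec.canonical()
        m = self._mom.get(key)
        if m is None:
            m = float(self.values(spec).mean())
            self._mom[key] = m
        return m

    def central_mixed_moment(self, left: MomentSpec, right: MomentSpec) -> float:
        """``E[V_left V_right] - E[V_left] E[V_right]``.

        This is the numerator pattern of the coordinate-function relations:
        the cross-moment of the two monomial groups minus the product of
        their marginal moments.  ``central_mixed_moment(s, s)`` with a
        power-1 spec is the sample variance (denominator ``L``).
        """
        return (
            self.estimate_moment(left.combine(right))
            - self.estimate_moment(left) * self.estimate_moment(right)
        )
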