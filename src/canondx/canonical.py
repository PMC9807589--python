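"""Generalized nonlinear canonical decomposition of a feature sequence.

The classical (Pugachev) canonical expansion represents a random sequence as
its mean plus a sum of *uncorrelated* random coefficients weighted by
deterministic coordinate functions; it only removes second-order structure.
The generalized decomposition implemented here augments the sequence with an
ordered dictionary of cross-time monomials

    C^{xi_g}(nu - r_{g-1}) ... C^{xi_1}(nu),      nu = 1..I,

and orthogonalizes the centered monomials *sequentially* under the empirical
inner product ``<a, b> = (1/L) sum_l a_l b_l``.  Each monomial yields one
random coefficient ``P`` (its residual after subtracting the projections
onto every earlier non-degenerate coefficient), one variance ``D = E[P^2]``,
and a row of coordinate functions ``omega[a][m] = E[P_a Y_m] / D_a`` giving
its contribution to every later centered monomial ``Y_m``.  Higher-order
moment structure up to the configured order is thereby converted into
*empirically uncorrelated* coefficients — the representation the diagnostic
decision rule consumes.

Two independent computational routes are provided:

* :func:`build_canonical_model` — the production path, which streams over
  the ordered dictionary and evaluates the variance/coordinate-function
  recursions purely from cross-moments (one centered cross-moment column
  per target monomial);
* :func:`gram_schmidt_oracle` — an explicit modified Gram-Schmidt
  orthogonalization of the centered monomial value columns, used in tests
  and validation as an algebraically equivalent but numerically distinct
  cross-check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .errors import DegenerateBlockError, InvalidInputError
from .moments import MomentSpec, MomentTable

__all__ = [
    "Monomial",
    "enumerate_monomials",
    "DictionaryOrder",
    "build_dictionary",
    "CanonicalModel",
    "build_canonical_model",
    "gram_schmidt_oracle",
    "extract_coefficients",
    "reconstruct_first_component",
    "select_decision_coefficients",
]

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class Monomial:
    """One dictionary entry ``C^{xi_g}(nu - r_{g-1}) ... C^{xi_1}(nu)``.

    ``powers[0]`` is the exponent at the block index ``nu`` itself,
    ``powers[j]`` the exponent at ``nu - lags[j-1]``.  Lags are strictly
    increasing positive integers bounded by ``nu - 1``.
    """

    nu: int
    lags: tuple[int, ...] = ()
    powers: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        lags = tuple(int(r) for r in self.lags)
        powers = tuple(int(p) for p in self.powers)
        if len(powers) != len(lags) + 1:
            raise InvalidInputError(
                f"monomial needs len(powers) == len(lags) + 1, got {powers}, {lags}"
            )
        if any(p < 1 for p in powers):
            raise InvalidInputError(f"powers must be positive, got {powers}")
        if any(b <= a for a, b in zip(lags, lags[1:])) or any(r < 1 for r in lags):
            raise InvalidInputError(f"lags must be strictly increasing >= 1, got {lags}")
        if lags and lags[-1] > self.nu - 1:
            raise InvalidInputError(
                f"largest lag {lags[-1]} exceeds nu - 1 = {self.nu - 1}"
            )
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "powers", powers)

    @property
    def g(self) -> int:
        """Number of factors."""
        return len(self.powers)

    @property
    def degree(self) -> int:
        return sum(self.powers)

    @property
    def time_points(self) -> tuple[int, ...]:
        return (self.nu,) + tuple(self.nu - r for r in self.lags)

    def spec(self) -> MomentSpec:
        return MomentSpec(self.time_points, self.powers)

    def sort_key(self) -> tuple:
        # within-block total order: factor count, then total degree, then
        # descending power at nu, then lexicographic on (lags, powers)
        return (self.g, self.degree, -self.powers[0], self.lags, self.powers)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"C^{self.powers[0]}({self.nu})"]
        for r, p in zip(self.lags, self.powers[1:]):
            parts.append(f"C^{p}({self.nu}-{r})")
        return "*".join(parts)


def _compositions(total: int, parts: int):
    """All tuples of ``parts`` positive integers summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_monomials(
    nu: int, N: int, B: int | None = None, cross: bool = True
) -> list[Monomial]:
    """Ordered monomials of one block of the dictionary array.

    ``N`` is the decomposition order, ``B`` the total-degree bound
    (default ``N - 1``).  ``cross=False`` restricts to single-factor
    monomials (the polynomial dictionary); the linear dictionary is the
    special case ``B = 1``.  Factor counts run up to
    ``min(nu, N - 1, B)``; lag tuples are all strictly increasing subsets of
    ``1..nu-1`` (the per-position bound ``r_j <= nu - g + j`` is implied).
    """
    if nu < 1:
        raise InvalidInputError(f"nu must be >= 1, got {nu}")
    if N < 2:
        raise InvalidInputError(f"order N must be >= 2, got {N}")
    B = N - 1 if B is None else int(B)
    if B < 1:
        raise InvalidInputError(f"degree bound B must be >= 1, got {B}")
    g_max = 1 if not cross else min(nu, N - 1, B)
    out: list[Monomial] = []
    for g in range(1, g_max + 1):
        for lags in itertools.combinations(range(1, nu), g - 1):
            for degree in range(g, B + 1):
                for powers in _compositions(degree, g):
                    out.append(Monomial(nu=nu, lags=lags, powers=powers))
    out.sort(key=Monomial.sort_key)
    return out


@dataclass(frozen=True)
class DictionaryOrder:
    """The full ordered monomial dictionary over blocks ``nu = 1..I``."""

    I: int
    N: int
    B: int
    cross: bool
    monomials: tuple[Monomial, ...]
    block_start: tuple[int, ...]  # start index of each block, plus total size

    @property
    def size(self) -> int:
        return len(self.monomials)

    def block_slice(self, nu: int) -> slice:
        if not 1 <= nu <= self.I:
            raise InvalidInputError(f"block {nu} outside 1..{self.I}")
        return slice(self.block_start[nu - 1], self.block_start[nu])

    def block_of(self, idx: int) -> int:
        return self.monomials[idx].nu

    def first_power_index(self, nu: int) -> int:
        """Position of the single-factor power-1 monomial ``C(nu)``."""
        return self.block_start[nu - 1]

    def last_monomial_of_block(self, nu: int) -> Monomial:
        return self.monomials[self.block_start[nu] - 1]


def build_dictionary(
    I: int, N: int, B: int | None = None, cross: bool = True
) -> DictionaryOrder:
    """Concatenate :func:`enumerate_monomials` over ``nu = 1..I``."""
    if I < 1:
        raise InvalidInputError(f"I must be >= 1, got {I}")
    B = N - 1 if B is None else int(B)
    mons: list[Monomial] = []
    starts = [0]
    for nu in range(1, I + 1):
        mons.extend(enumerate_monomials(nu, N, B, cross=cross))
        starts.append(len(mons))
    return DictionaryOrder(
        I=I, N=N, B=B, cross=cross, monomials=tuple(mons), block_start=tuple(starts)
    )


@dataclass
class CanonicalModel:
    """Parameters of one class's canonical decomposition.

    Attributes
    ----------
    order : DictionaryOrder
        The monomial dictionary the model is indexed by.
    monomial_means : (n,) array
        Training means of the raw monomial values (``mean`` of the feature
        sequence itself sits at the power-1 positions).
    variances : (n,) array
        Coefficient variances ``D``; exactly 0 at degenerate positions.
    omega : (n, n) array
        Coordinate functions; ``omega[a, m]`` is the weight of coefficient
        ``a`` in the expansion of centered monomial ``m`` (defined for
        non-degenerate ``a`` and targets ``m`` at or after ``a``;
        ``omega[m, m] = 1`` for non-degenerate ``m``).
    degenerate : (n,) bool array
        Monomials whose residual variance fell below tolerance (or beyond
        the sample-rank budget ``L - 1``) and are excluded from
        conditioning; their coefficients are fixed at 0.
    active : (k,) int array
        Indices of non-degenerate monomials, in dictionary order.
    decision_indices : dict[int, int | None]
        Per block ``i``, the position of the last non-degenerate monomial
        of the block (``None`` if the block is fully degenerate).
    """

    order: DictionaryOrder
    monomial_means: np.ndarray
    variances: np.ndarray
    omega: np.ndarray
    degenerate: np.ndarray
    active: np.ndarray
    decision_indices: dict[int, int | None]
    n_train: int
    var_tol: float

    @property
    def mean(self) -> np.ndarray:
        """Mean function ``E[C(i)]``, ``i = 1..I``."""
        idx = [self.order.first_power_index(nu) for nu in range(1, self.order.I + 1)]
        return self.monomial_means[idx]

    @property
    def usable_blocks(self) -> list[int]:
        return [nu for nu, m in self.decision_indices.items() if m is not None]


def monomial_values(X: np.ndarray, order: DictionaryOrder) -> np.ndarray:
    """Evaluate every dictionary monomial on realizations ``X`` (rows)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != order.I:
        raise InvalidInputError(
            f"realizations have {X.shape[1]} features, dictionary expects {order.I}"
        )
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("non-finite realization values")
    powers: dict[tuple[int, int], np.ndarray] = {}

    def pcol(t: int, p: int) -> np.ndarray:
        key = (t, p)
        if key not in powers:
            powers[key] = X[:, t - 1] ** p
        return powers[key]

    V = np.empty((X.shape[0], order.size))
    for j, mon in enumerate(order.monomials):
        tps = mon.time_points
        col = pcol(tps[0], mon.powers[0]).copy()
        for t, p in zip(tps[1:], mon.powers[1:]):
            col *= pcol(t, p)
        V[:, j] = col
    return V


def _decision_indices(
    order: DictionaryOrder, degenerate: np.ndarray
) -> dict[int, int | None]:
    out: dict[int, int | None] = {}
    for nu in range(1, order.I + 1):
        sl = order.block_slice(nu)
        idx = None
        for m in range(sl.stop - 1, sl.start - 1, -1):
            if not degenerate[m]:
                idx = m
                break
        out[nu] = idx
    return out


def build_canonical_model(
    table: MomentTable, order: DictionaryOrder, var_tol: float = 1e-10
) -> CanonicalModel:
    """Build coordinate functions and coefficient variances by recursion.

    Monomials are processed in dictionary order.  For target ``m`` with
    centered value ``Y_m``, the cross-moments ``E[P_a Y_m]`` with all earlier
    non-degenerate coefficients satisfy the forward recursion

        E[P_a Y_m] = E[Y_a Y_m] - sum_{b<a} omega[b][a] E[P_b Y_m],

    (a unit-lower-triangular solve), after which
    ``omega[a][m] = E[P_a Y_m] / D_a`` and
    ``D_m = E[Y_m^2] - sum_a E[P_a Y_m]^2 / D_a`` — the projection
    subtraction pattern of the coordinate-function relations.  Only one
    centered cross-moment column per target is formed; the full Gram matrix
    is never materialized.

    Degeneracy: ``D_m <= var_tol * E[Y_m^2]`` (or a negative roundoff value)
    marks ``m`` degenerate, as does exhaustion of the sample-rank budget
    ``L - 1`` — with ``L`` training rows at most ``L - 1`` centered columns
    can be linearly independent, so every later residual is exactly zero.
    """
    n = order.size
    if n == 0:
        raise InvalidInputError("empty dictionary")
    L = table.n_realizations
    if table.n_features != order.I:
        raise InvalidInputError(
            f"moment table has I={table.n_features}, dictionary expects {order.I}"
        )
    # raw monomial value columns via the moment table's cache
    V = np.column_stack([table.values(mon.spec()) for mon in order.monomials])
    mu = V.mean(axis=0)
    Y = V - mu

    omega = np.zeros((n, n))
    D = np.zeros(n)
    degenerate = np.zeros(n, dtype=bool)
    active: list[int] = []
    max_active = max(L - 1, 1)
    cap = min(n, max_active)
    Yact = np.empty((L, cap))
    lower = np.zeros((cap, cap))  # unit lower factor: lower[i, j] = omega[act[j], act[i]]
    Dact = np.empty(cap)

    for m in range(n):
        y = Y[:, m]
        ym2 = float(y @ y) / L
        raw2 = float(V[:, m] @ V[:, m]) / L  # degeneracy scale: raw 2nd moment
        k = len(active)
        if k:
            c = Yact[:, :k].T @ y / L
            u = solve_triangular(
                lower[:k, :k], c, lower=True, unit_diagonal=True,
                check_finite=False,
            )
            w = u / Dact[:k]
            d = ym2 - float(u @ w)
            omega[active, m] = w
        else:
            d = ym2
        if d <= var_tol * max(raw2, ym2, _TINY) or k >= max_active:
            degenerate[m] = True
        else:
            D[m] = d
            omega[m, m] = 1.0
            if k:
                lower[k, :k] = w
            Yact[:, k] = y
            Dact[k] = d
            active.append(m)

    decision = _decision_indices(order, degenerate)
    logger.info(
        "canonical model: dictionary size %d, non-degenerate %d, "
        "fully degenerate blocks %s",
        n,
        len(active),
        [nu for nu, v in decision.items() if v is None] or "none",
    )
    return CanonicalModel(
        order=order,
        monomial_means=mu,
        variances=D,
        omega=omega,
        degenerate=degenerate,
        active=np.asarray(active, dtype=int),
        decision_indices=decision,
        n_train=L,
        var_tol=var_tol,
    )


def gram_schmidt_oracle(
    table: MomentTable, order: DictionaryOrder, var_tol: float = 1e-10
) -> CanonicalModel:
    """Independent verification path: explicit sequential orthogonalization.

    Materializes the centered monomial value columns over the training
    sample and runs modified Gram-Schmidt in realization space: the residual
    vector of each monomial is formed explicitly, ``D`` is its mean square
    and ``omega`` the normalized inner products.  Mathematically equivalent
    to :func:`build_canonical_model`; numerically a different algorithm.
    Intended for tests and validation, not production training.
    """
    n = order.size
    if n == 0:
        raise InvalidInputError("empty dictionary")
    L = table.n_realizations
    V = np.column_stack([table.values(mon.spec()) for mon in order.monomials])
    mu = V.mean(axis=0)
    Y = V - mu

    omega = np.zeros((n, n))
    D = np.zeros(n)
    degenerate = np.zeros(n, dtype=bool)
    active: list[int] = []
    residuals: list[np.ndarray] = []
    max_active = max(L - 1, 1)

    for m in range(n):
        r = Y[:, m].copy()
        ym2 = float(r @ r) / L
        raw2 = float(V[:, m] @ V[:, m]) / L
        for pos, a in enumerate(active):
            w = float(residuals[pos] @ r) / L / D[a]
            omega[a, m] = w
            r -= w * residuals[pos]
        d = float(r @ r) / L
        if d <= var_tol * max(raw2, ym2, _TINY) or len(active) >= max_active:
            degenerate[m] = True
        else:
            D[m] = d
            omega[m, m] = 1.0
            active.append(m)
            residuals.append(r)

    return CanonicalModel(
        order=order,
        monomial_means=mu,
        variances=D,
        omega=omega,
        degenerate=degenerate,
        active=np.asarray(active, dtype=int),
        decision_indices=_decision_indices(order, degenerate),
        n_train=L,
        var_tol=var_tol,
    )


def extract_coefficients(model: CanonicalModel, realizations: np.ndarray) -> np.ndarray:
    """Map realizations to canonical coefficient vectors.

    Input must already be in the model's (standardized) feature space.  For
    each realization, in dictionary order,

        p[m] = Y_m - sum_{a earlier, non-degenerate} p[a] * omega[a][m],

    with ``Y_m`` the centered monomial value; degenerate positions carry 0.
    Returns shape ``(n_realizations, dictionary size)`` (or ``(n,)`` for a
    single 1-D realization).
    """
    X = np.asarray(realizations, dtype=float)
    single = X.ndim == 1
    V = monomial_values(X, model.order)
    Y = V - model.monomial_means
    P = np.zeros_like(Y)
    act = model.active
    if act.size:
        U = model.omega[np.ix_(act, act)]  # unit upper triangular
        # Y_act = P_act @ U  =>  U^T P_act^T = Y_act^T
        P_act = solve_triangular(
            U.T, Y[:, act].T, lower=True, unit_diagonal=True, check_finite=False
        ).T
        P[:, act] = P_act
    return P[0] if single else P


def reconstruct_first_component(
    model: CanonicalModel, coefficients: np.ndarray
) -> np.ndarray:
    """Rebuild the feature sequence from a coefficient vector.

    ``c(i) = mean_monomial(C(i)) + sum_a p[a] * omega[a][C(i) position]`` —
    the first-component expansion of the vector canonical decomposition
    (the self term enters through ``omega[m][m] = 1``).  Exact round-trip
    inverse of :func:`extract_coefficients` on the non-degenerate part; the
    zero coefficient vector reproduces the mean function.
    """
    P = np.asarray(coefficients, dtype=float)
    single = P.ndim == 1
    P = np.atleast_2d(P)
    if P.shape[1] != model.order.size:
        raise InvalidInputError(
            f"coefficient vector length {P.shape[1]} != dictionary size "
            f"{model.order.size}: mismatched model"
        )
    I = model.order.I
    out = np.empty((P.shape[0], I))
    for nu in range(1, I + 1):
        m0 = model.order.first_power_index(nu)
        out[:, nu - 1] = model.monomial_means[m0] + P @ model.omega[:, m0]
    return out[0] if single else out


def select_decision_coefficients(
    model: CanonicalModel, strict: bool = True
) -> list[Monomial]:
    """The last non-degenerate monomial of each block — the decision
    coefficients whose one-dimensional densities the decision rule
    multiplies.  With ``strict`` (default) a fully degenerate block raises
    :class:`DegenerateBlockError` naming the block; otherwise such blocks
    are omitted from the returned list.
    """
    out: list[Monomial] = []
    for nu in range(1, model.order.I + 1):
        idx = model.decision_indices[nu]
        if idx is None:
            if strict:
                raise DegenerateBlockError(
                    f"block i={nu} has no non-degenerate coefficient"
                )
            continue
        out.append(model.order.monomials[idx])
    return out
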