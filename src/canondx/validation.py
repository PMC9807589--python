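"""Model-adequacy diagnostics: coefficient independence and order selection.

The decomposition's claim is that the decision coefficients are independent
random variables; a chi-square contingency test on marginal-quantile bins
checks this pairwise on the training coefficients.  If dependence survives
(as it does for a linear decomposition of a sequence with genuine
higher-order structure), the order ``N`` is insufficient;
:func:`choose_order` returns the smallest adequate candidate.  A
permutation test on a mutual-information statistic is available as an
optional second, binning-free check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .canonical import build_canonical_model
from .errors import InvalidInputError, OrderSelectionError
from .moments import MomentTable, TrainingSet, standardize
from .canonical import build_dictionary, extract_coefficients

__all__ = [
    "chi2_from_table",
    "chi2_independence",
    "IndependenceReport",
    "coefficient_independence_report",
    "choose_order",
    "mutual_information_pvalue",
]


def chi2_from_table(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise InvalidInputError("contingency table must be 2-D with counts >= 0")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _quantile_bin(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0.0, 1.0, bins + 1))
    inner = edges[1:-1]
    if np.unique(inner).size != inner.size:
        raise InvalidInputError(
            "quantile bin edges collapse (heavy ties); use fewer bins"
        )
    return np.searchsorted(inner, x, side="left")


def chi2_independence(x, y, bins: int = 4) -> tuple[float, int, float]:
    """Pairwise independence test on marginal-quantile bins.

    Both samples are binned into ``bins`` equal-count classes, the Pearson
    statistic is computed on the resulting contingency table with expected
    counts from the margins; ``dof = (bins - 1)^2``.  Quantile binning makes
    the statistic invariant under monotone transforms of either sample.
    Requires at least ``5 * bins^2`` paired observations (expected-count
    budget of about 5 per cell).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if bins < 2:
        raise InvalidInputError(f"need bins >= 2, got {bins}")
    if x.size != y.size:
        raise InvalidInputError("samples must have equal length")
    if x.size < 5 * bins * bins:
        raise InvalidInputError(
            f"need at least {5 * bins * bins} pairs for {bins}x{bins} bins; "
            f"got {x.size} — use fewer bins"
        )
    bx = _quantile_bin(x, bins)
    by = _quantile_bin(y, bins)
    table = np.zeros((bins, bins))
    np.add.at(table, (bx, by), 1.0)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidInputError("empty marginal bin; use fewer bins")
    return chi2_from_table(table)


@dataclass
class IndependenceReport:
    """Pairwise chi-square results for one model's decision coefficients."""

    table: pd.DataFrame  # columns: block_i, block_j, statistic, dof, p, reject
    accept: bool
    alpha: float
    bins: int
    N: int
    n_samples: int

    def summary(self) -> str:
        n_reject = int(self.table["reject"].sum())
        verdict = "accepted" if self.accept else "rejected"
        return (
            f"independence {verdict} at family level alpha={self.alpha} "
            f"(N={self.N}, {len(self.table)} pairs, {n_reject} rejections, "
            f"n={self.n_samples})"
        )


def coefficient_independence_report(
    model,
    training: np.ndarray | TrainingSet,
    alpha: float = 0.05,
    bins: int = 4,
) -> IndependenceReport:
    """Test all pairs of decision coefficients extracted from ``training``.

    ``training`` must be in the model's (standardized) feature space.
    Holm's step-down rule controls the family-wise error over the pairs;
    the hypothesis of independence is accepted iff no pair remains
    significant.
    """
    data = training.values if isinstance(training, TrainingSet) else np.asarray(training)
    P = extract_coefficients(model, data)
    blocks = model.usable_blocks
    if len(blocks) < 2:
        raise InvalidInputError("need at least two usable decision coefficients")
    cols = {nu: P[:, model.decision_indices[nu]] for nu in blocks}
    rows = []
    for a, b in itertools.combinations(blocks, 2):
        stat, dof, p = chi2_independence(cols[a], cols[b], bins=bins)
        rows.append({"block_i": a, "block_j": b, "statistic": stat, "dof": dof, "p": p})
    df = pd.DataFrame(rows)
    reject, _, _, _ = multipletests(df["p"].to_numpy(), alpha=alpha, method="holm")
    df["reject"] = reject
    return IndependenceReport(
        table=df,
        accept=not bool(reject.any()),
        alpha=alpha,
        bins=bins,
        N=model.order.N,
        n_samples=data.shape[0],
    )


def choose_order(
    training: TrainingSet,
    candidates=(2, 3, 4),
    alpha: float = 0.05,
    bins: int = 4,
    var_tol: float = 1e-10,
) -> int:
    """Smallest candidate order ``N`` whose coefficients test independent.

    ``N = 2`` is the linear decomposition.  Raises
    :class:`OrderSelectionError` listing the per-candidate verdicts if no
    candidate is adequate.
    """
    candidates = sorted(set(int(N) for N in candidates))
    if not candidates:
        raise InvalidInputError("choose_order: no candidate orders")
    _, (std,) = standardize(training)
    failures = {}
    for N in candidates:
        order = build_dictionary(training.n_features, N=N)
        model = build_canonical_model(MomentTable(std), order, var_tol=var_tol)
        report = coefficient_independence_report(model, std, alpha=alpha, bins=bins)
        if report.accept:
            return N
        failures[N] = report.summary()
    raise OrderSelectionError(
        "no candidate order passed the independence test: "
        + "; ".join(f"N={N}: {msg}" for N, msg in failures.items())
    )


def mutual_information_pvalue(
    x, y, bins: int = 4, n_permutations: int = 200, seed=0
) -> float:
    """Permutation p-value for dependence via binned mutual information.

    An optional second, distribution-free check playing the same role as
    the chi-square test: the plug-in mutual information of the
    quantile-binned pair is compared with its permutation null.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 5 * bins * bins:
        raise InvalidInputError("samples too small or mismatched for MI test")
    bx = _quantile_bin(x, bins)
    by = _quantile_bin(y, bins)

    def mi(bu, bv):
        table = np.zeros((bins, bins))
        np.add.at(table, (bu, bv), 1.0)
        pxy = table / table.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        mask = pxy > 0
        return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))

    observed = mi(bx, by)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if mi(bx, rng.permutation(by)) >= observed:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)
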