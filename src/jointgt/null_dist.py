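"""Null distributions and p-values for the set-association statistics.

Two routes are provided:

* **Permutation** (default): the response (equivalently, under an
  intercept-only null, its residual vector) is permuted across samples and
  the statistic recomputed; the p-value uses the add-one estimator
  ``(1 + #{Q_perm >= Q_obs}) / (1 + n_perm)`` so it is never zero.  When the
  sample size is small enough that all ``N!`` permutations fit in the
  requested budget (and the null has no confounders), the enumeration is
  exhaustive and the p-value exact.

* **Ratio-of-quadratic-forms tail** (``spectral`` + ``asymptotic_pvalue``):
  under the linear model the null law of Q is the ratio

      Q  =  sum_i lambda_i chi2_1,i  /  sum_{j=1..d} chi2_1,j,

  where the ``lambda_i`` are the eigenvalues of the quadratic-form matrix
  restricted to the ``d``-dimensional residual space.  The tail probability
  P(Q >= q) equals P(sum_j (lambda_j - q) chi2_1,j >= 0), a weighted
  chi-square tail evaluated by numerical inversion of the characteristic
  function (Imhof's integral).  This law is exact in finite samples for
  gaussian errors, and the same spectrum applies to the merged-set sum
  statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate

from .core_test import (
    CovariateSet,
    NullModel,
    TestResult,
    joint_statistic,
    moments_q,
)

__all__ = [
    "PermutationPlan",
    "SpectralNull",
    "permutation_pvalue",
    "permutation_statistics",
    "spectral",
    "asymptotic_pvalue",
    "run_joint_test",
]

#: eigenvalues below this fraction of the largest are treated as zero
EIG_REL_TOL = 1e-10


@dataclass
class PermutationPlan:
    """How to build the permutation null.

    ``exhaustive=None`` auto-enables full enumeration whenever ``N!`` does
    not exceed ``n_perm`` and the null model has no confounders.
    """

    n_perm: int = 999
    seed: int = 42
    scheme: str = "permute_response"
    exhaustive: bool | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        if self.scheme not in ("permute_response", "permute_residuals"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")

    def is_exhaustive(self, null: NullModel) -> bool:
        if self.exhaustive is not None:
            return self.exhaustive
        n = null.n_samples
        return not null.has_confounders and math.factorial(n) <= self.n_perm

    def permutation_indices(self, null: NullModel) -> tuple[np.ndarray, bool]:
        """Index matrix (one permutation per row) and exhaustiveness flag."""
        n = null.n_samples
        if self.is_exhaustive(null):
            idx = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
            return idx, True
        rng = np.random.default_rng(self.seed)
        idx = np.argsort(rng.random((self.n_perm, n)), axis=1)
        return idx, False


@dataclass
class SpectralNull:
    """Eigenvalues defining the ratio-of-quadratic-forms null law."""

    eigenvalues: np.ndarray  # descending, zeros removed
    df_resid: int
    tolerance: float = EIG_REL_TOL


def _per_set_perm_q(
    null: NullModel, sets: Sequence[CovariateSet], idx: np.ndarray
) -> np.ndarray:
    """Matrix (n_perm x n_sets) of per-set Q statistics on permuted residuals."""
    r = null.residuals
    rtr = null.rss
    r_perm = r[idx]  # (n_perm, N)
    cols = []
    for xset in sets:
        if xset.n_probes == 0:
            cols.append(np.zeros(idx.shape[0]))
            continue
        xr = r_perm @ xset.values  # (n_perm, J)
        cols.append(np.einsum("ij,ij->i", xr, xr) / rtr)
    return np.column_stack(cols)


def permutation_statistics(
    null: NullModel,
    sets: Sequence[CovariateSet],
    mode: str = "sum",
    weights: Sequence[float] | None = None,
    plan: PermutationPlan | None = None,
) -> tuple[TestResult, np.ndarray, np.ndarray, bool]:
    """Observed result plus permuted combined and per-set statistics.

    Returns ``(observed, combined_perm, per_set_q_perm, exhaustive)``; the
    permuted arrays have one row per permutation, letting callers derive
    p-values for the joint and every individual test from a single
    permutation stream.
    """
    plan = plan or PermutationPlan()
    observed = joint_statistic(null, sets, mode=mode, weights=weights)
    if weights is None:
        weights = [s.weight for s in sets]
    idx, exhaustive = plan.permutation_indices(null)
    q_perm = _per_set_perm_q(null, sets, idx)  # (n_perm, M)
    w = np.asarray(weights, dtype=float)
    if mode == "sum":
        combined = q_perm @ w
    else:
        eq = np.zeros(len(sets))
        sd = np.ones(len(sets))
        active = np.ones(len(sets), dtype=bool)
        for m, xset in enumerate(sets):
            if xset.n_probes == 0:
                active[m] = False
                continue
            e, v = moments_q(null, xset)
            eq[m] = e
            if v > 0:
                sd[m] = np.sqrt(v)
            elif mode == "standardized_sum":
                active[m] = False
        centered = q_perm - eq
        if mode == "centered_squared":
            combined = ((centered**2) * w * active).sum(axis=1)
        else:  # standardized_sum
            combined = ((centered / sd) * w * active).sum(axis=1)
    return observed, np.asarray(combined, dtype=float), q_perm, exhaustive


def _tail_fraction(perm: np.ndarray, obs: float, exhaustive: bool) -> float:
    tol = 1e-12 * max(1.0, abs(obs))
    hits = int(np.count_nonzero(perm >= obs - tol))
    if exhaustive:
        return hits / perm.size
    return (1 + hits) / (1 + perm.size)


def permutation_pvalue(
    null: NullModel,
    sets: Sequence[CovariateSet],
    mode: str = "sum",
    weights: Sequence[float] | None = None,
    plan: PermutationPlan | None = None,
) -> float:
    """Permutation p-value of the combined statistic; ties count against rejection."""
    observed, combined, _, exhaustive = permutation_statistics(
        null, sets, mode=mode, weights=weights, plan=plan
    )
    return _tail_fraction(combined, observed.combined, exhaustive)


def spectral(
    null: NullModel,
    sets: Sequence[CovariateSet],
    weights: Sequence[float] | None = None,
    tolerance: float = EIG_REL_TOL,
) -> SpectralNull:
    """Eigenvalues of the merged, weighted quadratic form on the residual space.

    Only defined for the ``sum`` combination, which admits the single-matrix
    representation ``sum_m w_m X_m X_m'``.  Computed entirely in covariate
    space: the nonzero eigenvalues of the projected ``N x N`` form equal
    those of the ``J x J`` Gram matrix of the projected, weight-scaled
    columns.
    """
    if weights is None:
        weights = [s.weight for s in sets]
    blocks = [
        np.sqrt(w) * s.values
        for s, w in zip(sets, weights)
        if s.n_probes > 0
    ]
    if not blocks:
        raise ValueError("all covariate sets are empty")
    merged = np.hstack(blocks)
    if merged.shape[0] != null.n_samples:
        raise ValueError("covariate rows do not match null model")
    proj = null.project(merged)
    gram = proj.T @ proj
    vals = np.linalg.eigvalsh(gram)[::-1]
    top = vals[0] if vals.size else 0.0
    if top <= 0:
        raise ValueError("covariates have no variance on the residual space")
    vals = vals[vals > tolerance * top]
    return SpectralNull(eigenvalues=vals, df_resid=null.df_resid, tolerance=tolerance)


def _imhof_tail_at_zero(coefs: np.ndarray) -> float:
    """P(sum_r c_r chi2_1,r >= 0) by Imhof characteristic-function inversion."""
    c = np.asarray(coefs, dtype=float)
    c = c[c != 0.0]
    if c.size == 0:
        return 1.0
    if np.all(c > 0):
        return 1.0
    if np.all(c < 0):
        return 0.0

    scale = np.max(np.abs(c))
    c = c / scale  # pure rescaling of u; leaves the integral invariant

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(c * u))
        log_rho = 0.25 * np.sum(np.log1p((c * u) ** 2))
        if u == 0.0:
            return 0.5 * float(np.sum(c))
        return float(np.sin(theta) * np.exp(-log_rho) / u)

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=1e-9, epsrel=1e-9, limit=500
    )
    return min(1.0, max(0.0, 0.5 + val / np.pi))


def asymptotic_pvalue(q_obs: float, spec: SpectralNull) -> float:
    """Tail probability P(Q >= q_obs) of the ratio-of-quadratic-forms null.

    Exact in finite samples for gaussian errors under the linear model.
    Values of ``q_obs`` outside the support [0, lambda_max] return 0 or 1.
    """
    if not np.isfinite(q_obs):
        raise ValueError("q_obs must be finite")
    lam = spec.eigenvalues
    if lam.size == 0:
        raise ValueError("spectral null has no positive eigenvalues")
    if q_obs <= 0.0:
        return 1.0
    if q_obs >= lam[0]:
        return 0.0
    d = spec.df_resid
    n_zero = d - lam.size
    coefs = np.concatenate([lam - q_obs, np.full(max(n_zero, 0), -q_obs)])
    return _imhof_tail_at_zero(coefs)


def run_joint_test(
    null: NullModel,
    sets: Sequence[CovariateSet],
    mode: str = "sum",
    weights: Sequence[float] | None = None,
    plan: PermutationPlan | None = None,
    method: str = "permutation",
    response_id: str = "y",
) -> TestResult:
    """Run the joint and individual tests and attach p-values.

    ``method`` is one of ``permutation``, ``asymptotic``, ``both``; with
    ``both``, permutation p-values are reported and the asymptotic joint
    p-value stored under the ``"joint_asymptotic"`` key of ``p_per_set``.
    Individual (per-set) p-values always refer to the single-set statistic
    ``Q_m``.
    """
    if method not in ("permutation", "asymptotic", "both"):
        raise ValueError(f"unknown p-value method {method!r}")
    if weights is None:
        weights = [s.weight for s in sets]

    if method == "asymptotic":
        result = joint_statistic(null, sets, mode=mode, weights=weights,
                                 response_id=response_id)
        if mode != "sum":
            raise ValueError("asymptotic p-values are only defined for mode='sum'")
        for xset in sets:
            if xset.n_probes == 0:
                continue
            sp = spectral(null, [xset], weights=[1.0])
            result.p_per_set[xset.name] = asymptotic_pvalue(
                result.components[xset.name].q, sp
            )
        sp_joint = spectral(null, sets, weights=weights)
        result.p_joint = asymptotic_pvalue(result.combined, sp_joint)
        return result

    observed, combined, q_perm, exhaustive = permutation_statistics(
        null, sets, mode=mode, weights=weights, plan=plan
    )
    observed.response_id = response_id
    for m, xset in enumerate(sets):
        if xset.n_probes == 0:
            continue
        observed.p_per_set[xset.name] = _tail_fraction(
            q_perm[:, m], observed.components[xset.name].q, exhaustive
        )
    observed.p_joint = _tail_fraction(combined, observed.combined, exhaustive)
    if method == "both" and mode == "sum":
        sp_joint = spectral(null, sets, weights=weights)
        observed.p_per_set["joint_asymptotic"] = asymptotic_pvalue(
            observed.combined, sp_joint
        )
    return observed
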