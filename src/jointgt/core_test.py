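"""Variance-component score statistics for one or more covariate sets.

The model behind the test is a random-effects regression of a single
response ``y`` (length ``N``) on one or more sets of covariates, each set
entering through its own vector of random coefficients with variance
``tau_m``.  The null hypothesis is that every ``tau_m`` is zero, i.e. the
response is associated with none of the sets.  The score statistic for a
single set with design matrix ``X`` (``N x J``) is the ratio of quadratic
forms

    Q(X) = r' X X' r / r' r,

where ``r`` are the residuals of the response under the null design
(intercept plus optional confounders).  For several sets the per-set
statistics are combined; the default combination is the plain sum
``Q(X) + Q(Z) + ...`` which is identical to the single-set statistic on the
column-merged matrix ``[X | Z | ...]``.

All heavy linear algebra is done in covariate space (``J x J`` Gram
matrices); the ``N x N`` quadratic-form matrix is never materialised, so the
statistics scale to genome-wide screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ResponseVector",
    "CovariateSet",
    "NullModel",
    "TestComponents",
    "TestResult",
    "DegenerateResponseError",
    "fit_null",
    "q_statistic",
    "moments_q",
    "standardized_t",
    "joint_statistic",
    "standardize_columns",
    "impute_column_mean",
    "COMBINE_MODES",
]

logger = logging.getLogger(__name__)

COMBINE_MODES = ("sum", "centered_squared", "standardized_sum")

#: relative threshold below which the residual sum of squares is treated as zero
_DEGENERATE_RSS_REL = 1e-12


class DegenerateResponseError(ValueError):
    """Raised when the response carries no residual variance under the null."""


@dataclass
class ResponseVector:
    """One response (e.g. one gene's expression) across ``N`` samples.

    Parameters
    ----------
    values
        Real vector of length ``N``.
    sample_ids
        Unique sample identifiers, same length as ``values``.
    confounders
        Optional ``N x p`` matrix of covariates to adjust for under the
        null; an intercept is always implied and must not be included.
    response_id
        Identifier of the response feature (used in reports).
    """

    values: np.ndarray
    sample_ids: Sequence[str] | None = None
    confounders: np.ndarray | None = None
    response_id: str = "y"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        n = self.values.size
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response contains missing/non-finite values")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if self.confounders is not None:
            c = np.atleast_2d(np.asarray(self.confounders, dtype=float))
            if c.shape[0] != n:
                c = c.T
            if c.shape[0] != n:
                raise ValueError("confounder rows do not match response length")
            if not np.all(np.isfinite(c)):
                raise ValueError("confounders contain missing/non-finite values")
            self.confounders = c

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class CovariateSet:
    """A named ``N x J`` block of covariates tested jointly.

    ``weight`` is the prior constant eta relating this set's random-effect
    variance to the reference set's; it multiplies the set's statistic in
    the combined test.
    """

    name: str
    values: np.ndarray
    probe_ids: Sequence[str] | None = None
    positions: Sequence[tuple[str, int]] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("covariate values must be a 2-D matrix")
        n, j = self.values.shape
        if self.probe_ids is None:
            self.probe_ids = [f"{self.name}_{k}" for k in range(j)]
        self.probe_ids = list(self.probe_ids)
        if len(self.probe_ids) != j:
            raise ValueError("probe_ids length does not match number of columns")
        if self.weight <= 0:
            raise ValueError("set weight must be positive")
        if j > 0 and not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"covariate set {self.name!r} contains missing values; "
                "impute explicitly (impute_column_mean) or drop probes"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


@dataclass
class NullModel:
    """Artifacts of the null fit of a response on intercept (+ confounders).

    ``basis`` is an orthonormal basis of the null design's column space and
    realises the projection contract: ``project(M)`` maps any ``N``-row
    matrix onto the residual space.
    """

    fitted: np.ndarray
    residuals: np.ndarray
    df_resid: int
    design_rank: int
    basis: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.residuals.size

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def has_confounders(self) -> bool:
        return self.design_rank > 1

    def project(self, m: np.ndarray) -> np.ndarray:
        """Project columns of ``m`` onto the residual (orthogonal) space."""
        m = np.asarray(m, dtype=float)
        return m - self.basis @ (self.basis.T @ m)


@dataclass
class TestComponents:
    """Per-set pieces of the score statistic."""

    q: float
    expected_q: float
    var_q: float
    t: float
    trace_term: float


@dataclass
class TestResult:
    response_id: str
    components: Mapping[str, TestComponents]
    combined: float
    combine_mode: str
    set_sizes: Mapping[str, int]
    p_per_set: dict = field(default_factory=dict)
    p_joint: float = float("nan")
    flags: list = field(default_factory=list)


def fit_null(y: ResponseVector) -> NullModel:
    """Fit the null model: OLS of the response on intercept (+ confounders).

    Raises
    ------
    DegenerateResponseError
        If the residual sum of squares is (numerically) zero — constant
        response, or confounders that explain the response exactly.
    """
    n = y.n_samples
    cols = [np.ones((n, 1))]
    if y.confounders is not None:
        cols.append(y.confounders)
    design = np.hstack(cols)
    if design.shape[1] >= n:
        raise ValueError("null design has as many columns as samples")
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    tol = s[0] * max(design.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    basis = u[:, :rank]
    fitted = basis @ (basis.T @ y.values)
    residuals = y.values - fitted
    df_resid = n - rank
    if df_resid < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")
    rss = float(residuals @ residuals)
    var_y = float(np.var(y.values))
    if var_y <= 0.0 or rss < _DEGENERATE_RSS_REL * n * var_y:
        raise DegenerateResponseError(
            f"degenerate response {y.response_id!r}: no residual variance under the null"
        )
    return NullModel(
        fitted=fitted,
        residuals=residuals,
        df_resid=df_resid,
        design_rank=rank,
        basis=basis,
    )


def q_statistic(null: NullModel, xset: CovariateSet) -> float:
    """Single-set score statistic Q = ||X'r||^2 / r'r on the null residuals."""
    x = xset.values
    if x.shape[0] != null.n_samples:
        raise ValueError(
            f"covariate set {xset.name!r} has {x.shape[0]} rows, "
            f"null model has {null.n_samples} samples"
        )
    xr = x.T @ null.residuals
    return float(xr @ xr) / null.rss


def moments_q(null: NullModel, xset: CovariateSet) -> tuple[float, float]:
    """Null mean and variance of Q under the rotation-invariant null.

    The residual direction is taken uniform on the unit sphere of the
    ``d``-dimensional residual space (``d = df_resid``).  With ``A`` the
    quadratic-form matrix ``X X'`` projected onto that space,

        E[Q]   = tr(A) / d
        Var[Q] = 2 (d tr(A^2) - tr(A)^2) / (d^2 (d + 2)).

    Both traces are evaluated through the ``J x J`` Gram matrix of the
    projected covariates, never in sample space.
    """
    x = xset.values
    if x.shape[0] != null.n_samples:
        raise ValueError("covariate rows do not match null model")
    xp = null.project(x)
    gram = xp.T @ xp
    tr_a = float(np.trace(gram)) if gram.size else 0.0
    tr_a2 = float(np.sum(gram * gram))  # tr(A^2) = ||Gram||_F^2 for symmetric Gram
    d = null.df_resid
    expected_q = tr_a / d
    var_q = 2.0 * (d * tr_a2 - tr_a**2) / (d**2 * (d + 2))
    return expected_q, var_q


def standardized_t(q: float, expected_q: float, var_q: float) -> float:
    """Standardize Q to zero mean / unit variance under the null."""
    if var_q <= 0:
        raise ValueError("var_q must be positive to standardize")
    return (q - expected_q) / np.sqrt(var_q)


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Center and scale each column to unit sample variance (constants kept at 0)."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return centered / sd


def impute_column_mean(values: np.ndarray, name: str = "") -> np.ndarray:
    """Replace missing entries by their column mean, with a logged warning."""
    values = np.array(values, dtype=float)
    missing = ~np.isfinite(values)
    if missing.any():
        logger.warning(
            "imputing %d missing values by column means in set %r",
            int(missing.sum()),
            name,
        )
        col_mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        idx = np.nonzero(missing)
        values[idx] = col_mean[idx[1]]
    return values


def joint_statistic(
    null: NullModel,
    sets: Sequence[CovariateSet],
    mode: str = "sum",
    weights: Sequence[float] | None = None,
    standardize: bool = False,
    response_id: str = "y",
) -> TestResult:
    """Combined score statistic over one or more covariate sets.

    Modes
    -----
    ``sum``
        ``sum_m w_m Q_m`` — the default; with unit weights it equals the
        single-set statistic on the column-merged matrix.
    ``centered_squared``
        ``sum_m w_m (Q_m - E[Q_m])^2`` — the squared score-vector norm.
    ``standardized_sum``
        ``sum_m w_m T_m`` with ``T_m`` the standardized statistics;
        appropriate when sets differ strongly in size or scale.

    Sets with zero columns are flagged and excluded; sets with no variance
    on the residual space are flagged and contribute only through modes
    where they are well defined.
    """
    if len(sets) == 0:
        raise ValueError("need at least one covariate set")
    if mode not in COMBINE_MODES:
        raise ValueError(f"unknown combine mode {mode!r}; choose from {COMBINE_MODES}")
    if weights is None:
        weights = [s.weight for s in sets]
    if len(weights) != len(sets):
        raise ValueError("one weight per set required")

    components: dict[str, TestComponents] = {}
    set_sizes: dict[str, int] = {}
    flags: list[str] = []
    combined = 0.0
    for xset, w in zip(sets, weights):
        set_sizes[xset.name] = xset.n_probes
        if xset.n_probes == 0:
            flags.append(f"empty_set:{xset.name}")
            continue
        if standardize:
            xset = CovariateSet(
                name=xset.name,
                values=standardize_columns(xset.values),
                probe_ids=xset.probe_ids,
                positions=xset.positions,
                weight=xset.weight,
            )
        q = q_statistic(null, xset)
        expected_q, var_q = moments_q(null, xset)
        if var_q > 0:
            t = standardized_t(q, expected_q, var_q)
        else:
            t = float("nan")
            flags.append(f"zero_variance:{xset.name}")
        components[xset.name] = TestComponents(
            q=q,
            expected_q=expected_q,
            var_q=var_q,
            t=t,
            trace_term=expected_q * null.df_resid,
        )
        if mode == "sum":
            combined += w * q
        elif mode == "centered_squared":
            combined += w * (q - expected_q) ** 2
        else:  # standardized_sum
            combined += w * t if np.isfinite(t) else 0.0
    if not components:
        raise ValueError("all covariate sets are empty")
    return TestResult(
        response_id=response_id,
        components=components,
        combined=float(combined),
        combine_mode=mode,
        set_sizes=set_sizes,
        flags=flags,
    )
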