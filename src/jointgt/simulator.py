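"""Synthetic multi-omics study generator for power and calibration studies.

Emulates the canonical benchmarking design for joint covariate-set tests:
two covariate blocks X and Z (think cis copy number and methylation) with a
controlled correlation structure, plus a block of responses Y in which the
first ``n_associated`` features carry a genuine effect of one of four
region types and the remainder are pure noise.

Correlation between X and Z is introduced in one of two ways:

* **linkage** — ``Z_k = s * X_k + W_k`` with ``X_k ~ N(mean_x, var_x)``,
  ``W_k ~ N(0, var_w)`` independent of X and ``s = +-1``, giving matched-pair
  correlation ``s * sqrt(var_x / (var_x + var_w))`` and zero cross-pair
  correlation;
* **empirical covariance** — both blocks drawn jointly from a multivariate
  normal with a user-supplied covariance matrix (e.g. estimated from real
  tumour data).

The four association-region types ("x only", "additive", "multiplicative",
"split-samples") cover a single-profile effect, two additive profiles, an
interaction on top of the additive effects, and complementary regulation
where each profile drives a different half of the samples.

All matrices are features-in-rows (probes x samples), matching the on-disk
TSV convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LinkedSetConfig",
    "RegionConfig",
    "SimulatedStudy",
    "REGION_TYPES",
    "REGION_LABELS",
    "implied_correlation",
    "simulate_linked_sets",
    "simulate_from_covariance",
    "simulate_region",
    "study_pvalues",
]

REGION_TYPES = ("x_only", "additive", "multiplicative", "complementary")

#: display labels for the four association-region types
REGION_LABELS: Mapping[str, str] = {
    "x_only": "x only",
    "additive": "additive",
    "multiplicative": "multiplicative",
    "complementary": "split-samples",
}


@dataclass
class LinkedSetConfig:
    """Configuration of the linkage design ``Z = s*X + W``.

    Defaults follow the standard benchmarking setup: ``X_j ~ N(1, 2.25)``
    with independent probes, and ``var_w`` tuning the matched-pair
    correlation (1 -> 0.83 "strong", 5 -> 0.56 "weak").
    """

    n_samples: int
    n_probes: int
    mean_x: float = 1.0
    var_x: float = 2.25
    var_w: float = 1.0
    link_sign: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_probes < 1:
            raise ValueError("need at least 2 samples and 1 probe")
        if self.var_x <= 0 or self.var_w <= 0:
            raise ValueError("variances must be positive")
        if self.link_sign not in (1, -1):
            raise ValueError("link_sign must be +1 or -1")


@dataclass
class RegionConfig:
    """One association region: effect type, effect strength, noise level.

    ``n_associated`` leading response probes carry the effect; the rest are
    noise.  Each associated response uses the local mean of covariates in a
    window of half-width ``effect_halfwidth`` around its own index, so the
    signal is spread over a small covariate set rather than a single probe.
    """

    region_type: str
    n_associated: int = 500
    effect_size: float = 0.5
    noise_sd: float = 1.0
    effect_halfwidth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_type not in REGION_TYPES:
            raise ValueError(
                f"unknown region type {self.region_type!r}; choose from {REGION_TYPES}"
            )
        if self.n_associated < 0:
            raise ValueError("n_associated must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_halfwidth < 0:
            raise ValueError("effect_halfwidth must be nonnegative")


@dataclass
class SimulatedStudy:
    """Generated study: Y, X, Z (probes x samples) plus ground truth."""

    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    truth: np.ndarray  # boolean per response probe
    region_type: str
    label: str
    configs: dict = field(default_factory=dict)


def implied_correlation(var_x: float, var_w: float, link_sign: int = 1) -> float:
    """Matched-pair correlation implied by the linkage design.

    ``Cor(X_k, Z_k) = s * sqrt(var_x / (var_x + var_w))`` with ``s = +-1``.
    """
    if var_x <= 0 or var_w <= 0:
        raise ValueError("variances must be positive")
    if link_sign not in (1, -1):
        raise ValueError("link_sign must be +1 or -1")
    return link_sign * float(np.sqrt(var_x / (var_x + var_w)))


def simulate_linked_sets(cfg: LinkedSetConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw linked covariate blocks (probes x samples), reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_probes, cfg.n_samples)
    x = rng.normal(cfg.mean_x, np.sqrt(cfg.var_x), size=shape)
    w = rng.normal(0.0, np.sqrt(cfg.var_w), size=shape)
    z = cfg.link_sign * x + w
    return x, z


def simulate_from_covariance(
    cov: np.ndarray,
    n_x: int,
    n_samples: int,
    seed: int = 0,
    method: str = "cholesky",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, Z) blocks jointly from a zero-mean multivariate normal.

    ``cov`` covers the stacked (X-block, Z-block) variables; the first
    ``n_x`` rows/columns belong to X.  ``method`` selects the matrix square
    root ('cholesky' with an eigen fallback for singular PSD inputs, or
    'eigen'); both produce the same distribution.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    p = cov.shape[0]
    if not 0 < n_x < p:
        raise ValueError("n_x must split the covariance into two nonempty blocks")
    eigvals = np.linalg.eigvalsh(cov)
    top = max(eigvals[-1], 0.0)
    if eigvals[0] < -1e-8 * max(top, 1.0):
        raise ValueError(
            f"covariance is not positive semidefinite (smallest eigenvalue {eigvals[0]:.3e})"
        )
    if method not in ("cholesky", "eigen"):
        raise ValueError("method must be 'cholesky' or 'eigen'")
    root = None
    if method == "cholesky":
        try:
            root = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            root = None
    if root is None:
        w, v = np.linalg.eigh(cov)
        root = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_samples, p))
    samples = g @ root.T  # (n_samples, p)
    x = samples[:, :n_x].T
    z = samples[:, n_x:].T
    return x, z


def _window_means(m: np.ndarray, halfwidth: int) -> np.ndarray:
    """Per-row mean of rows in [i-h, i+h] clipped to valid range."""
    n = m.shape[0]
    cum = np.vstack([np.zeros((1, m.shape[1])), np.cumsum(m, axis=0)])
    idx = np.arange(n)
    lo = np.clip(idx - halfwidth, 0, n)
    hi = np.clip(idx + halfwidth + 1, 0, n)
    sums = cum[hi] - cum[lo]
    counts = (hi - lo).astype(float)[:, None]
    return sums / counts


def simulate_region(
    x: np.ndarray, z: np.ndarray, cfg: RegionConfig
) -> SimulatedStudy:
    """Generate responses under one association-region type.

    For associated probe ``i`` with local covariate means ``xw_i``, ``zw_i``
    and effect size ``b``:

    * x only:          ``Y_i = b*xw_i + eps``
    * additive:        ``Y_i = b*xw_i + b*zw_i + eps``
    * multiplicative:  ``Y_i = b*xw_i + b*zw_i + b*(xw_i*zw_i) + eps``
    * split-samples:   ``Y_i = b*xw_i + eps`` for the first half of the
      samples and ``b*zw_i + eps`` for the rest.

    Non-associated probes are pure noise ``N(0, noise_sd^2)``.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("X and Z must have identical shapes")
    n_probes, n_samples = x.shape
    if cfg.n_associated > n_probes:
        raise ValueError("n_associated exceeds number of probes")

    rng = np.random.default_rng(cfg.seed)
    b = cfg.effect_size
    y = rng.normal(0.0, cfg.noise_sd, size=(n_probes, n_samples))
    k = cfg.n_associated
    if k > 0 and b != 0.0:
        xw = _window_means(x, cfg.effect_halfwidth)[:k]
        zw = _window_means(z, cfg.effect_halfwidth)[:k]
        if cfg.region_type == "x_only":
            signal = b * xw
        elif cfg.region_type == "additive":
            signal = b * xw + b * zw
        elif cfg.region_type == "multiplicative":
            signal = b * xw + b * zw + b * (xw * zw)
        else:  # complementary / split-samples
            half = -(-n_samples // 2)  # ceil
            signal = np.empty_like(xw)
            signal[:, :half] = b * xw[:, :half]
            signal[:, half:] = b * zw[:, half:]
        y[:k] += signal

    truth = np.zeros(n_probes, dtype=bool)
    truth[:k] = True
    return SimulatedStudy(
        Y=y,
        X=x,
        Z=z,
        truth=truth,
        region_type=cfg.region_type,
        label=REGION_LABELS[cfg.region_type],
        configs={"region": cfg},
    )


def study_pvalues(
    study: SimulatedStudy,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "sum",
) -> "pd.DataFrame":
    """Permutation p-values for every response of a simulated study.

    Each response is tested against the full X and Z blocks (the study-wide
    covariate sets), individually and jointly, exactly as in a power
    evaluation: the returned frame has columns ``p_x``, ``p_z``, ``p_joint``
    and ``truth``.  The permutation stream is keyed per response by ``seed``.
    """
    import pandas as pd

    from .core_test import CovariateSet, ResponseVector, fit_null
    from .null_dist import PermutationPlan, run_joint_test

    sx = CovariateSet("x", study.X.T)
    sz = CovariateSet("z", study.Z.T)
    rows = []
    for i in range(study.Y.shape[0]):
        null = fit_null(ResponseVector(study.Y[i], response_id=f"y{i}"))
        plan = PermutationPlan(
            n_perm=n_perm, seed=(seed * 1_000_003 + i) % (2**31)
        )
        res = run_joint_test(null, [sx, sz], mode=mode, plan=plan)
        rows.append(
            {
                "response_id": f"y{i}",
                "p_x": res.p_per_set["x"],
                "p_z": res.p_per_set["z"],
                "p_joint": res.p_joint,
                "truth": bool(study.truth[i]),
            }
        )
    return pd.DataFrame(rows)
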