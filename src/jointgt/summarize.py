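"""Selection, overlap/dilution ratios, per-arm aggregation and ROC evaluation.

After a genome-wide screen each response probe carries a p-value for each
individual test (one per covariate set) and for the joint test.  At a
threshold ``alpha`` (inclusive, raw p-values by default):

* **overlap** — of the probes selected by the joint test, the fraction also
  selected by a given individual test;
* **new discoveries** — its complement on the same denominator: joint-test
  selections the individual test missed;
* **dilution** — of the probes selected by an individual test, the fraction
  the joint test misses (an individual effect too weak or too narrow to
  drive the combined statistic).

Ratios with an empty denominator are reported as missing (NaN), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RatioResult",
    "select",
    "ratios",
    "roc",
    "fdr_adjust",
    "selection_table",
    "ratio_report",
]


@dataclass(frozen=True)
class RatioResult:
    """Overlap/new-discovery/dilution ratios with their backing counts."""

    overlap: float
    new_disc: float
    dilution: float
    n_joint: int
    n_individual: int
    n_both: int

    @property
    def n_individual_not_joint(self) -> int:
        return self.n_individual - self.n_both


def select(p: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean selection at threshold ``alpha`` (closed comparison p <= alpha)."""
    p = np.asarray(p, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return p <= alpha


def ratios(sel_joint: np.ndarray, sel_a: np.ndarray) -> RatioResult:
    """Overlap, new-discovery and dilution ratios of one individual test
    against the joint test.

    overlap  = |joint & a| / |joint|;   new_disc = 1 - overlap;
    dilution = |a & ~joint| / |a|.  Empty denominators yield NaN.
    """
    sel_joint = np.asarray(sel_joint, dtype=bool)
    sel_a = np.asarray(sel_a, dtype=bool)
    if sel_joint.shape != sel_a.shape:
        raise ValueError("selection vectors must have equal length")
    n_joint = int(sel_joint.sum())
    n_a = int(sel_a.sum())
    n_both = int((sel_joint & sel_a).sum())
    if n_joint > 0:
        overlap = n_both / n_joint
        new_disc = 1.0 - overlap
    else:
        overlap = new_disc = float("nan")
    dilution = (n_a - n_both) / n_a if n_a > 0 else float("nan")
    return RatioResult(
        overlap=overlap,
        new_disc=new_disc,
        dilution=dilution,
        n_joint=n_joint,
        n_individual=n_a,
        n_both=n_both,
    )


def roc(p: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC of a p-value vector against ground truth.

    Smaller p-values rank as more positive; thresholds sweep the unique
    p-values with ties grouped, and the trapezoidal AUC equals the
    Mann-Whitney U statistic scaled by ``n1*n0`` with ties counted 1/2.

    Returns ``(fpr, tpr, auc)``.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if p.shape != truth.shape:
        raise ValueError("p and truth must have equal length")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain at least one positive and one negative")
    fpr, tpr, _ = _skm.roc_curve(truth, -p)
    return fpr, tpr, float(_skm.auc(fpr, tpr))


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def selection_table(
    results: pd.DataFrame,
    alpha: float = 0.001,
    p_columns: tuple[str, str, str] = ("p_cn", "p_me", "p_joint"),
) -> pd.DataFrame:
    """Add boolean selection columns at ``alpha`` to a per-probe results table.

    ``results`` must have a ``response_id`` column and the three p-value
    columns; an optional ``arm`` column is carried through.  Probes with a
    missing p-value (e.g. an empty covariate set) are never selected for
    that test.
    """
    table = results.copy()
    for col in p_columns:
        if col not in table.columns:
            raise ValueError(f"missing p-value column {col!r}")
        sel = np.zeros(len(table), dtype=bool)
        ok = table[col].notna().to_numpy()
        if ok.any():
            sel[ok] = select(table.loc[ok, col].to_numpy(), alpha)
        table["sel" + col.removeprefix("p")] = sel
    table.attrs["alpha"] = alpha
    return table


def _ratio_row(sub: pd.DataFrame) -> dict:
    r_cn = ratios(sub["sel_joint"].to_numpy(), sub["sel_cn"].to_numpy())
    r_me = ratios(sub["sel_joint"].to_numpy(), sub["sel_me"].to_numpy())
    joint_only = int(
        (sub["sel_joint"] & ~sub["sel_cn"] & ~sub["sel_me"]).sum()
    )
    return {
        "n_tests": len(sub),
        "n_sel_cn": r_cn.n_individual,
        "n_sel_me": r_me.n_individual,
        "n_sel_joint": r_cn.n_joint,
        "overlap_cn_joint": r_cn.overlap,
        "overlap_me_joint": r_me.overlap,
        "new_disc_vs_cn": r_cn.new_disc,
        "new_disc_vs_me": r_me.new_disc,
        "dilution_cn": r_cn.dilution,
        "dilution_me": r_me.dilution,
        "n_joint_only": joint_only,
    }


def ratio_report(table: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide and per-arm overlap/new-discovery/dilution report.

    ``table`` is a selection table (see :func:`selection_table`).  The first
    row aggregates all probes; one extra row per chromosome arm follows when
    an ``arm`` column is present.
    """
    rows = [{"arm": "genome", **_ratio_row(table)}]
    if "arm" in table.columns and table["arm"].notna().any():
        for arm, sub in table.groupby("arm", dropna=True, observed=True):
            rows.append({"arm": arm, **_ratio_row(sub)})
    return pd.DataFrame(rows)
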