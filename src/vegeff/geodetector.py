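"""Geodetector: factor, interaction and risk detection over stratified units.

The factor detector measures how much a categorical stratification of the
study units explains the spatial variance of a response y (here: county
restoration effectiveness) through the q statistic

    q = 1 - sum_h N_h sigma_h^2 / (N sigma^2)

with population variances, so q is exactly the between-strata share of the
total sum of squares and lies in [0, 1].

Significance: under the null of no stratified effect, the monotone transform
F = (N-L)/(L-1) * q/(1-q) is the one-way ANOVA F statistic and follows a
central F(L-1, N-L) distribution; the default p-value comes from it.
(The noncentral variant that plugs the sample stratum means into the
noncentrality parameter — as some distributed Geodetector implementations
do — is available via ``method="noncentral"``; it is strongly conservative
and location-dependent, so it is not the default.)
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConstantResponseError, FactorPartition, VegeffError

__all__ = [
    "FactorDetection",
    "InteractionDetection",
    "RiskDetection",
    "factor_q",
    "q_significance",
    "select_main_factors",
    "interaction_q",
    "risk_detect",
]

INTERACTION_TYPES = (
    "weaken-nonlinear",
    "weaken-single",
    "enhance-bivariate",
    "enhance-nonlinear",
    "independent",
)

_TOL = 1e-9


@dataclass
class FactorDetection:
    """q of one factor with its stratum decomposition."""

    factor_name: str
    q: float
    p: float = float("nan")
    n_total: int = 0
    sigma2: float = float("nan")
    strata: pd.DataFrame = field(default_factory=pd.DataFrame)  # N_h, mean, sigma2_h


@dataclass
class InteractionDetection:
    pair: tuple[str, str]
    q_a: float
    q_b: float
    q_ab: float
    type: str


@dataclass
class RiskDetection:
    factor_name: str
    strata: pd.DataFrame  # stratum, N_h, mean, value_lo, value_hi
    significance: pd.DataFrame  # pairwise p-value matrix (NaN for untested)
    argmax_stratum: int
    optimal_range: tuple[float, float]
    optimal_strata: list[int] = field(default_factory=list)


def _align(y, strata) -> tuple[np.ndarray, np.ndarray]:
    y = pd.Series(y, dtype=float)
    strata = pd.Series(strata)
    if not y.index.equals(strata.index):
        strata = strata.reindex(y.index)
        if strata.isna().any():
            raise VegeffError("every unit needs exactly one stratum label")
    return y.to_numpy(), strata.to_numpy()


def factor_q(y: pd.Series, partition: FactorPartition | pd.Series) -> FactorDetection:
    """Variance-decomposition q of a stratification, with central-F p-value.

    Empty strata are dropped (with a relabeling warning if any disappears);
    singleton strata contribute zero within-stratum variance. Requires at
    least two nonempty strata and a nonconstant response.
    """
    name = partition.factor_name if isinstance(partition, FactorPartition) else "factor"
    strata = partition.strata if isinstance(partition, FactorPartition) else partition
    yv, h = _align(y, strata)
    n = len(yv)
    labels, inv = np.unique(h, return_inverse=True)
    if labels.max() > len(labels):  # gaps: some labels in 1..L never occur
        warnings.warn(f"{name}: empty strata dropped and relabeled", stacklevel=2)
    ell = len(labels)
    if ell < 2:
        raise ConstantResponseError(f"{name}: fewer than two nonempty strata")
    sigma2 = float(yv.var())  # population variance
    if sigma2 <= 0:
        raise ConstantResponseError(f"{name}: response variance is zero")
    n_h = np.bincount(inv, minlength=ell).astype(float)
    sums = np.bincount(inv, weights=yv, minlength=ell)
    sums2 = np.bincount(inv, weights=yv**2, minlength=ell)
    means = sums / n_h
    var_h = np.maximum(sums2 / n_h - means**2, 0.0)
    ssw = float((n_h * var_h).sum())
    q = 1.0 - ssw / (n * sigma2)
    q = min(max(q, 0.0), 1.0)
    table = pd.DataFrame(
        {"stratum": labels, "N_h": n_h.astype(int), "mean": means, "sigma2_h": var_h}
    )
    det = FactorDetection(name, q, n_total=n, sigma2=sigma2, strata=table)
    if n > ell:
        det.p = q_significance(det)  # left NaN when N <= L (test undefined)
    return det


def q_significance(detection: FactorDetection, method: str = "central") -> float:
    """p-value of q via F = (N-L)/(L-1) * q/(1-q) with df (L-1, N-L).

    ``method="central"`` tests the null of no stratified effect (exact ANOVA
    F). ``method="noncentral"`` reproduces the transformation used by common
    Geodetector software, with the noncentrality estimated from the sample
    stratum means.
    """
    n, ell = detection.n_total, len(detection.strata)
    if n <= ell:
        raise VegeffError(f"q test undefined: N={n} <= L={ell}")
    q = detection.q
    if q >= 1.0:
        return 0.0
    f = (n - ell) / (ell - 1) * q / (1.0 - q)
    if method == "central":
        return float(stats.f.sf(f, ell - 1, n - ell))
    if method == "noncentral":
        n_h = detection.strata["N_h"].to_numpy(dtype=float)
        means = detection.strata["mean"].to_numpy()
        lam = (
            (means**2 * n_h).sum() - (np.sqrt(n_h) * means).sum() ** 2 / n
        ) / detection.sigma2
        return float(stats.ncf.sf(f, ell - 1, n - ell, max(lam, 0.0)))
    raise VegeffError("method must be 'central' or 'noncentral'")


def select_main_factors(
    detections: list[FactorDetection], top_fraction: float = 0.5, alpha: float = 0.05
) -> list[FactorDetection]:
    """Factors ranked in the top fraction by q that also pass significance.

    The default keeps q ranks 1..ceil(n/2) with p < 0.05, ordered by
    descending q.
    """
    if not detections:
        raise VegeffError("no detections to select from")
    ranked = sorted(detections, key=lambda d: -d.q)
    keep = int(np.ceil(len(ranked) * top_fraction))
    return [d for d in ranked[:keep] if d.p < alpha]


def interaction_q(
    y: pd.Series, part_a: FactorPartition, part_b: FactorPartition
) -> InteractionDetection:
    """q of the cross-classification of two factors, with its synergy type.

    The interaction stratum of a unit is its ordered pair of single-factor
    strata (empty combinations simply never occur as labels). Types follow the
    standard comparison of q_AB against q_A, q_B and their sum, with an
    equality tolerance of 1e-9 for independence.
    """
    if not part_a.strata.index.equals(part_b.strata.index):
        raise VegeffError("interaction partitions must cover the same units")
    q_a = factor_q(y, part_a).q
    q_b = factor_q(y, part_b).q
    ha = part_a.strata.to_numpy()
    hb = part_b.strata.to_numpy()
    combined = ha.astype(np.int64) * (hb.max() + 1) + hb
    cross = pd.Series(
        np.unique(combined, return_inverse=True)[1] + 1, index=part_a.strata.index
    )
    q_ab = factor_q(y, cross).q
    lo, hi = min(q_a, q_b), max(q_a, q_b)
    if abs(q_ab - (q_a + q_b)) <= _TOL:
        kind = "independent"
    elif q_ab > q_a + q_b:
        kind = "enhance-nonlinear"
    elif q_ab > hi + _TOL:
        kind = "enhance-bivariate"
    elif q_ab >= lo - _TOL:
        kind = "weaken-single"
    else:
        kind = "weaken-nonlinear"
    return InteractionDetection((part_a.factor_name, part_b.factor_name), q_a, q_b, q_ab, kind)


def risk_detect(
    y: pd.Series, partition: FactorPartition, alpha: float = 0.05
) -> RiskDetection:
    """Per-stratum mean response with pairwise Welch t-tests.

    Strata of size one are flagged and excluded from the tests. The reported
    optimal range spans the stratum with the highest mean response together
    with any adjacent strata not significantly different from it (mirroring
    ranges that behave alike being read as one favorable interval).
    """
    yv, h = _align(y, partition.strata)
    vals = partition.values.to_numpy()
    labels = np.unique(h)
    rows = []
    for lab in labels:
        sel = h == lab
        rows.append(
            {
                "stratum": int(lab),
                "N_h": int(sel.sum()),
                "mean": float(yv[sel].mean()),
                "value_lo": float(vals[sel].min()),
                "value_hi": float(vals[sel].max()),
            }
        )
    table = pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)
    testable = [int(r.stratum) for r in table.itertuples() if r.N_h >= 2]
    skipped = [int(r.stratum) for r in table.itertuples() if r.N_h < 2]
    if skipped:
        warnings.warn(f"strata of size 1 excluded from t-tests: {skipped}", stacklevel=2)
    pmat = pd.DataFrame(np.nan, index=table["stratum"], columns=table["stratum"])
    for a, b in itertools.combinations(testable, 2):
        res = stats.ttest_ind(yv[h == a], yv[h == b], equal_var=False)
        pmat.loc[a, b] = pmat.loc[b, a] = float(res.pvalue)
    top = int(table.loc[table["mean"].idxmax(), "stratum"])
    # Merge adjacent statistically indistinguishable strata into the range.
    merged = {top}
    order = sorted(table["stratum"])
    pos = order.index(top)
    for direction in (-1, 1):
        i = pos + direction
        while 0 <= i < len(order):
            lab = order[i]
            p = pmat.loc[top, lab]
            if np.isnan(p) or p < alpha:
                break
            merged.add(lab)
            i += direction
    sub = table[table["stratum"].isin(merged)]
    rng = (float(sub["value_lo"].min()), float(sub["value_hi"].max()))
    return RiskDetection(
        partition.factor_name, table, pmat, top, rng, sorted(int(s) for s in merged)
    )
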