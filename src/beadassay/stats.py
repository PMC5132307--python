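"""Group statistics for the dauer-recovery bioassay.

The experimental unit is the image (4-13 images per condition, up to ~100
worms each). Raw per-image activities are normalized to the positive control
— the mean activity of bacterial extract (BE) in solvent, defined as 100%;
when BE was assayed in several solvents, the solvent in which it showed the
maximum effect defines the control. Conditions are compared pairwise with
the two-sided Mann-Whitney U test, family-wise error is controlled with the
Bonferroni-Holm step-down procedure, and dose-response data are fitted by
linear least squares to a third-order orthogonal polynomial with pointwise
95% confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantification import ActivityMeasurement

__all__ = [
    "AssayGroup",
    "MannWhitneyResult",
    "ComparisonResult",
    "DoseResponseFit",
    "normalize",
    "mann_whitney",
    "holm_adjust",
    "significance_tier",
    "compare_groups",
    "fit_dose_response",
]

# Significance tiers used on the assay figures.
TIER_THRESHOLDS = ((1e-5, "***"), (1e-4, "**"), (1e-3, "*"))

# Exact Mann-Whitney null enumeration is used when both samples are small
# enough (and tie-free); larger designs use the tie- and
# continuity-corrected normal approximation.
EXACT_MAX_N = 12


@dataclass(frozen=True)
class AssayGroup:
    """One condition (compound + concentration + solvent) with its per-image
    measurements and, after normalization, activity percentages."""

    condition: str
    solvent: str
    measurements: tuple[ActivityMeasurement, ...]
    normalized_pct: tuple[float, ...] = ()

    def ratios(self) -> np.ndarray:
        """Raw per-image ratios of the valid measurements."""
        return np.array([m.ratio for m in self.measurements if m.valid], dtype=float)

    def mean_ratio(self) -> float:
        r = self.ratios()
        if r.size == 0:
            raise ValueError(f"group {self.condition!r} has no valid measurements")
        return float(r.mean())


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_raw: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise test: group vs reference, with the Holm family decision
    and the figure-style significance tier."""

    pair: tuple[str, str]
    U: float
    p_raw: float
    holm_reject: bool
    tier: str
    method: str = ""


@dataclass(frozen=True)
class DoseResponseFit:
    """Least-squares polynomial dose-response fit in an orthogonal basis.

    ``basis`` holds the orthonormal polynomial design matrix evaluated on
    the design points; ``coefficients`` are the corresponding basis weights.
    The confidence band is pointwise at 95%, from the t distribution with
    ``residual_df`` degrees of freedom.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    order: int
    basis: np.ndarray
    coefficients: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    residual_df: int
    residual_variance: float


def _control_group(groups: Sequence[AssayGroup], control_condition: str) -> AssayGroup:
    candidates = [g for g in groups if g.condition == control_condition]
    if not candidates:
        raise ValueError(f"control condition {control_condition!r} not present")
    # Maximum-effect rule: with several solvents, the control is the solvent
    # in which the positive control showed the highest mean activity.
    return max(candidates, key=lambda g: g.mean_ratio())


def normalize(
    groups: Sequence[AssayGroup], control_condition: str
) -> list[AssayGroup]:
    """Express every measurement as a percentage of the positive control.

    pct = 100 x ratio / mean(control ratios); the control group's own
    normalized mean is exactly 100 by construction. Rescaling every raw
    ratio by a common factor (a global gain change) leaves all percentages
    unchanged.
    """
    control = _control_group(groups, control_condition)
    control_mean = control.mean_ratio()
    if control_mean == 0:
        raise ValueError("control group mean activity is zero; normalization undefined")
    out = []
    for g in groups:
        pct = tuple(100.0 * r / control_mean for r in g.ratios())
        out.append(replace(g, normalized_pct=pct))
    return out


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The exact null distribution (full enumeration over labelings) is used
    when both samples have at most 12 observations and there are no ties;
    otherwise the normal approximation with midranks, tie-corrected variance
    and continuity correction is used. The method actually applied is
    recorded on the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


def holm_adjust(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Bonferroni-Holm step-down rejection decisions, in original order.

    Sort ascending; reject the k-th smallest while p(k) <= alpha/(m-k+1);
    stop at the first failure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return [bool(r) for r in reject]


def significance_tier(p_raw: float, holm_reject: bool) -> str:
    """Figure-style tier label for a comparison.

    "*", "**", "***" mark p <= 1e-3, 1e-4, 1e-5; "(*)" marks a test that is
    significant after Holm correction without reaching any tier threshold;
    "ns" otherwise.
    """
    for threshold, label in TIER_THRESHOLDS:
        if p_raw <= threshold:
            return label
    return "(*)" if holm_reject else "ns"


def compare_groups(
    groups: Sequence[AssayGroup],
    reference_condition: str,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """All pairwise Mann-Whitney tests against the reference (negative
    control), Holm-corrected as one family."""
    reference = next(
        (g for g in groups if g.condition == reference_condition), None
    )
    if reference is None:
        raise ValueError(f"reference condition {reference_condition!r} not present")
    if not reference.normalized_pct:
        raise ValueError("groups must be normalized before comparison")
    others = [g for g in groups if g is not reference]
    tests = [mann_whitney(g.normalized_pct, reference.normalized_pct) for g in others]
    rejects = holm_adjust([t.p_raw for t in tests], alpha=alpha)
    return [
        ComparisonResult(
            pair=(g.condition, reference.condition),
            U=t.U,
            p_raw=t.p_raw,
            holm_reject=rej,
            tier=significance_tier(t.p_raw, rej),
            method=t.method,
        )
        for g, t, rej in zip(others, tests, rejects)
    ]


def _orthonormal_basis(x: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal polynomial basis on the design points via QR of the
    Vandermonde matrix (discrete Gram-Schmidt)."""
    powers = np.vander(x, order + 1, increasing=True)
    q, r = np.linalg.qr(powers)
    if np.linalg.matrix_rank(r) < order + 1:
        raise ValueError("rank-deficient design")
    # Fix signs so the basis is deterministic (leading coefficient positive).
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


def fit_dose_response(
    concentrations: Sequence[float],
    responses: Sequence[float],
    order: int = 3,
    conf_level: float = 0.95,
) -> DoseResponseFit:
    """Least-squares polynomial fit of activity (%) against dose (mM).

    The basis is built by discrete Gram-Schmidt on the actual concentration
    design points, so its columns are exactly orthogonal there; the fitted
    values coincide with an ordinary raw-power polynomial fit of the same
    order. The 95% confidence band is pointwise: fitted +/- t * se(fit),
    with se from the hat-matrix leverage and the residual variance.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D and equal length")
    n_distinct = np.unique(x).size
    if n_distinct < order + 1:
        raise ValueError(
            f"need >= {order + 1} distinct concentrations, got {n_distinct}"
        )
    if x.size < order + 2:
        raise ValueError(f"need >= {order + 2} points, got {x.size}")
    basis = _orthonormal_basis(x, order)
    coefficients = basis.T @ y
    fitted = basis @ coefficients
    residual_df = x.size - (order + 1)
    rss = float(((y - fitted) ** 2).sum())
    sigma2 = rss / residual_df
    leverage = (basis**2).sum(axis=1)  # diag of the hat matrix Q Q^T
    se_fit = np.sqrt(sigma2 * leverage)
    t_crit = sps.t.ppf(0.5 + conf_level / 2.0, residual_df)
    return DoseResponseFit(
        concentrations=x,
        responses=y,
        order=order,
        basis=basis,
        coefficients=coefficients,
        fitted=fitted,
        band_lower=fitted - t_crit * se_fit,
        band_upper=fitted + t_crit * se_fit,
        residual_df=residual_df,
        residual_variance=sigma2,
    )
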