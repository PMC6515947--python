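"""ELISA calibration, cutoffs, positivity, and correlation analyses.

Covers the serological side of IgA anti-β2GP1 testing: converting raw
optical densities to units through kit calibrators, deriving 99th-percentile
cutoffs from a healthy reference population, strict greater-than positivity
classification, Pearson correlation with Fisher-z confidence intervals, a
two-regime correlation split (a subgroup whose anti-domain level tracks the
whole-molecule level linearly, and a low-level subgroup with no
association), and generic group comparisons (χ²/Fisher exact,
Mann-Whitney).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConstantInput,
    DegenerateTable,
    MissingAssay,
    NoFeasibleSplit,
    TooFewReference,
    UncalibratedAssay,
)

#: Default positivity cutoffs in units: whole-molecule IgA anti-β2GP1 at 20 U
#: (99th percentile of a healthy population), anti-domain-1 IgA at 23.8 U,
#: anti-domain-4/5 IgA at 22 U, and 18 U for the IgG/IgM assays.
DEFAULT_CUTOFFS: Mapping[str, float] = {
    "anti_b2gp1_iga": 20.0,
    "anti_d1_iga": 23.8,
    "anti_d45_iga": 22.0,
    "anti_b2gp1_igg": 18.0,
    "anti_b2gp1_igm": 18.0,
    "acl_igg": 18.0,
    "acl_igm": 18.0,
}

#: Hinkle's rule-of-thumb labels for |r|.
_HINKLE = [
    (0.9, "very high"),
    (0.7, "high"),
    (0.5, "moderate"),
    (0.3, "low"),
    (0.0, "negligible"),
]


@dataclass(frozen=True)
class Calibration:
    """Linear OD -> units calibration through >= 2 kit calibrator points."""

    points: tuple[tuple[float, float], ...]  # (OD, assigned units)
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise UncalibratedAssay("need >= 2 calibrator points")
        ods = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(sorted(ods), sorted(ods)[1:])):
            raise UncalibratedAssay("calibrator ODs must be distinct")
        slope, intercept = np.polyfit(ods, [p[1] for p in self.points], 1)
        object.__setattr__(self, "slope", float(slope))
        object.__setattr__(self, "intercept", float(intercept))


@dataclass(frozen=True)
class CutoffSet:
    cutoffs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cutoffs.values()):
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    label: str = ""


@dataclass(frozen=True)
class SplitResult:
    """Two-regime partition of a correlation cloud at a horizontal boundary."""

    boundary: float  # sera with y <= boundary go to group B
    group_b: np.ndarray  # boolean mask, True = low-y group
    corr_a: CorrelationResult
    corr_b: CorrelationResult
    informative: bool

    @property
    def separation(self) -> float:
        return abs(self.corr_a.r - self.corr_b.r)


def od_to_units(od: float | np.ndarray, cal: Calibration) -> float | np.ndarray:
    """Convert OD to units by the fitted line, clamped at 0 below blank."""
    units = cal.slope * np.asarray(od, dtype=float) + cal.intercept
    units = np.maximum(units, 0.0)
    return float(units) if np.isscalar(od) else units


def percentile_cutoff(values: Sequence[float], q: float = 0.99) -> float:
    """Empirical quantile of a healthy reference population.

    Linear interpolation between order statistics (numpy's default rule).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 20:
        raise TooFewReference(f"need >= 20 reference values, got {arr.size}")
    return float(np.quantile(arr, q))


def classify_positivity(
    panel: pd.DataFrame, cutoffs: CutoffSet = CutoffSet()
) -> pd.DataFrame:
    """Per-serum binary positivity per assay: positive iff value > cutoff.

    ``panel`` columns are assay names (a subset of the cutoff keys); the
    comparison is strictly greater-than, so a value exactly at the cutoff is
    negative.
    """
    out = {}
    for assay in panel.columns:
        if assay in ("group",):
            continue
        if assay not in cutoffs.cutoffs:
            raise MissingAssay(f"no cutoff defined for assay '{assay}'")
        out[assay] = panel[assay] > cutoffs.cutoffs[assay]
    if not out:
        raise MissingAssay("panel contains no assay columns")
    return pd.DataFrame(out, index=panel.index)


def hinkle_label(r: float) -> str:
    a = abs(r)
    for lo, name in _HINKLE:
        if a >= lo:
            return name
    return "negligible"


def pearson_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Pearson r with two-sided p and a Fisher-z confidence interval.

    CI: tanh(atanh(r) ± z_{1-α/2} / sqrt(n-3)); the Hinkle rule-of-thumb
    label for the magnitude of r is attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ConstantInput("need paired vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInput("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(x.size - 3)
    return CorrelationResult(
        r=float(r),
        ci_low=math.tanh(z - half),
        ci_high=math.tanh(z + half),
        p_value=float(p),
        n=int(x.size),
        label=hinkle_label(float(r)),
    )


def split_correlation(
    x: Sequence[float],
    y: Sequence[float],
    min_frac: float = 0.15,
    margin: float = 0.3,
) -> SplitResult:
    """Search for a two-regime split of an (x, y) correlation cloud.

    A deterministic grid search over horizontal boundaries ``y = c`` with
    candidates at the observed y values: sera with ``y <= c`` form the low
    group B, the rest group A. Each candidate boundary is scored by the
    profile log-likelihood of the two-regime model — group A as a Gaussian
    linear regression of y on x, group B as a flat Gaussian band independent
    of x — and the highest-likelihood boundary wins (ties break to the
    lowest boundary). A naive maximization of ``|r_A - r_B|`` is degenerate:
    the sample correlation of the smallest admissible group is the noisiest,
    so that objective chases sampling extremes rather than the regime
    boundary; the likelihood objective weighs group sizes and the flat
    band's small variance correctly. Both groups must keep at least
    ``min_frac * n`` sera. The split is flagged non-informative when
    ``|r_A - r_B|`` at the selected boundary is below ``margin`` — a
    homogeneous cloud has no second regime. This is a heuristic
    operationalization of a visually drawn partition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 20 or y.size != n:
        raise NoFeasibleSplit("need paired vectors with n >= 20")
    min_size = max(int(math.ceil(min_frac * n)), 4)
    best: tuple[float, float, np.ndarray] | None = None  # (loglik, boundary, mask)
    for c in np.unique(y):
        mask_b = y <= c
        nb = int(mask_b.sum())
        na = n - nb
        if nb < min_size or na < min_size:
            continue
        xa, ya = x[~mask_b], y[~mask_b]
        if (
            np.ptp(xa) == 0
            or np.ptp(x[mask_b]) == 0
            or np.ptp(ya) == 0
            or np.ptp(y[mask_b]) == 0
        ):
            continue
        beta = np.polyfit(xa, ya, 1)
        var_a = max(float(np.mean((ya - np.polyval(beta, xa)) ** 2)), 1e-12)
        var_b = max(float(np.var(y[mask_b])), 1e-12)
        loglik = -0.5 * na * (math.log(var_a) + 1) - 0.5 * nb * (math.log(var_b) + 1)
        if best is None or loglik > best[0]:
            best = (loglik, float(c), mask_b)
    if best is None:
        raise NoFeasibleSplit(
            f"no boundary leaves both groups with >= {min_size} of {n} sera"
        )
    _, boundary, mask_b = best
    corr_a = pearson_ci(x[~mask_b], y[~mask_b])
    corr_b = pearson_ci(x[mask_b], y[mask_b])
    return SplitResult(
        boundary=boundary,
        group_b=mask_b,
        corr_a=corr_a,
        corr_b=corr_b,
        informative=abs(corr_a.r - corr_b.r) >= margin,
    )


def group_compare(
    data: np.ndarray | tuple[Sequence[float], Sequence[float]],
    kind: str = "auto",
) -> tuple[str, float, float]:
    """Generic two-group comparison: (test name, statistic, p).

    A 2x2 (or r x c) integer table gets Pearson's χ² without continuity
    correction, replaced by Fisher's exact test when any expected count is
    below 5 (2x2 only). A pair of samples gets the two-sided Mann-Whitney U.
    ``kind`` can force "chi2", "fisher", or "mannwhitney".
    """
    if isinstance(data, tuple) and len(data) == 2 and kind in ("auto", "mannwhitney"):
        a = np.asarray(data[0], dtype=float)
        b = np.asarray(data[1], dtype=float)
        if a.size == 0 or b.size == 0:
            raise DegenerateTable("empty sample")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ("mannwhitney", float(res.statistic), float(res.pvalue))
    table = np.asarray(data)
    if table.ndim != 2 or table.min() < 0:
        raise DegenerateTable("need a non-negative 2-D contingency table")
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTable("table has an empty margin")
    expected = stats.contingency.expected_freq(table)
    use_fisher = kind == "fisher" or (
        kind == "auto" and table.shape == (2, 2) and (expected < 5).any()
    )
    if use_fisher:
        if table.shape != (2, 2):
            raise DegenerateTable("Fisher exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return ("fisher", float(odds), float(p))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ("chi2", float(chi2), float(p))
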