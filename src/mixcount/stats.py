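"""Plate-count back-calculation and method-comparison statistics.

Covers the full comparison layer used to validate image-cytometry counts
against colony plating: CFU/mL back-calculation from serial dilutions,
selection of the countable dilution level, base-10 log conversion, the
per-trial manual-vs-cytometry difference tables, symmetric percent
difference, titration linearity regression, Welch's t-test, and the
one-way method-factor ANOVA on per-trial means.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "PlateCount",
    "MethodComparison",
    "AnovaResult",
    "RegressionResult",
    "cfu_per_ml",
    "select_countable",
    "log10_concentration",
    "method_difference",
    "difference_from_means",
    "check_table_row",
    "percent_difference",
    "titration_regression",
    "two_sample_t",
    "method_anova",
    "DEFAULT_COUNTABLE_RANGES",
]

# Countable colony ranges per medium class.  These are artifact conventions
# (configurable), not published values.
DEFAULT_COUNTABLE_RANGES = {
    "bacteria": (25, 250),
    "yeast": (8, 80),
}


@dataclass(frozen=True)
class PlateCount:
    """One spread plate from a serial-dilution series.

    ``dilution_exponent`` is the (non-positive) base-10 exponent of the
    dilution factor actually plated, e.g. -5 for a 10^-5 dilution.
    """

    sample_id: str
    dilution_exponent: int
    plated_volume_ml: float
    colonies: int
    medium: str = ""

    def __post_init__(self) -> None:
        if self.dilution_exponent > 0:
            raise ValueError(
                "dilution_exponent must be <= 0 (dilutions only), got "
                f"{self.dilution_exponent}"
            )
        if not self.plated_volume_ml > 0:
            raise ValueError(
                f"plated_volume_ml must be > 0, got {self.plated_volume_ml}"
            )
        if self.colonies < 0:
            raise ValueError(f"colonies must be >= 0, got {self.colonies}")


@dataclass
class MethodComparison:
    """Paired log-scale results of the two counting methods for one trial.

    The difference is always recomputed from the means, never trusted from
    input.
    """

    experiment: str
    trial: int
    manual_log_mean: float
    manual_log_sd: float
    cytometry_log_mean: float
    cytometry_log_sd: float
    n_manual: int
    n_cytometry: int
    difference: float = field(init=False)
    p_value: float | None = None

    def __post_init__(self) -> None:
        self.difference = self.manual_log_mean - self.cytometry_log_mean


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def cfu_per_ml(
    plate: PlateCount,
    countable_range: tuple[int, int] | None = None,
) -> float:
    """Back-calculate the original-sample concentration from one plate.

    CFU/mL = colonies / (plated_volume * 10^dilution_exponent).  Counts
    outside the countable range (or zero) are flagged via the module
    logger, never fatal.
    """
    if countable_range is None:
        countable_range = DEFAULT_COUNTABLE_RANGES.get(
            plate.medium, DEFAULT_COUNTABLE_RANGES["bacteria"]
        )
    lo, hi = countable_range
    if plate.colonies == 0:
        log.warning(
            "plate %s at 10^%d: zero colonies (below detection)",
            plate.sample_id,
            plate.dilution_exponent,
        )
        return 0.0
    if not lo <= plate.colonies <= hi:
        log.warning(
            "plate %s at 10^%d: %d colonies outside countable range %s",
            plate.sample_id,
            plate.dilution_exponent,
            plate.colonies,
            countable_range,
        )
    return plate.colonies / (plate.plated_volume_ml * 10.0**plate.dilution_exponent)


def select_countable(
    plates: Sequence[PlateCount],
    countable_range: tuple[int, int] = (25, 250),
) -> list[PlateCount]:
    """Keep the dilution level whose mean colony count is countable.

    Among levels whose mean falls inside the range, ties break toward the
    higher-count (lower-dilution) level.  When no level is countable, the
    level closest to the range is returned and flagged.
    """
    if not plates:
        raise ValueError("need at least one plate")
    levels: dict[int, list[PlateCount]] = {}
    for p in plates:
        levels.setdefault(p.dilution_exponent, []).append(p)
    lo, hi = countable_range

    def score(exp: int):
        mean = float(np.mean([p.colonies for p in levels[exp]]))
        inside = lo <= mean <= hi
        dist = 0.0 if inside else (lo - mean if mean < lo else mean - hi)
        # prefer: inside range, then closest to range, then higher count,
        # then lower dilution (exponent closer to 0)
        return (not inside, dist, -mean, -exp)

    best = min(levels, key=score)
    mean = float(np.mean([p.colonies for p in levels[best]]))
    if not lo <= mean <= hi:
        log.warning(
            "no countable dilution level (range %s); returning closest level "
            "10^%d with mean %.1f colonies",
            countable_range,
            best,
            mean,
        )
    return levels[best]


def log10_concentration(conc: float) -> float | None:
    """Base-10 log of a concentration; zero yields ``None`` with a flag."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if conc == 0:
        log.warning("zero concentration has no log; reporting absent")
        return None
    return math.log10(conc)


def difference_from_means(manual_mean: float, cytometry_mean: float) -> float:
    """Manual minus cytometry log-mean, reported at two decimals."""
    return round(manual_mean - cytometry_mean, 2)


def method_difference(
    manual_logs: Sequence[float], cyto_logs: Sequence[float]
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Per-method mean +/- sd and their (manual - cytometry) difference.

    Returns ``((manual_mean, manual_sd), (cyto_mean, cyto_sd), difference)``
    with the difference rounded to two decimals.
    """
    if len(manual_logs) == 0 or len(cyto_logs) == 0:
        raise ValueError("each replicate list must be non-empty")
    m = np.asarray(manual_logs, dtype=float)
    c = np.asarray(cyto_logs, dtype=float)
    m_mean, c_mean = float(m.mean()), float(c.mean())
    m_sd = float(m.std(ddof=1)) if len(m) > 1 else 0.0
    c_sd = float(c.std(ddof=1)) if len(c) > 1 else 0.0
    return (m_mean, m_sd), (c_mean, c_sd), difference_from_means(m_mean, c_mean)


def check_table_row(
    manual_mean: float,
    cytometry_mean: float,
    printed_difference: float,
    tol: float = 0.005,
) -> bool:
    """Consistency check of a printed comparison-table row.

    True iff the printed difference equals the recomputed two-decimal
    difference of the printed means (within rounding slack).  Inconsistent
    rows are flagged, not silently reproduced.
    """
    recomputed = difference_from_means(manual_mean, cytometry_mean)
    ok = abs(recomputed - printed_difference) <= tol + 1e-12
    if not ok:
        log.warning(
            "inconsistent table row: %.2f - %.2f = %.2f but printed %.2f",
            manual_mean,
            cytometry_mean,
            recomputed,
            printed_difference,
        )
    return ok


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference: 100*|a-b| / mean(a, b)."""
    if not (a > 0 and b > 0):
        raise ValueError(f"both values must be > 0, got ({a}, {b})")
    return 100.0 * abs(a - b) / ((a + b) / 2.0)


def titration_regression(
    dilution_fractions: Sequence[float], concentrations: Sequence[float]
) -> RegressionResult:
    """OLS of concentration on dilution fraction, with R^2.

    R^2 is 1 - SS_res/SS_tot of the fitted line; requires >= 3 points and
    at least two distinct x values.
    """
    x = np.asarray(dilution_fractions, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all dilution fractions identical")
    with warnings.catch_warnings():
        # constant y triggers a harmless RuntimeWarning inside linregress
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.linregress(x, y)
        r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return RegressionResult(float(res.slope), float(res.intercept), r2)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], *, equal_var: bool = False
) -> float:
    """Two-sided two-sample t-test p-value (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def method_anova(
    per_trial_means: Iterable[tuple[int, str, float]],
    *,
    model: str = "oneway",
) -> AnovaResult:
    """ANOVA of per-trial mean log concentrations with method as the factor.

    ``per_trial_means`` is an iterable of ``(trial, method, mean)`` triples
    covering two methods over T >= 2 trials.  The default one-way model
    treats trial means as replicates within each method (F on 1 and
    2*(T-1) df for two balanced methods).  ``model="blocked"`` instead
    removes a trial block effect (randomized-block two-way without
    interaction).
    """
    triples = list(per_trial_means)
    methods = sorted({m for _, m, _ in triples})
    trials = sorted({t for t, _, _ in triples})
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    if len(trials) < 2:
        raise ValueError(
            "insufficient replication: need >= 2 trials per method for ANOVA"
        )
    groups = {
        m: np.array([v for t, mm, v in triples if mm == m], dtype=float)
        for m in methods
    }
    ns = {m: len(g) for m, g in groups.items()}
    if min(ns.values()) < 2:
        raise ValueError("insufficient replication: need >= 2 values per method")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    df_between = len(methods) - 1

    if model == "oneway":
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        df_within = len(all_vals) - len(methods)
    elif model == "blocked":
        if len(set(ns.values())) != 1 or len(all_vals) != len(methods) * len(trials):
            raise ValueError("blocked model requires a complete balanced layout")
        by_trial = {
            t: np.array([v for tt, _, v in triples if tt == t], dtype=float)
            for t in trials
        }
        ss_total = ((all_vals - grand) ** 2).sum()
        ss_trial = sum(len(g) * (g.mean() - grand) ** 2 for g in by_trial.values())
        ss_within = ss_total - ss_between - ss_trial
        df_within = (len(methods) - 1) * (len(trials) - 1)
    else:
        raise ValueError(f"unknown model {model!r}; use 'oneway' or 'blocked'")

    if df_within <= 0:
        raise ValueError("insufficient replication for the requested model")
    if ss_within <= 0:
        # zero residual variance: identical groups -> F = 0, else infinite
        if ss_between == 0:
            return AnovaResult(0.0, 1.0, df_between, df_within)
        return AnovaResult(math.inf, 0.0, df_between, df_within)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), p, df_between, df_within)
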