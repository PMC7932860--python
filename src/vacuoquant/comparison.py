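"""Method-comparison statistics for two vacuolization quantification methods.

Implements the full agreement workbench used to validate automated against
manual quantification of per-smear percentages:

* Passing-Bablok regression — a nonparametric fit robust to measurement
  error in both methods.  The slope is the shifted median of all pairwise
  slopes S_ij = (y_j − y_i)/(x_j − x_i) over i < j with x_i ≠ x_j: slopes
  equal to −1 are excluded, the median index is offset by K = #{S_ij < −1},
  and an even count averages the two middle order statistics after the
  shift.  The intercept is the median of y_i − slope·x_i.  Confidence
  intervals come from seeded percentile bootstrap over resampled pairs
  (999 resamples by default).
* Bland-Altman analysis — mean difference, sample SD (n−1 denominator) and
  limits of agreement mean ± 1.96 SD.  Differences run method A − method B
  (automated − manual when called from :func:`compare_methods`).
* Pearson product-moment correlation.
* Levene's test of variance homogeneity across paired-difference groups —
  classic Levene on absolute deviations from each group's mean, with the
  p-value from the F distribution on (k−1, N−k) degrees of freedom.

All statistics are computed from first principles (scipy supplies only the
F-distribution tail probability), and every fitted quantity round-trips
through JSON for reporting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "PairedMeasurements",
    "PassingBablokFit",
    "BlandAltmanResult",
    "LeveneResult",
    "MethodComparisonReport",
    "passing_bablok",
    "bland_altman",
    "pearson_r",
    "levene_test",
    "compare_methods",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Equal-length per-smear measurements from two methods."""

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        x = tuple(float(v) for v in self.x)
        y = tuple(float(v) for v in self.y)
        if len(x) != len(y):
            raise ParameterError(f"length mismatch: {len(x)} vs {len(y)}")
        if not all(np.isfinite(x)) or not all(np.isfinite(y)):
            raise ParameterError("measurements must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.x, dtype=np.float64), np.asarray(self.y, dtype=np.float64)


@dataclass(frozen=True)
class PassingBablokFit:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    intercept_ci_low: float
    intercept_ci_high: float
    n_pairwise_slopes: int
    bootstrap_samples: int
    seed: int

    def __post_init__(self) -> None:
        if not self.slope_ci_low <= self.slope <= self.slope_ci_high:
            raise ParameterError("slope outside its confidence interval")
        if not self.intercept_ci_low <= self.intercept <= self.intercept_ci_high:
            raise ParameterError("intercept outside its confidence interval")


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_low <= self.mean_difference <= self.loa_high:
            raise ParameterError("mean difference outside the limits of agreement")


@dataclass(frozen=True)
class LeveneResult:
    W_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.W_statistic < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ParameterError("invalid Levene statistic or p-value")


def _pb_point_estimate(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    valid = dx != 0
    slopes = dy[valid] / dx[valid]
    slopes = slopes[slopes != -1.0]
    n_slopes = int(slopes.size)
    if n_slopes < 1:
        raise DegenerateDataError("fewer than one valid pairwise slope")
    k_shift = int((slopes < -1.0).sum())
    s = np.sort(slopes)
    if n_slopes % 2:
        idx = (n_slopes - 1) // 2 + k_shift
        if idx >= n_slopes:
            raise DegenerateDataError("shifted median falls outside the slope range")
        slope = float(s[idx])
    else:
        lo = n_slopes // 2 - 1 + k_shift
        hi = n_slopes // 2 + k_shift
        if hi >= n_slopes:
            raise DegenerateDataError("shifted median falls outside the slope range")
        slope = float(0.5 * (s[lo] + s[hi]))
    intercept = float(np.median(y - slope * x))
    return slope, intercept, n_slopes


def passing_bablok(
    data: PairedMeasurements, bootstrap_samples: int = 999, seed: int = 0
) -> PassingBablokFit:
    """Passing-Bablok regression with seeded percentile-bootstrap CIs."""
    if data.n < 3:
        raise ParameterError("Passing-Bablok requires at least 3 pairs")
    x, y = data.arrays()
    if np.all(x == x[0]):
        raise ParameterError("all x values identical; regression undefined")
    slope, intercept, n_slopes = _pb_point_estimate(x, y)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    boot_slopes = np.empty(bootstrap_samples)
    boot_intercepts = np.empty(bootstrap_samples)
    filled = 0
    attempts = 0
    while filled < bootstrap_samples:
        attempts += 1
        if attempts > 20 * bootstrap_samples:
            raise DegenerateDataError("bootstrap resamples persistently degenerate")
        idx = rng.integers(data.n, size=data.n)
        try:
            b, a, _ = _pb_point_estimate(x[idx], y[idx])
        except DegenerateDataError:
            continue
        boot_slopes[filled] = b
        boot_intercepts[filled] = a
        filled += 1
    s_lo, s_hi = np.percentile(boot_slopes, [2.5, 97.5])
    a_lo, a_hi = np.percentile(boot_intercepts, [2.5, 97.5])
    return PassingBablokFit(
        slope=slope,
        intercept=intercept,
        slope_ci_low=float(min(s_lo, slope)),
        slope_ci_high=float(max(s_hi, slope)),
        intercept_ci_low=float(min(a_lo, intercept)),
        intercept_ci_high=float(max(a_hi, intercept)),
        n_pairwise_slopes=n_slopes,
        bootstrap_samples=bootstrap_samples,
        seed=int(seed),
    )


def bland_altman(data: PairedMeasurements) -> BlandAltmanResult:
    """Mean difference (x − y), sample SD and 1.96-SD limits of agreement."""
    if data.n < 2:
        raise ParameterError("Bland-Altman requires at least 2 pairs")
    x, y = data.arrays()
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=data.n,
    )


def pearson_r(data: PairedMeasurements) -> float:
    """Product-moment correlation; raises on a constant variable."""
    if data.n < 3:
        raise ParameterError("Pearson correlation requires at least 3 pairs")
    x, y = data.arrays()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise DegenerateDataError("constant variable; correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def levene_test(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> LeveneResult:
    """Classic Levene W on absolute deviations from each group's mean."""
    if len(groups) < 2:
        raise ParameterError("Levene's test requires at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs at least 2 values")
    if labels is None:
        labels = tuple(f"group_{i}" for i in range(len(arrays)))
    z = [np.abs(a - a.mean()) for a in arrays]
    k = len(z)
    n_total = sum(a.size for a in z)
    z_all = np.concatenate(z)
    grand = z_all.mean()
    between = sum(a.size * (a.mean() - grand) ** 2 for a in z)
    within = sum(((a - a.mean()) ** 2).sum() for a in z)
    df_between = k - 1
    df_within = n_total - k
    if within == 0:
        if between == 0:
            raise DegenerateDataError("all within-group deviations are zero")
        raise DegenerateDataError("zero within-group variance; W undefined")
    w = (between / df_between) / (within / df_within)
    p = float(_scipy_stats.f.sf(w, df_between, df_within))
    return LeveneResult(
        W_statistic=float(w),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        group_labels=tuple(labels),
    )


@dataclass(frozen=True)
class MethodComparisonReport:
    """Complete automated-vs-manual agreement report.

    Differences run automated − manual throughout ("net − manual"
    convention).  Degenerate statistics (constant consensus, zero spread)
    are recorded as flags instead of numbers so full-agreement edge cases
    surface explicitly.
    """

    passing_bablok_auto_vs_consensus: PassingBablokFit
    bland_altman_auto_vs_consensus: BlandAltmanResult
    bland_altman_manual1_vs_manual2: BlandAltmanResult
    pearson_r_auto_vs_consensus: float | None
    levene: LeveneResult | None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MethodComparisonReport":
        d = json.loads(text)
        levene = d["levene"]
        if levene is not None:
            levene = LeveneResult(**{**levene, "group_labels": tuple(levene["group_labels"])})
        return cls(
            passing_bablok_auto_vs_consensus=PassingBablokFit(
                **d["passing_bablok_auto_vs_consensus"]
            ),
            bland_altman_auto_vs_consensus=BlandAltmanResult(
                **d["bland_altman_auto_vs_consensus"]
            ),
            bland_altman_manual1_vs_manual2=BlandAltmanResult(
                **d["bland_altman_manual1_vs_manual2"]
            ),
            pearson_r_auto_vs_consensus=d["pearson_r_auto_vs_consensus"],
            levene=levene,
            flags=tuple(d.get("flags", ())),
        )


def compare_methods(
    auto: Sequence[float],
    manual1: Sequence[float],
    manual2: Sequence[float],
    bootstrap_samples: int = 999,
    seed: int = 0,
) -> MethodComparisonReport:
    """Full agreement analysis of automated vs consensus-manual percentages.

    The manual consensus is the per-smear mean of the two manual readings.
    Levene's test compares the three paired-difference groups
    auto − manual1, auto − manual2 and manual1 − manual2.
    """
    a = np.asarray(auto, dtype=np.float64)
    m1 = np.asarray(manual1, dtype=np.float64)
    m2 = np.asarray(manual2, dtype=np.float64)
    if not (len(a) == len(m1) == len(m2)):
        raise ParameterError("auto, manual1 and manual2 must have equal lengths")
    consensus = (m1 + m2) / 2.0
    flags: list[str] = []

    # regression of automated (y) on consensus manual (x): "net vs manual"
    pb = passing_bablok(
        PairedMeasurements(tuple(consensus), tuple(a)),
        bootstrap_samples=bootstrap_samples,
        seed=seed,
    )
    ba_auto = bland_altman(PairedMeasurements(tuple(a), tuple(consensus)))
    ba_manual = bland_altman(PairedMeasurements(tuple(m1), tuple(m2)))
    try:
        r = pearson_r(PairedMeasurements(tuple(a), tuple(consensus)))
    except DegenerateDataError:
        r = None
        flags.append("pearson_degenerate")
    try:
        levene = levene_test(
            [a - m1, a - m2, m1 - m2],
            labels=("auto-manual1", "auto-manual2", "manual1-manual2"),
        )
    except DegenerateDataError:
        levene = None
        flags.append("levene_degenerate")
    return MethodComparisonReport(
        passing_bablok_auto_vs_consensus=pb,
        bland_altman_auto_vs_consensus=ba_auto,
        bland_altman_manual1_vs_manual2=ba_manual,
        pearson_r_auto_vs_consensus=r,
        levene=levene,
        flags=tuple(flags),
    )
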