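"""Inter-method agreement statistics for paired ordinal risk scores.

Implements the statistical battery used to compare two posture-assessment
technologies scoring the same participants:

* Cohen's weighted kappa (linear or quadratic weights) with the asymptotic
  standard error of Fleiss, Cohen & Everitt for the 95% CI and the
  large-sample normal test of kappa = 0;
* Bland-Altman method-comparison statistics (mean difference and 1.96-SD
  limits of agreement, plus per-pair points for plotting);
* Mann-Whitney U with midrank tie handling and the rank-biserial effect
  size r_rb = 1 - 2U/(n1*n2);
* Bonferroni correction, Shapiro-Wilk normality gate, and post hoc power of
  the two-tailed t-test for a point-biserial correlation via the noncentral
  t distribution.

Continuous aggregated RULA scores are rounded half-up to integer levels
before kappa; all other statistics use the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedKappaError

__all__ = [
    "KappaResult",
    "BlandAltmanResult",
    "MannWhitneyResult",
    "AgreementReport",
    "StatsConfig",
    "REGION_LEVELS",
    "weighted_kappa",
    "bland_altman",
    "mann_whitney_rank_biserial",
    "bonferroni",
    "normality_check",
    "posthoc_power_point_biserial",
    "round_to_levels",
    "compare_methods",
]

#: Number of ordinal levels per score family (grand score plus sub-scores).
REGION_LEVELS = {
    "overall": 7,
    "upper_arm": 6,
    "lower_arm": 3,
    "wrist": 4,
    "neck": 6,
    "trunk": 6,
    "legs": 2,
}


class KappaResult(NamedTuple):
    kappa: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    se0: float


class BlandAltmanResult(NamedTuple):
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


class MannWhitneyResult(NamedTuple):
    u: float
    p_value: float
    rank_biserial: float


@dataclass
class StatsConfig:
    """Options for the full agreement analysis."""

    weights: Literal["linear", "quadratic"] = "linear"
    bonferroni_m: int | None = 6
    alpha: float = 0.05
    power_effect_r: float = 0.45
    mw_method: Literal["asymptotic", "exact", "auto"] = "asymptotic"
    on_degenerate: Literal["raise", "nan"] = "raise"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must be in (0, 1)")


@dataclass
class AgreementReport:
    """All agreement statistics for one score family."""

    region: str
    n: int
    kappa: float
    kappa_ci: tuple[float, float]
    p_value: float
    p_bonferroni: float
    bland_altman: tuple[float, float, float, float]  # mean_diff, sd, loa_low, loa_high
    mannwhitney: tuple[float, float, float]  # U, p, rank-biserial
    power: float
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "n": self.n,
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci),
            "p_value": self.p_value,
            "p_bonferroni": self.p_bonferroni,
            "bland_altman": {
                "mean_diff": self.bland_altman[0],
                "sd_diff": self.bland_altman[1],
                "loa_low": self.bland_altman[2],
                "loa_high": self.bland_altman[3],
            },
            "mann_whitney": {
                "U": self.mannwhitney[0],
                "p": self.mannwhitney[1],
                "rank_biserial": self.mannwhitney[2],
            },
            "power": self.power,
            "normality": {k: list(v) for k, v in self.normality.items()},
        }


def _weight_matrix(k: int, scheme: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    d = np.abs(i - j) / (k - 1)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise InputError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(
    x: Sequence[int],
    y: Sequence[int],
    k_levels: int,
    scheme: Literal["linear", "quadratic"] = "linear",
    conf_level: float = 0.95,
) -> KappaResult:
    """Cohen's weighted kappa with asymptotic CI and test of kappa = 0.

    ``x`` and ``y`` are paired ordinal ratings taking values in
    ``{1, ..., k_levels}``.  Agreement weights are ``1 - |i-j|/(k-1)``
    (linear) or ``1 - ((i-j)/(k-1))**2`` (quadratic).  The CI uses the
    non-null large-sample variance of Fleiss, Cohen & Everitt (1969); the
    p-value uses the corresponding null variance.
    """
    xa = np.asarray(x, dtype=int)
    ya = np.asarray(y, dtype=int)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InputError("x and y must be equal-length 1-D sequences")
    n = xa.size
    if n < 2:
        raise InputError("weighted kappa requires at least 2 pairs")
    if k_levels < 2:
        raise InputError("k_levels must be >= 2")
    if xa.min() < 1 or xa.max() > k_levels or ya.min() < 1 or ya.max() > k_levels:
        raise InputError(f"ratings must lie in 1..{k_levels}")

    k = k_levels
    counts = np.zeros((k, k))
    np.add.at(counts, (xa - 1, ya - 1), 1.0)
    p = counts / n
    w = _weight_matrix(k, scheme)

    pi = p.sum(axis=1)  # marginal of x
    pj = p.sum(axis=0)  # marginal of y
    po = float((p * w).sum())
    pe = float((np.outer(pi, pj) * w).sum())
    denom = 1.0 - pe
    if abs(denom) < 1e-12:
        raise UndefinedKappaError(
            "expected weighted agreement equals 1; kappa is undefined"
        )
    kappa = (po - pe) / denom

    # Row/column expected weights.
    wbar_i = w @ pj  # \bar w_{i.}
    wbar_j = pi @ w  # \bar w_{.j}
    cross = wbar_i[:, None] + wbar_j[None, :]

    var0 = (
        float((np.outer(pi, pj) * (w - cross) ** 2).sum()) - pe**2
    ) / (n * denom**2)
    var = (
        float((p * (w - cross * (1.0 - kappa)) ** 2).sum())
        - (kappa - pe * (1.0 - kappa)) ** 2
    ) / (n * denom**2)
    se0 = float(np.sqrt(max(var0, 0.0)))
    se = float(np.sqrt(max(var, 0.0)))

    z = kappa / se0 if se0 > 0 else np.inf * np.sign(kappa) if kappa else 0.0
    p_value = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    zc = stats.norm.ppf(0.5 + conf_level / 2.0)
    return KappaResult(
        float(kappa), float(kappa - zc * se), float(kappa + zc * se), p_value, se, se0
    )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman statistics for paired measurements (differences x - y).

    The limits of agreement are ``mean_diff +/- 1.96 * sd_diff`` with the
    sample (n-1) standard deviation; under normality they bracket about 95%
    of inter-method differences.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise InputError("bland_altman requires two equal-length arrays with n >= 2")
    d = xa - ya
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff,
        sd,
        mean_diff - 1.96 * sd,
        mean_diff + 1.96 * sd,
        (xa + ya) / 2.0,
        d,
    )


def mann_whitney_rank_biserial(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["asymptotic", "exact", "auto"] = "asymptotic",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with the rank-biserial effect size.

    U is the statistic for the first sample (midranks for ties); the
    asymptotic p-value uses the tie-corrected normal approximation.  The
    effect size is ``r_rb = 1 - 2U/(n1*n2)``: it is -1 when every x exceeds
    every y, +1 in the opposite separation, and 0 for identical multisets.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise InputError("both samples must be non-empty")
    if method == "exact" and (len(np.unique(np.concatenate([xa, ya]))) < xa.size + ya.size):
        method = "asymptotic"  # exact null distribution assumes no ties
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    u = float(res.statistic)
    r_rb = 1.0 - 2.0 * u / (xa.size * ya.size)
    return MannWhitneyResult(u, float(res.pvalue), float(r_rb))


def bonferroni(p_values: Sequence[float] | float, m: int) -> np.ndarray | float:
    """Bonferroni-adjusted p-values: ``min(1, p * m)``."""
    if m < 1:
        raise InputError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, p * m)
    return float(adj) if adj.ndim == 0 else adj


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test (W, p); requires 3 <= n <= 5000 and non-constant data."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise InputError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise InputError("Shapiro-Wilk is undefined for constant data")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def posthoc_power_point_biserial(
    r: float, alpha: float = 0.05, n: int = 45, tails: int = 2
) -> float:
    """Power of the t-test for a point-biserial correlation of size ``r``.

    Uses the noncentral t distribution with ``df = n - 2`` and noncentrality
    ``delta = r * sqrt(n) / sqrt(1 - r**2)`` — the model behind standard
    post hoc power calculators for correlation tests.
    """
    if not (0.0 < r < 1.0):
        raise InputError("effect size r must be in (0, 1)")
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    if n < 4:
        raise InputError("n must be >= 4")
    if tails not in (1, 2):
        raise InputError("tails must be 1 or 2")
    df = n - 2
    delta = r * np.sqrt(n) / np.sqrt(1.0 - r**2)
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        power = stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, delta)
    return float(power)


def round_to_levels(values: Sequence[float], k_levels: int) -> np.ndarray:
    """Round continuous scores half-up to integer levels clipped to 1..k."""
    v = np.asarray(values, dtype=float)
    return np.clip(np.floor(v + 0.5).astype(int), 1, k_levels)


def compare_methods(
    scores: pd.DataFrame,
    config: StatsConfig | None = None,
) -> dict[str, AgreementReport]:
    """Full agreement analysis per score family.

    ``scores`` is a long-format frame with columns ``participant``,
    ``region``, ``imu_score`` and ``pose_score`` — one row per participant
    and family ("overall" plus body regions).  For each family the paired
    scores are rounded to ordinal levels for weighted kappa and analysed
    raw for Bland-Altman and Mann-Whitney; Bonferroni correction uses
    ``config.bonferroni_m`` (default: the number of families).
    """
    config = config or StatsConfig()
    required = {"participant", "region", "imu_score", "pose_score"}
    missing = required - set(scores.columns)
    if missing:
        raise InputError(f"scores frame missing columns: {sorted(missing)}")
    regions = list(dict.fromkeys(scores["region"]))
    m = config.bonferroni_m or len(regions)

    reports: dict[str, AgreementReport] = {}
    for region in regions:
        sub = scores[scores["region"] == region].sort_values("participant")
        imu = sub["imu_score"].to_numpy(dtype=float)
        pose = sub["pose_score"].to_numpy(dtype=float)
        if np.isnan(imu).any() or np.isnan(pose).any():
            raise InputError(f"missing scores in region {region!r}")
        k = REGION_LEVELS.get(region, 7)
        xi = round_to_levels(imu, k)
        yi = round_to_levels(pose, k)
        try:
            kr = weighted_kappa(xi, yi, k, config.weights)
        except UndefinedKappaError:
            if config.on_degenerate == "raise":
                raise
            kr = KappaResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
        ba = bland_altman(imu, pose)
        mw = mann_whitney_rank_biserial(imu, pose, config.mw_method)
        normality = {}
        for label, v in (("imu", imu), ("pose", pose)):
            try:
                normality[label] = normality_check(v)
            except InputError:
                normality[label] = (np.nan, np.nan)
        reports[region] = AgreementReport(
            region=region,
            n=int(imu.size),
            kappa=kr.kappa,
            kappa_ci=(kr.ci_low, kr.ci_high),
            p_value=kr.p_value,
            p_bonferroni=float(bonferroni(kr.p_value, m))
            if np.isfinite(kr.p_value)
            else np.nan,
            bland_altman=(ba.mean_diff, ba.sd_diff, ba.loa_low, ba.loa_high),
            mannwhitney=(mw.u, mw.p_value, mw.rank_biserial),
            power=posthoc_power_point_biserial(
                config.power_effect_r, config.alpha, int(imu.size)
            )
            if imu.size >= 4
            else float("nan"),
            normality=normality,
        )
    return reports
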