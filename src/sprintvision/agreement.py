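"""Concurrent-validity statistics between two speed-measurement systems.

Given paired subtask speeds from the vision pipeline and a reference system,
this module computes the Pearson product-moment correlation (with a Fisher-z
95% confidence interval and a two-sided t-test p-value), maps |r| to the
conventional agreement bands (low < 0.50 <= moderate < 0.70 <= high < 0.90 <=
very high), and builds the Bland-Altman construction: mean difference and
mean +/- 1.96*SD limits of agreement, within which ~95% of the paired
differences are expected to fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import round_half_up

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "PairedSeries",
    "PearsonResult",
    "agreement_report",
    "bland_altman",
    "bland_altman_plot",
    "categorize_agreement",
    "pearson_r",
    "summarize_cohort",
]

#: (upper-edge, label) pairs for |r|; edges are half-open so the bands
#: partition [0, 1] with no gaps or overlaps.
_BANDS = ((0.50, "low"), (0.70, "moderate"), (0.90, "high"), (np.inf, "very high"))


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observations of the same quantity from two systems."""

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired series must be equal-length 1-D arrays")
        if len(a) < 3:
            raise ValueError(f"need at least 3 pairs, got {len(a)}")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("paired series must not contain missing values")
        if self.labels is not None and len(self.labels) != len(a):
            raise ValueError("labels must align with the paired values")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    def __len__(self) -> int:
        return len(self.values_a)


def _as_pair(a, b=None) -> tuple[np.ndarray, np.ndarray]:
    if b is None:
        if not isinstance(a, PairedSeries):
            raise TypeError("pass a PairedSeries or two array-likes")
        return a.values_a, a.values_b
    pair = PairedSeries(a, b)  # runs the shared validation
    return pair.values_a, pair.values_b


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def pearson_r(a, b=None) -> PearsonResult:
    """Pearson correlation with Fisher-z 95% CI and two-sided p (t, n-2 df).

    The product-moment coefficient is computed from centred dot products and
    clamped into [-1, 1]; a value within floating-point rounding of +/-1
    (perfectly linear pairs, e.g. a series against itself) is reported as
    exactly +/-1.
    """
    x, y = _as_pair(a, b)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError("degenerate series: zero variance")
    r = float(xc @ yc) / (np.sqrt(sxx) * np.sqrt(syy))
    r = min(1.0, max(-1.0, r))
    if 1.0 - abs(r) < 1e-14:
        r = 1.0 if r > 0 else -1.0
    n = len(x)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    if abs(r) >= 1.0 or n <= 3:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return PearsonResult(r=r, ci_low=ci[0], ci_high=ci[1], p_value=p, n=n)


def categorize_agreement(r: float) -> str:
    """Label the agreement strength of a correlation by its magnitude."""
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    magnitude = abs(r)
    for edge, label in _BANDS:
        if magnitude < edge:
            return label
    return "very high"  # pragma: no cover — inf edge always matches


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outside_loa: int
    means: np.ndarray  # per-pair (a+b)/2, for plotting
    diffs: np.ndarray  # per-pair a-b


def bland_altman(a, b=None) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean +/- 1.96*SD, SD with n-1)."""
    x, y = _as_pair(a, b)
    diffs = x - y
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    outside = int(np.sum((diffs < loa_low) | (diffs > loa_high)))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        n_outside_loa=outside,
        means=0.5 * (x + y),
        diffs=diffs,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Full concurrent-validity report for one paired series."""

    r: float
    r_ci_low: float
    r_ci_high: float
    p_value: float
    category: str
    mean_diff: float
    loa_low: float
    loa_high: float
    n_outside_loa: int
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def agreement_report(a, b=None) -> AgreementResult:
    pr = pearson_r(a, b)
    ba = bland_altman(a, b)
    return AgreementResult(
        r=pr.r,
        r_ci_low=pr.ci_low,
        r_ci_high=pr.ci_high,
        p_value=pr.p_value,
        category=categorize_agreement(pr.r),
        mean_diff=ba.mean_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        n_outside_loa=ba.n_outside_loa,
        n=pr.n,
    )


def bland_altman_plot(result: BlandAltmanResult, path, title: str | None = None) -> None:
    """Scatter of per-pair means vs differences with bias and LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18, color="tab:blue", alpha=0.8)
    ax.axhline(result.mean_diff, color="k", lw=1.2, label="mean difference")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel("mean of the two systems (m/s)")
    ax.set_ylabel("difference (m/s)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize_cohort(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of cohort characteristics and per-trial times/speeds.

    ``rows`` needs columns ``time_trial1_s`` and ``time_trial2_s`` (positive
    seconds); ``age_years``, ``height_cm``, ``weight_kg`` and ``bmi_kg_m2``
    are summarized when present.  Each athlete's speed is 100 m over their
    time, rounded to 3 decimals *before* averaging — the order report tables
    conventionally use.  With a single athlete the SD is missing.
    """
    out: dict[str, dict[str, float]] = {}
    for col in ("age_years", "height_cm", "weight_kg", "bmi_kg_m2"):
        if col in rows:
            out[col] = {"mean": rows[col].mean(), "sd": rows[col].std(ddof=1)}
    for trial in (1, 2):
        col = f"time_trial{trial}_s"
        if col not in rows:
            continue
        times = rows[col].astype(float)
        if (times <= 0).any():
            raise ValueError(f"{col}: times must be positive")
        speeds = times.map(lambda t: round_half_up(100.0 / t, 3))
        out[col] = {"mean": times.mean(), "sd": times.std(ddof=1)}
        out[f"speed_trial{trial}_m_per_s"] = {
            "mean": speeds.mean(),
            "sd": speeds.std(ddof=1),
        }
    return pd.DataFrame(out)
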