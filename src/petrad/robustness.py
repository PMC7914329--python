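"""Robustness statistics: Dice overlap, two-way consistency ICC, per-lesion
coefficient of variation, Pearson profiles and the robustness classification.

The ICC is the two-way mixed-effects consistency form built from the
between-subjects (lesion) mean square BMS and the residual mean square RMS
of the additive lesion x method ANOVA decomposition (no interaction term):

    ICC = (BMS - RMS) / (BMS + (N - 1) * RMS)

with N the number of methods/measurements per lesion.  Features are called
highly robust when ICC > 0.9, robust when 0.8 < ICC <= 0.9, moderately
robust when 0.5 <= ICC <= 0.8 and poorly robust below 0.5.

COV^L is the per-lesion coefficient of variation of one feature across the
N settings, 100 * sd / mean (sample sd), undefined when the mean is
numerically zero — features taking tiny near-zero values would otherwise
explode the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import VOIMask

# classification thresholds on ICC
CLASS_HIGH = 0.9
CLASS_ROBUST = 0.8
CLASS_MODERATE = 0.5

COVL_MEAN_EPS = 1e-12


class UndefinedICCError(ValueError):
    """Fewer than 2 complete lesion rows (or < 2 methods) were available."""


@dataclass
class ICCResult:
    """Consistency ICC with its ANOVA mean squares.

    ``n_lesions`` counts the complete-case rows actually used; ``degenerate``
    flags a table with zero total variance (ICC defined as 1 there).
    """

    icc: float
    bms: float
    rms: float
    n_methods: int
    n_lesions: int
    degenerate: bool = False


def dice(a: VOIMask, b: VOIMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two masks on
    the same grid; NaN (with a warning) when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.values.sum()), int(b.values.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks is undefined", stacklevel=2)
        return float("nan")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def icc_consistency(measurements: np.ndarray) -> ICCResult:
    """Two-way mixed-effects consistency ICC of a lesions x methods table.

    Rows containing any NaN are dropped (complete cases).  BMS and RMS come
    from the additive two-way ANOVA: SS_res = SS_total - SS_rows - SS_cols,
    df_res = (n-1)(k-1).  A table with zero total variance has ICC defined
    as 1 and is flagged degenerate.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise UndefinedICCError("need a 2-D table with >= 2 methods")
    complete = ~np.isnan(m).any(axis=1)
    m = m[complete]
    n, k = m.shape
    if n < 2:
        raise UndefinedICCError(f"only {n} complete lesion rows (need >= 2)")
    grand = m.mean()
    ss_total = float(((m - grand) ** 2).sum())
    if ss_total == 0.0:
        return ICCResult(icc=1.0, bms=0.0, rms=0.0, n_methods=k,
                         n_lesions=n, degenerate=True)
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_res = max(ss_total - ss_rows - ss_cols, 0.0)
    bms = ss_rows / (n - 1)
    rms = ss_res / ((n - 1) * (k - 1))
    icc = (bms - rms) / (bms + (k - 1) * rms) if (bms + (k - 1) * rms) > 0 else 1.0
    return ICCResult(icc=float(icc), bms=bms, rms=rms, n_methods=k, n_lesions=n)


def covl(values: np.ndarray) -> float:
    """Per-lesion coefficient of variation, in percent: 100 * sd / mean with
    the sample standard deviation (ddof=1).  NaN when any input is NaN or
    when |mean| is numerically zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("COV^L needs at least 2 measurements")
    if np.isnan(v).any():
        return float("nan")
    mean = v.mean()
    scale = max(np.abs(v).max(), 1.0)
    if np.abs(mean) < COVL_MEAN_EPS * scale or mean == 0.0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def classify_robustness(icc: float) -> str:
    """Map an ICC value onto the four robustness classes."""
    if np.isnan(icc):
        return "undefined"
    if icc > CLASS_HIGH:
        return "high"
    if icc > CLASS_ROBUST:
        return "robust"
    if icc >= CLASS_MODERATE:
        return "moderate"
    return "poor"


def pearson_profile(
    feature_table: pd.DataFrame,
    reference: str,
    feature_columns: list[str] | None = None,
    lesion_column: str = "lesion_id",
) -> pd.Series:
    """Pearson correlation of each feature with a per-lesion reference value.

    ``feature_table`` holds one row per (lesion, setting) with a
    ``reference`` column constant within a lesion (e.g. truth volume or
    SUVmax).  Feature values are first averaged across settings within each
    lesion, then correlated with the reference across lesions.  Features
    with < 3 finite lesion values or zero variance give NaN.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in feature_table.columns
            if c not in (lesion_column, reference)
            and pd.api.types.is_numeric_dtype(feature_table[c])
        ]
    per_lesion = feature_table.groupby(lesion_column)[
        feature_columns + [reference]
    ].mean()
    ref = per_lesion[reference].to_numpy()
    out = {}
    for c in feature_columns:
        x = per_lesion[c].to_numpy()
        ok = np.isfinite(x) & np.isfinite(ref)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(ref[ok]) == 0:
            out[c] = float("nan")
        else:
            out[c] = float(np.corrcoef(x[ok], ref[ok])[0, 1])
    return pd.Series(out, name=f"r_{reference}")


@dataclass
class RobustnessTable:
    """Per-feature robustness summary along one comparison axis.

    ``axis`` names what varies across the N measurements (segmentation,
    threshold or discretization); ``icc``/``covl_values`` are per-feature.
    """

    axis: str
    fixed: dict = field(default_factory=dict)
    icc: dict[str, ICCResult] = field(default_factory=dict)
    covl_values: dict[str, np.ndarray] = field(default_factory=dict)
    r_volume: dict[str, float] = field(default_factory=dict)
    r_suvmax: dict[str, float] = field(default_factory=dict)

    def robustness_class(self, feature: str) -> str:
        res = self.icc.get(feature)
        return classify_robustness(res.icc) if res is not None else "undefined"

    def median_covl(self, feature: str) -> float:
        v = self.covl_values.get(feature)
        if v is None:
            return float("nan")
        v = v[np.isfinite(v)]
        return float(np.median(v)) if v.size else float("nan")

    def high_icc_fraction(self) -> float:
        """Fraction of features with defined ICC that are highly robust."""
        defined = [r.icc for r in self.icc.values() if np.isfinite(r.icc)]
        if not defined:
            return float("nan")
        return float(np.mean([icc > CLASS_HIGH for icc in defined]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat, res in self.icc.items():
            v = self.covl_values.get(feat, np.asarray([]))
            finite = v[np.isfinite(v)] if v.size else v
            rows.append({
                "feature": feat,
                "axis": self.axis,
                "fixed": ";".join(f"{k}={v}" for k, v in sorted(self.fixed.items())),
                "icc": res.icc,
                "class": classify_robustness(res.icc),
                "n_lesions": res.n_lesions,
                "n_methods": res.n_methods,
                "median_covl_pct": float(np.median(finite)) if finite.size else float("nan"),
                "covl_q1_pct": float(np.percentile(finite, 25)) if finite.size else float("nan"),
                "covl_q3_pct": float(np.percentile(finite, 75)) if finite.size else float("nan"),
                "n_covl_defined": int(finite.size),
                "r_volume": self.r_volume.get(feat, float("nan")),
                "r_suvmax": self.r_suvmax.get(feat, float("nan")),
            })
        return pd.DataFrame(rows)
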