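"""Method-agreement and diagnostic statistics for device validation.

The device is validated against a reference measure (radiographic pelvic
tilt from the anterior pelvic plane) captured simultaneously.  Four
analyses are provided:

* Bland–Altman agreement — bias (mean device-minus-reference difference)
  and limits of agreement bias ± k·SD (k = 1.96 for the ~95% interval);
* diagnostic screening metrics from a 2×2 contingency table —
  sensitivity TP/(TP+FN), specificity TN/(TN+FP),
  accuracy (TP+TN)/total;
* correlation (Spearman by default, Pearson optional) between device and
  reference tilt changes;
* the distribution of absolute errors — median, third quartile, integer-
  binned histogram and a Poisson rate fitted by maximum likelihood (the
  sample mean of the binned errors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "PairedMeasures",
    "ContingencyTable",
    "AgreementStats",
    "bland_altman",
    "bland_altman_from_summary",
    "diagnostic_metrics",
    "build_contingency",
    "correlation",
    "error_distribution",
    "DEFAULT_LOA_K",
]

DEFAULT_LOA_K = 1.96


@dataclass(frozen=True)
class PairedMeasures:
    """Paired device / reference tilt changes (degrees), one row per
    patient-position; pairs with a missing side never enter statistics."""

    device_delta_deg: np.ndarray
    reference_delta_deg: np.ndarray
    position: np.ndarray  # per-pair position label
    patient_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        dev = np.asarray(self.device_delta_deg, dtype=float)
        ref = np.asarray(self.reference_delta_deg, dtype=float)
        pos = np.asarray(self.position, dtype=object)
        pid = None if self.patient_id is None else np.asarray(self.patient_id, dtype=object)
        if not (dev.size == ref.size == pos.size):
            raise ValueError("device, reference and position vectors must have equal length")
        keep = np.isfinite(dev) & np.isfinite(ref)
        object.__setattr__(self, "device_delta_deg", dev[keep])
        object.__setattr__(self, "reference_delta_deg", ref[keep])
        object.__setattr__(self, "position", pos[keep])
        object.__setattr__(self, "patient_id", None if pid is None else pid[keep])

    def __len__(self) -> int:
        return int(self.device_delta_deg.size)

    def subset(self, position: str) -> "PairedMeasures":
        mask = self.position == position
        return PairedMeasures(
            self.device_delta_deg[mask],
            self.reference_delta_deg[mask],
            self.position[mask],
            None if self.patient_id is None else self.patient_id[mask],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedMeasures":
        required = {"device_delta_deg", "reference_delta_deg", "position"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(
                f"paired-measures table is missing columns {sorted(missing)}; "
                f"expected schema: patient_id, position, device_delta_deg, reference_delta_deg"
            )
        return cls(
            df["device_delta_deg"].to_numpy(float),
            df["reference_delta_deg"].to_numpy(float),
            df["position"].to_numpy(object),
            df["patient_id"].to_numpy(object) if "patient_id" in df.columns else None,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "position": self.position,
            "device_delta_deg": self.device_delta_deg,
            "reference_delta_deg": self.reference_delta_deg,
        }
        if self.patient_id is not None:
            data = {"patient_id": self.patient_id, **data}
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 screening counts with the reference classification as truth."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary plus per-pair plot coordinates."""

    bias_deg: float
    sd_deg: float
    upper_loa_deg: float
    lower_loa_deg: float
    n: int
    k: float = DEFAULT_LOA_K
    means: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    differences: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def bland_altman_from_summary(bias_deg: float, sd_deg: float, n: int = 0,
                              k: float = DEFAULT_LOA_K) -> AgreementStats:
    """Limits of agreement from an already-computed bias and SD."""
    return AgreementStats(
        bias_deg=bias_deg,
        sd_deg=sd_deg,
        upper_loa_deg=bias_deg + k * sd_deg,
        lower_loa_deg=bias_deg - k * sd_deg,
        n=n,
        k=k,
        means=np.empty(0),
        differences=np.empty(0),
    )


def bland_altman(pairs: PairedMeasures, k: float = DEFAULT_LOA_K) -> AgreementStats:
    """Bland–Altman agreement between device and reference tilt changes.

    bias = mean(device - reference); sd = sample SD of the differences
    (n-1 denominator); limits of agreement = bias ± k·sd.  Per-pair means
    and differences are returned for plotting.
    """
    if len(pairs) < 2:
        raise ValueError(f"Bland-Altman requires at least 2 pairs, got {len(pairs)}")
    diff = pairs.device_delta_deg - pairs.reference_delta_deg
    mean = (pairs.device_delta_deg + pairs.reference_delta_deg) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    out = bland_altman_from_summary(bias, sd, n=len(pairs), k=k)
    return AgreementStats(
        bias_deg=out.bias_deg,
        sd_deg=out.sd_deg,
        upper_loa_deg=out.upper_loa_deg,
        lower_loa_deg=out.lower_loa_deg,
        n=out.n,
        k=k,
        means=mean,
        differences=diff,
    )


def diagnostic_metrics(table: ContingencyTable) -> dict:
    """Sensitivity, specificity and accuracy from a 2x2 table, as
    proportions in [0, 1].

    A metric whose denominator is zero is reported as ``nan`` (undefined),
    never as 0.
    """
    if table.total == 0:
        raise ValueError("empty contingency table")

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "sensitivity": _ratio(table.tp, table.tp + table.fn),
        "specificity": _ratio(table.tn, table.tn + table.fp),
        "accuracy": _ratio(table.tp + table.tn, table.total),
    }


def build_contingency(
    pairs: PairedMeasures,
    threshold_deg: float = 13.0,
    signed: bool = False,
) -> ContingencyTable:
    """Screening contingency table with the reference classification as
    ground truth.

    Both sides are classified with the same rule (|delta| >= threshold by
    default; ``signed=True`` uses delta >= threshold) and cross-tabulated.
    """
    if len(pairs) == 0:
        raise ValueError("no paired measures to classify")
    dev = pairs.device_delta_deg if signed else np.abs(pairs.device_delta_deg)
    ref = pairs.reference_delta_deg if signed else np.abs(pairs.reference_delta_deg)
    dev_pos = dev >= threshold_deg
    ref_pos = ref >= threshold_deg
    return ContingencyTable(
        tp=int(np.sum(dev_pos & ref_pos)),
        fn=int(np.sum(~dev_pos & ref_pos)),
        fp=int(np.sum(dev_pos & ~ref_pos)),
        tn=int(np.sum(~dev_pos & ~ref_pos)),
    )


def correlation(pairs: PairedMeasures, method: str = "spearman") -> dict:
    """Correlation between device and reference tilt changes.

    Returns the coefficient, its square (for comparability with R^2
    reporting), and the two-sided p-value.  A constant vector makes the
    coefficient undefined; it is returned as ``nan``.
    """
    if len(pairs) < 3:
        raise ValueError(f"correlation requires at least 3 pairs, got {len(pairs)}")
    x, y = pairs.device_delta_deg, pairs.reference_delta_deg
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"coefficient": math.nan, "r_squared": math.nan, "p_value": math.nan,
                "method": method, "n": len(pairs)}
    if method == "spearman":
        res = _scipy_stats.spearmanr(x, y)
    elif method == "pearson":
        res = _scipy_stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    coef = float(res.statistic)
    return {
        "coefficient": coef,
        "r_squared": coef**2,
        "p_value": float(res.pvalue),
        "method": method,
        "n": len(pairs),
    }


def error_distribution(pairs: PairedMeasures) -> dict:
    """Distribution of absolute device-reference errors pooled over
    positions.

    Median and third quartile use linear interpolation between order
    statistics (numpy's default quantile rule); the histogram bins errors
    to the nearest degree and the Poisson rate is the maximum-likelihood
    fit to those integer-binned errors (their sample mean).
    """
    if len(pairs) == 0:
        raise ValueError("no paired measures")
    abs_err = np.abs(pairs.device_delta_deg - pairs.reference_delta_deg)
    binned = np.rint(abs_err).astype(int)
    counts = np.bincount(binned)
    return {
        "n": len(pairs),
        "median": float(np.median(abs_err)),
        "q3": float(np.quantile(abs_err, 0.75)),
        "histogram_counts": counts.tolist(),
        "histogram_bin_deg": list(range(len(counts))),
        "poisson_lambda_mle": float(binned.mean()),
        "quantile_rule": "linear interpolation (numpy default, R type 7)",
    }
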