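"""Agreement analysis between a reference and a test measurement method.

For each phenotype parameter the reference series (``ref``, here the laser
scanner) is paired with the actual series (``act``, the photogrammetric
method) and summarized by

* RMSE  = sqrt( mean( (ref_i - act_i)^2 ) )            [parameter units]
* MAPE  = mean( |(ref_i - act_i) / ref_i| ) * 100      [percent]
* ordinary least squares act = slope * ref + intercept, with R^2 the
  squared Pearson correlation,

plus the distribution of absolute relative errors (histogram and the
fraction below 10 %, the customary tolerance between manual measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "MeasurementPairs", "RelativeErrorHistogram", "ParameterAccuracy",
    "AccuracyReport", "rmse", "mape", "regression", "relative_difference",
    "relative_error_histogram", "evaluate_pairs",
]


class PairValidationError(ValueError):
    pass


@dataclass(frozen=True)
class MeasurementPairs:
    """Paired reference/actual values for one parameter."""

    parameter_name: str
    ref: np.ndarray
    act: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", np.asarray(self.ref, dtype=np.float64))
        object.__setattr__(self, "act", np.asarray(self.act, dtype=np.float64))
        if self.ref.ndim != 1 or self.act.ndim != 1:
            raise PairValidationError("ref and act must be 1-D")
        if len(self.ref) != len(self.act):
            raise PairValidationError(
                f"length mismatch: {len(self.ref)} ref vs {len(self.act)} act")
        if len(self.ref) < 1:
            raise PairValidationError("need at least one pair")
        if not (np.isfinite(self.ref).all() and np.isfinite(self.act).all()):
            raise PairValidationError("non-finite measurement values")

    @property
    def n(self) -> int:
        return len(self.ref)


def rmse(pairs: MeasurementPairs) -> float:
    """Root-mean-square error, in the pairs' units."""
    return float(np.sqrt(np.mean((pairs.ref - pairs.act) ** 2)))


def _check_nonzero_ref(pairs: MeasurementPairs) -> None:
    zero = np.flatnonzero(pairs.ref == 0.0)
    if len(zero):
        raise PairValidationError(
            f"reference value is zero at index {int(zero[0])}; "
            "relative errors are undefined")


def mape(pairs: MeasurementPairs) -> float:
    """Mean absolute percentage error relative to the reference, in percent."""
    _check_nonzero_ref(pairs)
    return float(np.mean(np.abs((pairs.ref - pairs.act) / pairs.ref)) * 100.0)


def regression(pairs: MeasurementPairs) -> Tuple[float, float, float]:
    """OLS ``act = slope * ref + intercept``; returns (slope, intercept, R^2)."""
    if pairs.n < 2:
        raise PairValidationError("regression needs at least two pairs")
    if np.ptp(pairs.ref) == 0.0:
        raise PairValidationError("reference series is constant; regression degenerate")
    res = stats.linregress(pairs.ref, pairs.act)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def relative_difference(pre_value: float, post_value: float) -> float:
    """Percent change relative to the pre value: 100 * (pre - post) / pre.

    This is the "Difference (%)" of a pre/post-cleaning comparison; report
    layers round it to one decimal.
    """
    if pre_value == 0.0:
        raise PairValidationError("pre_value must be nonzero")
    return float(100.0 * (pre_value - post_value) / pre_value)


@dataclass(frozen=True)
class RelativeErrorHistogram:
    bin_edges: np.ndarray       # percent, [0, w, 2w, ...]
    counts: np.ndarray
    fraction_below_10pct: float


def relative_error_histogram(pairs: MeasurementPairs,
                             bin_width: float = 5.0) -> RelativeErrorHistogram:
    """Histogram of absolute relative errors (%) in fixed-width bins.

    Bins are ``[0, w), [w, 2w), ...`` up to the largest observed error;
    counts sum to n.  Also reports the fraction of pairs with relative error
    below 10 %.
    """
    _check_nonzero_ref(pairs)
    if bin_width <= 0:
        raise PairValidationError("bin_width must be > 0")
    errors = np.abs((pairs.ref - pairs.act) / pairs.ref) * 100.0
    n_bins = max(int(np.floor(errors.max() / bin_width)) + 1, 1)
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    idx = np.minimum((errors // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return RelativeErrorHistogram(
        bin_edges=edges, counts=counts,
        fraction_below_10pct=float(np.mean(errors < 10.0)),
    )


@dataclass
class ParameterAccuracy:
    """Full agreement summary for one parameter."""

    parameter_name: str
    units: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    mape: float
    relative_errors_pct: np.ndarray
    histogram: RelativeErrorHistogram

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter_name,
            "units": self.units,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "mape_pct": self.mape,
            "fraction_below_10pct": self.histogram.fraction_below_10pct,
            "histogram": {
                "bin_edges_pct": self.histogram.bin_edges.tolist(),
                "counts": self.histogram.counts.tolist(),
            },
        }


def evaluate_pairs(pairs: MeasurementPairs, bin_width: float = 5.0) -> ParameterAccuracy:
    slope, intercept, r2 = regression(pairs)
    hist = relative_error_histogram(pairs, bin_width=bin_width)
    rel = np.abs((pairs.ref - pairs.act) / pairs.ref) * 100.0
    return ParameterAccuracy(
        parameter_name=pairs.parameter_name, units=pairs.units, n=pairs.n,
        slope=slope, intercept=intercept, r_squared=r2,
        rmse=rmse(pairs), mape=mape(pairs),
        relative_errors_pct=rel, histogram=hist,
    )


@dataclass
class AccuracyReport:
    """Agreement summaries for all evaluated parameters."""

    parameters: Dict[str, ParameterAccuracy] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def add(self, pairs: MeasurementPairs, bin_width: float = 5.0) -> ParameterAccuracy:
        acc = evaluate_pairs(pairs, bin_width=bin_width)
        self.parameters[pairs.parameter_name] = acc
        return acc

    def overall_fraction_below_10pct(self) -> float:
        all_errors = np.concatenate(
            [acc.relative_errors_pct for acc in self.parameters.values()])
        return float(np.mean(all_errors < 10.0))

    def to_dict(self) -> dict:
        out = {name: acc.to_dict() for name, acc in self.parameters.items()}
        result = {"parameters": out}
        if self.parameters:
            result["overall_fraction_below_10pct"] = self.overall_fraction_below_10pct()
        result.update(self.extras)
        return result
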