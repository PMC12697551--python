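"""Conformal calibration of reference intervals (the ReForm method).

A naive interval [L(x), U(x)] fitted in a reference population generally
miscovers a new sample whose acquisition or population differs.  Given a
calibration set drawn from the *new* population, split-conformal calibration
restores validity: compute the lower residuals E_i = L(X_i) - Y_i and upper
residuals R_i = Y_i - U(X_i), take the conformal empirical quantile of each
tail, and widen (or tighten) the interval by those two constants:

    [L(x) - c_lower, U(x) + c_upper].

Exchangeability of the calibration set and the new observation is the only
assumption; neither the reference data nor its distribution is needed — a
gridded chart file is enough.  Each tail then miscovers with probability at
most alpha/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ReformError
from .tabular_io import ReferenceInterval, evaluate_bounds, records_to_frame

__all__ = [
    "ResidualSet",
    "CalibrationConstants",
    "compute_residuals",
    "conformal_quantile",
    "reform_calibrate",
    "evaluate_membership",
    "residual_diagnostics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidualSet:
    """Lower and upper conformity scores on a calibration set.

    ``lower_residuals[i] = L(X_i) - Y_i`` (positive when the observation
    undershoots the lower bound) and ``upper_residuals[i] = Y_i - U(X_i)``
    (positive when it overshoots the upper bound).
    """

    lower_residuals: np.ndarray
    upper_residuals: np.ndarray
    alpha: float

    def __post_init__(self):
        lo = np.asarray(self.lower_residuals, float)
        hi = np.asarray(self.upper_residuals, float)
        if lo.ndim != 1 or lo.shape != hi.shape or lo.size < 1:
            raise ConfigError("residual arrays must be equal-length, nonempty 1-D")
        object.__setattr__(self, "lower_residuals", lo)
        object.__setattr__(self, "upper_residuals", hi)

    @property
    def n_calibration(self) -> int:
        return int(self.lower_residuals.size)


@dataclass(frozen=True)
class CalibrationConstants:
    """Conformal adjustment constants with their provenance."""

    c_lower: float
    c_upper: float
    n_calibration: int
    alpha: float
    tail_level_convention: str = "half_alpha"
    overflow_events: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.c_lower) and np.isfinite(self.c_upper)):
            raise ConfigError("calibration constants must be finite")
        if self.overflow_events not in (0, 1, 2):
            raise ConfigError("overflow_events must be 0, 1 or 2")


def compute_residuals(interval: ReferenceInterval, calibration_records) -> ResidualSet:
    """Conformity scores of calibration records against a naive interval."""
    records = list(calibration_records)
    if not records:
        raise ReformError("calibration set is empty")
    if interval.calibrated:
        warnings.warn(
            "computing residuals against an already-calibrated interval",
            stacklevel=2,
        )
    df = records_to_frame(records)
    lo, hi = evaluate_bounds(interval, df["age"].to_numpy(), df["sex"].to_numpy(dtype=object))
    bad = ~(np.isfinite(lo) & np.isfinite(hi))
    if np.any(bad):
        rid = df["subject_id"].to_numpy()[bad][0]
        raise ReformError(f"interval not evaluable at record {rid!r}")
    y = df["value"].to_numpy()
    return ResidualSet(lower_residuals=lo - y, upper_residuals=y - hi, alpha=interval.alpha)


def conformal_quantile(values, level: float, n_calibration: int | None = None):
    """Conformal empirical quantile: the k-th smallest with k = ceil(level*(n+1)).

    When the order index overflows (k > n, which happens for extreme levels
    at small calibration sizes) the maximum value is returned and the
    overflow is reported.  Returns ``(value, overflowed)``.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ReformError("cannot take a conformal quantile of an empty set")
    n = values.size if n_calibration is None else int(n_calibration)
    if n != values.size:
        raise ConfigError(f"n_calibration={n} does not match {values.size} values")
    if not (0 < level < 1):
        raise ConfigError(f"level must be in (0, 1), got {level}")
    k = int(np.ceil(level * (n + 1)))
    ordered = np.sort(values)
    if k > n:
        return float(ordered[-1]), True
    return float(ordered[k - 1]), False


def reform_calibrate(
    interval: ReferenceInterval,
    calibration_records,
    tail_level_convention: str = "half_alpha",
    probe_ages=None,
):
    """Calibrate a naive interval to a new sample's calibration set.

    With the default ``half_alpha`` convention each tail uses the conformal
    quantile at level 1 - alpha/2, giving per-tail miscoverage at most
    alpha/2; ``full_alpha`` uses level 1 - alpha in both tails instead.
    Returns ``(calibrated_interval, constants)``.  Crossed bounds after
    calibration are retained (empty-interval semantics) with a warning noted
    in the interval's provenance.
    """
    if tail_level_convention not in ("half_alpha", "full_alpha"):
        raise ConfigError(
            f"unknown tail-level convention {tail_level_convention!r} "
            "(expected 'half_alpha' or 'full_alpha')"
        )
    residuals = compute_residuals(interval, calibration_records)
    alpha = interval.alpha
    tail_level = 1 - alpha / 2 if tail_level_convention == "half_alpha" else 1 - alpha
    c_lower, ov_lo = conformal_quantile(residuals.lower_residuals, tail_level)
    c_upper, ov_hi = conformal_quantile(residuals.upper_residuals, tail_level)
    constants = CalibrationConstants(
        c_lower=c_lower,
        c_upper=c_upper,
        n_calibration=residuals.n_calibration,
        alpha=alpha,
        tail_level_convention=tail_level_convention,
        overflow_events=int(ov_lo) + int(ov_hi),
    )
    prov = (interval.provenance + " | " if interval.provenance else "") + (
        f"reform(nC={constants.n_calibration}, {tail_level_convention}, "
        f"c_lower={c_lower:.6g}, c_upper={c_upper:.6g})"
    )
    calibrated = interval.shifted(c_lower, c_upper, calibrated=True, provenance=prov)

    if probe_ages is None:
        probe_ages = np.linspace(18.0, 100.0, 41)
    try:
        crossed = False
        for sex in ("F", "M"):
            lo, hi = evaluate_bounds(calibrated, probe_ages, np.full(len(probe_ages), sex, dtype=object))
            if np.any(lo > hi):
                crossed = True
    except ReformError:
        crossed = False  # probe grid outside the interval's support; skip
    if crossed:
        logger.warning("calibrated interval has crossed bounds on the probe grid")
        calibrated.provenance += " | warning: crossed bounds"
    return calibrated, constants


def evaluate_membership(interval: ReferenceInterval, record):
    """Classify one record as 'below', 'inside' or 'above' the interval.

    A value exactly on a bound counts as outside (the tails are defined by
    Y <= L and Y >= U).  With crossed bounds no value is inside; the nearer
    violated bound decides the reported tail.
    """
    lo, hi = evaluate_bounds(interval, [record.age], [record.sex])
    lo, hi = float(lo[0]), float(hi[0])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ReformError(f"interval not evaluable at record {record.subject_id!r}")
    y = record.value
    below, above = y <= lo, y >= hi
    if below and above:  # crossed bounds
        return "below" if abs(y - lo) <= abs(hi - y) else "above"
    if below:
        return "below"
    if above:
        return "above"
    return "inside"


def residual_diagnostics(residuals: ResidualSet, n_bins: int = 20, plot_path=None) -> dict:
    """Per-tail summary of conformity scores for qualitative model checking.

    A tail whose residuals center far from the corresponding naive quantile
    behaviour (e.g. strongly positive upper residuals) signals that the
    reference chart misses that side of the new population.  Fraction
    positive uses the strict > 0 convention.
    """
    out = {"n_calibration": residuals.n_calibration, "alpha": residuals.alpha}
    for name, vals in (
        ("lower", residuals.lower_residuals),
        ("upper", residuals.upper_residuals),
    ):
        counts, edges = np.histogram(vals, bins=n_bins)
        out[name] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals)),
            "quantiles": {
                str(q): float(np.quantile(vals, q))
                for q in (0.05, 0.25, 0.5, 0.75, 0.95)
            },
            "frac_positive": float(np.mean(vals > 0)),
            "hist_counts": counts.tolist(),
            "hist_edges": edges.tolist(),
        }
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, name, vals in (
            (axes[0], "lower residuals  E = L(x) - y", residuals.lower_residuals),
            (axes[1], "upper residuals  R = y - U(x)", residuals.upper_residuals),
        ):
            ax.hist(vals, bins=n_bins, color="steelblue", edgecolor="white")
            ax.axvline(0, color="firebrick", lw=1)
            ax.set_title(name, fontsize=9)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        out["plot_path"] = str(plot_path)
    return out
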