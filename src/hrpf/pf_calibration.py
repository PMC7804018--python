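"""Calibration of the lnPF -> neighbor count prediction line.

Labeled residues' neighbor counts correlate with the natural log of their
protection factors.  An ordinary least-squares line with neighbor count as
the dependent variable,

    predicted count = slope * lnPF + intercept,

turns experimental lnPF values into predicted neighbor counts for scoring.
The published calibration (slope 0.88, intercept 4.42, from mover-ensemble
averaged counts on the benchmark proteins) is the default.  Fit quality is
summarised by R^2 and the normalised RMS error

    NRMSE = sqrt(mean(diff_i^2)) / ybar,

where diff_i = |observed_i - predicted_i| and ybar is the mean observed
count.  The residue-set and angle-midpoint scans reproduce the calibration
protocol: which labeled residue types, and which cone midpoint, give the
tightest line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .exposure import ConeParams, NeighborCountProfile, ensemble_average_counts
from .structure_io import PFTable, ProteinModel

logger = logging.getLogger("hrpf")

#: published prediction line coefficients
DEFAULT_SLOPE = 0.88
DEFAULT_INTERCEPT = 4.42

#: residue-type combinations scanned during calibration, ordered by
#: decreasing intrinsic reactivity of the added types
DEFAULT_RESIDUE_SETS = (
    "WYF", "WYFH", "WYFHL", "WYFHLIR", "WYFHLIRK", "WYFLIRKV", "WYFLIRKVP",
)

#: angle midpoints scanned for the cone (radians)
DEFAULT_ANGLE_MIDPOINTS = (np.pi / 6, np.pi / 4, np.pi / 2, np.pi)


@dataclass(frozen=True)
class CalibrationLine:
    """The lnPF -> neighbor count prediction line."""

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT

    def predict(self, lnpf):
        return self.slope * np.asarray(lnpf, dtype=float) + self.intercept


@dataclass
class RegressionFit:
    """An OLS fit of neighbor count on lnPF with its quality metrics."""

    slope: float
    intercept: float
    nrmse: float
    r_squared: float
    n: int
    y_bar: float
    residue_set: str = ""
    stderr_slope: float = float("nan")

    @property
    def line(self) -> CalibrationLine:
        return CalibrationLine(self.slope, self.intercept)


def nrmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """RMS of |observed - predicted| normalised by the mean observed value."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValidationError("observed and predicted must have equal length")
    if observed.size == 0:
        raise ValidationError("need at least one observation")
    y_bar = observed.mean()
    if y_bar == 0:
        raise ValidationError("mean observed value is zero; NRMSE undefined")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)) / y_bar)


def predict_neighbor_count(lnpf: float, line: CalibrationLine = CalibrationLine()) -> float:
    """Predicted neighbor count for one lnPF value."""
    return float(line.predict(lnpf))


def fit_line(pairs: Sequence[tuple[float, float]], residue_set: str = "") -> RegressionFit:
    """OLS of neighbor count (y) on lnPF (x), with NRMSE and R^2.

    Requires at least 3 pairs and non-degenerate x variance.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 (lnPF, count) pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("lnPF values are all identical; slope undefined")
    res = stats.linregress(x, y)
    predicted = res.slope * x + res.intercept
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        nrmse=nrmse(y, predicted),
        r_squared=float(res.rvalue ** 2),
        n=len(pairs),
        y_bar=float(y.mean()),
        residue_set=residue_set,
        stderr_slope=float(res.stderr),
    )


def _pairs_for_set(pf: PFTable, profile: NeighborCountProfile,
                   codes: frozenset[str]) -> list[tuple[float, float]]:
    pairs = []
    for rec in pf.records:
        if rec.res_type not in codes:
            continue
        count = profile.counts.get((rec.chain_id, rec.seq_num))
        if count is None:
            continue
        pairs.append((rec.lnpf, count))
    return pairs


def scan_residue_sets(sources: Sequence[tuple[PFTable, NeighborCountProfile]],
                      sets: Iterable[str] = DEFAULT_RESIDUE_SETS,
                      ) -> dict[str, RegressionFit]:
    """One pooled fit per residue-type combination.

    *sources* pairs each protein's PF table with its neighbor-count profile;
    pairs are concatenated across proteins before fitting.  Combinations with
    fewer than 3 matching labeled residues are skipped with a warning.
    """
    out: dict[str, RegressionFit] = {}
    for s in sets:
        codes = frozenset(s)
        pairs: list[tuple[float, float]] = []
        for pf, profile in sources:
            pairs.extend(_pairs_for_set(pf, profile, codes))
        if len(pairs) < 3:
            logger.warning("residue set %s: only %d matching residues, skipped",
                           s, len(pairs))
            continue
        try:
            out[s] = fit_line(pairs, residue_set=s)
        except ValidationError as exc:
            logger.warning("residue set %s: %s", s, exc)
    return out


def scan_angle_midpoints(pf: PFTable, models: Sequence[ProteinModel],
                         midpoints: Sequence[float] = DEFAULT_ANGLE_MIDPOINTS,
                         base_params: ConeParams = ConeParams(),
                         residue_set: Optional[str] = None,
                         ) -> dict[float, RegressionFit]:
    """Refit the line for each cone angle midpoint.

    Neighbor counts are ensemble-averaged over *models* and recomputed per
    midpoint; the returned map keys are the midpoints.
    """
    midpoints = list(midpoints)
    if not midpoints:
        raise ValidationError("need at least one angle midpoint")
    codes = frozenset(residue_set) if residue_set else pf.residue_filter
    targets = [(r.chain_id, r.seq_num) for r in pf.records if r.res_type in codes]
    out: dict[float, RegressionFit] = {}
    for m in midpoints:
        params = ConeParams(angle_midpoint=m,
                            angle_steepness=base_params.angle_steepness,
                            dist_midpoint=base_params.dist_midpoint,
                            dist_steepness=base_params.dist_steepness)
        profile = ensemble_average_counts(models, targets, params)
        pairs = _pairs_for_set(pf, profile, codes)
        out[m] = fit_line(pairs, residue_set="".join(sorted(codes)))
    return out
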