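"""The hrf_dynamics score term and decoy rescoring.

For each labeled residue i the model's observed conical neighbor count is
compared with the count predicted from experimental lnPF.  The per-residue
contribution is a sigmoid of the absolute difference,

    score_i = -1.0 / (1 + exp(steepness * (|diff_i| - delta))),

ranging from ~-1 (complete agreement, diff -> 0) to 0 (complete
disagreement); with defaults steepness 2.0 and delta 3.5 the contribution is
exactly -0.5 at |diff| = 3.5.  The model's hrf_dynamics score is the sum over
labeled residues, and the total used for ranking is

    total = weight * hrf_dynamics + base (Ref15) score

with default weight 12.0.  Lower totals rank better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .exposure import ConeParams, neighbor_count_profile
from .pf_calibration import CalibrationLine
from .structure_io import PFTable, ProteinModel

logger = logging.getLogger("hrpf")

DEFAULT_STEEPNESS = 2.0
DEFAULT_DELTA = 3.5
DEFAULT_WEIGHT = 12.0

#: delta sweep grid: 0.5 to 4.5 inclusive, step 0.1
DEFAULT_SWEEP_DELTAS = tuple(np.round(np.arange(0.5, 4.5 + 1e-9, 0.1), 10))


@dataclass(frozen=True)
class ScoreParams:
    """Constants of the hrf_dynamics term and total-score weighting."""

    steepness: float = DEFAULT_STEEPNESS
    delta: float = DEFAULT_DELTA
    weight: float = DEFAULT_WEIGHT
    line: CalibrationLine = field(default_factory=CalibrationLine)
    cone: ConeParams = field(default_factory=ConeParams)

    def __post_init__(self) -> None:
        if self.steepness <= 0 or self.delta <= 0:
            raise ValidationError("steepness and delta must be positive")
        if self.weight < 0:
            raise ValidationError("weight must be non-negative")


@dataclass
class ScoreRecord:
    """Per-model scores: base (Ref15), hrf_dynamics, weighted total, RMSD."""

    model_id: str
    base_score: float
    hrf_score: float
    total_score: float
    rmsd: Optional[float] = None
    per_residue: Optional[dict[tuple[str, int], float]] = None


def per_residue_score(diff, params: ScoreParams = ScoreParams()):
    """Per-residue hrf_dynamics contribution in (-1, 0) for |diff| >= 0."""
    diff = np.asarray(diff, dtype=float)
    if np.any(diff < 0):
        raise ValidationError("diff must be non-negative (absolute difference)")
    return -1.0 / (1.0 + np.exp(params.steepness * (diff - params.delta)))


def _labeled_diffs(model: ProteinModel, pf: PFTable, params: ScoreParams,
                   skip_missing: bool = False, strict: bool = False,
                   ) -> dict[tuple[str, int], float]:
    """|observed - predicted| neighbor count per active labeled residue."""
    active = pf.active_records
    if not active:
        raise ValidationError("PF table has no active labeled residues")
    by_key = model.residue_map()
    targets, predicted = [], []
    for rec in active:
        key = (rec.chain_id, rec.seq_num)
        if key not in by_key:
            if skip_missing:
                logger.warning("labeled residue %s missing from model %s; skipped",
                               key, model.model_id)
                continue
            raise ValidationError(
                f"labeled residue {key} not present in model {model.model_id!r}")
        if by_key[key].res_type != rec.res_type:
            msg = (f"residue type mismatch at {key}: PF table says {rec.res_type}, "
                   f"model {model.model_id!r} has {by_key[key].res_type}")
            if strict:
                raise ValidationError(msg)
            logger.warning(msg)
        targets.append(key)
        predicted.append(params.line.predict(rec.lnpf))
    if not targets:
        raise ValidationError(
            f"no labeled residue present in model {model.model_id!r}")
    profile = neighbor_count_profile(model, targets, params.cone)
    return {t: abs(profile.counts[t] - p) for t, p in zip(targets, predicted)}


def hrf_dynamics_score(model: ProteinModel, pf: PFTable,
                       params: ScoreParams = ScoreParams(),
                       skip_missing: bool = False, strict: bool = False,
                       ) -> tuple[float, dict[tuple[str, int], float]]:
    """Sum of per-residue contributions; returns (score, per-residue map).

    Observed counts come from the single structure being scored; ensemble
    averaging is a calibration-time device only.  *strict* escalates a
    PF-table/model residue-type mismatch from a warning to an error.
    """
    diffs = _labeled_diffs(model, pf, params, skip_missing, strict)
    per_res = {k: float(per_residue_score(d, params)) for k, d in diffs.items()}
    return float(sum(per_res.values())), per_res


def total_score(base: float, hrf: float, params: ScoreParams = ScoreParams()) -> float:
    """Weighted total: weight * hrf_dynamics + base score."""
    return params.weight * hrf + base


def rescore_ensemble(models: Sequence[ProteinModel], pf: PFTable,
                     base_scores: Mapping[str, float],
                     params: ScoreParams = ScoreParams(),
                     keep_per_residue: bool = False,
                     skip_missing: bool = False) -> list[ScoreRecord]:
    """Score every model and rank ascending by total score.

    Ties break on model_id so the ordering is fully deterministic.
    """
    records = []
    for model in models:
        if model.model_id not in base_scores:
            raise ValidationError(f"no base score for model {model.model_id!r}")
        hrf, per_res = hrf_dynamics_score(model, pf, params, skip_missing)
        base = float(base_scores[model.model_id])
        records.append(ScoreRecord(
            model_id=model.model_id,
            base_score=base,
            hrf_score=hrf,
            total_score=total_score(base, hrf, params),
            rmsd=model.meta.get("rmsd_to_native"),
            per_residue=per_res if keep_per_residue else None))
    records.sort(key=lambda r: (r.total_score, r.model_id))
    return records


def select_low_high_sets(records: Sequence[ScoreRecord],
                         models_by_id: Mapping[str, ProteinModel],
                         n_top: int = 10, low_window: float = 5.0,
                         high_cutoff: float = 10.0,
                         ) -> tuple[list[ProteinModel], list[ProteinModel]]:
    """Top-scoring low-/high-RMSD model sets for the delta sweep.

    Low set: the *n_top* best-scoring models whose RMSD lies within
    *low_window* of the best RMSD generated; high set: the *n_top*
    best-scoring models with RMSD above *high_cutoff*.
    """
    with_rmsd = [r for r in records if r.rmsd is not None]
    if not with_rmsd:
        raise ValidationError("records carry no RMSD annotations")
    best_rmsd = min(r.rmsd for r in with_rmsd)
    ranked = sorted(with_rmsd, key=lambda r: (r.total_score, r.model_id))
    low = [r for r in ranked if r.rmsd <= best_rmsd + low_window][:n_top]
    high = [r for r in ranked if r.rmsd > high_cutoff][:n_top]
    return ([models_by_id[r.model_id] for r in low],
            [models_by_id[r.model_id] for r in high])


def delta_sweep(low_set: Sequence[ProteinModel], high_set: Sequence[ProteinModel],
                pf: PFTable, params: ScoreParams = ScoreParams(),
                deltas: Sequence[float] = DEFAULT_SWEEP_DELTAS,
                skip_missing: bool = False) -> list[dict]:
    """Agreement fraction versus delta for low- vs high-RMSD model sets.

    For each delta, reports the percentage (and count) of labeled residues —
    pooled over each set's models — whose |observed - predicted| neighbor
    count difference is <= delta, plus the low-minus-high difference.
    """
    deltas = list(deltas)
    if not deltas:
        raise ValidationError("empty delta list")
    if not low_set or not high_set:
        raise ValidationError("both model sets must be non-empty")

    def pooled_diffs(models: Sequence[ProteinModel]) -> np.ndarray:
        all_d = []
        for m in models:
            all_d.extend(_labeled_diffs(m, pf, params, skip_missing).values())
        return np.asarray(all_d)

    d_low = pooled_diffs(low_set)
    d_high = pooled_diffs(high_set)
    rows = []
    for delta in deltas:
        n_low = int(np.sum(d_low <= delta))
        n_high = int(np.sum(d_high <= delta))
        pct_low = 100.0 * n_low / d_low.size
        pct_high = 100.0 * n_high / d_high.size
        rows.append({"delta": float(delta),
                     "pct_low": pct_low, "n_low": n_low,
                     "pct_high": pct_high, "n_high": n_high,
                     "pct_diff": pct_low - pct_high})
    return rows
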