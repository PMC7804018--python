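"""Structural accuracy and funnel metrics for scored decoy ensembles.

RMSD uses least-squares (Kabsch) superposition over CA atoms; RMSD_SSE
restricts both the superposition and the deviation to residues inside
secondary-structure elements.  Funnel quality is measured by the
Boltzmann-weighted

    P_near = sum_m exp(-rmsd_m^2/lambda^2) exp(-score_m/kT)
             / sum_m exp(-score_m/kT)

with lambda = 2.0 A and kT = 1.0 by default: 1 means every thermodynamically
relevant model sits at the native, 0 means none does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .hrpf_scoring import ScoreRecord
from .structure_io import ProteinModel, SSESpec

DEFAULT_LAMBDA = 2.0  # Angstrom
DEFAULT_KBT = 1.0


@dataclass(frozen=True)
class PnearParams:
    lambda_: float = DEFAULT_LAMBDA
    kbt: float = DEFAULT_KBT

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.kbt <= 0:
            raise ValidationError("lambda and kBT must be positive")


@dataclass
class EnsembleReport:
    """Summary metrics for one scored, RMSD-annotated ensemble."""

    p_near: float
    best_model_id: str
    best_model_rmsd: float
    best_model_rmsd_sse: Optional[float]
    top_n: int
    pct_under_threshold: float
    mean_top_rmsd: float
    n_models: int
    truncated_top_n: bool = False  # fewer records than requested top_n


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal least-squares superposition (proper rotation).

    The SVD-based Kabsch algorithm; a reflection in the optimal orthogonal
    transform is corrected by flipping the smallest singular direction.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError("coordinate arrays must both be N x 3")
    if a.shape[0] < 3:
        raise ValidationError("need at least 3 paired points")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # explicit residual (not the singular-value identity): exact zero for
    # congruent point sets instead of sqrt of a cancellation error
    resid = a @ rot.T - b
    return float(np.sqrt((resid ** 2).sum() / a.shape[0]))


def _paired_ca(model: ProteinModel, native: ProteinModel,
               keys: Optional[set[tuple[str, int]]] = None
               ) -> tuple[np.ndarray, np.ndarray]:
    mmap = model.residue_map()
    nmap = native.residue_map()
    shared = [k for k in nmap if k in mmap]
    if keys is not None:
        shared = [k for k in shared if k in keys]
    shared.sort()
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared residues; need >= 3")
    return (np.array([mmap[k].ca for k in shared]),
            np.array([nmap[k].ca for k in shared]))


def rmsd_to_native(model: ProteinModel, native: ProteinModel,
                   atom_set: str = "CA") -> float:
    """CA Kabsch RMSD over residues common to model and native."""
    if atom_set != "CA":
        raise ValidationError("only the CA atom set is supported")
    a, b = _paired_ca(model, native)
    return kabsch_rmsd(a, b)


def rmsd_sse(model: ProteinModel, native: ProteinModel, sse: SSESpec) -> float:
    """CA Kabsch RMSD restricted to (and superposed on) SSE residues."""
    if not sse.residues:
        raise ValidationError("empty SSE residue set")
    a, b = _paired_ca(model, native, keys=set(sse.residues))
    return kabsch_rmsd(a, b)


def p_near(records: Sequence[ScoreRecord],
           params: PnearParams = PnearParams()) -> float:
    """Funnel metric in [0, 1] over score/RMSD-annotated records.

    Scores are shifted by their minimum before exponentiation; the shift
    cancels exactly between numerator and denominator.
    """
    records = list(records)
    if not records:
        raise ValidationError("empty ensemble")
    rmsds, scores = [], []
    for r in records:
        if r.rmsd is None or not np.isfinite(r.rmsd):
            raise ValidationError(f"record {r.model_id!r} lacks a finite RMSD")
        if not np.isfinite(r.total_score):
            raise ValidationError(f"record {r.model_id!r} lacks a finite score")
        rmsds.append(r.rmsd)
        scores.append(r.total_score)
    rmsds = np.asarray(rmsds)
    scores = np.asarray(scores)
    w = np.exp(-(scores - scores.min()) / params.kbt)
    near = np.exp(-(rmsds ** 2) / params.lambda_ ** 2)
    return float((w * near).sum() / w.sum())


def summarize_ensemble(records: Sequence[ScoreRecord],
                       native: Optional[ProteinModel] = None,
                       models_by_id: Optional[dict[str, ProteinModel]] = None,
                       sse: Optional[SSESpec] = None,
                       top_n: int = 1000, threshold: float = 10.0,
                       params: PnearParams = PnearParams()) -> EnsembleReport:
    """Best-scorer RMSD/RMSD_SSE, P_near, and top-N RMSD summaries.

    If fewer than *top_n* records exist, all are used and the report is
    flagged as truncated.
    """
    records = sorted(records, key=lambda r: (r.total_score, r.model_id))
    if not records:
        raise ValidationError("empty ensemble")
    best = records[0]
    if best.rmsd is None:
        raise ValidationError("records must carry RMSD annotations")
    best_sse = None
    if sse is not None and native is not None and models_by_id is not None:
        best_sse = rmsd_sse(models_by_id[best.model_id], native, sse)
    truncated = len(records) < top_n
    top = records[:top_n]
    top_rmsds = np.array([r.rmsd for r in top], dtype=float)
    return EnsembleReport(
        p_near=p_near(records, params),
        best_model_id=best.model_id,
        best_model_rmsd=float(best.rmsd),
        best_model_rmsd_sse=best_sse,
        top_n=len(top),
        pct_under_threshold=float(100.0 * np.mean(top_rmsds < threshold)),
        mean_top_rmsd=float(top_rmsds.mean()),
        n_models=len(records),
        truncated_top_n=truncated)
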