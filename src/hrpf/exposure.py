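"""Conical neighbor count: a residue burial proxy for covalent labeling.

A residue's exposure is summarised by summing, over every other residue j,
the product of a distance sigmoid and an angle sigmoid:

    count_i = sum_j  1/(1 + exp(s_d (d_ij - m_d))) * 1/(1 + exp(s_a (theta_ij - M)))

with theta_ij the angle between the side-chain direction CB_i - CA_i and the
vector CB_j - CB_i, and d_ij = |CB_j - CB_i|.  Neighbors inside a cone along
the side-chain direction therefore count almost fully; residues behind the
backbone or far away contribute nothing.  Buried residues see many neighbors
(high count), exposed residues few.  Glycine uses an ideal tetrahedral
pseudo-CB constructed from N, CA and C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .structure_io import ProteinModel, Residue

#: default angle midpoint (rad): pi/2, selected to balance NRMSE and R^2
DEFAULT_ANGLE_MIDPOINT = np.pi / 2
#: default angle steepness: 2*pi (dimensionless)
DEFAULT_ANGLE_STEEPNESS = 2 * np.pi
#: distance sigmoid midpoint (Angstrom) and steepness (1/Angstrom),
#: the Rosetta neighbor-count convention
DEFAULT_DIST_MIDPOINT = 9.0
DEFAULT_DIST_STEEPNESS = 1.0

CB_BOND_LENGTH = 1.53  # Angstrom, ideal CA-CB bond for the pseudo-CB
_TETRAHEDRAL = np.deg2rad(109.47122)


@dataclass(frozen=True)
class ConeParams:
    """Constants of the distance and angle sigmoids."""

    angle_midpoint: float = DEFAULT_ANGLE_MIDPOINT
    angle_steepness: float = DEFAULT_ANGLE_STEEPNESS
    dist_midpoint: float = DEFAULT_DIST_MIDPOINT
    dist_steepness: float = DEFAULT_DIST_STEEPNESS

    def __post_init__(self) -> None:
        if not (0 < self.angle_midpoint < np.pi + 1e-12):
            raise ValidationError("angle_midpoint must lie in (0, pi]")
        for name in ("angle_steepness", "dist_midpoint", "dist_steepness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class NeighborCountProfile:
    """Per-residue neighbor counts, possibly averaged over several models."""

    counts: dict[tuple[str, int], float]
    params: ConeParams
    n_models_averaged: int = 1


def angle_contribution(theta, params: ConeParams = ConeParams()):
    """Fraction in (0,1): 1/(1+exp(steepness*(theta - midpoint))).

    *theta* is the cone angle in radians, in [0, pi]; the value is 0.5 at
    the midpoint and decreases toward pi.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12):
        raise ValidationError("theta must lie in [0, pi]")
    return 1.0 / (1.0 + np.exp(params.angle_steepness * (theta - params.angle_midpoint)))


def distance_contribution(d, params: ConeParams = ConeParams()):
    """Fraction in (0,1): 1/(1+exp(steepness*(d - midpoint))), d in Angstrom."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distance must be non-negative")
    return 1.0 / (1.0 + np.exp(params.dist_steepness * (d - params.dist_midpoint)))


def pseudo_cb(residue: Residue) -> np.ndarray:
    """Ideal tetrahedral CB position built from N, CA and C (bond 1.53 A)."""
    if residue.cb is not None:
        return residue.cb
    if residue.n is None or residue.c is None:
        raise ValidationError(
            f"residue {residue.chain_id}{residue.seq_num} ({residue.res_type}) "
            "lacks CB and the N/C backbone atoms needed for a pseudo-CB")
    n1 = residue.n - residue.ca
    n2 = residue.c - residue.ca
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    bisector = n1 + n2
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(n1, n2)
    perp /= np.linalg.norm(perp)
    # choose the out-of-plane tilt so CB makes the tetrahedral angle with N
    c0 = float(np.dot(bisector, n1))
    cos_g = -np.cos(_TETRAHEDRAL) / c0
    cos_g = np.clip(cos_g, -1.0, 1.0)
    sin_g = np.sqrt(1.0 - cos_g ** 2)
    direction = -bisector * cos_g + perp * sin_g
    return residue.ca + CB_BOND_LENGTH * direction


def _coordinate_arrays(model: ProteinModel) -> tuple[np.ndarray, np.ndarray]:
    ca = np.array([r.ca for r in model.residues])
    cb = np.array([pseudo_cb(r) for r in model.residues])
    return ca, cb


def _counts_for_indices(ca: np.ndarray, cb: np.ndarray, indices: Sequence[int],
                        params: ConeParams) -> np.ndarray:
    n = len(ca)
    out = np.empty(len(indices))
    for k, i in enumerate(indices):
        v1 = cb[i] - ca[i]
        norm_v1 = np.linalg.norm(v1)
        if norm_v1 < 1e-9:
            raise ValidationError("degenerate side-chain vector (CB == CA)")
        vecs = cb - cb[i]
        d = np.linalg.norm(vecs, axis=1)
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        # coincident CBs sit at the cone apex: full angle contribution
        safe = np.where(d > 1e-9, d, 1.0)
        cos_t = np.clip(vecs @ v1 / (safe * norm_v1), -1.0, 1.0)
        theta = np.where(d > 1e-9, np.arccos(cos_t), 0.0)
        contrib = distance_contribution(d, params) * angle_contribution(theta, params)
        out[k] = contrib[mask].sum()
    return out


def conical_neighbor_count(model: ProteinModel, target: tuple[str, int],
                           params: ConeParams = ConeParams()) -> float:
    """Conical neighbor count of one residue on one model."""
    if len(model.residues) < 2:
        raise ValidationError("model must contain at least 2 residues")
    ca, cb = _coordinate_arrays(model)
    keys = [r.key for r in model.residues]
    try:
        idx = keys.index(tuple(target))
    except ValueError:
        raise ValidationError(f"residue {target} not found in model {model.model_id!r}")
    return float(_counts_for_indices(ca, cb, [idx], params)[0])


def neighbor_count_profile(model: ProteinModel,
                           residues: Optional[Iterable[tuple[str, int]]] = None,
                           params: ConeParams = ConeParams()) -> NeighborCountProfile:
    """Counts for a set of residues (default: all) on a single model."""
    if len(model.residues) < 2:
        raise ValidationError("model must contain at least 2 residues")
    ca, cb = _coordinate_arrays(model)
    keys = [r.key for r in model.residues]
    if residues is None:
        targets = list(keys)
    else:
        targets = [tuple(t) for t in residues]
    indices = []
    for t in targets:
        try:
            indices.append(keys.index(t))
        except ValueError:
            raise ValidationError(f"residue {t} not found in model {model.model_id!r}")
    counts = _counts_for_indices(ca, cb, indices, params)
    return NeighborCountProfile(counts=dict(zip(targets, counts)), params=params)


def ensemble_average_counts(models: Sequence[ProteinModel],
                            residues: Optional[Iterable[tuple[str, int]]] = None,
                            params: ConeParams = ConeParams(),
                            skip_missing: bool = False,
                            stride: int = 1) -> NeighborCountProfile:
    """Arithmetic mean of per-residue counts over a set of models.

    *stride* subsamples the model list (every stride-th model), the plain
    analogue of extracting trajectory frames at a coarser interval.
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    models = list(models)[::stride]
    if not models:
        raise ValidationError("need at least one model to average over")
    if residues is None:
        residues = [r.key for r in models[0].residues]
    targets = [tuple(t) for t in residues]
    if skip_missing:
        present = [set(r.key for r in m.residues) for m in models]
        targets = [t for t in targets if all(t in p for p in present)]
        if not targets:
            raise ValidationError("no requested residue is present in every model")
    acc = np.zeros(len(targets))
    for m in models:
        prof = neighbor_count_profile(m, targets, params)
        acc += np.array([prof.counts[t] for t in targets])
    acc /= len(models)
    return NeighborCountProfile(counts=dict(zip(targets, acc)), params=params,
                                n_models_averaged=len(models))
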