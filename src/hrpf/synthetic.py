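"""Synthetic natives, decoy ensembles, PF tables and mock base scores.

These generators stand in for the heavyweight inputs of a real study —
crystal-structure natives, ab initio decoy sets, Ref15 score files and
experimental protection factors — so every stage of the method can be
exercised end to end from a seed.  Natives are ideal helical CA/CB traces;
decoys perturb the native with (optionally window-correlated) Gaussian
displacement fields; PF tables are built by inverting the calibration line
on the native's own neighbor counts; base scores are RMSD-correlated
Gaussians with a tunable funnel strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import ValidationError
from .exposure import ConeParams, neighbor_count_profile
from .pf_calibration import CalibrationLine
from .structure_io import PFRecord, PFTable, ProteinModel, Residue

#: ideal alpha-helix CA-trace parameters
HELIX_RISE = 1.5       # Angstrom per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Angstrom
CB_OFFSET = 1.53       # Angstrom, radial CB placement

LABELED_TYPES = "WYFHL"
FILLER_TYPES = "ADEIKNQRSTV"  # no G (keeps CB present), no C/M


@dataclass(frozen=True)
class DecoyConfig:
    """Decoy ensemble parameters: count, per-atom noise scale(s), seed."""

    n_decoys: int = 200
    noise_sigma: Union[float, Sequence[float]] = (0.5, 2.0, 5.0)
    seed: int = 0
    correlated: bool = True
    window: int = 5  # residues; smoothing window for correlated noise

    def __post_init__(self) -> None:
        if self.n_decoys < 1:
            raise ValidationError("n_decoys must be >= 1")
        sigmas = np.atleast_1d(np.asarray(self.noise_sigma, dtype=float))
        if np.any(sigmas < 0):
            raise ValidationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class SyntheticPFConfig:
    """PF-table generation: calibration line, lnPF noise, residue filter."""

    line: CalibrationLine = field(default_factory=CalibrationLine)
    noise_sigma_lnpf: float = 0.0
    residue_filter: str = LABELED_TYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_lnpf < 0:
            raise ValidationError("noise_sigma_lnpf must be >= 0")


def _helix_trace(n: int, origin: np.ndarray, axis_z: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """CA positions and outward radial unit vectors for an ideal helix."""
    i = np.arange(n)
    phi = np.deg2rad(HELIX_TWIST) * i
    radial = np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
    ca = origin + HELIX_RADIUS * radial
    ca[:, 2] += axis_z * HELIX_RISE * i
    return ca, radial


def make_ideal_native(n_residues: int, fold: str = "helix", seed: int = 0) -> ProteinModel:
    """Idealised native: helical CA trace with radially placed CB atoms.

    The sequence is drawn from the generator's RNG but always contains at
    least 10 labeled-eligible residues (types W/Y/F/H/L), interleaved at
    roughly every third position.
    """
    if n_residues < 10:
        raise ValidationError("need at least 10 residues")
    if fold not in ("helix", "helix-bundle"):
        raise ValidationError(f"unknown fold {fold!r}")
    rng = np.random.default_rng(seed)
    if fold == "helix":
        ca, radial = _helix_trace(n_residues, np.zeros(3))
    else:
        # two antiparallel helices 10 A apart joined mid-sequence
        n1 = n_residues // 2
        n2 = n_residues - n1
        ca1, r1 = _helix_trace(n1, np.zeros(3), axis_z=1.0)
        ca2, r2 = _helix_trace(n2, np.array([10.0, 0.0, n1 * HELIX_RISE]), axis_z=-1.0)
        ca = np.vstack([ca1, ca2])
        radial = np.vstack([r1, r2])
    cb = ca + CB_OFFSET * radial

    n_labeled = max(10, n_residues // 3)
    step = max(1, n_residues // n_labeled)
    labeled_pos = list(range(0, n_residues, step))[:n_labeled]
    if len(labeled_pos) < 10:
        labeled_pos = list(range(min(10, n_residues)))
    seq = [FILLER_TYPES[rng.integers(len(FILLER_TYPES))] for _ in range(n_residues)]
    for j, pos in enumerate(labeled_pos):
        seq[pos] = LABELED_TYPES[j % len(LABELED_TYPES)]

    residues = [Residue(chain_id="A", seq_num=i + 1, res_type=seq[i],
                        ca=ca[i], cb=cb[i]) for i in range(n_residues)]
    return ProteinModel(model_id=f"native_{fold}_n{n_residues}_s{seed}",
                        residues=residues, source="synthetic")


def _smooth_field(field_arr: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing along the residue axis, variance-preserving."""
    if window <= 1:
        return field_arr
    kernel = np.ones(window) / window
    out = np.empty_like(field_arr)
    for k in range(3):
        out[:, k] = np.convolve(field_arr[:, k], kernel, mode="same")
    # rescale so per-atom displacement variance matches the requested sigma
    out *= np.sqrt(window)
    return out


def make_decoys(native: ProteinModel, config: DecoyConfig) -> list[ProteinModel]:
    """Perturbed copies of the native with per-decoy achieved RMSD recorded.

    Each decoy displaces every residue (CA and CB jointly) by a Gaussian
    field of scale sigma; correlated mode smooths the field over a sliding
    window so the error is fold-level rather than independent jitter.  The
    achieved CA RMSD to the native is stored in ``model.meta["rmsd_to_native"]``.
    """
    from .evaluation import kabsch_rmsd  # local import: avoid cycle

    rng = np.random.default_rng(config.seed)
    sigmas = np.atleast_1d(np.asarray(config.noise_sigma, dtype=float))
    per_level = [config.n_decoys // len(sigmas)] * len(sigmas)
    for i in range(config.n_decoys - sum(per_level)):
        per_level[i] += 1
    n = len(native.residues)
    ca0 = np.array([r.ca for r in native.residues])
    decoys: list[ProteinModel] = []
    idx = 0
    for sigma, count in zip(sigmas, per_level):
        for _ in range(count):
            idx += 1
            disp = rng.normal(0.0, sigma, size=(n, 3))
            if config.correlated:
                disp = _smooth_field(disp, config.window)
            residues = []
            for r, d in zip(native.residues, disp):
                residues.append(Residue(
                    chain_id=r.chain_id, seq_num=r.seq_num, res_type=r.res_type,
                    ca=r.ca + d, cb=None if r.cb is None else r.cb + d,
                    n=None if r.n is None else r.n + d,
                    c=None if r.c is None else r.c + d, icode=r.icode))
            ca = np.array([x.ca for x in residues])
            achieved = kabsch_rmsd(ca, ca0) if sigma > 0 else 0.0
            m = ProteinModel(model_id=f"decoy_{idx:05d}_sig{sigma:g}",
                             residues=residues, source="synthetic")
            m.meta["rmsd_to_native"] = achieved
            m.meta["noise_sigma"] = float(sigma)
            decoys.append(m)
    return decoys


def make_synthetic_pf(native: ProteinModel, config: SyntheticPFConfig = SyntheticPFConfig(),
                      cone: ConeParams = ConeParams()) -> PFTable:
    """PF table consistent with the calibration line on the native.

    Inverts the prediction line at each eligible residue's observed neighbor
    count, adds Gaussian lnPF noise, and exponentiates: with zero noise the
    native's predicted counts equal its observed counts exactly.
    """
    if config.line.slope == 0:
        raise ValidationError("calibration slope must be non-zero to invert")
    rng = np.random.default_rng(config.seed)
    codes = frozenset(config.residue_filter)
    eligible = [r for r in native.residues if r.res_type in codes]
    if len(eligible) < 3:
        raise ValidationError("native has fewer than 3 residues in the filter")
    profile = neighbor_count_profile(native, [r.key for r in eligible], cone)
    records = []
    for r in eligible:
        count = profile.counts[r.key]
        lnpf = (count - config.line.intercept) / config.line.slope
        lnpf += rng.normal(0.0, config.noise_sigma_lnpf) if config.noise_sigma_lnpf else 0.0
        records.append(PFRecord(chain_id=r.chain_id, seq_num=r.seq_num,
                                res_type=r.res_type, lnpf=lnpf,
                                pf=float(np.exp(lnpf))))
    return PFTable(records=records, residue_filter=codes)


def make_mock_base_scores(rmsd_by_id: Mapping[str, float], funnel_strength: float = 0.5,
                          seed: int = 0, scale: float = 20.0,
                          offset: float = -150.0) -> dict[str, float]:
    """RMSD-correlated mock base scores standing in for Ref15 energies.

    score = scale * (rho * z_rmsd + sqrt(1 - rho^2) * noise) + offset, so the
    Pearson correlation with RMSD is approximately *funnel_strength*; rho = 1
    reproduces the RMSD ranking exactly.
    """
    if not 0.0 <= funnel_strength <= 1.0:
        raise ValidationError("funnel_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = list(rmsd_by_id)
    r = np.array([rmsd_by_id[i] for i in ids], dtype=float)
    sd = r.std()
    z = (r - r.mean()) / sd if sd > 0 else np.zeros_like(r)
    rho = funnel_strength
    noise = rng.standard_normal(len(ids)) if rho < 1.0 else np.zeros(len(ids))
    mixed = rho * z + np.sqrt(1.0 - rho ** 2) * noise
    return {i: float(scale * m + offset) for i, m in zip(ids, mixed)}
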