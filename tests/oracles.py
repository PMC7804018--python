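"""Independent reference implementations used only to cross-check results.

Deliberately written in plain Python / a different algorithm from the
package: the neighbor count as a naive double loop over residue pairs, and
the optimal-superposition RMSD via Horn's quaternion method instead of the
SVD-based Kabsch algorithm.
"""

import math

import numpy as np


def brute_force_neighbor_count(model, target, params):
    """Naive per-pair loop re-deriving the conical neighbor count."""
    from hrpf.exposure import pseudo_cb

    residues = model.residues
    tgt = next(r for r in residues if (r.chain_id, r.seq_num) == tuple(target))
    ca_i = tgt.ca
    cb_i = pseudo_cb(tgt)
    v1 = [cb_i[k] - ca_i[k] for k in range(3)]
    n1 = math.sqrt(sum(x * x for x in v1))
    total = 0.0
    for other in residues:
        if other is tgt:
            continue
        cb_j = pseudo_cb(other)
        v2 = [cb_j[k] - cb_i[k] for k in range(3)]
        d = math.sqrt(sum(x * x for x in v2))
        if d > 1e-9:
            cos_t = sum(a * b for a, b in zip(v1, v2)) / (n1 * d)
            cos_t = min(1.0, max(-1.0, cos_t))
            theta = math.acos(cos_t)
        else:
            theta = 0.0
        dist_c = 1.0 / (1.0 + math.exp(params.dist_steepness * (d - params.dist_midpoint)))
        ang_c = 1.0 / (1.0 + math.exp(params.angle_steepness * (theta - params.angle_midpoint)))
        total += dist_c * ang_c
    return total


def quaternion_rmsd(coords_a, coords_b):
    """Optimal-superposition RMSD via the largest eigenvalue of Horn's
    4x4 quaternion matrix (reflections excluded by construction)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (a ** 2).sum() + (b ** 2).sum()
    msd = max(e0 - 2.0 * lam, 0.0) / a.shape[0]
    return math.sqrt(msd)
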