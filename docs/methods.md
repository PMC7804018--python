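# Methods

## Background and model

Hydroxyl radical protein footprinting (HRPF) exposes a protein to •OH
radicals that covalently modify solvent-exposed side chains; mass
spectrometry then yields, per labeled residue *i*, a labeling rate constant
*k<sub>i</sub>*. Normalising by the residue type's intrinsic reactivity
*R<sub>i</sub>* gives the protection factor, used on the log scale:

    lnPF_i = ln(R_i / k_i)

Higher lnPF means more burial. The package links lnPF to a purely geometric
burial proxy, the **conical neighbor count**,

    count_i = Σ_{j≠i}  D(d_ij) · A(θ_ij)
    D(d)  = 1 / (1 + exp(s_d (d − m_d)))          s_d = 1.0 Å⁻¹, m_d = 9.0 Å
    A(θ)  = 1 / (1 + exp(s_a (θ − M)))            s_a = 2π,      M = π/2

where θ_ij is the angle between the side-chain direction CB_i − CA_i and the
inter-residue vector CB_j − CB_i, and d_ij = |CB_j − CB_i|. Neighbors inside
a cone along the side-chain direction count almost fully; residues behind
the backbone or beyond ~9 Å contribute essentially nothing. Glycine gets an
ideal tetrahedral pseudo-CB constructed from N, CA, C with a 1.53 Å bond.

A calibration line maps experimental lnPF onto a predicted count,

    predicted count = 0.88 · lnPF + 4.42

(the published coefficients, obtained from mover-ensemble-averaged counts on
benchmark proteins, are the package defaults). The **hrf_dynamics** score of
a candidate model sums a per-residue agreement sigmoid over labeled
residues,

    hrf_dynamics = Σ_i  −1 / (1 + exp(2.0 (|diff_i| − 3.5)))

with diff_i the |observed − predicted| count on the structure being scored.
Each term lies in (−1, 0): ≈ −0.999 at perfect agreement, −0.5 at
|diff| = 3.5, → 0 at complete disagreement. The ranking score is

    total = 12.0 · hrf_dynamics + base score

where the base score is an externally supplied all-atom energy (Ref15 in
practice; the package consumes it as a number). Ensembles are summarised by
the best-scoring model's RMSD, RMSD over secondary-structure elements, the
fraction of the top-1000 models under 10 Å, and the funnel metric

    P_near = Σ_m exp(−rmsd_m²/λ²) exp(−score_m/kT) / Σ_m exp(−score_m/kT)

with λ = 2.0 Å and kT = 1.0.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| angle midpoint M | π/2 | rad | cone half-opening where A = 0.5; scanned over {π/6, π/4, π/2, π} during calibration |
| angle steepness | 2π | — | sharpness of the cone edge |
| distance midpoint | 9.0 | Å | CB–CB distance where D = 0.5 (standard neighbor-count convention) |
| distance steepness | 1.0 | Å⁻¹ | decay width of the distance sigmoid |
| slope / intercept | 0.88 / 4.42 | counts per lnPF / counts | calibration line |
| steepness (score) | 2.0 | per count | width of the per-residue agreement sigmoid |
| delta | 3.5 | counts | agreement half-width: per-residue score = −0.5 at this deviation |
| weight | 12.0 | — | hrf_dynamics weight in the total; 1–20 scannable, ≥12 saturating |
| λ, kT | 2.0 Å, 1.0 | — | P_near native-similarity scale and funnel-depth temperature |
| residue filter | WYFHL | — | labeled types scored; high-to-intermediate intrinsic reactivity |

The residue-set scan covers the seven combinations WYF, WYFH, WYFHL,
WYFHLIR, WYFHLIRK, WYFLIRKV, WYFLIRKVP (each must supply ≥ 3 labeled
residues to be fit). C and M are excluded as overly reactive; S, T, D as
unreliable under long exposure.

## Geometry conventions and numerical choices

- **Vector endpoints.** θ_ij uses v₁ = CB_i − CA_i and v₂ = CB_j − CB_i;
  d_ij is CB–CB. These endpoints are configurable in principle but fixed
  here as the package's convention, consistent with cone-based exposure
  metrics in Rosetta. No sequence-separation exclusion is applied: every
  j ≠ i in every chain is a candidate neighbor.
- **Coincident CBs** (d < 10⁻⁹ Å) are treated as sitting on the cone apex
  (θ = 0); a residue whose CB coincides with its CA is rejected.
- **Kabsch RMSD** uses the SVD form with the reflection corrected to a
  proper rotation, and evaluates the residual explicitly after rotating
  (rather than via the singular-value identity), so congruent point sets
  give an exact zero instead of the square root of a cancellation error.
  RMSD is CA-only; RMSD_SSE superposes on the SSE subset itself.
- **P_near** subtracts the minimum score before exponentiating; the shift
  cancels exactly between numerator and denominator, avoiding overflow for
  scores of hundreds of energy units.
- **Ties** in ranking break lexicographically on model id, making every
  ordering, and therefore every output file, deterministic.
- **Residue matching** between PF tables and models is by (chain, author
  residue number); fragment-resolved PF data are plain rows repeating the
  fragment's PF. Labeled residues missing from a model are an error unless
  `skip_missing` is set, because silently dropping them changes the number
  of terms in the hrf_dynamics sum.

## What the synthetic generators emulate

`make_ideal_native` builds a single helix or a two-helix bundle on ideal
α-helix geometry (rise 1.5 Å, 100°/residue, radius 2.3 Å) with CB placed
radially outward; the sequence always contains ≥ 10 residues from WYFHL so
a labeled set exists. `make_decoys` perturbs the native with per-residue
Gaussian displacement fields; in correlated mode the field is smoothed over
a 5-residue window (variance-preserving), which produces fold-level error
rather than uncorrelated jitter — closer in character to ab initio model
error. `make_synthetic_pf` inverts the calibration line at the native's own
neighbor counts and adds Gaussian noise on the lnPF scale (multiplicative
on PF, matching the log form of the protection factor); with zero noise the
native's predicted and observed counts agree exactly, which closes the loop:
the native then attains the minimum achievable hrf_dynamics score.
`make_mock_base_scores` draws scores as a mixture of standardised RMSD and
Gaussian noise with a requested correlation, standing in for a physics-based
energy of tunable funnel quality.

What these generators do **not** reproduce: realistic backbone torsions or
sterics, compact misfolded topologies (decoy error is a displacement field,
not an alternative fold), residue-type-dependent labeling noise, and the
systematic component of real PF/structure disagreement that motivates
ensemble averaging. Passing tests therefore demonstrate the correctness and
internal consistency of the scoring machinery and its discrimination under
controlled noise — not prediction accuracy on experimental data.

## Design choices where the design was open

- **Regression direction.** The calibration regresses neighbor count on
  lnPF, matching the prediction equation's form; R² is the squared Pearson
  correlation (identical to the OLS coefficient of determination here).
  Pooling across proteins concatenates (lnPF, count) pairs without
  per-protein weighting, and pooled NRMSE uses the pooled-fit line.
- **Slope recovery under lnPF noise.** Because synthetic noise enters the
  regressor (lnPF), OLS exhibits classical errors-in-variables attenuation:
  at noise σ = 0.5 against an lnPF spread of ≈ 2 the fitted slope is biased
  low by ≈ 5%. This is inherent to the noise placement, not an estimator
  defect; the recovery test accordingly checks agreement within the
  regression's own slope standard error, the relevant scale of uncertainty
  for an n = 15 fit.
- **Observed counts for scoring** come from the single structure being
  scored; ensemble averaging over models/frames (plain stride subsampling
  for trajectories) is used only upstream, during calibration.
- **Delta sweep pooling.** The agreement percentage pools residues over all
  models of each set (rather than averaging per-model percentages); the
  low-RMSD set is the top-10 scorers within 5 Å of the best RMSD generated,
  the high set the top-10 scorers above 10 Å.
- **Residue-set scan defaults.** Seven unique combinations (above); an
  eighth listed combination is a verbatim repeat of WYFLIRKVP and is not
  duplicated.
- **SSE extraction** unions HELIX/SHEET record ranges with inclusive
  endpoints in author numbering; files without such records require
  user-supplied ranges (`A:5-10`).

## Problem sizes used in the test and acceptance runs

Synthetic studies run at 40–60 residues, 10–200 decoys over noise levels
{0.5, 2, 5} Å, 15–20 labeled residues, and 10–100 seeds per property —
sizes at which every statistical check completes in seconds while the
discrimination and recovery effects are comfortably resolved.

## Known limitations

- Only PDB-format structures (no mmCIF); only CA/CB/N/C atoms are used.
- The base score is consumed as an opaque number; no energy function is
  computed in-package.
- The published calibration line is a default, not re-derived: re-deriving
  it requires the original benchmark structures and mover ensembles.
- Insertion codes are carried but PF matching keys ignore them.
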