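import math

import numpy as np
import pytest

import hrpf
from hrpf.errors import ValidationError


class TestPerResidueScore:
    def test_half_penalty_at_delta(self):
        assert hrpf.per_residue_score(3.5) == pytest.approx(-0.5, abs=1e-15)

    def test_full_agreement_value(self):
        # diff 0 with defaults: -1/(1+e^-7)
        expected = -1.0 / (1.0 + math.exp(-7.0))
        assert hrpf.per_residue_score(0.0) == pytest.approx(expected, rel=1e-12)

    def test_large_disagreement_tail(self):
        expected = -1.0 / (1.0 + math.exp(13.0))
        assert hrpf.per_residue_score(10.0) == pytest.approx(expected, rel=1e-9)
        assert float(hrpf.per_residue_score(10.0)) == pytest.approx(0.0, abs=1e-5)

    def test_bounded_open_interval_over_dense_sweep(self):
        diffs = np.linspace(0.0, 20.0, 10_000)
        vals = hrpf.per_residue_score(diffs)
        assert np.all(vals > -1.0)
        assert np.all(vals < 0.0)
        # strictly increasing toward 0 with growing disagreement
        assert np.all(np.diff(vals) > 0)

    def test_negative_diff_rejected(self):
        with pytest.raises(ValidationError):
            hrpf.per_residue_score(-0.1)


class TestHrfDynamicsScore:
    def test_native_with_noise_free_pf_scores_near_minus_n(self, native60, pf_noise_free):
        score, per_res = hrpf.hrf_dynamics_score(native60, pf_noise_free)
        n = len(per_res)
        expected = -n / (1.0 + math.exp(-7.0))
        assert score == pytest.approx(expected, abs=1e-9)

    def test_bounds(self, native60, pf_noise_free):
        decoys = hrpf.make_decoys(native60, hrpf.DecoyConfig(n_decoys=5, noise_sigma=3.0,
                                                             seed=1))
        n = len(pf_noise_free.active_records)
        for m in [native60] + decoys:
            score, per_res = hrpf.hrf_dynamics_score(m, pf_noise_free)
            assert -n < score <= 0.0
            assert all(-1.0 < v < 0.0 for v in per_res.values())

    def test_rigid_motion_invariance(self, native60, pf_noise_free):
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("zyx", [1.0, 0.3, -0.8]).as_matrix()
        moved = hrpf.ProteinModel("moved", [
            hrpf.Residue(r.chain_id, r.seq_num, r.res_type,
                         ca=rot @ r.ca + 7.0, cb=rot @ r.cb + 7.0)
            for r in native60.residues])
        s0, _ = hrpf.hrf_dynamics_score(native60, pf_noise_free)
        s1, _ = hrpf.hrf_dynamics_score(moved, pf_noise_free)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_inactive_records_do_not_contribute(self, native60, pf_noise_free):
        extra = hrpf.PFRecord("A", native60.residues[1].seq_num,
                              native60.residues[1].res_type, lnpf=0.5, pf=math.exp(0.5),
                              active=False)
        augmented = hrpf.PFTable(records=pf_noise_free.records + [extra],
                                 residue_filter=pf_noise_free.residue_filter)
        s0, _ = hrpf.hrf_dynamics_score(native60, pf_noise_free)
        s1, _ = hrpf.hrf_dynamics_score(native60, augmented)
        assert s1 == s0

    def test_missing_labeled_residue_errors_unless_skipped(self, native60, pf_noise_free):
        labeled = {(r.chain_id, r.seq_num) for r in pf_noise_free.active_records}
        kept = [r for r in native60.residues if r.key not in list(labeled)[:1]]
        truncated = hrpf.ProteinModel("trunc", [
            hrpf.Residue(r.chain_id, r.seq_num, r.res_type, ca=r.ca, cb=r.cb)
            for r in kept])
        with pytest.raises(ValidationError, match="not present"):
            hrpf.hrf_dynamics_score(truncated, pf_noise_free)
        score, per_res = hrpf.hrf_dynamics_score(truncated, pf_noise_free,
                                                 skip_missing=True)
        assert len(per_res) == len(pf_noise_free.active_records) - 1

    def test_all_inactive_rejected(self, native60, pf_noise_free):
        table = hrpf.PFTable(
            records=[hrpf.PFRecord(r.chain_id, r.seq_num, r.res_type, r.lnpf,
                                   pf=r.pf, active=False)
                     for r in pf_noise_free.records],
            residue_filter=frozenset())
        with pytest.raises(ValidationError, match="active"):
            hrpf.hrf_dynamics_score(native60, table)


class TestTotalScoreAndRescoring:
    def test_weighted_sum(self):
        params = hrpf.ScoreParams(weight=12.0)
        assert hrpf.total_score(-100.0, -20.0, params) == pytest.approx(-340.0)

    def test_zero_hrf_or_zero_weight_leave_base(self):
        assert hrpf.total_score(-55.0, 0.0) == -55.0
        assert hrpf.total_score(-55.0, -9.0, hrpf.ScoreParams(weight=0.0)) == -55.0

    @pytest.fixture
    def scored_setup(self, native60, pf_noise_free):
        decoys = hrpf.make_decoys(native60, hrpf.DecoyConfig(
            n_decoys=20, noise_sigma=(0.5, 2.0, 5.0), seed=4))
        base = hrpf.make_mock_base_scores(
            {d.model_id: d.meta["rmsd_to_native"] for d in decoys},
            funnel_strength=0.5, seed=4)
        return decoys, base

    def test_weight_zero_ranking_equals_base_ranking(self, scored_setup, pf_noise_free):
        decoys, base = scored_setup
        records = hrpf.rescore_ensemble(decoys, pf_noise_free, base,
                                        hrpf.ScoreParams(weight=0.0))
        expected = sorted(base, key=lambda k: (base[k], k))
        assert [r.model_id for r in records] == expected

    def test_lower_diff_model_ranks_better_at_equal_base(self, native60, pf_noise_free):
        decoy = hrpf.make_decoys(native60, hrpf.DecoyConfig(
            n_decoys=1, noise_sigma=4.0, seed=9))[0]
        near = hrpf.ProteinModel("near_native", [
            hrpf.Residue(r.chain_id, r.seq_num, r.res_type, ca=r.ca.copy(),
                         cb=r.cb.copy()) for r in native60.residues])
        base = {"near_native": -100.0, decoy.model_id: -100.0}
        records = hrpf.rescore_ensemble([near, decoy], pf_noise_free, base)
        assert records[0].model_id == "near_native"

    def test_missing_base_score_names_model(self, scored_setup, pf_noise_free):
        decoys, base = scored_setup
        del base[decoys[0].model_id]
        with pytest.raises(ValidationError, match=decoys[0].model_id):
            hrpf.rescore_ensemble(decoys, pf_noise_free, base)

    def test_sort_is_deterministic_with_ties(self, native60, pf_noise_free):
        copies = []
        for name in ("b", "a", "c"):
            copies.append(hrpf.ProteinModel(name, [
                hrpf.Residue(r.chain_id, r.seq_num, r.res_type, ca=r.ca.copy(),
                             cb=r.cb.copy()) for r in native60.residues]))
        base = {"a": -10.0, "b": -10.0, "c": -10.0}
        records = hrpf.rescore_ensemble(copies, pf_noise_free, base)
        assert [r.model_id for r in records] == ["a", "b", "c"]


class TestDeltaSweep:
    def test_identical_sets_have_zero_difference(self, native60, pf_noise_free):
        decoys = hrpf.make_decoys(native60, hrpf.DecoyConfig(
            n_decoys=3, noise_sigma=2.0, seed=6))
        rows = hrpf.delta_sweep(decoys, decoys, pf_noise_free)
        assert all(row["pct_diff"] == 0.0 for row in rows)

    def test_default_grid_has_41_values(self):
        assert len(hrpf.DEFAULT_SWEEP_DELTAS) == 41
        assert hrpf.DEFAULT_SWEEP_DELTAS[0] == pytest.approx(0.5)
        assert hrpf.DEFAULT_SWEEP_DELTAS[-1] == pytest.approx(4.5)

    def test_percentage_monotone_in_delta(self, native60, pf_noise_free):
        low = hrpf.make_decoys(native60, hrpf.DecoyConfig(n_decoys=4, noise_sigma=0.5,
                                                          seed=7))
        high = hrpf.make_decoys(native60, hrpf.DecoyConfig(n_decoys=4, noise_sigma=5.0,
                                                           seed=8))
        rows = hrpf.delta_sweep(low, high, pf_noise_free)
        pct_low = [r["pct_low"] for r in rows]
        pct_high = [r["pct_high"] for r in rows]
        assert all(b >= a for a, b in zip(pct_low, pct_low[1:]))
        assert all(b >= a for a, b in zip(pct_high, pct_high[1:]))
        # low-RMSD models agree better over the sweep
        assert max(r["pct_diff"] for r in rows) > 0

    def test_empty_inputs_rejected(self, native60, pf_noise_free):
        decoys = hrpf.make_decoys(native60, hrpf.DecoyConfig(n_decoys=2, noise_sigma=1.0,
                                                             seed=1))
        with pytest.raises(ValidationError):
            hrpf.delta_sweep(decoys, decoys, pf_noise_free, deltas=[])
        with pytest.raises(ValidationError):
            hrpf.delta_sweep([], decoys, pf_noise_free)


class TestLowHighSelection:
    def test_sets_respect_rmsd_windows(self, native60, pf_noise_free):
        decoys = hrpf.make_decoys(native60, hrpf.DecoyConfig(
            n_decoys=60, noise_sigma=(0.5, 2.0, 8.0), seed=12))
        base = hrpf.make_mock_base_scores(
            {d.model_id: d.meta["rmsd_to_native"] for d in decoys},
            funnel_strength=0.5, seed=12)
        records = hrpf.rescore_ensemble(decoys, pf_noise_free, base)
        by_id = {d.model_id: d for d in decoys}
        low, high = hrpf.select_low_high_sets(records, by_id, n_top=5)
        best_rmsd = min(d.meta["rmsd_to_native"] for d in decoys)
        assert 0 < len(low) <= 5 and 0 < len(high) <= 5
        for m in low:
            assert m.meta["rmsd_to_native"] <= best_rmsd + 5.0
        for m in high:
            assert m.meta["rmsd_to_native"] > 10.0


class TestResidueTypeCrossCheck:
    def test_mismatch_warns_by_default_and_errors_in_strict_mode(
            self, native60, pf_noise_free, caplog):
        import dataclasses
        wrong = [dataclasses.replace(pf_noise_free.records[0],
                                     res_type="W" if pf_noise_free.records[0].res_type != "W"
                                     else "Y")]
        table = hrpf.PFTable(records=wrong + pf_noise_free.records[1:],
                             residue_filter=pf_noise_free.residue_filter)
        with caplog.at_level("WARNING", logger="hrpf"):
            hrpf.hrf_dynamics_score(native60, table)
        assert any("mismatch" in r.message for r in caplog.records)
        with pytest.raises(ValidationError, match="mismatch"):
            hrpf.hrf_dynamics_score(native60, table, strict=True)
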