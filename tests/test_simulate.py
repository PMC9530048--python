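"""Forward simulator: exact integration, protocol builder, noise, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rbcmech import (
    CohortSpec,
    ProtocolSpec,
    SLSParams,
    add_noise,
    analyze_relaxation_curve,
    make_protocol,
    simulate_cohort,
    simulate_cohort_table,
    simulate_relaxation_curve,
    simulate_sls_response,
    simulate_speed_sweep,
)
from rbcmech.exceptions import ProtocolError, SpecError, ValidationError
from rbcmech.simulate import apparent_stiffness, dwell_deflection
from rbcmech.sls import aggregate


class TestSimulatorTheory:
    def test_dwell_matches_closed_form_exponential(self, default_params):
        """Constant-height relaxation equals the analytic exponential."""
        dZ = 1e-6
        d0 = default_params.da(dZ)
        t, Z, d = simulate_sls_response(default_params, [0, 2.0], [dZ, dZ],
                                        2000.0, d0=d0)
        ref = dwell_deflection(default_params, dZ, d0, t)
        assert np.max(np.abs(d - ref)) / np.max(np.abs(ref)) < 1e-9

    def test_quasi_static_ramp_reaches_equilibrium_stiffness(self, default_params):
        """At vanishing speed the dashpot relaxes and stiffness tends to k2."""
        delta, F = apparent_stiffness(default_params, 0.01e-6)
        S = F[-1] / delta[-1]
        assert S == pytest.approx(default_params.k2, rel=0.02)

    def test_fast_ramp_reaches_parallel_spring_stiffness(self, default_params):
        delta, F = apparent_stiffness(default_params, 35000e-6)
        S = F[-1] / delta[-1]
        assert S == pytest.approx(default_params.k1 + default_params.k2, rel=0.02)

    def test_dissipated_work_nonnegative_and_vanishes_without_damping(self):
        """Load-unload hysteresis is non-negative and tends to zero as f -> 0."""
        losses = []
        for f in (2e-3, 2e-5, 2e-7):
            p = SLSParams(k1=0.02, k2=0.01, f=f, kc=0.03)
            t, Z, d = simulate_sls_response(
                p, [0, 0.1, 0.2], [0, 1e-6, 0], 50000.0
            )
            delta = Z - d
            work = np.trapezoid(p.kc * d, delta)
            losses.append(work)
        assert all(w >= -1e-18 for w in losses)
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 5e-3 * losses[0]

    def test_invalid_trajectory_rejected(self, default_params):
        with pytest.raises(ValidationError):
            simulate_sls_response(default_params, [0, 1, 0.5], [0, 1e-6, 0], 100.0)


class TestMakeProtocol:
    def test_ramp_stops_at_target_force(self, default_params, default_protocol):
        proto = make_protocol(default_protocol, default_params)
        t, Z, d = simulate_sls_response(
            default_params, proto["t_knots"], proto["Z_knots"],
            default_protocol.sample_rate,
        )
        i_a = proto["boundaries"]["approach_end"]
        F_a = default_params.kc * d[i_a]
        dF = default_params.kc * (d[i_a] - d[i_a - 1])
        assert abs(F_a - default_protocol.target_force) <= abs(dF) * 1.5

    def test_zero_step_makes_dwell2_continue_dwell1(self, default_params):
        spec = ProtocolSpec(J=0.0)
        curve, truth = simulate_relaxation_curve(default_params, spec)
        d1 = curve.segment("dwell1")
        d2 = curve.segment("dwell2")
        # dwell2 continues the same exponential toward the same asymptote
        ref = dwell_deflection(default_params, truth["dZ"], d1.d[0],
                               d2.t - d1.t[0])
        np.testing.assert_allclose(d2.d, ref, rtol=1e-9)

    def test_sample_rate_does_not_move_boundary_times(self, default_params):
        p1 = make_protocol(ProtocolSpec(sample_rate=2000.0), default_params)
        p2 = make_protocol(ProtocolSpec(sample_rate=4000.0), default_params)
        assert p1["t_a"] == pytest.approx(p2["t_a"], abs=1 / 2000.0)

    def test_unreachable_force_is_protocol_error(self):
        soft = SLSParams(k1=1e-6, k2=1e-6, f=1e-6, kc=0.03)
        with pytest.raises(ProtocolError):
            make_protocol(ProtocolSpec(target_force=2e-9), soft)


class TestAddNoise:
    def test_zero_noise_is_identity(self, clean_relaxation):
        curve, _ = clean_relaxation
        assert add_noise(curve, 0.0, 0.0) is curve

    def test_seed_reproducible(self, clean_relaxation):
        curve, _ = clean_relaxation
        a = add_noise(curve, 1e-9, seed=42)
        b = add_noise(curve, 1e-9, seed=42)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.d, sb.d)

    def test_noise_amplitude_matches_sigma(self, clean_relaxation):
        curve, _ = clean_relaxation
        noisy = add_noise(curve, 1e-9, seed=0)
        resid = np.concatenate(
            [n.d - c.d for n, c in zip(noisy.segments, curve.segments)]
        )
        assert resid.size > 5000
        assert np.std(resid) == pytest.approx(1e-9, rel=0.05)


class TestSpeedSweep:
    def test_apparent_modulus_nondecreasing_in_speed(self, default_params):
        speeds = np.array([0.1, 0.5, 1, 2, 5, 10, 20, 50]) * 1e-6
        pts = simulate_speed_sweep(default_params, speeds)
        E = [e for _, e in pts]
        assert all(b >= a for a, b in zip(E, E[1:]))

    def test_asymptote_ratio_matches_spring_limits(self, default_params):
        pts = simulate_speed_sweep(default_params, [0.005e-6, 5000e-6])
        ratio = pts[1][1] / pts[0][1]
        expected = (default_params.k1 + default_params.k2) / default_params.k2
        assert ratio == pytest.approx(expected, rel=0.1)

    def test_tiny_damping_gives_flat_modulus(self):
        p = SLSParams(k1=0.02, k2=0.01, f=1e-7, kc=0.03)
        pts = simulate_speed_sweep(p, [1e-6, 5e-6, 20e-6])
        E = [e for _, e in pts]
        assert max(E) / min(E) == pytest.approx(1.0, rel=0.02)


class TestCohortGeneration:
    def test_zero_variability_gives_identical_curves(self):
        spec = CohortSpec(n_control=2, n_AD=1, cells_per_subject=2,
                          curves_per_cell=2, subject_cv=0.0, cell_cv=0.0,
                          geometry_cv=0.0, sigma_d=0.0)
        curves, table, truth = simulate_cohort(spec, seed=1)
        ctrl = [c for c in curves if not c.subject_id.startswith("S00")]
        ref = curves[0].segment("dwell1").d
        for c in curves[:4]:  # same group, zero variability
            np.testing.assert_allclose(c.segment("dwell1").d, ref, rtol=1e-12)

    def test_fixed_seed_reproducible(self):
        spec = CohortSpec(n_control=2, n_AD=2, cells_per_subject=1,
                          curves_per_cell=2)
        c1, t1, u1 = simulate_cohort(spec, seed=7)
        c2, t2, u2 = simulate_cohort(spec, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(u1, u2)
        np.testing.assert_array_equal(c1[0].segment("dwell1").d,
                                      c2[0].segment("dwell1").d)

    def test_group_means_recovered_through_pipeline(self):
        """Fitting every generated curve recovers the configured group means."""
        spec = CohortSpec(n_control=5, n_AD=5, cells_per_subject=5,
                          curves_per_cell=8, sigma_d=0.5e-9)
        curves, table, truth = simulate_cohort(spec, seed=3)
        rows = []
        for c in curves:
            fit = analyze_relaxation_curve(c)
            rows.append({"subject_id": c.subject_id, "cell_id": c.cell_id,
                         "k1": fit.k1, "k2": fit.k2, "f": fit.f,
                         "tau_c": fit.tau_c})
        per_curve = pd.DataFrame(rows)
        per_cell = aggregate(per_curve, by="cell_id",
                             fields=("k1", "k2", "f", "tau_c"))
        per_cell["subject_id"] = per_cell["cell_id"].str.split("_").str[0]
        per_subj = aggregate(per_cell, by="subject_id",
                             fields=("k1", "k2", "f", "tau_c"))
        merged = per_subj.merge(table[["subject_id", "group"]], on="subject_id")
        for grp in ("control", "AD"):
            want = dict(zip(("k1", "k2", "f"), spec.group_means(grp)))
            got = merged[merged.group == grp][["k1", "k2", "f"]].mean()
            latent = table[table.group == grp][["k1", "k2", "f"]].mean()
            for p in ("k1", "k2", "f"):
                # fitted group mean tracks the sampled latent mean closely
                assert got[p] == pytest.approx(latent[p], rel=0.05)

    def test_covariate_rank_correlations_match_targets(self):
        spec = CohortSpec(n_control=500, n_AD=500)
        tab = simulate_cohort_table(spec, seed=9)
        for group, targets in spec.rank_corr.items():
            sub = tab[tab.group == group]
            for (cov, mech), rho_target in targets.items():
                rho = sps.spearmanr(sub[cov], sub[mech]).statistic
                assert abs(rho - rho_target) < 0.1, (group, cov, mech)

    def test_non_psd_targets_rejected(self):
        bad = {"control": {("MCV", "k1"): -0.99, ("Hb", "k1"): -0.99,
                           ("MCV", "k2"): 0.99, ("Hb", "k2"): -0.99},
               "AD": {}}
        spec = CohortSpec(rank_corr=bad)
        with pytest.raises(SpecError, match="positive-definite"):
            simulate_cohort_table(spec, seed=0)

    def test_apparent_E_group_null_at_population_scale(self):
        """Configured E effect: group means differ by < 5% (population)."""
        tab = simulate_cohort_table(CohortSpec(n_control=1500, n_AD=1500), seed=4)
        m = tab.groupby("group")["E"].mean()
        assert abs(m["AD"] - m["control"]) / m["control"] < 0.05

    def test_dataset_written_as_tree(self, tmp_path):
        spec = CohortSpec(n_control=1, n_AD=1, cells_per_subject=1,
                          curves_per_cell=2)
        simulate_cohort(spec, out_dir=tmp_path, seed=5)
        assert (tmp_path / "cohort.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        assert len(list(tmp_path.glob("S*/S*_c*/curve_*.tsv"))) == 4
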