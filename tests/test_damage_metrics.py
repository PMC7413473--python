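"""PLI accumulation, platelet shear statistics and tip-volume metrics."""

import numpy as np
import pytest

from cathflow.damage_metrics import (
    PLIParameters,
    TipVolumeSpec,
    ensemble_pli,
    pathline_pli,
    platelet_shear_stats,
    region_integral_average,
    residence_time,
    step_pli,
    tip_volume_stats,
)
from cathflow.fields import AnalyticFieldSpec, make_analytic_field
from cathflow.rheology import BLOOD_CARREAU, CarreauParameters, scalar_shear_stress
from cathflow.tracking import PathLine

PLI = PLIParameters()


def make_line(taus, dts, gdots=None):
    n = len(taus)
    taus = np.asarray(taus, float)
    dts = np.asarray(dts, float)
    gdots = np.asarray(gdots, float) if gdots is not None else taus / 0.00345
    t = np.concatenate([[0.0], np.cumsum(dts)[:-1]])
    return PathLine(
        t=t,
        position=np.zeros((n, 2)),
        velocity=np.zeros((n, 2)),
        fluid_velocity=np.zeros((n, 2)),
        gamma_dot=gdots,
        tau=taus,
        dt=dts,
        termination="max_time",
    )


class TestStepPLI:
    def test_unit_dose_equals_prefactor(self):
        assert step_pli(PLI, 1.0, 1.0) == pytest.approx(3.31e-6)

    def test_zero_time_or_stress_gives_zero(self):
        assert step_pli(PLI, 0.0, 5.0) == 0.0
        assert step_pli(PLI, 5.0, 0.0) == 0.0

    def test_stress_doubling_scales_by_exponent(self):
        lo = step_pli(PLI, 0.5, 3.0)
        hi = step_pli(PLI, 0.5, 6.0)
        assert hi / lo == pytest.approx(2.0**3.075, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            step_pli(PLI, -1.0, 1.0)


class TestPathlinePLI:
    def test_single_step_line(self):
        line = make_line([4.0, 4.0], [0.01, 0.0])
        assert pathline_pli(PLI, line) == pytest.approx(step_pli(PLI, 0.01, 4.0))

    def test_concatenation_additive(self):
        a = make_line([2.0, 3.0, 0.0], [0.01, 0.02, 0.0])
        b = make_line([5.0, 1.0, 0.0], [0.005, 0.01, 0.0])
        joined = make_line([2.0, 3.0, 5.0, 1.0, 0.0],
                           [0.01, 0.02, 0.005, 0.01, 0.0])
        assert pathline_pli(PLI, joined) == pytest.approx(
            pathline_pli(PLI, a) + pathline_pli(PLI, b)
        )

    def test_constant_stress_closed_form(self):
        n, T, tau = 8, 0.04, 6.0
        line = make_line([tau] * (n + 1), [T / n] * n + [0.0])
        expected = 3.31e-6 * n * (T / n) ** 0.77 * tau**3.075
        assert pathline_pli(PLI, line) == pytest.approx(expected, rel=1e-12)


class TestEnsemblePLI:
    def test_identical_lines_equal_single(self):
        line = make_line([2.0, 2.0], [0.01, 0.0])
        v = pathline_pli(PLI, line)
        assert ensemble_pli(PLI, [line, line, line]) == pytest.approx(v)

    def test_mean_bracketed_by_extremes(self):
        lines = [make_line([t, t], [0.01, 0.0]) for t in (1.0, 3.0, 9.0)]
        vals = [pathline_pli(PLI, ln) for ln in lines]
        e = ensemble_pli(PLI, lines)
        assert min(vals) <= e <= max(vals)

    def test_per_step_mode(self):
        a = make_line([2.0, 2.0, 0.0], [0.01, 0.01, 0.0])  # 2 live steps
        b = make_line([4.0, 0.0], [0.01, 0.0])             # 1 live step
        total = pathline_pli(PLI, a) + pathline_pli(PLI, b)
        assert ensemble_pli(PLI, [a, b], mode="per_step") == pytest.approx(total / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_pli(PLI, [])

    def test_monotone_in_stress(self):
        base = make_line([2.0, 3.0, 0.0], [0.01, 0.01, 0.0])
        raised = make_line([2.5, 3.0, 0.0], [0.01, 0.01, 0.0])
        assert ensemble_pli(PLI, [raised]) > ensemble_pli(PLI, [base])


class TestShearStats:
    def test_constant_stress_below_threshold(self):
        line = make_line([5.0, 5.0, 5.0], [0.01, 0.01, 0.0])
        mean, pct, _ = platelet_shear_stats([line], threshold=10.0)
        assert mean == pytest.approx(5.0)
        assert pct == 0.0

    def test_half_time_above_threshold(self):
        line = make_line([20.0, 0.0, 0.0], [0.01, 0.01, 0.0])
        _, pct, _ = platelet_shear_stats([line], threshold=10.0)
        assert pct == pytest.approx(50.0)

    def test_zero_threshold_counts_everything_positive(self):
        line = make_line([1.0, 2.0, 3.0], [0.01, 0.01, 0.0])
        _, pct, _ = platelet_shear_stats([line], threshold=1e-300)
        assert pct == pytest.approx(100.0)

    def test_time_vs_step_weighting_differ_with_nonuniform_dt(self):
        line = make_line([10.0, 2.0, 0.0], [0.03, 0.01, 0.0])
        mean_t, _, _ = platelet_shear_stats([line], weighting="time")
        mean_s, _, _ = platelet_shear_stats([line], weighting="step")
        assert mean_t == pytest.approx((10 * 0.03 + 2 * 0.01) / 0.04)
        assert mean_s == pytest.approx(6.0)

    def test_residence_time_of_capped_line(self):
        line = make_line([1.0, 1.0, 1.0], [0.5, 0.5, 0.0])
        assert residence_time(line) == pytest.approx(1.0)


class TestTipVolumeStats:
    def test_couette_uniform_stress(self):
        # Couette: constant shear rate everywhere -> mean tau exactly tau0
        spec = AnalyticFieldSpec("couette", 0.4, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (26, 21))
        gdot = 0.4 / 0.02
        tau0 = scalar_shear_stress(BLOOD_CARREAU, gdot)
        tv = TipVolumeSpec(bounds=(0.01, 0.04, 0.005, 0.015), threshold=10.0)
        mx, mean_tau, pct = tip_volume_stats(f, tv, BLOOD_CARREAU)
        assert mean_tau == pytest.approx(tau0, rel=1e-9)
        assert pct == (100.0 if tau0 > 10.0 else 0.0)

    def test_poiseuille_mean_stress_matches_integral(self):
        # Newtonian planar Poiseuille: tau = mu |du/dy| linear in y; the
        # region-average over the full gap is mu * 3 U / h
        newt = CarreauParameters(mu_inf=0.001, mu_zero=0.004, lambda_time=1.0,
                                 n_index=1.0)
        U, H = 0.2, 0.02
        spec = AnalyticFieldSpec("poiseuille_planar", U, H, (0.05, H))
        f = make_analytic_field(spec, (11, 161))
        tv = TipVolumeSpec(bounds=(0.01, 0.04, 0.0, H), threshold=10.0)
        _, mean_tau, _ = tip_volume_stats(f, tv, newt)
        exact = 0.004 * 3.0 * U / H
        assert mean_tau == pytest.approx(exact, rel=2e-2)

    def test_max_speed_is_centerline_value(self):
        spec = AnalyticFieldSpec("poiseuille_planar", 0.2, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (11, 41))
        tv = TipVolumeSpec(bounds=(0.01, 0.04, 0.0, 0.02))
        mx, _, _ = tip_volume_stats(f, tv, BLOOD_CARREAU)
        assert mx == pytest.approx(0.3, rel=1e-9)

    def test_threshold_monotonicity(self):
        spec = AnalyticFieldSpec("poiseuille_planar", 0.5, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (11, 41))
        pcts = []
        for thr in (0.5, 1.0, 2.0):
            tv = TipVolumeSpec(bounds=(0.01, 0.04, 0.0, 0.02), threshold=thr)
            pcts.append(tip_volume_stats(f, tv, BLOOD_CARREAU)[2])
        assert pcts[0] >= pcts[1] >= pcts[2]

    def test_region_without_fluid_rejected(self):
        spec = AnalyticFieldSpec("uniform", 0.1, 0.01, (0.05, 0.02))
        f = make_analytic_field(spec, (11, 11))
        f.mask[:, :, :] = False
        f.velocity[:] = 0.0
        tv = TipVolumeSpec(bounds=(0.01, 0.04, 0.005, 0.015))
        with pytest.raises(ValueError, match="no fluid"):
            tip_volume_stats(f, tv, BLOOD_CARREAU)

    def test_integral_average_of_linear_field_exact(self):
        spec = AnalyticFieldSpec("couette", 0.4, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (26, 21))
        u = f.velocity[:, :, 0, 0]  # linear in y
        avg = region_integral_average(f, u, (0.0, 0.05, 0.0, 0.02))
        assert avg == pytest.approx(0.2, rel=1e-12)


class TestPostHocRecomputation:
    def test_platelet_metrics_recomputable_from_csv(self, tmp_path):
        # every Lagrangian metric must be recoverable bit-exactly from the
        # persisted per-step path-line records alone
        import pandas as pd

        from cathflow.rheology import CarreauParameters
        from cathflow.tracking import IntegrationSettings, PathLine, SeedSpec, track_ensemble

        newt = CarreauParameters(mu_inf=0.001, mu_zero=0.004, lambda_time=1.0,
                                 n_index=1.0)
        spec = AnalyticFieldSpec("poiseuille_planar", 0.2, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (26, 21))
        lines = track_ensemble(
            SeedSpec(count=3), None, f, newt,
            settings=IntegrationSettings(target_step=1e-4),
            positions=[(0.002, 0.005), (0.002, 0.011), (0.002, 0.016)],
        )
        path = tmp_path / "pathlines.csv"
        pd.concat([ln.to_frame(i) for i, ln in enumerate(lines)],
                  ignore_index=True).to_csv(path, index=False, float_format="%.17g")

        # 17 significant digits on write plus correctly-rounded parsing on
        # read give a bit-exact round trip
        frame = pd.read_csv(path, float_precision="round_trip")
        rebuilt = []
        for _, grp in frame.groupby("id"):
            rebuilt.append(PathLine(
                t=grp["t"].to_numpy(),
                position=grp[["x", "y"]].to_numpy(),
                velocity=grp[["up", "vp"]].to_numpy(),
                fluid_velocity=grp[["up", "vp"]].to_numpy(),
                gamma_dot=grp["gamma_dot"].to_numpy(),
                tau=grp["tau"].to_numpy(),
                dt=grp["dt"].to_numpy(),
                termination=grp["termination"].iloc[0],
            ))
        assert ensemble_pli(PLI, rebuilt) == ensemble_pli(PLI, lines)
        assert platelet_shear_stats(rebuilt) == platelet_shear_stats(lines)
        assert [residence_time(ln) for ln in rebuilt] == [
            residence_time(ln) for ln in lines
        ]
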