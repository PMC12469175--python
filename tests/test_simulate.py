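"""Fate-model simulators M0-M3: validity, reproducibility, limit behaviour."""

import dataclasses

import numpy as np
import pytest

from persistlin import (EMGParams, FateMatrix, HazardModel, SimConfig,
                        TransitionMatrix, euler_lotka_rate, population_curve,
                        regression_rate, simulate)
from persistlin.simulate import (simulate_M0, simulate_M1, simulate_M2,
                                 simulate_M3)

NEAR_EXP = EMGParams(0.0, 1e-2, 0.05)  # effectively Exp(0.05/h)


def _cfg(**kw):
    defaults = dict(model="M3", n_founders=30)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestEngineBasics:
    @pytest.mark.parametrize("model", ["M0", "M1", "M2", "M3"])
    def test_output_table_validates(self, model):
        res = simulate(_cfg(model=model), seed=1)
        res.table.validate(strict=True)  # raises on violation

    @pytest.mark.parametrize("model", ["M0", "M3"])
    def test_seeded_runs_bit_reproducible(self, model):
        a = simulate(_cfg(model=model), seed=7)
        b = simulate(_cfg(model=model), seed=7)
        assert a.table.to_frame().equals(b.table.to_frame())
        assert a.annotations.equals(b.annotations)

    def test_dt_validation(self):
        with pytest.raises(ValueError):
            SimConfig(model="M0", pre_imt=EMGParams(0.0, 0.01, 30.0), dt=0.05)
        with pytest.warns(UserWarning):
            SimConfig(model="M0", dt=5.0)

    def test_forward_mode_keeps_one_tracked_daughter(self):
        res = simulate(_cfg(model="M2", tracking_mode="forward_lineage"), seed=2)
        t = res.table
        for r in t.records:
            if r.end_event == "division":
                kids = t.children(r.cell_id)
                assert len(kids) == 2
                assert sum(k.tracked for k in kids) == 1
        # tracked population never exceeds the founder count
        _, counts = population_curve(t)
        assert counts.max() <= len(t.founders)

    def test_snapshot_rounding_preserves_validity(self):
        res = simulate(_cfg(model="M3", snapshot_round=True), seed=3)
        res.table.validate(strict=True)
        for r in res.table.records:
            assert r.birth_time == pytest.approx(
                round(r.birth_time / 0.5) * 0.5, abs=1e-9
            )


class TestM0:
    def test_exponential_imt_growth_rate(self):
        cfg = _cfg(model="M0", n_founders=400, pre_imt=NEAR_EXP,
                   t_drug=71.9, t_end=72.0)
        res = simulate_M0(cfg, seed=4)
        t, c = res.population_curve(np.arange(0, 72.5, 0.5))
        slope = regression_rate(t, c).gamma
        assert slope == pytest.approx(0.05, abs=0.006)

    def test_constant_hazard_death_fraction(self):
        """With constant post-drug hazards h_m=0.02, h_a=0.06 the event
        ratio rule makes ~75% of first events deaths."""
        cfg = _cfg(
            model="M0",
            n_founders=600,
            t_drug=2.0,
            t_end=400.0,
            pre_imt=EMGParams(100.0, 1.0, 1.0),  # nobody divides pre-drug
            post_imt=EMGParams(0.0, 1e-2, 0.02),
            post_at=EMGParams(0.0, 1e-2, 0.06),
        )
        res = simulate_M0(cfg, seed=5)
        founders = {r.cell_id for r in res.table.founders}
        ev = [r.end_event for r in res.table.records if r.cell_id in founders]
        deaths = sum(e == "death" for e in ev)
        events = sum(e in ("death", "division") for e in ev)
        assert deaths / events == pytest.approx(0.75, abs=0.06)

    def test_emg_hazards_match_euler_lotka(self):
        imt = EMGParams(13, 2.5, 0.15)
        el = euler_lotka_rate(HazardModel.from_emg(imt)).gamma
        cfg = _cfg(model="M0", n_founders=100, pre_imt=imt,
                   t_drug=71.9, t_end=72.0)
        errs = []
        for s in range(5):
            res = simulate_M0(cfg, seed=s)
            t, c = res.population_curve(np.arange(0, 72.5, 0.5))
            slope = regression_rate(t, c, window=(10.0, 71.5)).gamma
            errs.append(abs(slope - el) / el)
        assert np.mean(errs) < 0.05


class TestM1:
    def test_all_sensitive_population_extinct(self):
        cfg = _cfg(
            model="M1",
            transitions=TransitionMatrix(0.0, 0.0),
            initial_p_fraction=0.0,
            n_founders=40,
            t_end=400.0,
            t_drug=48.0,
        )
        res = simulate_M1(cfg, seed=6)
        _, counts = res.population_curve(np.array([399.9]))
        assert counts[0] == 0
        assert sum(r.end_event == "censored" and r.tracked
                   for r in res.table.records) == 0

    def test_all_persister_no_division_plateau(self):
        cfg = _cfg(
            model="M1",
            transitions=TransitionMatrix(0.0, 0.0),
            initial_p_fraction=1.0,
            fates=FateMatrix((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
            n_founders=40,
        )
        res = simulate_M1(cfg, seed=7)
        t, c = res.population_curve()
        n_drug = c[t == 48.0][0]
        assert np.all(c[t >= 48.0] == n_drug)

    def test_symmetric_switching_reaches_half_half(self):
        cfg = _cfg(
            model="M1",
            transitions=TransitionMatrix(0.05, 0.05),
            initial_p_fraction=0.0,  # start far from stationarity
            n_founders=150,
        )
        res = simulate_M1(cfg, seed=8)
        ann = res.annotations
        at_drug = ann[ann.state_at_drug.notna()]
        frac_p = (at_drug.state_at_drug == "P'").mean()
        # relaxation e^(-2k*48) ~ 0.008: effectively stationary
        assert frac_p == pytest.approx(0.5, abs=0.06)


class TestM2:
    def test_fate_probability_boundaries(self):
        ext = simulate_M2(_cfg(model="M2", m2_fates=(1.0, 0.0, 0.0),
                               n_founders=30, t_end=400.0), seed=9)
        _, c = ext.population_curve(np.array([399.9]))
        assert c[0] == 0
        alive = simulate_M2(_cfg(model="M2", m2_fates=(0.0, 0.0, 1.0),
                                 n_founders=30), seed=10)
        assert all(r.end_event != "death" for r in alive.table.records)

    def test_sister_fates_independent(self):
        """i.i.d. fate assignment leaves sister end-fates uncorrelated."""
        from persistlin.linstats import lineage_fate_correlation

        cfg = _cfg(model="M2", n_founders=120, m2_fates=(0.45, 0.1, 0.45))
        rs = []
        for s in range(6):
            res = simulate_M2(cfg, seed=s)
            out = lineage_fate_correlation(res.table, seed=s)
            if "sister" in out:
                rs.append(out["sister"]["r"])
        assert abs(np.mean(rs)) < 0.08

    def test_decay_rate_monotone_in_death_probability(self):
        slopes = []
        for p_die in (0.2, 0.45, 0.7):
            stay = 1.0 - p_die - 0.1
            cfg = _cfg(model="M2", m2_fates=(p_die, 0.1, stay), n_founders=120)
            got = []
            for s in range(4):
                res = simulate_M2(cfg, seed=s)
                t, c = res.population_curve()
                got.append(regression_rate(t, c, window=(50.0, 85.0)).gamma)
            slopes.append(np.mean(got))
        assert slopes[0] > slopes[1] > slopes[2]


class TestM3:
    def test_frozen_deterministic_fates(self):
        """T=0 with deterministic F: persisters are exactly the P' cells."""
        cfg = _cfg(
            model="M3",
            transitions=TransitionMatrix(0.0, 0.0),
            fates=FateMatrix((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
            initial_p_fraction=0.4,
            n_founders=60,
            t_end=400.0,  # long horizon: every assigned death completes
        )
        res = simulate_M3(cfg, seed=11)
        ann = res.annotations
        at_drug = ann[ann.state_at_drug.notna()].set_index("cell_id")
        for r in res.table.extant_at_drug():
            state = at_drug.loc[r.cell_id, "state_at_drug"]
            if state == "P'":
                assert r.end_event == "censored"
            else:
                assert r.end_event == "death"

    def test_biphasic_shape_with_published_parameters(self, hct116_cfg):
        """Published T and F produce a steep first decay then a plateau."""
        res = simulate(hct116_cfg, seed=12)
        t, c = res.population_curve()
        pre = regression_rate(t, c, window=(5.0, 47.5)).gamma
        first = regression_rate(t, c, window=(50.0, 80.0)).gamma
        late = regression_rate(t, c, window=(100.0, 120.0)).gamma
        assert pre > 0
        assert first < -0.01
        assert first < late  # plateau: slower decay late

    def test_equal_fate_rows_reduce_to_m2(self):
        """With identical F rows the state is irrelevant: persister
        fractions match M2 in distribution."""
        row = (0.5, 0.1, 0.4)
        cfg3 = _cfg(model="M3", fates=FateMatrix(row, row), n_founders=80)
        cfg2 = _cfg(model="M2", m2_fates=row, n_founders=80)
        f3, f2 = [], []
        for s in range(10):
            for cfg, acc in ((cfg3, f3), (cfg2, f2)):
                res = simulate(cfg, seed=100 + s)
                cells = res.table.extant_at_drug()
                surv = [
                    1 if r.end_event == "censored" else 0 for r in cells
                ]
                acc.append(np.mean(surv))
        assert abs(np.mean(f3) - np.mean(f2)) < 0.05

    def test_varying_fate_matrix_spans_decay_rates(self):
        """With IMT and AT fixed, scaling P(die|.) alone sweeps the
        first-phase decay rate."""
        slopes = []
        for scale in (0.6, 1.0):
            F = FateMatrix(
                (0.9125 * scale, 0.05, 1 - 0.9125 * scale - 0.05),
                (0.35 * scale, 0.10, 1 - 0.35 * scale - 0.10),
            )
            cfg = dataclasses.replace(_cfg(n_founders=100), fates=F)
            got = []
            for s in range(4):
                res = simulate_M3(cfg, seed=s)
                t, c = res.population_curve()
                got.append(regression_rate(t, c, window=(50.0, 85.0)).gamma)
            slopes.append(np.mean(got))
        assert slopes[0] > slopes[1]

    def test_barcodes_propagate_unchanged(self):
        res = simulate_M3(_cfg(n_founders=20), seed=13)
        t = res.table
        for r in t.records:
            if r.parent_id is not None:
                assert r.lineage_id == t[r.parent_id].lineage_id
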