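"""Lineage table model: I/O, validation, exclusions, durations, curves."""

import numpy as np
import pytest

from persistlin import (CellRecord, ExperimentConfig, ExperimentTable,
                        LineageValidationError, apply_exclusions,
                        extract_durations, population_curve, read_cell_table,
                        simulate, summary_counts, write_cell_table)
from persistlin.simulate import SimConfig
from persistlin.synth import table_one_fixture


def _rec(cid, parent, lin, b, e, ev, tracked=True):
    return CellRecord(cid, parent, lin, b, e, ev, tracked)


class TestValidation:
    def test_minimal_tree_valid(self, fixtures):
        t = fixtures["three_cell"]
        assert len(t) == 3
        assert len(t.founders) == 1

    def test_time_inconsistency_names_child(self):
        cfg = ExperimentConfig()
        recs = [
            _rec("a", None, "L0", 0.0, 10.0, "division"),
            _rec("a1", "a", "L0", 11.0, 120.0, "censored"),
            _rec("a2", "a", "L0", 10.0, 120.0, "censored"),
        ]
        with pytest.raises(LineageValidationError, match="a1"):
            ExperimentTable(recs, cfg)

    @pytest.mark.parametrize(
        "mutation,match",
        [
            (dict(cell_id="a"), "duplicate"),
            (dict(parent_id="ghost"), "dangling"),
            (dict(end_time=200.0), "outside"),
        ],
    )
    def test_structural_errors(self, mutation, match):
        cfg = ExperimentConfig()
        base = dict(cell_id="b", parent_id=None, lineage_id="L1",
                    birth_time=0.0, end_time=120.0, end_event="censored",
                    tracked=True)
        base.update(mutation)
        recs = [
            _rec("a", None, "L0", 0.0, 120.0, "censored"),
            CellRecord(**base),
        ]
        with pytest.raises(LineageValidationError, match=match):
            ExperimentTable(recs, cfg)

    def test_division_child_count_enforced_in_full_tree(self):
        cfg = ExperimentConfig()
        recs = [
            _rec("a", None, "L0", 0.0, 10.0, "division"),
            _rec("a1", "a", "L0", 10.0, 120.0, "censored"),
        ]
        with pytest.raises(LineageValidationError, match="children"):
            ExperimentTable(recs, cfg)
        ExperimentTable(recs, cfg, strict=False)  # relaxed mode accepts


class TestIO:
    def test_round_trip_on_simulated_table(self, tmp_path):
        res = simulate(SimConfig(model="M3", n_founders=30), seed=5)
        path = tmp_path / "table.csv"
        write_cell_table(res.table, path)
        back = read_cell_table(path, res.table.config)
        assert len(back) == len(res.table)
        for r in res.table.records:
            r2 = back[r.cell_id]
            assert r2.parent_id == r.parent_id
            assert r2.lineage_id == r.lineage_id
            assert r2.end_event == r.end_event
            assert r2.tracked == r.tracked
            assert r2.birth_time == pytest.approx(r.birth_time, abs=1e-6)
            assert r2.end_time == pytest.approx(r.end_time, abs=1e-6)

    def test_bad_row_reports_location(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "cell_id,parent_id,lineage_id,birth_time,end_time,end_event,tracked\n"
            "a,,L0,0.0,10.0,fission,True\n"
        )
        with pytest.raises(LineageValidationError, match="row 2"):
            read_cell_table(p, ExperimentConfig())


class TestExclusions:
    def test_never_divider_removed(self, fixtures):
        t2, rep = apply_exclusions(fixtures["never_divider"])
        assert rep.n_never_dividers == 1
        assert rep.n_pre_drug_deaths == 0
        assert "b" not in t2
        assert len(t2.founders) == 1

    def test_pre_drug_death_removed(self):
        cfg = ExperimentConfig()
        recs = [
            _rec("a", None, "L0", 0.0, 10.0, "division"),
            _rec("a1", "a", "L0", 10.0, 30.0, "death"),
            _rec("a2", "a", "L0", 10.0, 120.0, "censored"),
        ]
        t2, rep = apply_exclusions(ExperimentTable(recs, cfg))
        assert rep.n_pre_drug_deaths == 1
        assert rep.n_never_dividers == 0
        assert "a1" not in t2

    def test_no_double_counting_and_report_arithmetic(self):
        cfg = ExperimentConfig()
        # a founder that dies pre-drug never divided: counted once
        recs = [_rec("a", None, "L0", 0.0, 30.0, "death"),
                _rec("b", None, "L1", 0.0, 20.0, "division"),
                _rec("b1", "b", "L1", 20.0, 120.0, "censored"),
                _rec("b2", "b", "L1", 20.0, 120.0, "censored")]
        _, rep = apply_exclusions(ExperimentTable(recs, cfg))
        assert rep.n_never_dividers == 1
        assert rep.n_pre_drug_deaths == 0
        assert rep.n_excluded == 1
        assert rep.n_included == rep.n_total - rep.n_excluded

    def test_idempotent(self, fixtures):
        t1, _ = apply_exclusions(fixtures["never_divider"])
        t2, rep2 = apply_exclusions(t1)
        assert rep2.n_excluded == 0
        assert len(t2) == len(t1)

    def test_hct116_like_has_no_pre_drug_deaths(self):
        from persistlin import hct116_like

        tbl, _ = hct116_like(seed=0)
        _, rep = apply_exclusions(tbl)
        assert rep.n_pre_drug_deaths == 0
        assert rep.n_never_dividers == 13


class TestDurations:
    def test_window_and_event_filters(self, fixtures):
        t = fixtures["straddler"]  # divide at 40, death at 60, censored 120
        pre = extract_durations(t, "pre", "division")
        assert len(pre) == 1
        assert pre[0].duration == pytest.approx(40.0)
        assert not pre[0].straddles_drug
        post_death = extract_durations(t, "post", "death")
        assert len(post_death) == 1
        assert post_death[0].duration == pytest.approx(20.0)
        assert post_death[0].straddles_drug
        # censored cells only appear with event='any'
        assert all(not d.censored for d in extract_durations(t, "post", "death"))
        anyd = extract_durations(t, "post", "any")
        assert sum(d.censored for d in anyd) == 1

    def test_pre_division_durations_match_generator_mean(self):
        """Founder division durations in a long drug-free window (no
        right-truncation) average the generator's EMG mean mu + 1/lam."""
        cfg = SimConfig(model="M0", n_founders=150, t_drug=100.0, t_end=120.0)
        res = simulate(cfg, seed=9)
        founder_ids = {r.cell_id for r in res.table.founders}
        durs = [
            r.duration
            for r in res.table.records
            if r.cell_id in founder_ids and r.end_event == "division"
        ]
        mean = cfg.pre_imt.mean
        se = np.sqrt(cfg.pre_imt.variance / len(durs))
        # stepping discretization adds up to ~dt of bias
        assert abs(np.mean(durs) - mean) < 4 * se + cfg.dt


class TestPopulationCurve:
    def test_single_survivor_flat(self):
        cfg = ExperimentConfig()
        t = ExperimentTable([_rec("a", None, "L0", 0.0, 120.0, "censored")], cfg)
        grid, counts = population_curve(t)
        assert np.all(counts == 1)

    def test_division_steps_count(self, fixtures):
        grid, counts = population_curve(fixtures["three_cell"])
        assert counts[grid < 10].max() == 1
        assert np.all(counts[grid >= 10] == 2)

    def test_conservation_in_full_tree(self):
        res = simulate(SimConfig(model="M3", n_founders=25), seed=3)
        t = res.table
        grid, counts = population_curve(t)
        n_end = counts[-1]
        n_divisions = sum(r.end_event == "division" for r in t.records)
        n_deaths = sum(r.end_event == "death" for r in t.records)
        # each division adds one net cell; deaths remove one
        assert n_end == len(t.founders) + n_divisions - n_deaths


class TestSummaryCounts:
    def test_printed_census_arithmetic(self):
        """The fixture encodes the published HCT116 tallies: 275 cells at
        drug time, 123 die, 52 both-died pairs -> ~64% full death."""
        sc = summary_counts(table_one_fixture())
        assert sc.n_at_drug == 275
        assert (sc.n_divided, sc.n_died, sc.n_survived) == (112, 123, 40)
        assert (sc.pairs_both_survived, sc.pairs_split, sc.pairs_both_died) == (35, 25, 52)
        assert sc.death_fraction == pytest.approx((123 + 52) / 275)
        assert sc.death_fraction == pytest.approx(0.636, abs=5e-4)

    def test_straddler_daughters_counted_at_drug(self, fixtures):
        # the division at t=40 is pre-drug: both daughters are drug-time
        # cells and no post-drug pair exists
        sc = summary_counts(fixtures["straddler"])
        assert sc.n_at_drug == 2
        assert (sc.n_died, sc.n_survived) == (1, 1)
        assert sc.pairs_split == 0

    def test_split_pair(self, fixtures):
        # ld_toy: x1 divides post-drug into one survivor and one death
        sc = summary_counts(fixtures["ld_toy"])
        assert sc.n_at_drug == 4
        assert sc.pairs_split == 1
        assert sc.pairs_both_survived == 0 and sc.pairs_both_died == 0

    def test_fate_conservation_on_simulation(self):
        res = simulate(SimConfig(model="M3", n_founders=40), seed=4)
        sc = summary_counts(res.table)
        assert sc.n_divided + sc.n_died + sc.n_survived == sc.n_at_drug

    def test_forward_mode_pairs_absent(self):
        res = simulate(
            SimConfig(model="M2", n_founders=30, tracking_mode="forward_lineage"),
            seed=6,
        )
        sc = summary_counts(res.table)
        assert sc.pairs_both_died is None
        assert sc.death_fraction is None
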