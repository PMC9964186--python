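"""Stochastic division and death, the dead-cell switch, and purging."""

import numpy as np
import pytest

from epinvade.cpm_core import (CellTypeParams, LatticeState, PottsConfig,
                               mcs_sweep)
from epinvade.experiments import ExperimentConfig, build_monolayer
from epinvade.turnover import (TurnoverEventLog, apply_turnover, divide_cell,
                               mark_dead, purge_vanished, sample_deaths,
                               sample_divisions)


def _layer(b=0.0, m=0.0, width=60, height=60, **mech):
    params = dict(lambda_area=10.0, lambda_cont=0.5, lambda_adh=-10.0,
                  target_area=100.0)
    params.update(mech)
    cfg = ExperimentConfig(width=width, height=height,
                           cell_types=(CellTypeParams(type_id=1, birth_prob=b,
                                                      death_prob=m, **params),))
    return build_monolayer(cfg), cfg


class TestSampleDeaths:
    def test_zero_mortality_never_selects(self, rng):
        lat, _ = _layer(m=0.0)
        assert all(sample_deaths(lat, rng) == [] for _ in range(20))

    def test_unit_mortality_selects_every_live_cell(self, rng):
        lat, _ = _layer(m=1.0)
        assert sample_deaths(lat, rng) == [int(c) for c in lat.live_ids()]

    def test_dead_cells_are_never_drawn(self, rng):
        lat, _ = _layer(m=1.0)
        mark_dead(lat, 1)
        assert 1 not in sample_deaths(lat, rng)

    def test_binomial_death_rate(self, rng):
        """With n cells at mortality M the draws-per-MCS mean is n*M."""
        lat, _ = _layer(m=0.003)
        n = len(lat.live_ids())
        trials = 4000
        total = sum(len(sample_deaths(lat, rng)) for _ in range(trials))
        expected = n * 0.003
        se = np.sqrt(n * 0.003 * 0.997 / trials)
        assert abs(total / trials - expected) < 3 * se


class TestMarkDead:
    def test_dead_cell_parameter_switch(self):
        lat, _ = _layer()
        rec = mark_dead(lat, 3)
        assert not rec.alive
        assert rec.lambda_cont == 0.0
        assert rec.lambda_adh == 0.0
        assert rec.target_area == 0.0
        assert rec.lambda_area == 200.0
        # bookkeeping identity is preserved
        assert rec.cell_id == 3 and rec.type_id == 1

    def test_double_death_is_a_contract_violation(self):
        lat, _ = _layer()
        mark_dead(lat, 3)
        with pytest.raises(ValueError):
            mark_dead(lat, 3)

    def test_dead_cells_shrink_to_extrusion(self):
        """The raised compressibility with zero target drives monotone
        shrinkage of a corpse surrounded by live cells (trend over replicates)."""
        finals = []
        for seed in range(5):
            lat, _ = _layer(width=30, height=30)
            mark_dead(lat, 5)  # a central cell in the 3x3 tiling
            rng = np.random.default_rng(seed)
            areas = [lat.area_of(5)]
            for _ in range(300):
                mcs_sweep(lat, PottsConfig(), rng)
                areas.append(lat.area_of(5))
            finals.append(areas[-1])
            assert areas[-1] < areas[0]
        assert np.mean(finals) < 20  # most corpses are (nearly) gone


class TestSampleDivisions:
    def test_below_target_area_is_ineligible(self, rng):
        lat, _ = _layer(b=1.0)
        # move one boundary pixel from cell 2 to cell 1
        assert lat.owner[1, 11] == 2
        lat.owner[1, 11] = 1
        lat.recount_cell(1)
        lat.recount_cell(2)
        sel = sample_divisions(lat, rng)
        assert 2 not in sel  # area 99 < A0
        assert 1 in sel      # area 101 >= A0

    def test_at_target_with_unit_probability_always_selected(self, rng):
        lat, _ = _layer(b=1.0)
        assert sample_divisions(lat, rng) == [int(c) for c in lat.live_ids()]

    def test_binomial_division_rate(self, rng):
        lat, _ = _layer(b=0.1, width=100, height=100)
        n = len(lat.live_ids())  # 100 eligible cells at A0
        trials = 1000
        total = sum(len(sample_divisions(lat, rng)) for _ in range(trials))
        se = np.sqrt(n * 0.1 * 0.9 / trials)
        assert abs(total / trials - n * 0.1) < 3 * se


class TestDivideCell:
    def test_daughters_partition_the_parent(self, rng):
        lat, _ = _layer()
        others = {int(c): lat.owner[lat.owner == c].size for c in lat.ids() if c != 5}
        pair = divide_cell(lat, 5, rng)
        assert pair is not None
        parent, daughter = pair
        a, b = lat.area_of(parent), lat.area_of(daughter)
        assert a + b == 100
        assert abs(a - 50) <= 10  # centroid cut of a square is near-even
        # locality: no other cell's pixels change
        for cid, area in others.items():
            assert lat.area_of(cid) == area
        lat.validate()

    def test_tiny_cell_division_skipped(self, rng):
        owner = np.zeros((3, 3), np.int32)
        owner[1, 1] = 1
        lat = LatticeState.from_grid(
            owner, {1: CellTypeParams(1, 1.0, 0.0, 0.0, 1.0)})
        assert divide_cell(lat, 1, rng) is None

    def test_daughters_regrow_toward_target(self):
        """After division among compliant neighbours, daughters regrow most
        of the way back to the target area within a couple hundred MCS."""
        soft = CellTypeParams(type_id=1, lambda_area=0.05, lambda_cont=0.0,
                              lambda_adh=-2.0, target_area=100.0)
        firm = CellTypeParams(type_id=1, lambda_area=10.0, lambda_cont=0.5,
                              lambda_adh=-2.0, target_area=100.0)
        cfg = ExperimentConfig(width=60, height=60, cell_types=(soft,))
        lat = build_monolayer(cfg)
        centre = 15  # middle cell of the 6x6 tiling
        lat._lam_area[centre] = firm.lambda_area
        lat._lam_cont[centre] = firm.lambda_cont
        rng = np.random.default_rng(2)
        parent, daughter = divide_cell(lat, centre, rng)
        lat._lam_area[daughter] = firm.lambda_area
        lat._lam_cont[daughter] = firm.lambda_cont
        for _ in range(200):
            mcs_sweep(lat, PottsConfig(), rng)
        mean_daughter = 0.5 * (lat.area_of(parent) + lat.area_of(daughter))
        assert mean_daughter > 0.8 * 100.0


class TestPurge:
    def test_nothing_to_purge(self):
        lat, _ = _layer()
        assert purge_vanished(lat) == []

    def test_vanished_dead_cell_removed(self, rng):
        lat, _ = _layer(width=30, height=30)
        mark_dead(lat, 5)
        rng = np.random.default_rng(3)
        for _ in range(600):
            mcs_sweep(lat, PottsConfig(), rng)
            if lat.area_of(5) == 0:
                break
        assert lat.area_of(5) == 0
        assert purge_vanished(lat) == [5]
        assert 5 not in lat.ids()
        lat.validate()


class TestTurnoverProtocol:
    def test_no_turnover_leaves_registry_invariant(self, rng):
        lat, _ = _layer(b=0.0, m=0.0, width=30, height=30)
        ids0 = list(lat.ids())
        log = TurnoverEventLog()
        for mcs in range(50):
            mcs_sweep(lat, PottsConfig(), rng)
            apply_turnover(lat, rng, mcs=mcs, event_log=log)
        assert list(lat.ids()) == ids0
        assert len(log) == 0

    def test_pure_death_reaches_extinction(self):
        """With B=0 and M>0 the live population is non-increasing and dies out."""
        lat, _ = _layer(b=0.0, m=0.02, width=30, height=30)
        rng = np.random.default_rng(11)
        prev = len(lat.live_ids())
        for mcs in range(4000):
            mcs_sweep(lat, PottsConfig(), rng)
            apply_turnover(lat, rng, mcs=mcs)
            live = len(lat.live_ids())
            assert live <= prev
            prev = live
            if live == 0 and len(lat.ids()) == 0:
                break
        assert prev == 0

    def test_event_log_is_reproducible(self):
        lat1, _ = _layer(b=0.05, m=0.005, width=30, height=30)
        lat2, _ = _layer(b=0.05, m=0.005, width=30, height=30)
        logs = []
        for lat, seed in ((lat1, 9), (lat2, 9)):
            rng = np.random.default_rng(seed)
            log = TurnoverEventLog()
            for mcs in range(200):
                mcs_sweep(lat, PottsConfig(), rng)
                apply_turnover(lat, rng, mcs=mcs, event_log=log)
            logs.append(log.to_frame())
        assert logs[0].equals(logs[1])
        assert np.array_equal(lat1.owner, lat2.owner)

    def test_division_conserves_pixels(self):
        lat, _ = _layer(b=0.5, m=0.0, width=40, height=40)
        rng = np.random.default_rng(4)
        free = lat.free_pixel_count
        for mcs in range(30):
            mcs_sweep(lat, PottsConfig(), rng)
            apply_turnover(lat, rng, mcs=mcs)
            assert int(lat._area.sum()) == free
        lat.validate()
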