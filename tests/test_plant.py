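"""Plant physiology and root growth: initialization, demand, delivery,
allocation, elongation/branching bookkeeping."""

import math

import numpy as np
import pytest

from rhizosim.constants import ModelConstants
from rhizosim.genotype import Genotype
from rhizosim.plant import (
    delivered_water,
    grow_roots,
    init_plant,
    segment_cost,
    shoot_fraction,
    water_demands,
    water_to_growth,
)
from rhizosim.soil import SoilParams


def make_genotype(**overrides):
    base = dict(
        rotang=0.5,
        branchang=1.0,
        gravitrop=0.1,
        basezonelength=10.0,
        basezonep=0.5,
        maxorder=4,
        orderweightings=1.0,
        kshoot1=0.0,
        kshoot2=0.0,
    )
    base.update(overrides)
    return Genotype(**base)


BASE = np.array([100.0, 100.0, 0.0])


class TestInit:
    def test_single_downward_segment_no_shoot(self):
        plant = init_plant(make_genotype(), BASE)
        assert plant.n_segments == 1
        assert plant.n_branches == 1
        assert plant.shoot_biomass == 0.0
        np.testing.assert_allclose(plant.seg_end[0], [100.0, 100.0, 2.0])

    def test_segment_length_passthrough(self):
        c = ModelConstants(segment_length=5.0)
        plant = init_plant(make_genotype(), BASE, constants=c)
        assert plant.seg_end[0, 2] == pytest.approx(5.0)

    def test_root_biomass_is_cylinder_cost(self):
        plant = init_plant(make_genotype(), BASE)
        expected = math.pi * 0.5**2 * 2.0 * 0.001
        assert plant.root_biomass == pytest.approx(expected)

    def test_off_surface_base_rejected(self):
        with pytest.raises(ValueError):
            init_plant(make_genotype(), np.array([100.0, 100.0, 5.0]))


class TestSegmentCost:
    def test_default_cylinder(self):
        assert segment_cost(ModelConstants()) == pytest.approx(0.0015708, rel=1e-4)

    def test_quadratic_in_radius(self):
        c1 = ModelConstants(root_radius=0.5)
        c2 = ModelConstants(root_radius=1.0)
        assert segment_cost(c2) == pytest.approx(4 * segment_cost(c1))


class TestWaterDemands:
    def test_single_segment_demands_twenty(self):
        plant = init_plant(make_genotype(), BASE)
        demands = water_demands(plant)
        assert len(demands) == 1
        (voxel, volume, sid) = demands[0]
        assert voxel == (5, 5, 0)
        assert volume == pytest.approx(20.0)

    def test_per_segment_demand_independent_of_crowding(self):
        # three segments of one straight axis share the first 20 mm voxel
        # column: the first voxel holds segments 0-9 of a vertical axis
        plant = init_plant(make_genotype(gravitrop=0.0, basezonep=0.0, basezonelength=1e9), BASE)
        for _ in range(4):
            grow_roots(plant, 1.0)  # abundant budget, no branching
        demands = water_demands(plant)
        volumes = [v for _, v, _ in demands]
        assert all(v == pytest.approx(20.0) for v in volumes)

    def test_below_floor_segments_demand_nothing(self):
        params = SoilParams(nz=1)  # 20 mm deep world
        plant = init_plant(make_genotype(gravitrop=0.0, basezonep=0.0, basezonelength=1e9),
                           BASE, soil_params=params)
        for _ in range(20):
            grow_roots(plant, 1.0)
        demands = water_demands(plant)
        assert len(demands) == 10  # only the segments inside the 20 mm world


class TestDeliveredWater:
    def test_plain_sum_without_transport_loss(self):
        c = ModelConstants(water_trans_efficiency=0.0)
        plant = init_plant(make_genotype(gravitrop=0.0, basezonep=0.0, basezonelength=1e9),
                           BASE, constants=c)
        grow_roots(plant, 1.0)
        realized = np.full(plant.n_segments, 20.0)
        assert delivered_water(realized, plant) == pytest.approx(20.0 * plant.n_segments)

    def test_no_discount_at_the_base(self):
        plant = init_plant(make_genotype(), BASE)
        assert delivered_water([20.0], plant) == pytest.approx(20.0)

    def test_per_mm_power_discount(self):
        # a segment whose proximal end is 500 mm down the path
        c = ModelConstants(water_trans_efficiency=0.002)
        plant = init_plant(make_genotype(gravitrop=0.0, basezonep=0.0, basezonelength=1e9),
                           BASE, constants=c)
        for _ in range(100):
            grow_roots(plant, 1.0)
        i = int(np.nonzero(np.isclose(plant.seg_path, 500.0))[0][0])
        realized = np.zeros(plant.n_segments)
        realized[i] = 20.0
        assert delivered_water(realized, plant) == pytest.approx(20.0 * 0.998**500, rel=1e-9)


@pytest.mark.parametrize("delivered,expected", [(20.0, 0.0002), (0.0, 0.0), (800.0, 0.008)])
def test_water_to_growth(delivered, expected):
    assert water_to_growth(delivered, ModelConstants()) == pytest.approx(expected)


class TestShootFraction:
    def test_zero_coefficients_give_half(self):
        g = make_genotype(kshoot1=0.0, kshoot2=0.0)
        for allocable in (0.0, 0.01, 5.0):
            assert shoot_fraction(allocable, g) == pytest.approx(0.5)

    def test_large_intercept_saturates(self):
        g = make_genotype(kshoot1=50.0)
        assert shoot_fraction(0.01, g) == pytest.approx(1.0)

    def test_milligram_scaling(self):
        # kshoot1 = 1, kshoot2 = -0.1 per mg, allocable 10 mg -> logistic(0)
        g = make_genotype(kshoot1=1.0, kshoot2=-0.1)
        assert shoot_fraction(0.010, g) == pytest.approx(0.5)

    def test_strictly_inside_unit_interval_and_monotone(self):
        g = make_genotype(kshoot1=-2.0, kshoot2=0.01)
        fracs = [shoot_fraction(a, g) for a in (0.0, 0.1, 0.5, 1.0)]
        assert all(0.0 < f < 1.0 for f in fracs)
        assert fracs == sorted(fracs)


def unbranched(**overrides):
    """Genotype that never branches: single axis growth."""
    return make_genotype(basezonep=0.0, basezonelength=1e9, **overrides)


class TestGrowRoots:
    def test_carryover_bookkeeping_over_two_days(self):
        plant = init_plant(unbranched(gravitrop=0.0), BASE)
        cost = plant.constants.segment_cost
        grow_roots(plant, 10 * cost)  # budget >> demand: funded 5 mm
        assert plant.n_segments == 1 + 2  # floor(5/2)
        assert plant.branch_carryover[0] == pytest.approx(1.0)
        grow_roots(plant, 10 * cost)  # carry 1 + 5 = 6 mm -> 3 segments
        assert plant.n_segments == 1 + 2 + 3
        assert plant.branch_carryover[0] == pytest.approx(0.0)

    def test_zero_budget_changes_nothing(self):
        plant = init_plant(unbranched(), BASE)
        grow_roots(plant, 0.6 * plant.constants.segment_cost)
        carry = plant.branch_carryover.copy()
        n = plant.n_segments
        grow_roots(plant, 0.0)
        assert plant.n_segments == n
        np.testing.assert_allclose(plant.branch_carryover, carry)

    def test_negative_budget_rejected(self):
        plant = init_plant(unbranched(), BASE)
        with pytest.raises(ValueError):
            grow_roots(plant, -1.0)

    def test_zero_gravitropism_grows_straight_down(self):
        plant = init_plant(unbranched(gravitrop=0.0), BASE)
        for _ in range(10):
            grow_roots(plant, 1.0)
        np.testing.assert_allclose(plant.seg_start[:, :2], 100.0)
        depths = np.sort(plant.seg_end[:, 2])
        np.testing.assert_allclose(depths, 2.0 * np.arange(1, plant.n_segments + 1))

    def test_unbranched_axis_hand_trajectory(self):
        # gravitropism pulls a tilted heading towards vertical; with the
        # single axis starting straight down the whole trajectory stays
        # vertical and advances exactly 4 mm (2 whole segments) per day
        plant = init_plant(unbranched(gravitrop=0.25), BASE)
        budget = 2 * plant.constants.segment_cost  # fund exactly 4 mm
        for day in range(5):
            grow_roots(plant, budget)
        assert plant.n_segments == 1 + 10
        np.testing.assert_allclose(plant.seg_end[-1], [100.0, 100.0, 22.0], atol=1e-12)

    def test_budget_split_equal_weights(self):
        # two tips of different order, orderweightings = 1: 50% funding each
        g = make_genotype(orderweightings=1.0, basezonep=1.0, basezonelength=1e9,
                          branchang=1.0, gravitrop=0.0)
        plant = init_plant(g, BASE)
        grow_roots(plant, 1.0)  # creates laterals along the way
        assert plant.n_branches >= 2
        cost = plant.constants.segment_cost
        demand = 5.0 * cost / 2.0  # per tip
        n_tips = plant.n_branches
        n_before = plant.n_segments
        carry_before = plant.branch_carryover.copy()
        grow_roots(plant, n_tips * demand / 2.0)  # half of total demand
        # each tip funded 2.5 mm: carryover + 2.5 split into segments
        new_len = (plant.n_segments - n_before) * 2.0 + plant.branch_carryover.sum() - carry_before.sum()
        assert new_len == pytest.approx(2.5 * n_tips)

    def test_order_weights_favour_high_order(self):
        from rhizosim.plant import _share_budget

        demands = np.full(4, 1.0)
        weights = np.array([1.0, 2.0, 4.0, 8.0])
        alloc = _share_budget(1.0, demands, weights)
        assert alloc[3] > alloc[2] > alloc[1] > alloc[0]
        assert alloc.sum() == pytest.approx(1.0)

    def test_share_budget_caps_and_redistributes(self):
        from rhizosim.plant import _share_budget

        demands = np.array([1.0, 1.0])
        weights = np.array([1.0, 100.0])
        alloc = _share_budget(1.5, demands, weights)
        assert alloc[1] == pytest.approx(1.0)  # capped at demand
        assert alloc[0] == pytest.approx(0.5)  # surplus redistributed

    def test_maxorder_never_exceeded(self):
        g = make_genotype(maxorder=2, basezonep=1.0, basezonelength=0.0,
                          branchang=1.2, rotang=0.8)
        plant = init_plant(g, BASE, rng=np.random.default_rng(7))
        for _ in range(25):
            grow_roots(plant, 0.05)
        assert set(np.unique(plant.seg_order)) <= {0, 1, 2}
        assert plant.branch_order.max() <= 2

    def test_headings_are_unit_vectors(self):
        g = make_genotype(basezonep=1.0, basezonelength=0.0, branchang=1.3,
                          rotang=1.1, gravitrop=0.2)
        plant = init_plant(g, BASE, rng=np.random.default_rng(3))
        for _ in range(15):
            grow_roots(plant, 0.05)
        lengths = np.linalg.norm(plant.seg_end - plant.seg_start, axis=1)
        np.testing.assert_allclose(lengths, 2.0, atol=1e-9)

    def test_gravitropism_monotone_z_heading_on_unbranched_axis(self):
        plant = init_plant(unbranched(gravitrop=0.15, branchang=0.0), BASE)
        # tilt the initial heading artificially to watch it straighten
        plant._b_heading[0] = np.array([math.sin(1.0), 0.0, math.cos(1.0)])
        for _ in range(30):
            grow_roots(plant, 1.0)
        directions = (plant.seg_end - plant.seg_start) / 2.0
        dz = directions[:, 2]
        assert np.all(np.diff(dz[1:]) >= -1e-12)

    def test_biomass_increases_by_whole_segments_only(self):
        plant = init_plant(unbranched(), BASE)
        cost = plant.constants.segment_cost
        before = plant.root_biomass
        grow_roots(plant, 0.4 * cost)  # funds 0.8 mm: no whole segment
        assert plant.root_biomass == before
        assert plant.branch_carryover[0] == pytest.approx(0.8)

    def test_deterministic_given_genotype_and_seed(self):
        g = make_genotype(basezonep=0.6, basezonelength=12.0)
        runs = []
        for _ in range(2):
            plant = init_plant(g, BASE, rng=np.random.default_rng(11))
            for _ in range(20):
                grow_roots(plant, 0.03)
            runs.append((plant.n_segments, plant.seg_end.copy()))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_no_branching_keeps_single_axis(self):
        plant = init_plant(unbranched(), BASE, rng=np.random.default_rng(5))
        for _ in range(30):
            grow_roots(plant, 1.0)
        assert plant.n_branches == 1
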