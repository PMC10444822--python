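"""Growing-domain simulation: insertion events, growth modes, symmetries."""

import numpy as np
import pytest
from dataclasses import replace

from dentalcascade.errors import SimulationError
from dentalcascade.io import events_to_frame
from dentalcascade.kinetics import get_kinetics
from dentalcascade.rd_simulator import (
    Detection,
    GradientSpec,
    Grid,
    GrowthSchedule,
    InsertionEvent,
    RDParameters,
    gradient_run,
    insertion_sequence_summary,
    linear_stability,
    simulate,
    two_cascade_run,
)

LAMBDA_C = linear_stability(get_kinetics("schnakenberg"), 1.0, 40.0).lambda_c


def static_params(L0, seed=3, **kw):
    return RDParameters(grid=Grid(dx=0.25, dt=0.05, L0=L0), seed=seed, **kw)


class TestParameterValidation:
    def test_inhibitor_must_diffuse_faster(self):
        with pytest.raises(ValueError, match="D_v / D_u"):
            RDParameters(D_u=1.0, D_v=1.0)

    def test_gradient_floor_domain(self):
        with pytest.raises(ValueError, match="floor"):
            GradientSpec(shape="exponential", floor=0.0, scale=1.0)

    def test_growth_schedule_ordering(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            GrowthSchedule(points=((10.0, 1.0), (0.0, 1.0)))

    def test_gradient_target_must_be_kinetic_constant(self):
        p = static_params(12.0, gradient=GradientSpec(
            shape="exponential", target="zeta", floor=0.5, scale=10.0))
        with pytest.raises(ValueError, match="zeta"):
            simulate(p, 5.0, store="final")


class TestStaticDomain:
    def test_single_wavelength_holds_one_peak(self):
        res = simulate(static_params(0.8 * LAMBDA_C), 150.0, store="final")
        assert res.n_events == 1
        assert res.events[0].t_event == 0.0  # the seeded bud itself

    def test_three_wavelengths_match_refined_grid(self):
        """Peak count on a 3-wavelength static domain is 3 +- 1 and agrees
        with a brute-force integration on a 4x finer grid."""
        p = static_params(3.0 * LAMBDA_C)
        res = simulate(p, 200.0, store="final")
        fine = replace(p, grid=replace(p.grid, dx=p.grid.dx / 4, dt=p.grid.dt / 4))
        res_fine = simulate(fine, 200.0, store="final")
        assert abs(res.n_events - 3) <= 1
        assert res.n_events == res_fine.n_events

    def test_stable_regime_relaxes_to_homogeneous_state(self):
        """With the diffusion ratio below critical the analysis reports
        stability and the fields relax to (u*, v*) with no events."""
        kin = get_kinetics("schnakenberg")
        assert not linear_stability(kin, 1.0, 8.0).unstable
        p = RDParameters(D_u=1.0, D_v=8.0, grid=Grid(dx=0.25, dt=0.05, L0=15.0),
                         seed=9, bud_amplitude=0.0)
        res = simulate(p, 100.0, store="final")
        u0, v0 = kin.steady_state()
        assert res.n_events == 0
        assert np.max(np.abs(res.final_state.u - u0)) < 1e-4
        assert np.max(np.abs(res.final_state.v - v0)) < 1e-4


GROWTH = GrowthSchedule(points=((0.0, 0.48), (75.0, 0.48), (76.0, 0.0)),
                        mode="apical", direction="anterior")


class TestGrowth:
    def test_sequential_insertions_toward_growing_end(self):
        p = static_params(12.0, growth=GROWTH, seed=11)
        res = simulate(p, 150.0, store="all")
        assert res.n_events == 3
        xs = [e.x_event for e in res.events]
        assert xs == sorted(xs) and xs[0] == 0.0
        ts = [e.t_event for e in res.events]
        assert ts == sorted(ts)

    def test_grid_length_invariant(self):
        p = static_params(12.0, growth=GROWTH, seed=11)
        res = simulate(p, 80.0, store="all")
        for snap in res.snapshots:
            assert len(snap.u) == round(snap.L / p.grid.dx) + 1

    def test_events_within_domain(self):
        p = static_params(12.0, growth=GROWTH, seed=11)
        res = simulate(p, 150.0, store="all")
        for e in res.events:
            assert 0.0 <= e.x_event <= res.final_state.L

    def test_determinism_same_seed_identical_event_csv(self):
        p = static_params(12.0, growth=GROWTH, seed=4)
        csv1 = events_to_frame(simulate(p, 120.0, store="final").events
                               ).to_csv(index=False)
        csv2 = events_to_frame(simulate(p, 120.0, store="final").events
                               ).to_csv(index=False)
        assert csv1 == csv2

    def test_apical_equals_uniform_without_growth(self):
        zero = GrowthSchedule(points=((0.0, 0.0),), mode="apical")
        pa = static_params(12.0, growth=zero, seed=5)
        pu = replace(pa, growth=replace(zero, mode="uniform"))
        ra = simulate(pa, 30.0, store="final")
        ru = simulate(pu, 30.0, store="final")
        assert np.array_equal(ra.final_state.u, ru.final_state.u)
        assert np.array_equal(ra.final_state.v, ru.final_state.v)

    def test_mirror_symmetry_of_growth_direction(self):
        """Growing at the left end instead of the right reflects event
        positions; cascade coordinates (distance from the bud) coincide."""
        pr = static_params(12.0, growth=GROWTH, seed=7)
        pl = replace(pr, growth=replace(GROWTH, growth_end="left"))
        rr = simulate(pr, 150.0, store="final")
        rl = simulate(pl, 150.0, store="final")
        assert rr.n_events == rl.n_events
        for er, el in zip(rr.events, rl.events):
            assert abs(er.x_event - el.x_event) <= pr.grid.dx
            # lab positions are mirror images about the domain midpoint
            assert abs((rr.final_state.L - el.x_lab) - er.x_lab) <= pr.grid.dx

    def test_growth_monotonicity_in_integrated_growth(self):
        counts = []
        for s in (0.0, 0.5, 1.0, 1.5):
            p = static_params(12.0, growth=GROWTH.scaled(s), seed=11)
            counts.append(simulate(p, 150.0, store="final").n_events)
        assert counts == sorted(counts)

    def test_uniform_growth_dilution_suppresses_insertions(self):
        pa = static_params(12.0, growth=GROWTH, seed=5)
        pu = replace(pa, growth=replace(GROWTH, mode="uniform"))
        ra = simulate(pa, 150.0, store="final")
        ru = simulate(pu, 150.0, store="final")
        assert ru.n_events <= ra.n_events

    def test_unstable_time_step_aborts_with_diagnostic(self):
        p = RDParameters(grid=Grid(dx=0.25, dt=0.6, L0=12.0),
                         kinetics=get_kinetics("schnakenberg", gamma=8.0),
                         seed=1)
        with pytest.raises(SimulationError, match="reduce dt"):
            simulate(p, 10.0, store="final")


class TestTwoCascades:
    def test_zero_growth_gives_two_tied_initial_buds(self):
        zero = GrowthSchedule(points=((0.0, 0.0),), mode="apical",
                              direction="anterior")
        pre = static_params(12.0, growth=zero, cascade="premolar", seed=1)
        mol = replace(pre, growth=replace(zero, direction="posterior"),
                      cascade="molar", seed=2)
        res = two_cascade_run(pre, mol, 60.0, store="final")
        timeline = res.merged_timeline
        assert len(timeline) == 2
        assert timeline[0]["t_event"] == timeline[1]["t_event"] == 0.0
        assert {r["locus_label"] for r in timeline} == {"dP4", "M1"}

    def test_direction_enforcement(self):
        zero = GrowthSchedule(points=((0.0, 0.0),), mode="apical",
                              direction="posterior")
        pre = static_params(12.0, growth=zero, cascade="premolar")
        mol = static_params(12.0, growth=zero, cascade="molar")
        with pytest.raises(ValueError, match="anteriorly"):
            two_cascade_run(pre, mol, 10.0)
        # override runs fine
        two_cascade_run(pre, mol, 1.0, enforce_directions=False, store="final")

    def test_merged_timeline_signs_jaw_axis(self):
        pre = static_params(12.0, growth=GROWTH, cascade="premolar", seed=1)
        mol = replace(pre, growth=replace(GROWTH, direction="posterior"),
                      cascade="molar", seed=2)
        res = two_cascade_run(pre, mol, 150.0, store="final")
        for row in res.merged_timeline:
            if row["cascade"] == "premolar":
                assert row["x_jaw"] <= 0.0
            else:
                assert row["x_jaw"] >= 0.0


class TestGradient:
    def test_uniform_modulation_gives_equal_interior_peaks(self):
        """With m(x) = 1 the pattern is translation-symmetric up to boundary
        effects: interior peak masses agree within 5%."""
        p = static_params(4.0 * LAMBDA_C, seed=3,
                          detection=Detection(size_delay=1e6))
        res = simulate(p, 250.0, store="final")
        L = res.final_state.L
        w = res.min_separation / 2.0
        interior = [e.size_proxy for e in res.events
                    if w < e.x_lab < L - w and e.size_proxy is not None]
        assert len(interior) >= 2
        assert max(interior) / min(interior) < 1.05

    def test_decaying_gradient_orders_molar_sizes(self):
        grad = GradientSpec(shape="exponential", target="b", floor=0.4,
                            scale=30.0)
        p = static_params(12.0, growth=replace(GROWTH, direction="posterior"),
                          gradient=grad, cascade="molar", seed=42)
        res = gradient_run(p, 150.0, store="final")
        sizes = [e.size_proxy for e in res.events]
        assert len(sizes) == 3
        assert sizes[0] > sizes[1] > sizes[2]

    def test_steepening_gradient_shrinks_then_suppresses_last_peak(self):
        """Deepening the posterior gradient (lower floor) monotonically
        shrinks the settled mass of the last molar peak until the M3 is
        suppressed outright."""
        from dentalcascade.config import load_config

        base = load_config("short_jaw_artibeus").molar
        sizes, counts = [], []
        for floor in (0.7, 0.6, 0.5, 0.4, 0.35, 0.3):
            p = replace(base,
                        gradient=replace(base.gradient, floor=floor),
                        detection=replace(base.detection, size_delay=1e6))
            res = simulate(p, 150.0, store="final")
            counts.append(res.n_events)
            if res.n_events == 3:
                sizes.append(res.events[-1].size_proxy)
        assert counts == [3, 3, 3, 3, 3, 2]  # suppressed at the lowest floor
        assert sizes == sorted(sizes, reverse=True)

    def test_gradient_run_requires_active_gradient(self):
        with pytest.raises(ValueError, match="gradient"):
            gradient_run(static_params(12.0), 10.0)


class TestSequenceSummary:
    def test_three_premolar_events_labelled(self):
        events = [InsertionEvent(t, x, "premolar", i + 1)
                  for i, (t, x) in enumerate([(0.0, 0.0), (10.0, 15.0), (20.0, 30.0)])]
        summ = insertion_sequence_summary(events)
        assert summ.locus_labels == ("dP4", "dP3", "P2")
        assert summ.absent == ()
        assert summ.intervals == (10.0, 10.0)

    def test_empty_summary(self):
        summ = insertion_sequence_summary([], cascade="molar")
        assert summ.n_events == 0 and summ.locus_labels == ()
        assert summ.absent == ("M1", "M2", "M3")

    def test_two_molar_events_report_m3_absent(self):
        events = [InsertionEvent(0.0, 0.0, "molar", 1),
                  InsertionEvent(12.0, 14.0, "molar", 2)]
        summ = insertion_sequence_summary(events)
        assert summ.locus_labels == ("M1", "M2") and summ.absent == ("M3",)

    def test_mixed_cascades_rejected(self):
        events = [InsertionEvent(0.0, 0.0, "molar", 1),
                  InsertionEvent(1.0, 0.0, "premolar", 2)]
        with pytest.raises(ValueError, match="multiple cascades"):
            insertion_sequence_summary(events)
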