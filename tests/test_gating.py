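import numpy as np
import pandas as pd
import pytest

from ploidygate import (
    GateLabel,
    GateRegions,
    PipelineConfig,
    analyze_events,
    assign_gates,
    delineate_regions,
    filter_focused,
    filter_singlets,
    find_c1_peak,
    gate_composition,
    generate_population,
)
from ploidygate.errors import (
    DegenerateGatingError,
    EmptyGateError,
    FeatureMissingError,
    InsufficientDataError,
    ValidationError,
)
from ploidygate.gating import auto_focus_threshold

from conftest import clean_config, make_event_set


# ---------------------------------------------------------------------------
# focus filter
# ---------------------------------------------------------------------------

class TestFilterFocused:
    def test_fixed_threshold_partitions_by_metric(self):
        es = make_event_set([1.0, 1.0, 1.0], focus=60.0)
        es.table["focus_metric"] = [10.0, 60.0, 70.0]
        focused, unfocused = filter_focused(es, threshold=50.0)
        assert list(focused.table["focus_metric"]) == [60.0, 70.0]
        assert list(unfocused.table["focus_metric"]) == [10.0]

    def test_auto_falls_back_to_tenth_percentile_when_unimodal(self):
        rng = np.random.default_rng(2)
        es = make_event_set(np.ones(1000))
        es.table["focus_metric"] = rng.normal(60.0, 5.0, 1000)
        focused, unfocused = filter_focused(es, "auto")
        assert len(focused) == 900
        assert len(unfocused) == 100

    def test_auto_recovers_simulated_unfocused_fraction(self):
        cfg = clean_config(n_events=10_000, unfocused_fraction=0.1, seed=13)
        events, truth = generate_population(cfg)
        _, unfocused = filter_focused(events, "auto")
        tol = 3 * np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(len(unfocused) / 10_000 - 0.1) <= tol
        # and the removed events are exactly the simulated unfocused ones
        removed = set(unfocused.table["event_id"])
        truly = set(truth.loc[truth["artifact_class"] == "unfocused", "event_id"])
        assert removed == truly

    def test_missing_focus_metric_raises(self):
        es = make_event_set([1.0] * 5)
        es.table.loc[2, "focus_metric"] = np.nan
        with pytest.raises(FeatureMissingError):
            filter_focused(es, 10.0)

    def test_single_outlier_does_not_fool_auto_threshold(self):
        rng = np.random.default_rng(7)
        metric = np.concatenate([rng.normal(60.0, 5.0, 999), [200.0]])
        es = make_event_set(np.ones(1000))
        es.table["focus_metric"] = metric
        threshold = auto_focus_threshold(metric)
        assert threshold < 60.0  # tail straggler must not become a "mode"


# ---------------------------------------------------------------------------
# singlet filter
# ---------------------------------------------------------------------------

class TestFilterSinglets:
    def test_gross_area_outlier_is_flagged(self):
        fluor = np.linspace(100.0, 200.0, 101)
        area = 0.5 * fluor
        area[50] *= 5.0
        es = make_event_set(fluor, area=area)
        singlets, aggregates = filter_singlets(es)
        assert len(aggregates) == 1
        assert aggregates.table["event_id"].iloc[0] == "50"

    def test_noise_free_singlet_population_is_untouched(self):
        cfg = clean_config(n_events=500, noise_cv=0.0)
        events, _ = generate_population(cfg)
        singlets, aggregates = filter_singlets(events)
        assert len(aggregates) == 0
        assert len(singlets) == 500

    def test_simulated_aggregate_fraction_is_recovered(self):
        cfg = clean_config(n_events=20_000, aggregate_fraction=0.05,
                           noise_cv=0.03, seed=9)
        events, _ = generate_population(cfg)
        _, aggregates = filter_singlets(events)
        assert 0.02 <= len(aggregates) / 20_000 <= 0.08

    def test_result_is_input_order_invariant(self):
        cfg = clean_config(n_events=2000, aggregate_fraction=0.05,
                           noise_cv=0.03, seed=17)
        events, _ = generate_population(cfg)
        _, agg_fwd = filter_singlets(events)
        reversed_events = events.subset(np.ones(len(events), dtype=bool))
        reversed_events.table = events.table.iloc[::-1].reset_index(drop=True)
        _, agg_rev = filter_singlets(reversed_events)
        assert set(agg_fwd.table["event_id"]) == set(agg_rev.table["event_id"])

    def test_too_few_events_raise(self):
        with pytest.raises(InsufficientDataError):
            filter_singlets(make_event_set(np.linspace(1, 2, 19)))


# ---------------------------------------------------------------------------
# 1C peak
# ---------------------------------------------------------------------------

class TestFindC1Peak:
    def test_degenerate_distribution_returns_its_value(self):
        assert find_c1_peak(np.full(200, 100.0)) == 100.0

    def test_majority_mode_at_lowest_content_wins(self):
        values = np.concatenate([np.full(800, 100.0), np.full(200, 200.0)])
        assert find_c1_peak(values) == 100.0

    def test_lognormal_mixture_peak_near_main_mode(self):
        rng = np.random.default_rng(5)
        sigma = np.sqrt(np.log(1 + 0.05 ** 2))
        values = np.concatenate(
            [100.0 * np.exp(rng.normal(0, sigma, 8000)),
             200.0 * np.exp(rng.normal(0, sigma, 2000))]
        )
        peak = find_c1_peak(values)
        assert 95.0 <= peak <= 105.0
        # brute-force cross-check: mode of a fine histogram
        counts, edges = np.histogram(values, bins=2048, range=(0, values.max()))
        fine_mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert abs(peak - fine_mode) < 5.0

    def test_too_few_values_raise(self):
        with pytest.raises(InsufficientDataError):
            find_c1_peak(np.full(99, 100.0))


# ---------------------------------------------------------------------------
# region delineation
# ---------------------------------------------------------------------------

class TestDelineateRegions:
    def test_forced_width_zero_noise(self):
        regions = delineate_regions(np.full(300, 100.0), 100.0, width=10.0)
        assert (regions.c1_low, regions.c1_high) == (90.0, 110.0)
        assert regions.c1_geometric_mean == pytest.approx(100.0, rel=1e-12)
        assert regions.c2_low == pytest.approx(190.0, rel=1e-12)
        assert regions.c2_high == pytest.approx(210.0, rel=1e-12)

    def test_geometric_mean_closed_form(self):
        values = np.array([100.0, 200.0] * 60)
        regions = delineate_regions(values, 150.0, width=60.0)
        assert regions.c1_geometric_mean == pytest.approx(np.sqrt(100 * 200),
                                                          rel=1e-12)
        center = 0.5 * (regions.c2_low + regions.c2_high)
        assert center == pytest.approx(2 * np.sqrt(100 * 200), rel=1e-12)

    def test_true_1c_events_fall_inside_the_1c_region(self):
        cfg = clean_config(n_events=20_000, noise_cv=0.05, seed=11,
                           morphology_error_rate=0.01)
        events, truth = generate_population(cfg)
        f = events.table["dna_fluorescence"].to_numpy()
        regions = delineate_regions(f, find_c1_peak(f))
        veg = (truth["true_stage"] == "VEGETATIVE").to_numpy(dtype=bool)
        inside = (f >= regions.c1_low) & (f < regions.c1_high)
        assert inside[veg].mean() >= 0.95

    def test_overlapping_regions_raise_degenerate_error(self):
        values = np.array([100.0, 200.0] * 60)
        with pytest.raises(DegenerateGatingError, match="overlap"):
            delineate_regions(values, 150.0, width=120.0)

    def test_invariants_hold_on_seeded_samples(self):
        for seed in range(10):
            cfg = clean_config(n_events=4000, noise_cv=0.04, seed=seed)
            events, _ = generate_population(cfg)
            f = events.table["dna_fluorescence"].to_numpy()
            r = delineate_regions(f, find_c1_peak(f))
            assert 0 < r.c1_low < r.c1_high <= r.c2_low < r.c2_high <= r.hyper_high
            assert (r.c2_high - r.c2_low) == pytest.approx(
                r.c1_high - r.c1_low, rel=1e-9)
            assert 0.5 * (r.c2_low + r.c2_high) == pytest.approx(
                2 * r.c1_geometric_mean, rel=1e-9)


def test_gate_regions_reject_inconsistent_boundaries():
    with pytest.raises(ValidationError):
        GateRegions(90.0, 110.0, 150.0, 180.0, 500.0, 100.0)  # width mismatch
    with pytest.raises(ValidationError):
        GateRegions(90.0, 110.0, 180.0, 200.0, 500.0, 100.0)  # centre off 2x GM
    with pytest.raises(ValidationError):
        GateRegions(110.0, 90.0, 190.0, 210.0, 500.0, 100.0)  # disordered


# ---------------------------------------------------------------------------
# gate assignment and composition
# ---------------------------------------------------------------------------

REGIONS = GateRegions(90.0, 110.0, 190.0, 210.0, 500.0, 100.0)


class TestAssignGates:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (50.0, GateLabel.SUB_C1),
            (90.0, GateLabel.C1),
            (109.999, GateLabel.C1),
            (110.0, GateLabel.S),
            (189.999, GateLabel.S),
            (190.0, GateLabel.C2),
            (210.0, GateLabel.HYPER),
            (500.0, GateLabel.HYPER),  # brightest event is gated
        ],
    )
    def test_half_open_boundary_convention(self, value, expected):
        es = make_event_set([value])
        labeled = assign_gates(es, REGIONS)
        assert labeled.table["gate"].iloc[0] == expected.value

    def test_noise_free_truth_stages_land_in_their_gates(self):
        cfg = clean_config(n_events=6000, noise_cv=0.01, seed=3)
        events, truth = generate_population(cfg)
        f = events.table["dna_fluorescence"].to_numpy()
        labeled = assign_gates(events, delineate_regions(f, find_c1_peak(f)))
        merged = labeled.table.merge(truth, on="event_id")
        veg = merged[merged["true_stage"] == "VEGETATIVE"]
        assert (veg["gate"] == GateLabel.C1.value).all()
        meiotic = merged[merged["true_stage"].isin(["DYAD", "TRIAD", "TETRAD"])]
        assert (meiotic["gate"] == GateLabel.HYPER.value).all()


class TestGateComposition:
    def test_debris_is_excluded_from_the_denominator(self):
        labels = (["C1"] * 90 + ["S"] * 2 + ["C2"] * 5 + ["HYPER"] * 3
                  + ["SUB_C1"] * 10)
        es = make_event_set(np.ones(len(labels)))
        es.table["gate"] = labels
        comp = gate_composition(es)
        assert comp.rounded() == (92.0, 5.0, 3.0)
        assert comp.n_gated == 100

    def test_single_gate_degenerate_composition(self):
        es = make_event_set(np.ones(50))
        es.table["gate"] = "C1"
        assert gate_composition(es).rounded() == (100.0, 0.0, 0.0)

    def test_percentages_sum_to_100(self):
        cfg = clean_config(n_events=5000, noise_cv=0.04, seed=8,
                           debris_fraction=0.02)
        events, _ = generate_population(cfg)
        f = events.table["dna_fluorescence"].to_numpy()
        labeled = assign_gates(events, delineate_regions(f, find_c1_peak(f)))
        comp = gate_composition(labeled)
        assert comp.pct_c1_plus_s + comp.pct_c2 + comp.pct_hyper == pytest.approx(
            100.0, abs=1e-9)

    def test_empty_denominator_raises(self):
        es = make_event_set(np.ones(5))
        es.table["gate"] = "SUB_C1"
        with pytest.raises(EmptyGateError):
            gate_composition(es)


def test_gating_is_scale_equivariant():
    """Doubling every fluorescence doubles all boundaries and leaves the
    composition unchanged (doubling is exact in floating point)."""
    cfg = clean_config(n_events=8000, noise_cv=0.04, seed=19,
                       debris_fraction=0.01)
    events, _ = generate_population(cfg)
    f = events.table["dna_fluorescence"].to_numpy()
    r1 = delineate_regions(f, find_c1_peak(f))
    c1 = gate_composition(assign_gates(events, r1))

    scaled = events.copy()
    scaled.table["dna_fluorescence"] = 2.0 * f
    f2 = scaled.table["dna_fluorescence"].to_numpy()
    r2 = delineate_regions(f2, find_c1_peak(f2))
    c2 = gate_composition(assign_gates(scaled, r2))

    for name in ("c1_low", "c1_high", "c2_low", "c2_high", "hyper_high"):
        assert getattr(r2, name) == pytest.approx(2 * getattr(r1, name), rel=1e-9)
    assert (c1.pct_c1_plus_s, c1.pct_c2, c1.pct_hyper) == (
        c2.pct_c1_plus_s, c2.pct_c2, c2.pct_hyper)


def test_recovered_hyper_fraction_matches_configured_sexual_fraction(
        default_population):
    cfg, events, truth = default_population
    result = analyze_events(events, PipelineConfig(classify=False))
    recovered = result.gate_comp.pct_hyper / 100.0
    tol = max(0.005, 3 * np.sqrt(0.015 * 0.985 / cfg.n_events))
    assert abs(recovered - 0.015) <= tol
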