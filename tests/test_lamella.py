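"""Yield equations, throughput estimates and the preparation planner."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryoet_census import (
    Freezing,
    ImagingGeometry,
    PlannerThresholds,
    SectioningModel,
    Sectioning,
    Shape,
    ShapeDims,
    cells_per_lamella,
    default_sectioning_model,
    default_workflow,
    display_cells_per_lamella,
    n_lamellae,
    percent_imaged,
    recommend_workflow,
    time_for_n_cells,
    tomograms_per_lamella,
    yield_report,
)
from cryoet_census.lamella import NlRule


class TestSectioningModel:
    def test_defaults_per_method(self):
        assert default_sectioning_model(Sectioning.FIB_SEM).nl_rule is \
            NlRule.SINGLE_LAMELLA
        serial = default_sectioning_model(Sectioning.SERIAL_LIFT_OUT)
        assert serial.separation_um == 4.0
        ultra = default_sectioning_model(Sectioning.ULTRAMICROTOME)
        assert ultra.separation_um == ultra.lamella_width_l == 0.18

    def test_separation_below_lamella_width_rejected(self):
        with pytest.raises(ValueError):
            SectioningModel(method=Sectioning.SERIAL_LIFT_OUT,
                            separation_um=0.05,
                            nl_rule=NlRule.LENGTH_OVER_SEPARATION)

    def test_rule_must_match_method(self):
        with pytest.raises(ValueError):
            SectioningModel(method=Sectioning.FIB_SEM, separation_um=4.0,
                            nl_rule=NlRule.LENGTH_OVER_SEPARATION)

    def test_unsectioned_has_no_model(self):
        with pytest.raises(ValueError):
            default_sectioning_model(Sectioning.NONE)


class TestNLamellae:
    def test_fib_sem_always_single(self):
        model = default_sectioning_model(Sectioning.FIB_SEM)
        assert n_lamellae(model, 17.0) == 1
        assert n_lamellae(model, 2000.0) == 1

    def test_serial_lift_out_packs_blocks_along_length(self):
        model = default_sectioning_model(Sectioning.SERIAL_LIFT_OUT)
        assert n_lamellae(model, 50.0) == 12  # floor(50 / 4)

    def test_ultramicrotome_single_slice_spans_short_cell(self):
        model = default_sectioning_model(Sectioning.ULTRAMICROTOME)
        assert n_lamellae(model, 0.18) == 1

    def test_minimum_one_lamella(self):
        model = default_sectioning_model(Sectioning.SERIAL_LIFT_OUT)
        assert n_lamellae(model, 2.0) == 1  # cell shorter than the separation


class TestPercentImaged:
    def test_typical_bacterium_is_9_percent(self):
        assert percent_imaged(0.18, 1, 2.0) == pytest.approx(9.0)

    def test_lamella_spanning_cell_is_100_percent(self):
        assert percent_imaged(0.18, 1, 0.18) == pytest.approx(100.0)

    def test_large_tissue_tiny_fraction(self):
        assert percent_imaged(0.18, 1, 2000.0) == pytest.approx(0.009)

    def test_capped_at_100(self):
        # contiguous ultramicrotome slices on a cell of exact multiple length
        model = default_sectioning_model(Sectioning.ULTRAMICROTOME)
        length = 0.18 * 7
        nl = n_lamellae(model, length)
        assert percent_imaged(0.18, nl, length) == 100.0
        assert percent_imaged(0.18, 100, 0.5) == 100.0

    @given(
        length=st.floats(min_value=0.2, max_value=2000),
        sep=st.floats(min_value=0.18, max_value=10),
        k=st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance_of_serial_coverage(self, length, sep, k):
        """Scaling l, separation and L together leaves P unchanged."""
        m1 = SectioningModel(Sectioning.SERIAL_LIFT_OUT, 0.18, sep,
                             NlRule.LENGTH_OVER_SEPARATION)
        m2 = SectioningModel(Sectioning.SERIAL_LIFT_OUT, 0.18 * k, sep * k,
                             NlRule.LENGTH_OVER_SEPARATION)
        p1 = percent_imaged(m1.lamella_width_l, n_lamellae(m1, length), length)
        p2 = percent_imaged(m2.lamella_width_l, n_lamellae(m2, k * length),
                            k * length)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            percent_imaged(0.0, 1, 2.0)
        with pytest.raises(ValueError):
            percent_imaged(0.18, 0, 2.0)
        with pytest.raises(ValueError):
            percent_imaged(0.18, 1, -2.0)


class TestCellsPerLamella:
    @pytest.mark.parametrize(
        "al, ac, displayed",
        [
            (50.0, 2.0, 25.0),     # biofilm lamella packed with bacteria
            (100.0, 100.0, 1.0),
            (100.0, 227.0, 0.5),   # lamella smaller than one HeLa cell
        ],
    )
    def test_display_convention(self, al, ac, displayed):
        assert display_cells_per_lamella(cells_per_lamella(al, ac)) == displayed

    def test_full_precision_retained(self):
        assert cells_per_lamella(100.0, 227.0) == pytest.approx(0.4405, abs=1e-4)

    def test_nonpositive_areas_rejected(self):
        with pytest.raises(ValueError):
            cells_per_lamella(0.0, 2.0)
        with pytest.raises(ValueError):
            cells_per_lamella(50.0, -2.0)


class TestTimeForNCells:
    def test_plunge_fib_on_biofilm(self):
        assert time_for_n_cells(60.0, 25.0, 100) == pytest.approx(240.0)

    def test_one_lamella_suffices_when_nc_equals_n(self):
        assert time_for_n_cells(75.0, 50.0, 50) == pytest.approx(75.0)

    def test_serial_lift_out_on_bacteria(self):
        nc = cells_per_lamella(250.0, 2.0)
        assert time_for_n_cells(75.0, nc, 100) == pytest.approx(60.0)

    @given(nc1=st.floats(0.1, 100), nc2=st.floats(0.1, 100))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_cells_per_lamella(self, nc1, nc2):
        if nc1 == nc2:
            return
        lo, hi = sorted((nc1, nc2))
        assert time_for_n_cells(60.0, hi) < time_for_n_cells(60.0, lo)


class TestTomogramsPerLamella:
    @pytest.mark.parametrize("al, expected", [(400.0, 32), (250.0, 20),
                                              (100.0, 8), (50.0, 4)])
    def test_benchmark_lamella_areas(self, al, expected):
        assert tomograms_per_lamella(al) == expected

    def test_single_illumination_area(self):
        assert tomograms_per_lamella(4 * math.pi) == 1

    def test_illumination_area_constant(self):
        assert ImagingGeometry().illumination_area_um2 == pytest.approx(12.6,
                                                                        abs=0.07)

    def test_illumination_must_cover_tomogram(self):
        with pytest.raises(ValueError):
            ImagingGeometry(tomogram_side_um=1.8, illumination_radius_um=0.5)


class TestRecommendWorkflow:
    def test_thin_bacterium_plunge_no_sectioning(self):
        rec = recommend_workflow(ShapeDims(Shape.CAPSULE, 2.0, 1.0))
        assert rec.freezing is Freezing.PLUNGE
        assert rec.sectioning is Sectioning.NONE
        assert not rec.cryoprotectant

    def test_mammalian_cell_plunge_plus_fib(self):
        rec = recommend_workflow(ShapeDims(Shape.SPHERE, 17.0, 17.0))
        assert rec.freezing is Freezing.PLUNGE
        # gallium or plasma: either way the cell is FIB milled on-grid
        assert rec.sectioning in (Sectioning.FIB_SEM, Sectioning.PLASMA_FIB)

    def test_thick_cell_below_100_uses_plasma_fib(self):
        rec = recommend_workflow(ShapeDims(Shape.SPHERE, 50.0, 50.0))
        assert rec.freezing is Freezing.PLUNGE
        assert rec.sectioning is Sectioning.PLASMA_FIB

    def test_mid_size_tissue_hpf_lift_out(self):
        rec = recommend_workflow(ShapeDims(Shape.CAPSULE, 150.0, 40.0))
        assert rec.freezing is Freezing.HPF
        assert rec.sectioning is Sectioning.LIFT_OUT
        assert not rec.cryoprotectant

    def test_large_tissue_needs_hpf_and_cryoprotectant(self):
        rec = recommend_workflow(ShapeDims(Shape.CAPSULE, 300.0, 60.0))
        assert rec.freezing is Freezing.HPF
        assert rec.sectioning is Sectioning.SERIAL_LIFT_OUT
        assert rec.cryoprotectant
        assert not rec.warnings

    def test_warning_when_cryoprotectant_unavailable(self):
        rec = recommend_workflow(ShapeDims(Shape.CAPSULE, 300.0, 60.0),
                                 cryoprotectant_available=False)
        assert rec.warnings

    def test_rationale_cites_the_triggering_rule(self):
        rec = recommend_workflow(ShapeDims(Shape.CAPSULE, 2.0, 1.0))
        assert any("thickness" in r for r in rec.rationale)

    def test_custom_thresholds(self):
        t = PlannerThresholds(no_section_max_thickness_um=0.3)
        rec = recommend_workflow(ShapeDims(Shape.CAPSULE, 2.0, 1.0), thresholds=t)
        assert rec.sectioning is Sectioning.FIB_SEM

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            PlannerThresholds(hpf_min_dimension_um=500.0,
                              cryoprotectant_min_dimension_um=200.0)


class TestYieldReport:
    def test_biofilm_composition(self):
        # E. coli in a biofilm lamella: diameter 1.6 um -> Ac ~ 2 um^2
        report = yield_report(
            ShapeDims(Shape.SPHERE, 1.6, 1.6),
            default_workflow("plunge_fib", bacterial_biofilm=True),
        )
        assert display_cells_per_lamella(report.cells_per_lamella_nc) == 25.0
        assert report.tomograms_per_lamella == 4
        assert not report.sub_single_cell

    def test_yeast_in_waffle_lamella(self):
        report = yield_report(ShapeDims(Shape.SPHERE, 5.0, 5.0),
                              default_workflow("hpf_waffle"))
        assert report.cells_per_lamella_nc == pytest.approx(20.4, abs=0.05)

    def test_cell_larger_than_lamella_flagged(self):
        report = yield_report(ShapeDims(Shape.SPHERE, 17.0, 17.0),
                              default_workflow("plunge_fib"))
        assert report.sub_single_cell
        assert report.display()["cells_per_lamella"] == 0.5

    def test_serial_lift_out_most_time_efficient(self):
        """Across the four benchmark cell areas the HPF + serial lift-out
        route mills 100 cells fastest; Waffle beats plunge + FIB-SEM too."""
        for ac in (2.0, 19.6, 50.3, 227.0):
            t = {}
            for name in ("plunge_fib", "hpf_waffle", "hpf_serial"):
                wf = default_workflow(name, bacterial_biofilm=(ac == 2.0))
                nc = cells_per_lamella(wf.lamella_area_al_um2, ac)
                t[name] = time_for_n_cells(wf.mill_time_tl_min, nc, 100)
            assert t["hpf_serial"] < t["hpf_waffle"] < t["plunge_fib"]

    def test_tomogram_throughput_ordering(self):
        tomos = {
            name: tomograms_per_lamella(default_workflow(name).lamella_area_al_um2)
            for name in ("plunge_fib", "hpf_waffle", "hpf_serial")
        }
        assert tomos["hpf_waffle"] > tomos["hpf_serial"] > tomos["plunge_fib"]

    def test_unknown_workflow_name(self):
        with pytest.raises(ValueError):
            default_workflow("dunk_and_hope")
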