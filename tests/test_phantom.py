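"""Phantom generator: reproducibility, invariants, cohort sampling."""

import numpy as np
import pandas as pd
import pytest

from rdmorph.errors import InvalidDesignError, InvalidSpecError
from rdmorph.phantom import (
    LABEL_INL,
    LABEL_ONL,
    LABEL_RPE,
    CohortDesign,
    PhantomSpec,
    attached_only_spec,
    published_cohort_design,
    generate_cohort_table,
    generate_phantom_tile,
)


class TestTileGeneration:
    def test_bit_reproducible_under_seed(self):
        spec = attached_only_spec()
        img1, lab1, gt1 = generate_phantom_tile(spec, 7)
        img2, lab2, gt2 = generate_phantom_tile(spec, 7)
        assert np.array_equal(img1, img2)
        assert np.array_equal(lab1, lab2)
        assert gt1.digest() == gt2.digest()
        img3, _, gt3 = generate_phantom_tile(spec, 8)
        assert not np.array_equal(img1, img3)
        assert gt1.digest() != gt3.digest()

    def test_label_mask_contents(self, full_phantom):
        _, image, labels, _ = full_phantom
        assert image.dtype == np.uint16
        assert labels.dtype == np.uint8
        assert set(np.unique(labels)) == {0, LABEL_RPE, LABEL_ONL, LABEL_INL}

    def test_attached_only_has_no_detachment(self, small_phantom):
        _, _, labels, gt = small_phantom
        assert gt.peak_onl_arc_um is None
        assert gt.rd_height_um is None
        assert gt.detached_onl_interval_um is None
        # the ONL band hugs the RPE everywhere: its vertical extent stays
        # within gap + ONL + sagitta of the shallow arc
        rows_onl = np.where((labels == LABEL_ONL).any(axis=1))[0]
        rows_rpe = np.where((labels == LABEL_RPE).any(axis=1))[0]
        assert rows_rpe.min() - rows_onl.min() < 200

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(onl_um=-1),
            dict(um_per_px=0),
            dict(base_stretch=0.0),
            dict(base_stretch=1.5),
            dict(overlap_fraction=1.0),
            dict(rd_height_um=-5),
            dict(attached_arc_um=9000.0),  # arc exceeds the image width
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(**kwargs).validate()

    def test_attached_central_density_hits_study_count(self):
        """Default density yields ~1250 ONL nuclei per 400 µm segment."""
        spec = attached_only_spec()
        counts = []
        for seed in (1, 2, 3):
            _, _, gt = generate_phantom_tile(spec, seed)
            counts.append(gt.region_counts["attached_central"])
        for c in counts:
            assert abs(c - 1250) < 4 * np.sqrt(1250) + 25  # Poisson + placement loss

    def test_counts_conserved(self, full_phantom):
        _, _, _, gt = full_phantom
        assert sum(gt.region_counts.values()) <= gt.total_onl_nuclei
        for name, (lo, hi) in gt.region_intervals_um.items():
            in_arc = np.sum((gt.centroid_arc_um >= lo) & (gt.centroid_arc_um < hi))
            assert in_arc == gt.region_counts[name]

    @pytest.mark.parametrize("seed", [1, 5, 6])
    def test_sparse_nonoverlapping_nuclei_are_separable(self, seed):
        """With overlap 0, ~50 placed nuclei give exactly that many
        thresholded components (independent connected-component oracle)."""
        from skimage.measure import label as cc_label

        spec = attached_only_spec(
            onl_density_per_100um=6.5,
            overlap_fraction=0.0,
            nucleus_radius_sd_um=0.0,
        )
        image, labels, gt = generate_phantom_tile(spec, seed)
        # half-amplitude threshold keeps hard-core-separated footprints apart
        thr = spec.background + 0.5 * spec.foreground
        binary = (image.astype(float) > thr) & (labels == LABEL_ONL)
        n_components = cc_label(binary, connectivity=2).max()
        assert n_components == gt.total_onl_nuclei
        assert 40 <= gt.total_onl_nuclei <= 70  # ~50 expected at this density

    def test_doubling_density_doubles_counts(self):
        """Expected counts scale linearly in the dilute regime (+-3%)."""
        totals = {60.0: 0, 120.0: 0}
        for density in totals:
            spec = attached_only_spec(onl_density_per_100um=density)
            for seed in range(20):
                _, _, gt = generate_phantom_tile(spec, 100 + seed)
                totals[density] += gt.total_onl_nuclei
        ratio = totals[120.0] / totals[60.0]
        assert 1.94 < ratio < 2.06

    def test_base_stretch_reduces_base_count(self, full_phantom):
        _, _, _, gt = full_phantom
        base = gt.region_counts["detached_base"]
        central = gt.region_counts["attached_central"]
        assert 0.72 < base / central < 0.90
        assert gt.region_onl_um["detached_base"] < gt.region_onl_um["detached_apex"]

    def test_analytic_thickness_recorded(self, full_phantom):
        spec, _, _, gt = full_phantom
        assert gt.region_onl_um["attached_central"] == pytest.approx(spec.onl_um)
        assert gt.region_inl_um["attached_central"] == pytest.approx(spec.inl_um)


class TestCohorts:
    def test_zero_sd_reproduces_cell_means(self):
        design = published_cohort_design(3)
        t = design.table.copy()
        t["count_sd"] = 0.0
        t["ratio_sd"] = 0.0
        cohort = generate_cohort_table(CohortDesign(t), 5)
        for (region, day), grp in cohort.groupby(["region", "day"]):
            cell = design.cell(region, day)
            assert (grp.onl_count == cell.count_mean).all()
            assert (grp.onl_inl_ratio == cell.ratio_mean).all()

    def test_law_of_large_numbers(self):
        design = published_cohort_design(10_000)
        cohort = generate_cohort_table(design, 11)
        for (region, day), grp in cohort.groupby(["region", "day"]):
            cell = design.cell(region, day)
            assert grp.onl_count.mean() == pytest.approx(cell.count_mean, rel=0.01)
            assert grp.onl_inl_ratio.mean() == pytest.approx(cell.ratio_mean, rel=0.01)

    def test_cohort_shape_matches_study_design(self):
        cohort = generate_cohort_table(published_cohort_design(6), 1)
        assert len(cohort) == 4 * 4 * 6  # regions x days x animals
        assert set(cohort.day) == {0, 1, 7, 14}
        assert cohort.groupby("day").animal_id.nunique().eq(6).all()
        assert (cohort.onl_count >= 0).all()

    def test_negative_sd_rejected(self):
        t = published_cohort_design(4).table.copy()
        t.loc[0, "count_sd"] = -1.0
        with pytest.raises(InvalidDesignError):
            CohortDesign(t)

    def test_small_n_rejected(self):
        t = published_cohort_design(4).table.copy()
        t["n"] = 1
        with pytest.raises(InvalidDesignError):
            CohortDesign(t)

    @pytest.mark.parametrize(
        "region, day, count_mean, count_sd, ratio_mean, ratio_sd",
        [
            ("detached_apex", 0, 1264.00, 150.71, 1.98, 0.16),
            ("detached_base", 14, 954.00, 122.38, 1.81, 0.24),
            ("attached_central", 0, 1247.60, 64.62, 2.00, 0.17),
            ("attached_paracentral", 0, 1157.80, 163.33, 1.92, 0.23),
            ("detached_base", 0, 1013.80, 67.16, 1.85, 0.15),
        ],
    )
    def test_default_design_carries_study_values(
        self, region, day, count_mean, count_sd, ratio_mean, ratio_sd
    ):
        cell = published_cohort_design().cell(region, day)
        assert cell.count_mean == count_mean
        assert cell.count_sd == count_sd
        assert cell.ratio_mean == ratio_mean
        assert cell.ratio_sd == ratio_sd
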