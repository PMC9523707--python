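"""Template matching, reliable-peak selection, composites and feature tables."""

import numpy as np
import pandas as pd
import pytest

import gcxfp as g
from gcxfp.align import (
    RetentionTransform, Template, TemplateEntry, build_composite,
    build_template, delineate_regions, load_feature_table, match_peaks,
    save_feature_table, warp_raster,
)


def mk_peak(rt1, rt2, key, volume=1e6):
    return g.Peak2D(rt1=rt1, rt2=rt2, volume=volume, height=volume / 100,
                    snr=500.0, apex_spectrum=g.simulate_spectrum(key),
                    apex_index=(0, 0), footprint=np.empty((0, 2), int))


def mk_template(peaks):
    return Template(entries=[
        TemplateEntry(p.rt1, p.rt2, p.apex_spectrum) for p in peaks])


PANEL = [(7.0, 1.2, "c-1"), (9.0, 0.6, "c-2"), (12.0, 2.4, "c-3"),
         (15.5, 1.8, "c-4"), (20.0, 0.9, "c-5")]


class TestMatchPeaks:
    def test_identical_run_matches_every_entry(self):
        peaks = [mk_peak(*p) for p in PANEL]
        tmpl = mk_template(peaks)
        matches = match_peaks(tmpl, peaks)
        assert all(matches[i] is not None for i in range(len(PANEL)))

    def test_small_shift_inside_window_still_matches(self):
        tmpl = mk_template([mk_peak(*p) for p in PANEL])
        shifted = [mk_peak(r1 + 0.1, r2, k) for r1, r2, k in PANEL]
        matches = match_peaks(tmpl, shifted)
        assert all(m is not None for m in matches.values())

    def test_shift_beyond_window_matches_nothing(self):
        tmpl = mk_template([mk_peak(*p) for p in PANEL])
        shifted = [mk_peak(r1 + 1.0, r2, k) for r1, r2, k in PANEL]
        matches = match_peaks(tmpl, shifted)
        assert all(m is None for m in matches.values())

    def test_spectral_gate_blocks_coincident_but_unrelated_peak(self):
        tmpl = mk_template([mk_peak(7.0, 1.2, "c-1")])
        impostor = [mk_peak(7.0, 1.2, "someone-else")]
        assert match_peaks(tmpl, impostor)[0] is None

    def test_each_peak_used_at_most_once(self):
        tmpl = mk_template([mk_peak(7.00, 1.2, "c-1"),
                            mk_peak(7.05, 1.2, "c-1")])
        one = [mk_peak(7.02, 1.2, "c-1")]
        matches = match_peaks(tmpl, one)
        assert sum(m is not None for m in matches.values()) == 1


class TestBuildTemplate:
    def _runs(self, n_runs, drop=()):
        """n_runs near-identical synthetic peak sets; (run, key) pairs in
        ``drop`` are omitted."""
        rng = np.random.default_rng(0)
        runs = []
        for r in range(n_runs):
            ps = []
            for r1, r2, key in PANEL:
                if (r, key) in drop:
                    continue
                ps.append(mk_peak(r1 + rng.normal(0, 0.02),
                                  r2 + rng.normal(0, 0.01), key))
            runs.append(ps)
        return runs

    def test_peak_present_everywhere_retained(self):
        tmpl = build_template(self._runs(10))
        assert len(tmpl.entries) == len(PANEL)
        assert all(e.presence == 10 for e in tmpl.entries)

    def test_all_but_one_rule_keeps_single_absence(self):
        tmpl = build_template(self._runs(10, drop={(3, "c-2")}))
        assert len(tmpl.entries) == len(PANEL)

    def test_two_absences_drop_the_entry(self):
        tmpl = build_template(self._runs(10, drop={(3, "c-2"), (7, "c-2")}))
        assert len(tmpl.entries) == len(PANEL) - 1

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ValueError):
            build_template(self._runs(1))

    def test_transform_reduces_matched_residuals_under_drift(self):
        base = [mk_peak(*p) for p in PANEL]
        drifted = [mk_peak(r1 * 1.004 + 0.05, r2 * 1.01, k)
                   for r1, r2, k in PANEL]
        tmpl = mk_template(base)
        naive = match_peaks(tmpl, drifted)
        resid_naive = np.mean([abs(m.rt1 - e.rt1) for e, m in
                               zip(tmpl.entries, naive.values())])
        from gcxfp.align import _fit_alignment
        al = _fit_alignment(tmpl, drifted)
        exp1, _ = al.transform.apply(
            np.array([e.rt1 for e in tmpl.entries]),
            np.array([e.rt2 for e in tmpl.entries]))
        resid_fit = np.mean([abs(m.rt1 - x) for x, m in
                             zip(exp1, al.matches.values())])
        assert resid_fit < resid_naive


class TestComposite:
    def test_single_run_composite_is_that_raster(self):
        r = np.random.default_rng(0).random((30, 20))
        assert np.allclose(build_composite([r]), r)

    def test_identical_runs_average_to_the_same_raster(self):
        r = np.random.default_rng(1).random((30, 20))
        assert np.allclose(build_composite([r, r.copy()]), r)

    def test_composite_is_linear_in_planted_volumes(self):
        base = np.zeros((30, 20))
        base[10, 10] = 1000.0
        comp = build_composite([base, 3.0 * base])
        assert comp[10, 10] == pytest.approx(2000.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_composite([])

    def test_warp_with_identity_transform_is_noop(self):
        r = np.random.default_rng(2).random((40, 30))
        w = warp_raster(r, RetentionTransform.identity(), 3.5, 100.0)
        assert np.allclose(w, r)


class TestDelineateRegions:
    def _composite(self, peaks):
        from tests.conftest import make_raster
        return make_raster(shape=(120, 80), baseline=50.0, noise_sd=2.0,
                           seed=5, peaks=peaks)

    def test_blank_composite_has_no_regions(self):
        comp = self._composite([])
        tmpl = Template(entries=[])
        assert delineate_regions(comp, tmpl) == []

    def test_template_covered_peaks_yield_no_untargeted_regions(self):
        # one bright peak at raster index (60, 40) = (3.5 min, 0.4 s)
        comp = self._composite([(60, 40, 3, 5, 5e5)])
        tmpl = Template(entries=[
            TemplateEntry(60 * 3.5 / 60.0, 40 / 100.0,
                          g.simulate_spectrum("c-1"))])
        regions = delineate_regions(comp, tmpl)
        assert len(regions) == 1 and regions[0].template_covered
        assert all(r.template_covered for r in regions)

    def test_extra_planted_peak_becomes_one_untargeted_region(self):
        comp = self._composite([(60, 40, 3, 5, 5e5), (90, 20, 3, 5, 4e5)])
        tmpl = Template(entries=[
            TemplateEntry(60 * 3.5 / 60.0, 40 / 100.0,
                          g.simulate_spectrum("c-1"))])
        regions = delineate_regions(comp, tmpl)
        open_regions = [r for r in regions if not r.template_covered]
        assert len(open_regions) == 1
        assert open_regions[0].apex_rt1 == pytest.approx(90 * 3.5 / 60, abs=0.12)


class TestFeatureTable:
    def test_normalized_response_arithmetic(self, full_study):
        # %normalized = 100 · volume / mean(IS volumes): verify on one run
        table = full_study["table"]
        design = full_study["design"]
        runs = full_study["runs"]
        from gcxfp.align import align_runs
        al = align_runs(full_study["template"],
                        [r.peaks for r in runs])[0]
        is_names = {s.name for s in design.internal_standards}
        # IS entries are the template entries nearest the planted positions
        is_vols = []
        for s in design.internal_standards:
            cand = min(full_study["template"].entries,
                       key=lambda e: abs(e.rt1 - s.rt1_min)
                       + abs(e.rt2 - s.rt2_s))
            j = full_study["template"].entries.index(cand)
            is_vols.append(al.matches[j].volume)
        col = runs[0].meta.sample_id
        fid = table.responses.index[0]
        expected = 100.0 * table.responses.loc[fid, col] / np.mean(is_vols)
        assert table.normalized.loc[fid, col] == pytest.approx(expected)
        assert is_names  # design really carries two standards

    def test_explicit_normalization_example(self):
        # analyte volume 5000 against IS volumes 9000 and 11000 -> 50.0%
        assert 100.0 * 5000 / np.mean([9000, 11000]) == pytest.approx(50.0)

    def test_save_load_round_trip(self, full_study, tmp_path):
        table = full_study["table"]
        save_feature_table(table, tmp_path / "ft")
        back = load_feature_table(tmp_path / "ft")
        pd.testing.assert_frame_equal(back.responses, table.responses)
        pd.testing.assert_frame_equal(back.missing, table.missing)
        assert [m.sample_id for m in back.meta] == \
            [m.sample_id for m in table.meta]

    def test_targeted_plus_untargeted_counts_sum(self, full_study):
        table = full_study["table"]
        assert table.n_targeted + table.n_untargeted == len(table.features)
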