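"""Targeted compound tracking: matching windows, qualification, filters,
baseline subtraction, and ground-truth recovery on simulated feature lists."""

import numpy as np
import pytest

from foodtrace.io import CompoundRecord
from foodtrace.tracking import (
    MatchParams,
    TrackingReport,
    apply_detection_filters,
    define_extract_compounds,
    mass_match,
    match_to_plasma,
    remove_baseline,
    track,
)


def rec(cid="c1", mass=400.0, rt=3.0, fraction="lipid", area=1e5, m2=None, adduct=None):
    return CompoundRecord(
        compound_id=cid, neutral_mass=mass, rt=rt, fraction=fraction,
        area_m1=area, area_m2=m2, adduct_mass=adduct,
    )


class TestMassMatch:
    @pytest.mark.parametrize(
        "query,cand,window,expected",
        [
            (500.0000, 500.0049, 10, True),   # 9.8 ppm
            (500.0000, 500.0060, 10, False),  # 12 ppm
            (500.0000, 500.0000, 10, True),
        ],
    )
    def test_ppm_window(self, query, cand, window, expected):
        assert mass_match(query, cand, window) is expected

    def test_nonpositive_mass_is_error(self):
        with pytest.raises(ValueError):
            mass_match(0.0, 500.0, 10)


class TestDefineExtractCompounds:
    def test_requires_full_presence_and_no_blank(self):
        base = rec()
        extracts = [[base]] * 4
        assert len(define_extract_compounds(extracts, [])) == 1
        # present in 3/4 extracts only -> dropped
        extracts_partial = [[base]] * 3 + [[rec(cid="other", mass=900.0)]]
        assert define_extract_compounds(extracts_partial, []) == []
        # present in a blank -> dropped
        assert define_extract_compounds([[base]] * 4, [[rec(cid="b", mass=400.0)]]) == []

    def test_rt_ceiling_and_consensus_mean(self):
        late = rec(cid="late", rt=10.5)
        jittered = [
            [rec(mass=400.0000, rt=3.00), late],
            [rec(mass=400.0008, rt=3.04, area=2e5)],
        ]
        out = define_extract_compounds(jittered, [])
        assert [c.compound_id for c in out] == ["c1"]
        assert out[0].neutral_mass == pytest.approx(400.0004)
        assert out[0].rt == pytest.approx(3.02)

    def test_empty_extract_set_is_error(self):
        with pytest.raises(ValueError):
            define_extract_compounds([], [])


class TestMatchToPlasma:
    def test_match_and_rt_outlier(self):
        extract = [rec(mass=400.0000, rt=3.00, m2=1e4, area=1e5)]
        good = rec(cid="p1", mass=400.0020, rt=3.10, area=5e4, m2=5.5e3)
        outlier = rec(cid="p2", mass=400.0020, rt=3.35, area=5e4)
        table = match_to_plasma(extract, {"s1": [good], "s2": [outlier]})
        assert table.areas[0, 0] == 5e4
        assert table.areas[1, 0] == 0.0

    def test_isotope_qualifier(self):
        # extract M2/M1 = 0.10; plasma observed 0.13 deviates 30% -> unmatched
        extract = [rec(mass=400.0, rt=3.0, area=1e5, m2=1e4)]
        bad = rec(cid="p", mass=400.0, rt=3.0, area=1e5, m2=1.3e4)
        ok = rec(cid="p", mass=400.0, rt=3.0, area=1e5, m2=1.1e4)
        assert match_to_plasma(extract, {"s": [bad]}).areas[0, 0] == 0.0
        assert match_to_plasma(extract, {"s": [ok]}).areas[0, 0] == 1e5

    def test_m1_only_plasma_record_still_matches(self):
        extract = [rec(mass=400.0, rt=3.0, area=1e5, m2=1e4)]
        m1_only = rec(cid="p", mass=400.0, rt=3.0, area=7e4)
        assert match_to_plasma(extract, {"s": [m1_only]}).areas[0, 0] == 7e4

    def test_best_match_is_nearest_ppm(self):
        extract = [rec(mass=400.0, rt=3.0)]
        near = rec(cid="near", mass=400.0004, rt=3.15, area=1.0)
        far = rec(cid="far", mass=400.0020, rt=3.00, area=2.0)
        table = match_to_plasma(extract, {"s": [far, near]})
        assert table.areas[0, 0] == 1.0

    def test_window_monotonicity(self):
        rng = np.random.default_rng(0)
        extract = [rec(cid=f"e{i}", mass=300 + 10 * i, rt=2 + 0.3 * i) for i in range(5)]
        plasma = {
            "s": [
                rec(
                    cid=f"p{k}",
                    mass=float(rng.uniform(295, 360)),
                    rt=float(rng.uniform(1.5, 4.5)),
                    area=1.0,
                )
                for k in range(40)
            ]
        }
        counts = []
        for ppm, rtw in [(2, 0.05), (10, 0.2), (50, 0.3)]:
            params = MatchParams(ppm_window=ppm, rt_window=rtw)
            counts.append(np.count_nonzero(match_to_plasma(extract, plasma, params).areas))
        assert counts == sorted(counts)


class TestDetectionFilters:
    def make_table(self, areas, fraction):
        from foodtrace.io import CompoundTable

        areas = np.asarray(areas, dtype=float).reshape(-1, 1)
        return CompoundTable(
            [f"s{i}" for i in range(len(areas))], ["c1"], areas, {"c1": fraction}
        )

    @pytest.mark.parametrize(
        "areas,fraction,kept",
        [
            ([25000, 21000, 20000, 0, 0], "aqueous", True),
            ([25000, 21000, 19999, 0, 0], "aqueous", False),
            ([55000, 55000, 55000, 0], "lipid", True),  # boundary inclusive
            ([54999, 55000, 55000, 0], "lipid", False),
        ],
    )
    def test_min_samples_at_threshold(self, areas, fraction, kept):
        out = apply_detection_filters(self.make_table(areas, fraction))
        assert (out.shape[1] == 1) is kept


class TestBaselineRemoval:
    def test_matched_in_baseline_removed_and_counted(self):
        extract = [rec(cid="c1", mass=400.0, rt=3.0), rec(cid="c2", mass=500.0, rt=4.0)]
        tracked = match_to_plasma(
            extract, {"s1": [rec(cid="x", mass=400.0, rt=3.0), rec(cid="y", mass=500.0, rt=4.0)]}
        )
        baseline = {"b1": [rec(cid="z", mass=400.00001, rt=3.05)]}
        report = remove_baseline(tracked, baseline, extract)
        assert report.n_baseline_removed == {"lipid": 1}
        assert report.retained.compound_ids == ["c2"]

    def test_empty_baseline_keeps_everything(self):
        extract = [rec(cid="c1")]
        tracked = match_to_plasma(extract, {"s1": [rec(cid="x")]})
        report = remove_baseline(tracked, {}, extract)
        assert report.total_baseline_removed == 0
        assert report.total_retained == report.total_detected

    def test_conservation_identity_enforced(self):
        with pytest.raises(ValueError, match="accounting"):
            TrackingReport(
                n_extract_compounds=5,
                n_detected={"lipid": 3},
                n_baseline_removed={"lipid": 1},
                n_retained={"lipid": 3},
            )


class TestGroundTruthRecovery:
    def test_recall_one_no_decoys_correct_baseline(self, small_world):
        """Planted true compounds are all recovered, decoys all rejected, and
        the baseline-designated compounds land in n_baseline_removed."""
        cfg, world = small_world
        truth = world["ground_truth"]
        report = track(
            list(world["lcms"]["extract"].values()),
            list(world["lcms"]["blanks"].values()),
            world["lcms"]["plasma"],
            world["lcms"]["baseline"],
        )
        retained = set(report.retained.compound_ids)
        assert retained == set(truth.true_compound_ids)  # recall 1, no decoys
        assert report.total_baseline_removed == len(truth.baseline_compounds)
        assert not retained & set(truth.decoy_ids)
        assert not retained & set(truth.blank_contaminants)
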