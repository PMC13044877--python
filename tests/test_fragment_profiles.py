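"""Cross-energy fragment tracking and profile hygiene."""
import random

import pytest

from conftest import make_feature, make_profile
from umrm.config import TrackingConfig
from umrm.fragment_profiles import (
    PrecursorSpectrumSet,
    build_spectrum_sets,
    flag_irregular,
    track_fragments,
)
from umrm.records import POSITIVE, SpectrumRecord


def _ms2(precursor_mz, rt, ce, peaks, scan_id="s"):
    return SpectrumRecord(
        scan_id=scan_id,
        ms_level=2,
        rt_min=rt,
        polarity=POSITIVE,
        peaks=peaks,
        precursor_mz=precursor_mz,
        collision_energy_ev=ce,
    )


class TestBuildSpectrumSets:
    def test_all_four_energies(self):
        prec = make_feature("p", 400.2, rt_min=5.0)
        ms2 = [_ms2(400.2, 5.0, ce, [(150.0, 100.0)]) for ce in (0.0, 10.0, 20.0, 40.0)]
        (sset,) = build_spectrum_sets([prec], ms2)
        assert sorted(sset.spectra) == [0.0, 10.0, 20.0, 40.0]

    def test_duplicate_energy_highest_tic_wins(self):
        prec = make_feature("p", 400.2, rt_min=5.0)
        low = _ms2(400.2, 5.0, 20.0, [(150.0, 100.0)], "low")
        high = _ms2(400.2, 5.01, 20.0, [(150.0, 900.0)], "high")
        (sset,) = build_spectrum_sets([prec], [low, high])
        assert sset.spectra[20.0].scan_id == "high"

    def test_uncovered_precursor_dropped(self):
        prec = make_feature("p", 400.2, rt_min=5.0)
        far = _ms2(500.0, 5.0, 20.0, [(150.0, 100.0)])
        assert build_spectrum_sets([prec], [far]) == []


class TestTrackFragments:
    def _set(self, peaks_by_ce, precursor_mz=400.2):
        prec = make_feature("p", precursor_mz, rt_min=5.0)
        spectra = {
            ce: _ms2(precursor_mz, 5.0, ce, peaks) for ce, peaks in peaks_by_ce.items()
        }
        return PrecursorSpectrumSet(precursor=prec, spectra=spectra)

    def test_half_dalton_grouping(self):
        # 150.10 vs 150.45: delta 0.35 <= 0.5 -> one group
        sset = self._set({10.0: [(150.10, 500.0)], 20.0: [(150.45, 800.0)]})
        profiles = track_fragments(sset)
        assert len(profiles) == 1
        assert profiles[0].fragment.n_energies == 2

    def test_beyond_tolerance_two_groups(self):
        sset = self._set({10.0: [(150.10, 500.0)], 20.0: [(150.80, 800.0)]})
        profiles = track_fragments(sset)
        assert len(profiles) == 2

    def test_single_energy_not_spline_eligible(self):
        sset = self._set({40.0: [(150.10, 500.0)]})
        (profile,) = track_fragments(sset)
        assert profile.fragment.n_energies == 1
        assert not profile.eligible_for_spline

    def test_top_ten_cap_per_energy(self):
        peaks = [(100.0 + 5 * i, 1000.0 - i) for i in range(15)]
        sset = self._set({20.0: peaks})
        profiles = track_fragments(sset)
        assert len(profiles) == 10
        kept = {p.fragment.group_mz for p in profiles}
        assert kept == {100.0 + 5 * i for i in range(10)}

    def test_precursor_proximity_excluded(self):
        sset = self._set(
            {20.0: [(399.0, 5000.0), (398.3, 4000.0), (150.0, 100.0)]},
            precursor_mz=400.2,
        )
        profiles = track_fragments(sset)
        assert [p.fragment.group_mz for p in profiles] == [150.0]
        for p in profiles:
            assert abs(p.precursor_mz - p.fragment.group_mz) >= 2.0

    def test_peak_order_permutation_invariant(self):
        peaks_by_ce = {
            0.0: [(150.1, 300.0), (210.4, 900.0), (87.2, 50.0)],
            10.0: [(150.3, 700.0), (210.2, 600.0)],
            20.0: [(150.2, 950.0), (87.0, 80.0)],
            40.0: [(150.4, 200.0)],
        }
        ref = track_fragments(self._set(peaks_by_ce))
        rng = random.Random(0)
        for _ in range(5):
            shuffled = {
                ce: rng.sample(peaks, len(peaks)) for ce, peaks in peaks_by_ce.items()
            }
            got = track_fragments(self._set(shuffled))
            assert [
                (round(p.fragment.group_mz, 6), sorted(p.fragment.observations.items()))
                for p in got
            ] == [
                (round(p.fragment.group_mz, 6), sorted(p.fragment.observations.items()))
                for p in ref
            ]

    def test_planted_fragments_recovered_exactly(self, noiseless_run):
        from umrm.records import SAMPLED_ENERGIES

        truth = noiseless_run.truth
        comp = truth.compounds[0]
        feats = [f for f in noiseless_run.features if f.feature_id == comp.base_feature_id]
        ms2 = [s for s in noiseless_run.spectra if s.ms_level == 2]
        (sset,) = build_spectrum_sets(feats, ms2)
        profiles = track_fragments(sset)
        spec_floor = 1.0
        for frag in comp.fragments:
            matches = [p for p in profiles if abs(p.fragment.group_mz - frag.mz) <= 0.5]
            assert len(matches) == 1
            obs = matches[0].fragment.observations
            for ce in SAMPLED_ENERGIES:
                expected = frag.response(ce)
                if expected >= spec_floor:
                    assert obs[ce] == pytest.approx(expected, rel=1e-9)
                else:
                    assert ce not in obs


class TestFlagIrregular:
    @pytest.mark.parametrize(
        "intens,expected",
        [
            ((0.0, 100.0, 60.0, 20.0), False),   # monotone after the peak
            ((100.0, 2.0, 90.0, 5.0), True),     # collapses to 2% then rebounds to 90%
            ((10.0, 500.0, 900.0, 950.0), False),  # monotone rising
            ((900.0, 500.0, 100.0, 5.0), False),   # monotone falling
        ],
    )
    def test_rebound_rule(self, intens, expected):
        profile = make_profile(dict(zip((0.0, 10.0, 20.0, 40.0), intens)))
        assert flag_irregular(profile).irregular is expected

    def test_sparse_profiles_not_flagged(self):
        profile = make_profile({0.0: 100.0, 40.0: 90.0})
        assert flag_irregular(profile).irregular is False
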