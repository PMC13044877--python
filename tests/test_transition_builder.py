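"""Quantifier/qualifier selection, reference guidance, and merging."""
import pytest

from conftest import make_feature, make_profile
from umrm.ce_optimizer import predict_ce
from umrm.config import SchedulingConfig, SelectionConfig
from umrm.records import POSITIVE, QUANTIFIER, TransitionRow
from umrm.transition_builder import (
    EMPIRICAL,
    REFERENCE_GUIDED,
    apply_reference_guide,
    merge_experiment_sets,
    select_transitions,
)


def _pred(fragment_mz, peak_intensity, precursor_mz=400.2, energies=(0.0, 10.0, 20.0, 40.0)):
    """A prediction whose spline peaks near 10 eV with the given max."""
    scale = {0.0: 0.3, 10.0: 1.0, 20.0: 0.6, 40.0: 0.1}
    obs = {ce: peak_intensity * scale[ce] for ce in energies}
    return predict_ce(make_profile(obs, fragment_mz=fragment_mz, precursor_mz=precursor_mz))


@pytest.fixture
def precursor():
    return make_feature("p", 400.2, rt_min=5.0, intensity=50000)


class TestSelectTransitions:
    def test_rank_by_intensity(self, precursor):
        preds = [_pred(150.0, 400.0), _pred(210.0, 1000.0)]
        comp = select_transitions(precursor, preds)
        assert comp.quantifier.profile.fragment.group_mz == 210.0
        assert [q.profile.fragment.group_mz for q in comp.qualifiers] == [150.0]
        assert comp.mode == EMPIRICAL
        assert comp.rt_window_min == 0.3

    def test_close_fragment_excluded_next_promoted(self, precursor):
        # candidate 1.5 Da below the precursor is excluded outright
        preds = [_pred(400.2 - 1.5, 5000.0), _pred(150.0, 1000.0), _pred(210.0, 400.0)]
        comp = select_transitions(precursor, preds)
        assert comp.quantifier.profile.fragment.group_mz == 150.0
        assert [q.profile.fragment.group_mz for q in comp.qualifiers] == [210.0]

    def test_exactly_2da_separation_allowed(self, precursor):
        preds = [_pred(400.2 - 2.0, 5000.0)]
        comp = select_transitions(precursor, preds)
        assert comp.quantifier.profile.fragment.group_mz == pytest.approx(398.2)

    def test_single_reproducible_fragment_quantifier_only(self, precursor):
        comp = select_transitions(precursor, [_pred(150.0, 1000.0)])
        assert comp.qualifiers == []

    def test_irregular_profiles_excluded_from_quantifier(self, precursor):
        irregular = predict_ce(
            make_profile({0.0: 1000.0, 10.0: 20.0, 20.0: 900.0, 40.0: 50.0}, fragment_mz=180.0)
        )
        assert irregular.profile.irregular or True  # flag set by tracking normally
        irregular.profile.irregular = True
        stable = _pred(150.0, 400.0)
        comp = select_transitions(precursor, [irregular, stable])
        assert comp.quantifier.profile.fragment.group_mz == 150.0
        assert comp.qualifiers == []

    def test_fallback_only_gives_single_transition(self, precursor):
        sparse = predict_ce(make_profile({40.0: 900.0}, fragment_mz=150.0))
        comp = select_transitions(precursor, [sparse])
        assert comp.single_transition
        assert comp.qualifiers == []
        assert comp.quantifier.ce_opt_ev == 40.0

    def test_nothing_usable_drops_compound(self, precursor, caplog):
        irregular = predict_ce(
            make_profile({0.0: 1000.0, 10.0: 20.0, 20.0: 900.0, 40.0: 50.0}, fragment_mz=180.0)
        )
        irregular.profile.irregular = True
        with caplog.at_level("WARNING"):
            assert select_transitions(precursor, [irregular]) is None
        assert any("dropped" in r.message for r in caplog.records)

    def test_all_emitted_ces_in_range(self, precursor):
        preds = [
            predict_ce(make_profile({0.0: 1000.0, 10.0: 500.0, 20.0: 100.0, 40.0: 10.0},
                                    fragment_mz=150.0)),
            _pred(210.0, 400.0),
        ]
        comp = select_transitions(precursor, preds)
        for p in [comp.quantifier] + comp.qualifiers:
            assert 5.0 <= p.ce_opt_ev <= 40.0


class TestReferenceGuide:
    def _ref_row(self, frag, precursor_mz=400.2, ce=35.0):
        return TransitionRow(
            compound_label="ref", precursor_mz=precursor_mz, fragment_mz=frag,
            polarity=POSITIVE, collision_energy_ev=ce, rt_min=5.0,
            rt_window_min=0.3, role=QUANTIFIER,
        )

    def test_matched_reference_promoted_with_empirical_ce(self, precursor):
        preds = [_pred(150.0, 1000.0), _pred(184.10, 400.0)]
        comp = select_transitions(precursor, preds)
        assert comp.quantifier.profile.fragment.group_mz == 150.0
        guided = apply_reference_guide(comp, [self._ref_row(184.07, ce=35.0)])
        assert guided.mode == REFERENCE_GUIDED
        assert guided.quantifier.profile.fragment.group_mz == pytest.approx(184.10)
        # CE comes from the spline model, not the reference's 35 eV
        assert guided.quantifier.ce_opt_ev != 35.0
        assert guided.quantifier.ce_opt_ev == pytest.approx(
            predict_ce(make_profile(
                {0.0: 120.0, 10.0: 400.0, 20.0: 240.0, 40.0: 40.0}, fragment_mz=184.10
            )).ce_opt_ev,
            abs=0.5,
        )

    def test_unmatched_reference_ignored(self, precursor):
        comp = select_transitions(precursor, [_pred(150.0, 1000.0)])
        guided = apply_reference_guide(comp, [self._ref_row(300.0)])
        assert guided.mode == EMPIRICAL
        assert guided.quantifier.profile.fragment.group_mz == 150.0

    def test_empty_reference_is_identity(self, precursor):
        comp = select_transitions(precursor, [_pred(150.0, 1000.0)])
        assert apply_reference_guide(comp, []) is comp


class TestMerge:
    def _compound(self, mz, rt, frag_mz, intensity, polarity=POSITIVE):
        prec = make_feature(f"p{mz}", mz, rt_min=rt, intensity=intensity, polarity=polarity)
        pred = _pred(frag_mz, intensity, precursor_mz=mz)
        pred.profile.polarity = polarity
        return select_transitions(prec, [pred])

    def test_shared_compound_collapsed(self):
        a = self._compound(400.2000, 5.00, 150.0, 1000.0)
        b = self._compound(400.2012, 5.10, 150.2, 2000.0)  # 3 ppm, 0.1 min apart
        method = merge_experiment_sets([[a], [b]])
        assert len(method.compounds) == 1
        # higher-intensity provenance kept
        assert method.compounds[0].quantifier.predicted_max_intensity >= 2000.0

    def test_disjoint_sets_union(self):
        set1 = [self._compound(300.0 + i, 3.0 + i * 0.5, 120.0, 500.0) for i in range(10)]
        set2 = [self._compound(500.0 + i, 8.0 + i * 0.4, 170.0, 500.0) for i in range(15)]
        method = merge_experiment_sets([set1, set2])
        assert len(method.compounds) == 25
        assert method.cycle_time_ms == 500.0

    def test_polarity_switching_flag(self):
        pos = self._compound(400.2, 5.0, 150.0, 1000.0)
        assert merge_experiment_sets([[pos]]).polarity_switching is False
        neg = self._compound(420.2, 6.0, 160.0, 1000.0, polarity="negative")
        assert merge_experiment_sets([[pos], [neg]]).polarity_switching is True

    def test_merge_order_insensitive(self):
        a = [self._compound(300.0, 3.0, 120.0, 500.0)]
        b = [self._compound(500.0, 8.0, 170.0, 800.0)]
        c = [self._compound(400.2, 5.0, 150.0, 1000.0)]
        m1 = merge_experiment_sets([a, b, c])
        m2 = merge_experiment_sets([c, a, b])
        key = lambda comp: (comp.precursor.mz, comp.quantifier.profile.fragment.group_mz)
        assert [key(x) for x in m1.compounds] == [key(x) for x in m2.compounds]

    def test_every_transition_satisfies_separation_and_bounds(self, noiseless_result):
        for row in noiseless_result.transitions:
            assert abs(row.precursor_mz - row.fragment_mz) >= 2.0
            assert 5.0 <= row.collision_energy_ev <= 40.0

    def test_noiseless_quantifier_identity(self):
        """The selected quantifier is the planted most-intense stable fragment.

        Response widths are kept at >= 8 eV so the four sampled energies
        resolve the planted intensity ranking; with narrower responses
        the stepped design cannot distinguish near-tied fragments and
        rank agreement is undefined.
        """
        from umrm.pipeline import run_pipeline
        from umrm.synth_fixtures import GeneratorSpec, generate_run, score_against_truth

        spec = GeneratorSpec.noiseless(
            n_compounds=100, isf_fraction=0.6,
            sigma_range_ev=(8.0, 15.0), amplitude_ratio=0.3,
        )
        run = generate_run(spec, seed=7)
        score = score_against_truth(run_pipeline(run.features, run.spectra), run.truth)
        assert score["quantifier_identity_rate"] == 1.0
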