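"""Species spectra, transition assignment, band tools, topology discrimination."""

import numpy as np
import pytest

from cyclefit.analysis import (
    GTACR1_TRANSITION_REFERENCE,
    amplitude_spectra_to_species,
    assign_transitions,
    band_scale_factor,
    detect_band,
    discriminate_topologies,
    noise_threshold,
    scale_to_band,
)
from cyclefit.dataset import Spectrum
from cyclefit.globalfit import fit_global
from cyclefit.kinetics import GROUND, KineticScheme, get_template
from cyclefit.synthetic import (
    Band,
    PhotocycleModel,
    default_gtacr1_model,
    simulate_dataset,
)


def small_chain_model():
    scheme = KineticScheme(
        states=(GROUND, "A", "B"),
        rates=(("A", "B", 200.0), ("B", GROUND, 4.0)),
        initial={"A": 1.0},
    )
    spectra = {
        "A": (Band(1200.0, 10.0, 1.0), Band(1500.0, 12.0, -0.8)),
        "B": (Band(1300.0, 10.0, 0.6), Band(1500.0, 12.0, -0.8)),
    }
    return PhotocycleModel(scheme=scheme, species_spectra=spectra)


class TestSpeciesReconstruction:
    def test_single_state_scheme_is_identity(self):
        scheme = KineticScheme(states=(GROUND, "A"), rates=(("A", GROUND, 5.0),),
                               initial={"A": 1.0})
        model = PhotocycleModel(scheme=scheme,
                                species_spectra={"A": (Band(1200.0, 10.0, 1.0),)})
        ds = simulate_dataset(model, axis=np.arange(1150.0, 1251.0, 2.0),
                              times=np.geomspace(1e-3, 2, 40))
        fit = fit_global(ds, 1, n_starts=3, seed=0)
        spectra = amplitude_spectra_to_species(fit, scheme)
        assert np.allclose(spectra["A"].values, fit.amplitude_spectra[0], atol=1e-12)

    def test_generator_round_trip_on_chain(self):
        model = small_chain_model()
        axis = np.arange(1100.0, 1601.0, 2.0)
        ds = simulate_dataset(model, axis=axis, times=np.geomspace(1e-4, 5, 60))
        fit = fit_global(ds, 2, n_starts=4, seed=0)
        spectra = amplitude_spectra_to_species(fit, model.scheme)
        for state in ("A", "B"):
            expect = model.state_spectrum(state, axis).values
            err = np.max(np.abs(spectra[state].values - expect))
            assert err < 1e-6 * np.max(np.abs(expect))

    def test_reversible_scheme_rejected(self):
        scheme = KineticScheme(
            states=(GROUND, "A", "B"),
            rates=(("A", "B", 10.0), ("B", "A", 3.0), ("B", GROUND, 1.0)),
            initial={"A": 1.0},
        )
        model = small_chain_model()
        ds = simulate_dataset(model, times=np.geomspace(1e-4, 5, 30),
                              axis=np.arange(1100.0, 1601.0, 10.0))
        fit = fit_global(ds, 2, n_starts=3, seed=0)
        with pytest.raises(ValueError, match="reversible"):
            amplitude_spectra_to_species(fit, scheme)

    def test_rate_mismatch_rejected(self):
        model = small_chain_model()
        wrong = KineticScheme(
            states=(GROUND, "A", "B"),
            rates=(("A", "B", 500.0), ("B", GROUND, 4.0)),  # 2.5x off
            initial={"A": 1.0},
        )
        ds = simulate_dataset(model, axis=np.arange(1100.0, 1601.0, 10.0),
                              times=np.geomspace(1e-4, 5, 50))
        fit = fit_global(ds, 2, n_starts=4, seed=0)
        with pytest.raises(ValueError, match="deviates"):
            amplitude_spectra_to_species(fit, wrong)


class TestAssignTransitions:
    @staticmethod
    def _perfect_fit():
        """Fit of the noiseless default model on a coarse grid."""
        model = default_gtacr1_model()
        ds = simulate_dataset(model, axis=np.arange(1100.0, 1801.0, 8.0),
                              times=np.geomspace(1e-7, 20, 80))
        return fit_global(ds, 6, n_starts=8, seed=1)

    def test_fast_opening_matched_with_unit_ratio(self):
        fit = self._perfect_fit()
        assignment = assign_transitions(fit, GTACR1_TRANSITION_REFERENCE)
        t2 = assignment.entries[1]
        assert t2.name == "T2"
        assert "fast channel opening" in t2.label
        assert t2.ratio == pytest.approx(1.0, rel=1e-4)
        fitted = [e.fitted_halflife for e in assignment]
        assert fitted == sorted(fitted)

    def test_single_transition_case(self):
        scheme = KineticScheme(states=(GROUND, "A"), rates=(("A", GROUND, 5.0),),
                               initial={"A": 1.0})
        model = PhotocycleModel(scheme=scheme,
                                species_spectra={"A": (Band(1200.0, 10.0, 1.0),)})
        ds = simulate_dataset(model, axis=np.arange(1150.0, 1251.0, 5.0),
                              times=np.geomspace(1e-3, 2, 30))
        fit = fit_global(ds, 1, n_starts=2, seed=0)
        assignment = assign_transitions(fit, [(np.log(2) / 5.0, "only decay")])
        assert len(assignment.entries) == 1
        assert assignment.entries[0].ratio == pytest.approx(1.0, rel=1e-5)

    def test_assignment_depends_only_on_sorted_reference(self):
        fit = self._perfect_fit()
        shuffled = list(GTACR1_TRANSITION_REFERENCE)[::-1]
        a = assign_transitions(fit, GTACR1_TRANSITION_REFERENCE)
        b = assign_transitions(fit, shuffled)
        assert [(e.label, e.ratio) for e in a] == [(e.label, e.ratio) for e in b]

    def test_length_mismatch_rejected(self):
        fit = self._perfect_fit()
        with pytest.raises(ValueError, match="transitions"):
            assign_transitions(fit, [(1.0, "x")])


class TestBandTools:
    @staticmethod
    def _spec(scale=1.0):
        axis = np.arange(1100.0, 1301.0, 1.0)
        vals = scale * (np.exp(-((axis - 1234.0) ** 2) / 50.0)
                        - 0.4 * np.exp(-((axis - 1150.0) ** 2) / 80.0))
        return Spectrum(axis=axis, values=vals)

    def test_scale_to_itself_is_one(self):
        s = self._spec()
        assert band_scale_factor(s, s, 1234.0, 20.0) == pytest.approx(1.0)

    def test_triple_spectrum_scales_one_third(self):
        ref = self._spec()
        assert band_scale_factor(self._spec(3.0), ref, 1234.0, 20.0) == \
            pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_scaled_extrema_agree(self):
        ref = self._spec()
        scaled = scale_to_band(self._spec(0.37), ref, 1234.0, 20.0)
        win = (ref.axis >= 1224) & (ref.axis <= 1244)
        assert np.max(np.abs(scaled.values[win])) == \
            pytest.approx(np.max(np.abs(ref.values[win])), abs=1e-12)

    def test_scaling_is_idempotent(self):
        ref = self._spec()
        once = scale_to_band(self._spec(5.0), ref, 1234.0, 20.0)
        assert band_scale_factor(once, ref, 1234.0, 20.0) == pytest.approx(1.0, rel=1e-12)

    def test_zero_band_rejected(self):
        s = self._spec()
        zero = Spectrum(axis=s.axis, values=np.zeros_like(s.values))
        with pytest.raises(ValueError, match="zero amplitude"):
            band_scale_factor(zero, s, 1234.0, 20.0)

    def test_detection_monotone_in_threshold(self):
        s = self._spec()
        thresholds = np.linspace(0, 2, 20)
        hits = [detect_band(s, 1234.0, 12.0, t).detected for t in thresholds]
        assert all(a >= b for a, b in zip(hits[:-1], hits[1:]))  # never re-detects

    def test_zero_threshold_detects_any_nonzero(self):
        assert detect_band(self._spec(), 1150.0, 10.0, 0.0).detected

    def test_quiet_region_threshold(self):
        s = self._spec()
        thr = noise_threshold(s, 1290.0, 1300.0, n_sigma=3.0)
        assert thr >= 0.0
        assert detect_band(s, 1234.0, 12.0, max(thr, 0.05)).detected

    def test_syn_marker_absent_unless_injected(self, gtacr1_model):
        axis = np.arange(1100.0, 1801.0, 2.0)
        threshold = 0.05
        for state in gtacr1_model.scheme.nonground_states:
            sp = gtacr1_model.state_spectrum(state, axis)
            assert not detect_band(sp, 1154.0, 12.0, threshold).detected
        injected = PhotocycleModel(
            scheme=gtacr1_model.scheme,
            species_spectra={
                **gtacr1_model.species_spectra,
                "L2": gtacr1_model.species_spectra["L2"] + (Band(1154.0, 8.0, 0.1),),
            },
        )
        sp = injected.state_spectrum("L2", axis)
        det = detect_band(sp, 1154.0, 12.0, threshold)
        assert det.detected and abs(det.peak_position - 1154.0) <= 6.0


class TestTopologyDiscrimination:
    @staticmethod
    def _data(noise=0.0, seed=0, n_times=60):
        model = default_gtacr1_model()
        return simulate_dataset(
            model,
            axis=np.arange(1100.0, 1801.0, 8.0),
            times=np.geomspace(1e-7, 20, n_times),
            noise_sigma=noise,
            seed=seed if noise else None,
        )

    def test_true_topology_beats_reduced_model(self):
        ds = self._data(noise=0.005, seed=1)
        ranking = discriminate_topologies(
            ds, [get_template("parallel"), get_template("unbranched")],
            n_starts=2, seed=0, tol=1e-8,
        )
        assert ranking.results[0].name == "parallel"
        assert not ranking.indistinguishable

    def test_reparameterized_topologies_indistinguishable_on_noiseless_data(self):
        """Parallel and sequential schemes span the same exponential structure."""
        ds = self._data()
        ranking = discriminate_topologies(
            ds, [get_template("parallel"), get_template("sequential")],
            n_starts=2, seed=0, tol=1e-10,
        )
        assert ranking.indistinguishable

    def test_evidence_grows_with_dataset_size(self):
        """True vs over-parameterized topology: the parsimony margin scales
        with the data size (extra per-channel state spectra cost ~ln M each)."""
        scheme_model = default_gtacr1_model()  # axis only; kinetics below
        tpl_true = get_template("unbranched")
        deltas = []
        for n_times in (40, 120):
            from cyclefit.synthetic import PhotocycleModel, Band, simulate_dataset

            truth = PhotocycleModel(
                scheme=tpl_true.build(reverse_ratio=0.0),
                species_spectra={
                    "K": scheme_model.species_spectra["K"],
                    "L1": scheme_model.species_spectra["L1"],
                    "L2": scheme_model.species_spectra["L2"],
                    "M": scheme_model.species_spectra["M"],
                    "NO": scheme_model.species_spectra["NO"],
                },
            )
            ds = simulate_dataset(
                truth, axis=np.arange(1100.0, 1801.0, 8.0),
                times=np.geomspace(1e-7, 20, n_times),
                noise_sigma=0.02, seed=5,
            )
            r = discriminate_topologies(
                ds, [tpl_true, get_template("parallel")],
                n_starts=2, seed=0, tol=1e-8,
            )
            assert r.results[0].name == "unbranched"
            deltas.append(r.delta_bic)
        assert deltas[1] > deltas[0]

    def test_no_dominated_candidate_ranked_first(self):
        ds = self._data(noise=0.01, seed=2)
        ranking = discriminate_topologies(
            ds,
            [get_template("parallel"), get_template("parallel-exchange"),
             get_template("unbranched")],
            n_starts=2, seed=0, tol=1e-8,
        )
        for hi, lo in zip(ranking.results[:-1], ranking.results[1:]):
            dominated = hi.F > lo.F and hi.n_parameters > lo.n_parameters
            assert not dominated

    def test_fewer_than_two_candidates_rejected(self):
        ds = self._data()
        with pytest.raises(ValueError, match="at least 2"):
            discriminate_topologies(ds, [get_template("parallel")])
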