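"""Generator contracts: closed-form truth, seeded determinism, count laws."""

import numpy as np
import pytest

from nebfish import profile_fit as pf
from nebfish import synthetic as syn
from nebfish.profile_fit import HWHM_FACTOR


class TestProfileTrain:
    def test_noiseless_profile_equals_model_closed_form(self, noiseless_single_unit):
        """Zero-noise, bump-free output is pixel-exactly the forward model."""
        spec, profile, truth, _ = noiseless_single_unit
        expected = pf.eval_unit_model(truth[0], profile.positions)
        np.testing.assert_allclose(profile.intensities, expected, rtol=0, atol=1e-12)

    def test_noiseless_train_is_sum_of_units(self, noiseless_train):
        spec, profile, truth, _ = noiseless_train
        expected = np.full_like(profile.positions, spec.baseline)
        for u in truth:
            expected += pf.eval_unit_model(u, profile.positions) - u.baseline
        np.testing.assert_allclose(profile.intensities, expected, rtol=0, atol=1e-10)

    def test_truth_tf_closed_form(self, noiseless_train):
        """TF = W/2 + sqrt(2 ln 2)*sigma for every unit of the train."""
        _, _, _, measurements = noiseless_train
        expected = 1.6 / 2 + HWHM_FACTOR * 0.15  # 0.97661...
        assert len(measurements) == 8
        for m in measurements:
            assert m.tf_length == pytest.approx(expected, abs=1e-12)
            assert m.tf_length == pytest.approx(0.9766, abs=5e-4)

    def test_seeded_reproducibility(self):
        spec = syn.ProfileSimSpec(noise_sd=0.05, zbump_amplitude=0.2, seed=42)
        p1, _, _ = syn.generate_profile_train(spec)
        p2, _, _ = syn.generate_profile_train(spec)
        assert np.array_equal(p1.intensities, p2.intensities)

    def test_colliding_plateaus_rejected(self):
        with pytest.raises(ValueError, match="collide"):
            syn.ProfileSimSpec(rect_width=2.1, sarcomere_length=2.0)

    @pytest.mark.parametrize("field,value", [("noise_sd", -0.1),
                                             ("pixel_size", 0.0),
                                             ("sigma_left", -1.0)])
    def test_invalid_spec_rejected(self, field, value):
        with pytest.raises(ValueError):
            syn.ProfileSimSpec(**{field: value})

    def test_spec_for_tf_hits_target(self):
        spec = syn.profile_spec_for_tf(0.94, sigma=0.12)
        _, _, meas = syn.generate_profile_train(spec)
        assert meas[0].tf_length == pytest.approx(0.94, abs=1e-12)


class TestJunctionCounts:
    def test_degenerate_mixture_all_canonical(self):
        spec = syn.SpliceSimSpec(event_frequencies={"canonical": 1.0},
                                 total_junction_reads=100, seed=0)
        _, locus = syn.simulate_junction_counts(spec)
        assert locus.canonical_reads == 100
        assert locus.retention_reads == 0
        assert locus.alternative_junctions == ()

    def test_counts_sum_exactly(self):
        spec = syn.SpliceSimSpec(total_junction_reads=12345, seed=9)
        _, locus = syn.simulate_junction_counts(spec)
        assert locus.total_reads == 12345

    def test_psi_law_of_large_numbers(self):
        """Empirical PSI converges to the generating inclusion fraction."""
        from nebfish.splicing import psi

        depth = 200_000
        spec = syn.SpliceSimSpec(true_psi={"e": 0.5}, depth=depth, seed=3)
        records, _ = syn.simulate_junction_counts(spec)
        est = psi(records[0]).psi
        # delta-method sd of the normalized estimator is < binomial sd of p_inc
        sd_pct = 100.0 * 0.5 / np.sqrt(depth)
        assert est == pytest.approx(50.0, abs=3 * sd_pct + 0.05)

    def test_seeded_tables_identical(self):
        spec = syn.SpliceSimSpec(seed=5)
        r1, l1 = syn.simulate_junction_counts(spec)
        r2, l2 = syn.simulate_junction_counts(spec)
        assert r1 == r2 and l1 == l2

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            syn.SpliceSimSpec(event_frequencies={"canonical": 0.7, "alt": 0.2})


class TestToyTranscript:
    def test_canonical_orf_has_single_terminal_stop(self):
        tm = syn.generate_toy_transcript([120, 90, 150], [96, 60], seed=4)
        mrna = tm.canonical_mrna()
        stops = [i for i in range(0, len(mrna), 3)
                 if mrna[i:i + 3] in ("TAA", "TAG", "TGA")]
        assert stops == [len(mrna) - 3]
        assert mrna.startswith("ATG")

    def test_mrna_length_is_sum_of_exons(self):
        tm = syn.generate_toy_transcript([100, 200, 150], [50, 50], seed=1)
        assert len(tm.canonical_mrna()) == 450

    def test_same_seed_same_sequence(self):
        a = syn.generate_toy_transcript([60, 60], [30], seed=8)
        b = syn.generate_toy_transcript([60, 60], [30], seed=8)
        assert a.sequence == b.sequence

    @pytest.mark.parametrize("exons,introns", [([100], []),
                                               ([100, 103], [50]),
                                               ([60, 60], [30, 30])])
    def test_invalid_structures_rejected(self, exons, introns):
        with pytest.raises(ValueError):
            syn.generate_toy_transcript(exons, introns, seed=0)


class TestTwitch:
    def test_noiseless_peak_value_and_time(self):
        spec = syn.TwitchSimSpec(peak_force=1.0, rise_time=30.0, stim_onset=0.0,
                                 noise_sd=0.0)
        tr = syn.simulate_twitch_trace(spec)
        i = int(np.argmax(tr.force))
        assert tr.force[i] == pytest.approx(1.0)
        assert tr.time[i] == pytest.approx(30.0)

    def test_rise_10_to_100_is_ninety_percent_of_rise_time(self):
        spec = syn.TwitchSimSpec(rise_time=30.0, sample_interval=0.1)
        tr = syn.simulate_twitch_trace(spec)
        f = tr.force
        peak_i = int(np.argmax(f))
        t10 = np.interp(0.1 * f[peak_i], f[:peak_i + 1], tr.time[:peak_i + 1])
        assert tr.time[peak_i] - t10 == pytest.approx(27.0, abs=0.1)

    def test_decay_to_10pct_takes_tau_ln10(self):
        spec = syn.TwitchSimSpec(decay_tau=20.0, sample_interval=0.1,
                                 duration=400.0)
        tr = syn.simulate_twitch_trace(spec)
        peak_i = int(np.argmax(tr.force))
        below = np.flatnonzero(tr.force[peak_i:] < 0.1)  # baseline 0, peak 1
        assert tr.time[peak_i + below[0]] - tr.time[peak_i] == pytest.approx(
            20.0 * np.log(10.0), abs=0.2)
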