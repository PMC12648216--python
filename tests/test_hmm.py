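"""Windowing, trial exclusion, emissions and the variational HMM fit."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from raic.hmm import (
    build_emissions,
    exclude_trials,
    fit_vb_hmm,
    max_fixation_gap_s,
    sequence_loglik,
    window_sequence,
)
from raic.synthetic import SyntheticConfig, sample_scanpaths
from raic.types import ROI, ExpertGazePattern, FixationSequence, GazeHMM


def seq_from(onsets_ms, durations_ms=None, condition="colour", **kw):
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    if durations_ms is None:
        durations_ms = np.full(len(onsets_ms), 200.0)
    n = len(onsets_ms)
    return FixationSequence(
        participant_id="p", image_id="i", condition=condition,
        x=np.linspace(100, 500, n), y=np.full(n, 300.0),
        onset_ms=onsets_ms, duration_ms=durations_ms, **kw,
    )


class TestExclusion:
    def test_mid_trial_gap_excludes(self):
        # 2.5 s with no fixation between the two fixations
        s = seq_from([1000.0, 3700.0], [200.0, 26_100.0])
        kept, log = exclude_trials([s])
        assert kept == []
        assert log[0]["rule"] == "fixation_gap"
        assert log[0]["max_gap_s"] == pytest.approx(2.5)

    def test_gap_below_threshold_kept(self):
        onsets = np.arange(0, 30_000, 1900.0)
        s = seq_from(onsets, np.full(len(onsets), 1.0))
        assert max_fixation_gap_s(s) < 2.0
        kept, log = exclude_trials([s])
        assert len(kept) == 1 and log == []

    def test_leading_and_trailing_spans_count(self):
        s = seq_from([2500.0], [25_000.0])  # leading 2.5 s uncovered
        kept, _ = exclude_trials([s])
        assert kept == []

    def test_grayscale_dropped(self):
        onsets = np.arange(0, 30_000, 500.0)
        s = seq_from(onsets, condition="grayscale")
        kept, log = exclude_trials([s])
        assert kept == [] and log[0]["rule"] == "grayscale"

    def test_injected_exclusions_are_found_exactly(self):
        """Gap-injected trials, and only those, land in the exclusion log."""
        from raic.synthetic import gen_roi_layout, gen_strategy_hmms

        cfg = SyntheticConfig(seed=4, n_participants=8)
        egp = gen_roi_layout(cfg, 0)
        hmm = gen_strategy_hmms(egp, "explorative", seed=4)
        pids = [f"p{i}" for i in range(8)]
        seqs = sample_scanpaths(hmm, cfg, pids, "img00", inject_gap_for={"p2", "p5"})
        kept, log = exclude_trials(seqs)
        assert {e["participant_id"] for e in log} == {"p2", "p5"}
        assert len(kept) == 6


class TestWindowing:
    def test_full_window_is_identity(self):
        s = seq_from([500.0, 2900.0, 3100.0])
        w = window_sequence(s, 30)
        assert np.array_equal(w.onset_ms, s.onset_ms)

    def test_half_open_boundary(self):
        s = seq_from([500.0, 2900.0, 3000.0, 3100.0])
        w = window_sequence(s, 3)
        # fixation at exactly 3000 ms belongs to the next window
        assert list(w.onset_ms) == [500.0, 2900.0]

    def test_nested_and_idempotent(self):
        s = seq_from(np.arange(0, 30_000, 700.0))
        w3, w6 = window_sequence(s, 3), window_sequence(s, 6)
        assert set(w3.onset_ms) <= set(w6.onset_ms)
        again = window_sequence(w3, 3)
        assert np.array_equal(again.onset_ms, w3.onset_ms)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            window_sequence(seq_from([100.0]), 0)


class TestEmissions:
    def test_circle_gives_isotropic_sigma_half_radius(self):
        r = 60.0
        egp = ExpertGazePattern("c", [ROI(1, 500, 400, 2 * r, 2 * r, 0.3)])
        _, covs = build_emissions(egp, axis_sigma_divisor=4)
        assert np.allclose(covs[0], (r / 2) ** 2 * np.eye(2), atol=1e-9)

    def test_axis_aligned_is_diagonal(self):
        egp = ExpertGazePattern("d", [ROI(1, 0, 0, 80, 40, 0.0)])
        _, covs = build_emissions(egp)
        assert covs[0][0, 1] == pytest.approx(0.0, abs=1e-12)
        assert covs[0][0, 0] == pytest.approx(20.0**2)
        assert covs[0][1, 1] == pytest.approx(10.0**2)

    def test_rotation_by_pi_is_invariant(self):
        a = ExpertGazePattern("a", [ROI(1, 0, 0, 80, 40, 0.7)])
        b = ExpertGazePattern("b", [ROI(1, 0, 0, 80, 40, 0.7 + np.pi)])
        assert np.allclose(build_emissions(a)[1], build_emissions(b)[1])

    def test_nonpositive_axes_rejected(self):
        with pytest.raises(ValueError):
            ROI(1, 0, 0, 0.0, 40, 0.0)


def _chain_hmm(emissions, A, pi):
    means, covs = emissions
    return GazeHMM(means=means, covs=covs, alpha=np.asarray(pi) * 1e9,
                   beta=np.asarray(A) * 1e9, n_obs=1000)


class TestVBFit:
    def test_single_state_is_trivial(self):
        egp = ExpertGazePattern("one", [ROI(1, 500, 400, 100, 80, 0.0)])
        em = build_emissions(egp)
        s = seq_from([100.0, 600.0, 1200.0])
        fit = fit_vb_hmm(s, em)
        assert fit.pi == pytest.approx([1.0])
        assert np.allclose(fit.A, [[1.0]])

    def test_single_fixation_gives_prior_mean_transitions(self, egp5, emissions5):
        # one fixation at ROI 3's centroid: pi concentrates there, A stays uniform
        roi = egp5.rois[2]
        s = FixationSequence("p", "i", "colour", [roi.cx], [roi.cy], [100.0], [200.0])
        fit = fit_vb_hmm(s, emissions5)
        assert np.argmax(fit.pi) == 2
        assert np.allclose(fit.A, 0.2, atol=1e-12)

    def test_empty_window_rejected(self, emissions5):
        s = seq_from([5000.0])
        with pytest.raises(ValueError):
            fit_vb_hmm(window_sequence(s, 3), emissions5)

    def test_bound_nondecreasing(self, egp5, emissions5):
        from raic.synthetic import gen_strategy_hmms

        gen = gen_strategy_hmms(egp5, "focused", seed=2)
        cfg = SyntheticConfig(seed=2, trial_seconds=60.0)
        seq = sample_scanpaths(gen, cfg, ["p"], "i")[0]
        fit = fit_vb_hmm(seq, emissions5)
        diffs = np.diff(fit.elbo_trace)
        assert np.all(diffs > -1e-8)

    def test_rows_stochastic_and_prior_shrinks_toward_uniform(self, egp5, emissions5):
        from conftest import make_chain

        A = make_chain(5, 0.8)
        gen = _chain_hmm(emissions5, A, np.full(5, 0.2))
        cfg = SyntheticConfig(seed=6, trial_seconds=120.0)
        seq = sample_scanpaths(gen, cfg, ["p"], "i")[0]
        uniform = np.full((5, 5), 0.2)
        dists = []
        for strength in (1.0, 10.0, 100.0):
            fit = fit_vb_hmm(seq, emissions5, prior_strength=strength)
            assert np.allclose(fit.A.sum(axis=1), 1.0, atol=1e-10)
            assert fit.pi.sum() == pytest.approx(1.0, abs=1e-10)
            dists.append(np.linalg.norm(fit.A - uniform))
        assert dists[0] > dists[1] > dists[2]

    @pytest.mark.parametrize("t_seconds,max_err", [(70.0, 0.15), (670.0, 0.055)])
    def test_parameter_recovery_improves_with_t(self, egp5, emissions5, t_seconds, max_err):
        from conftest import make_chain

        A = make_chain(5, 0.8)
        gen = _chain_hmm(emissions5, A, np.full(5, 0.2))
        cfg = SyntheticConfig(seed=0, trial_seconds=t_seconds)
        seq = sample_scanpaths(gen, cfg, ["p"], "i")[0]
        fit = fit_vb_hmm(seq, emissions5)
        assert np.abs(fit.A - A).max() < max_err


class TestSequenceLoglik:
    def test_single_fixation_at_mode_is_density_log(self):
        egp = ExpertGazePattern("one", [ROI(1, 500, 400, 100, 80, 0.0)])
        means, covs = build_emissions(egp)
        hmm = _chain_hmm((means, covs), [[1.0]], [1.0])
        s = FixationSequence("p", "i", "colour", [500.0], [400.0], [10.0], [200.0])
        expected = multivariate_normal(means[0], covs[0]).logpdf([500.0, 400.0])
        assert sequence_loglik(hmm, s) == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_path_enumeration(self, egp5, emissions5):
        """T=4, n=3: forward algorithm equals the sum over all 81 paths."""
        from itertools import product

        means, covs = emissions5[0][:3], emissions5[1][:3]
        rng = np.random.default_rng(5)
        A = rng.dirichlet(np.ones(3), size=3)
        pi = rng.dirichlet(np.ones(3))
        hmm = GazeHMM(means=means, covs=covs, alpha=pi * 1e9, beta=A * 1e9)
        xs = rng.uniform(100, 900, 4)
        ys = rng.uniform(100, 700, 4)
        s = FixationSequence("p", "i", "colour", xs, ys,
                             [0.0, 300.0, 600.0, 900.0], np.full(4, 150.0))
        dens = np.array(
            [[multivariate_normal(means[j], covs[j]).pdf([xs[t], ys[t]])
              for j in range(3)] for t in range(4)]
        )
        total = 0.0
        for path in product(range(3), repeat=4):
            p = pi[path[0]] * dens[0, path[0]]
            for t in range(1, 4):
                p *= A[path[t - 1], path[t]] * dens[t, path[t]]
            total += p
        assert sequence_loglik(hmm, s) == pytest.approx(np.log(total), abs=1e-10)

    def test_appending_fixations_decreases_loglik(self, egp5, emissions5):
        from conftest import make_chain

        hmm = _chain_hmm(emissions5, make_chain(5, 0.5), np.full(5, 0.2))
        cfg = SyntheticConfig(seed=8, trial_seconds=30.0)
        seq = sample_scanpaths(hmm, cfg, ["p"], "i")[0]
        lls = [
            sequence_loglik(hmm, FixationSequence(
                "p", "i", "colour", seq.x[:t], seq.y[:t],
                seq.onset_ms[:t], seq.duration_ms[:t]))
            for t in range(1, len(seq) + 1)
        ]
        assert np.all(np.diff(lls) < 0)

    def test_empty_sequence_rejected(self, egp5, emissions5):
        hmm = _chain_hmm(emissions5, np.full((5, 5), 0.2), np.full(5, 0.2))
        empty = FixationSequence("p", "i", "colour", [], [], [], [])
        with pytest.raises(ValueError):
            sequence_loglik(hmm, empty)
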