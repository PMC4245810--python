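import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leakyscan.errors import ContractError
from leakyscan.model import Method, ScanSimConfig
from leakyscan.probability import ls_probabilities, pas_probabilities
from leakyscan.selection import OrfLabel, classify_orf_configuration
from leakyscan.simulate import (
    assign_codons_and_sequences,
    expected_counts,
    recovery_experiment,
    sample_counts,
)

from conftest import make_tis_set


class TestExpectedCounts:
    def test_weak_then_two_strong(self):
        """One 20%-efficient then two 80%-efficient TISs under 1000
        scanning ribosomes yield 200/640/128 with 32 undetected."""
        counts, residual = expected_counts([0.2, 0.8, 0.8], 1000)
        assert counts == pytest.approx([200.0, 640.0, 128.0])
        assert residual == pytest.approx(32.0)

    def test_absorbing_start(self):
        counts, residual = expected_counts([1.0], 777)
        assert counts == [777.0] and residual == 0.0

    def test_halving(self):
        counts, residual = expected_counts([0.5, 0.5], 4)
        assert counts == pytest.approx([2.0, 1.0])
        assert residual == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.lists(
            st.floats(min_value=1e-4, max_value=1.0), min_size=1, max_size=8
        ),
        budget=st.floats(min_value=1.0, max_value=1e8),
    )
    def test_conservation(self, p, budget):
        counts, residual = expected_counts(p, budget)
        assert math.isclose(
            sum(counts) + residual, budget, rel_tol=1e-12
        )

    def test_invalid_probability_rejected(self):
        with pytest.raises(Exception):
            expected_counts([0.0], 10)


class TestSampleCounts:
    def test_counts_within_binomial_noise_of_expectation(self):
        config = ScanSimConfig(
            n_transcripts=1,
            tis_per_transcript=3,
            true_probabilities=[0.2, 0.8, 0.8],
            ribosome_budget=100_000,
            seed=11,
        )
        sim = sample_counts(config)
        budget = 100_000
        expected, _ = expected_counts([0.2, 0.8, 0.8], budget)
        # by binomial thinning, count_i ~ Binomial(budget, mu_i / budget)
        # marginally, which absorbs upstream sampling noise
        for signal, mu in zip(sim.observed[0].signals, expected):
            pi = mu / budget
            sd = math.sqrt(budget * pi * (1 - pi))
            assert abs(signal - mu) < 3 * sd

    def test_budget_conserved_per_transcript(self):
        config = ScanSimConfig(
            n_transcripts=20, ribosome_budget=5000, seed=3
        )
        sim = sample_counts(config)
        for tx, group in sim.truth.groupby("transcript_id"):
            assert group["count"].sum() + sim.uninitiated[tx] == 5000

    def test_seed_determinism(self):
        config = ScanSimConfig(n_transcripts=10, seed=42)
        a, b = sample_counts(config), sample_counts(config)
        assert a.truth.equals(b.truth)
        for ts_a, ts_b in zip(a.observed, b.observed):
            assert ts_a.signals == ts_b.signals

    def test_threshold_hides_but_truth_retains(self):
        config = ScanSimConfig(
            n_transcripts=5,
            ribosome_budget=100,
            detection_threshold=1e9,
            seed=0,
        )
        sim = sample_counts(config)
        assert all(len(ts) == 0 for ts in sim.observed)
        assert len(sim.truth) == 10  # 2 planted TISs per transcript
        assert not sim.truth["detected"].any()

    def test_mean_converges_to_expectation(self):
        """Law of large numbers over transcripts sharing one truth."""
        config = ScanSimConfig(
            n_transcripts=400,
            tis_per_transcript=2,
            true_probabilities=[0.3, 0.6],
            ribosome_budget=1000,
            seed=7,
        )
        sim = sample_counts(config)
        expected, _ = expected_counts([0.3, 0.6], 1000)
        means = sim.truth.groupby("rank")["count"].mean()
        assert means[1] == pytest.approx(expected[0], rel=0.02)
        assert means[2] == pytest.approx(expected[1], rel=0.02)

    def test_loss_hook_thins_scanning_pool(self):
        base = ScanSimConfig(
            n_transcripts=200,
            tis_per_transcript=2,
            true_probabilities=[0.5, 0.5],
            ribosome_budget=1000,
            seed=5,
        )
        lossy = ScanSimConfig(**{**base.__dict__, "loss_hook": 0.3})
        mean_base = sample_counts(base).truth.groupby("rank")["count"].mean()
        mean_lossy = sample_counts(lossy).truth.groupby("rank")["count"].mean()
        # 30% of the pool is lost before each TIS
        assert mean_lossy[1] == pytest.approx(0.7 * mean_base[1], rel=0.05)


class TestAssignCodonsAndSequences:
    @pytest.mark.parametrize(
        "label, positions",
        [
            (OrfLabel.SAME_ORF, (12, 21)),
            (OrfLabel.SEPARATED_ORFS, (12, 24)),
            (OrfLabel.OVERLAPPING_ORFS, (12, 22)),
        ],
    )
    def test_requested_configuration_realized(self, label, positions):
        ts = make_tis_set([5.0, 3.0], positions=list(positions))
        config = ScanSimConfig(seed=9)
        out = assign_codons_and_sequences([ts], config, orf_configuration=label)
        a, b = out[0].positions
        assert classify_orf_configuration(a, b, out[0].sequence).label is label

    def test_impossible_frame_request_rejected(self):
        ts = make_tis_set([1.0, 1.0], positions=[12, 22])  # offset 1
        with pytest.raises(ContractError):
            assign_codons_and_sequences(
                [ts], ScanSimConfig(), orf_configuration=OrfLabel.SAME_ORF
            )

    def test_single_codon_pool(self):
        ts = make_tis_set([1.0, 1.0, 1.0])
        config = ScanSimConfig(codon_pool={"ATG": 1.0}, seed=2)
        out = assign_codons_and_sequences([ts], config)
        assert [t.codon for t in out[0].tis_list] == ["ATG"] * 3

    def test_sequence_invariant_holds(self):
        ts = make_tis_set([1.0, 2.0, 3.0])
        out = assign_codons_and_sequences([ts], ScanSimConfig(seed=1))
        seq = out[0].sequence
        for t in out[0].tis_list:
            assert seq[t.position : t.position + 3] == t.codon


class TestRecoveryExperiment:
    def test_expected_mode_ls_is_exact(self):
        config = ScanSimConfig(
            n_transcripts=20,
            tis_per_transcript=3,
            true_probabilities=(0.05, 0.9),
            ribosome_budget=1000,
            seed=13,
        )
        report = recovery_experiment(config, Method.LS,
                                     ru_policy="residual", mode="expected")
        assert np.allclose(report.by_rank["bias"], 0.0, atol=1e-12)
        assert np.allclose(report.by_rank["rmse"], 0.0, atol=1e-12)

    def test_pas_downstream_attenuation_closed_form(self):
        """On noise-free two-TIS data the PAS downstream estimate is
        p2(1-p1)/(p1 + p2(1-p1)) — attenuated by upstream initiation —
        while the LS estimate is p2 itself."""
        p1, p2 = 0.4, 0.7
        counts, residual = expected_counts([p1, p2], 10_000)
        ts = make_tis_set(counts)
        pas = pas_probabilities(ts).probabilities
        ls = ls_probabilities(ts, ru=residual).probabilities
        closed_form = p2 * (1 - p1) / (p1 + p2 * (1 - p1))
        assert pas[1] == pytest.approx(closed_form, abs=1e-12)
        assert ls[1] == pytest.approx(p2, abs=1e-12)
        # varying upstream p1 moves PAS but not LS downstream estimates
        for p1_alt in (0.1, 0.8):
            counts_alt, residual_alt = expected_counts([p1_alt, p2], 10_000)
            ts_alt = make_tis_set(counts_alt)
            assert pas_probabilities(ts_alt).probabilities[1] != pytest.approx(
                pas[1], abs=1e-6
            )
            assert ls_probabilities(
                ts_alt, ru=residual_alt
            ).probabilities[1] == pytest.approx(p2, abs=1e-12)

    def test_stochastic_ls_beats_pas_downstream(self):
        config = ScanSimConfig(
            n_transcripts=200,
            tis_per_transcript=2,
            true_probabilities=(0.1, 0.8),
            ribosome_budget=100_000,
            seed=21,
        )
        ls_report = recovery_experiment(
            config, Method.LS, ru_policy="residual", mode="sample"
        )
        pas_report = recovery_experiment(config, Method.PAS, mode="sample")
        ls_rmse = ls_report.by_rank.set_index("rank")["rmse"]
        pas_rmse = pas_report.by_rank.set_index("rank")["rmse"]
        assert ls_rmse[2] < pas_rmse[2]

    def test_deterministic_under_seed(self):
        config = ScanSimConfig(n_transcripts=10, seed=4)
        a = recovery_experiment(config, Method.LS, mode="sample")
        b = recovery_experiment(config, Method.LS, mode="sample")
        assert a.per_tis.equals(b.per_tis)

    def test_bad_mode_rejected(self):
        with pytest.raises(ContractError):
            recovery_experiment(ScanSimConfig(), mode="nope")
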