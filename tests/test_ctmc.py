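"""CTMC of vagitype dynamics: sequences, matrix exponential, MLE, diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vmptb as v
from vmptb.ctmc import (
    DEFAULT_STATES,
    count_transitions,
    transition_probability,
)


def two_state_P(a, b, t):
    """Closed-form transition matrix of the 2-state chain (rates a, b)."""
    s = a + b
    e = np.exp(-s * t)
    return np.array([
        [(b + a * e) / s, a * (1 - e) / s],
        [b * (1 - e) / s, (a + b * e) / s],
    ])


class TestBuildStateSequences:
    @staticmethod
    def _inputs(rows):
        assign = pd.DataFrame(rows, columns=["sample_id", "vagitype"])
        rec = pd.DataFrame({
            "sample_id": assign["sample_id"],
            "subject_id": [s.split("_")[0] for s in assign["sample_id"]],
            "gestational_age": [int(s.split("_")[1]) for s in assign["sample_id"]],
            "outcome": "TB",
        })
        return assign, rec

    def test_self_transition_interval(self):
        assign, rec = self._inputs([
            ("u1_100", "Lactobacillus_crispatus_cluster"),
            ("u1_128", "Lactobacillus_crispatus_cluster"),
        ])
        seqs = v.build_state_sequences(assign, rec)
        assert seqs["u1"] == [("Lactobacillus_crispatus_cluster", 100),
                              ("Lactobacillus_crispatus_cluster", 128)]

    def test_non_focal_vagitype_maps_to_other(self):
        assign, rec = self._inputs([("u1_100", "Clostridiales_BVAB2"),
                                    ("u1_128", "UNASSIGNED")])
        seqs = v.build_state_sequences(assign, rec)
        assert [s for s, _ in seqs["u1"]] == ["Other", "Other"]

    def test_single_visit_subject_kept_without_transitions(self):
        assign, rec = self._inputs([("u1_100", "Lactobacillus_iners")])
        seqs = v.build_state_sequences(assign, rec)
        assert len(seqs["u1"]) == 1
        assert count_transitions(seqs).sum() == 0

    def test_duplicate_day_collapsed(self, caplog):
        assign = pd.DataFrame({
            "sample_id": ["u1_b", "u1_a", "u1_c"],
            "vagitype": ["Gardnerella_vaginalis", "Lactobacillus_iners", "Other"],
        })
        rec = pd.DataFrame({
            "sample_id": ["u1_b", "u1_a", "u1_c"],
            "subject_id": "u1",
            "gestational_age": [100, 100, 128],
            "outcome": "TB",
        })
        with caplog.at_level("WARNING"):
            seqs = v.build_state_sequences(assign, rec)
        assert seqs["u1"][0] == ("Lactobacillus_iners", 100)  # lexicographic first


class TestTransitionProbability:
    def test_time_zero_is_identity(self):
        Q = np.array([[-0.1, 0.1], [0.2, -0.2]])
        np.testing.assert_allclose(transition_probability(Q, 0.0), np.eye(2))

    def test_two_state_closed_form(self):
        a, b = 0.03, 0.07
        Q = np.array([[-a, a], [b, -b]])
        for t in (1.0, 10.0, 91.0):
            np.testing.assert_allclose(transition_probability(Q, t),
                                       two_state_P(a, b, t), atol=1e-12)

    def test_semigroup_property(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            off = rng.uniform(0, 0.05, size=(4, 4))
            np.fill_diagonal(off, 0)
            Q = off - np.diag(off.sum(axis=1))
            s, t = rng.uniform(1, 50, 2)
            np.testing.assert_allclose(
                transition_probability(Q, s + t),
                transition_probability(Q, s) @ transition_probability(Q, t),
                atol=1e-9)

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            off = rng.uniform(0.001, 0.05, size=(4, 4))
            np.fill_diagonal(off, 0)
            Q = off - np.diag(off.sum(axis=1))
            vals, vecs = np.linalg.eig(Q)
            t = 30.0
            P_eig = (vecs @ np.diag(np.exp(vals * t)) @ np.linalg.inv(vecs)).real
            np.testing.assert_allclose(transition_probability(Q, t), P_eig,
                                       atol=1e-8)

    def test_invalid_generator_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(np.array([[-0.1, 0.2], [0.1, -0.1]]), 1.0)
        with pytest.raises(ValueError):
            transition_probability(np.array([[0.1, -0.1], [0.1, -0.1]]), 1.0)


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        Q = np.array([[-1.0, 1.0], [2.0, -2.0]])
        np.testing.assert_allclose(v.stationary_distribution(Q), [2 / 3, 1 / 3],
                                   atol=1e-9)

    def test_zero_generator_keeps_initial(self):
        pi = v.stationary_distribution(np.zeros((3, 3)))
        np.testing.assert_allclose(pi, [1, 0, 0])  # row of the identity

    def test_null_space_residual(self):
        rng = np.random.default_rng(14)
        off = rng.uniform(0.005, 0.05, size=(5, 5))
        np.fill_diagonal(off, 0)
        Q = off - np.diag(off.sum(axis=1))
        pi = v.stationary_distribution(Q)
        assert np.max(np.abs(pi @ Q)) < 1e-6


class TestDynamicBalance:
    def test_symmetric_generator_balances(self):
        Q = np.array([[-0.02, 0.01, 0.01],
                      [0.01, -0.02, 0.01],
                      [0.01, 0.01, -0.02]])
        table = v.dynamic_balance(Q, t=91.0)
        np.testing.assert_allclose(table["forward_minus_reverse"], 0, atol=1e-12)

    def test_two_state_against_closed_form(self):
        Q = np.array([[-1.0, 1.0], [2.0, -2.0]])
        table = v.dynamic_balance(Q, t=91.0)
        P = two_state_P(1.0, 2.0, 91.0)
        assert table["forward_minus_reverse"].iloc[0] == pytest.approx(
            P[0, 1] - P[1, 0])

    def test_reversible_chain_has_zero_flux(self):
        # birth-death chains are reversible
        Q = np.array([[-0.02, 0.02, 0.0],
                      [0.01, -0.04, 0.03],
                      [0.0, 0.02, -0.02]])
        table = v.dynamic_balance(Q, t=50.0)
        np.testing.assert_allclose(table["detailed_balance_flux"], 0, atol=1e-10)


def simulate_panel(Qtrue, states, n_subjects, visits, seed, init=None):
    rng = np.random.default_rng(seed)
    init = init or [1 / len(states)] * len(states)
    return {
        f"s{i}": [(states[s], d) for s, d in
                  zip(v.simulate_vagitype_path(Qtrue, init, visits, rng=rng), visits)]
        for i in range(n_subjects)
    }


class TestFitCtmc:
    STATES3 = ["A", "B", "C"]
    QTRUE = np.array([[-0.012, 0.008, 0.004],
                      [0.006, -0.010, 0.004],
                      [0.003, 0.009, -0.012]])

    def test_recovers_log_intensities_within_3se(self):
        seqs = simulate_panel(self.QTRUE, self.STATES3, 120,
                              list(range(0, 240, 28)), seed=15)
        model = v.fit_ctmc(seqs, states=self.STATES3, seed=0)
        assert model.converged
        hits = total = 0
        for r in range(3):
            for s in range(3):
                if r == s or not model.allowed_mask[r, s]:
                    continue
                se = model.standard_errors[("log_q0", self.STATES3[r], self.STATES3[s])]
                err = abs(np.log(model.Q0[r, s]) - np.log(self.QTRUE[r, s]))
                total += 1
                hits += err <= 3 * se
        assert total >= 4
        assert hits == total

    def test_mle_beats_truth_loglik(self):
        seqs = simulate_panel(self.QTRUE, self.STATES3, 60,
                              list(range(0, 200, 28)), seed=16)
        model = v.fit_ctmc(seqs, states=self.STATES3, seed=0)

        def loglik_at(Q):
            total = 0.0
            for seq in seqs.values():
                for (s1, t1), (s2, t2) in zip(seq, seq[1:]):
                    P = transition_probability(Q, t2 - t1)
                    i, j = self.STATES3.index(s1), self.STATES3.index(s2)
                    total += np.log(max(P[i, j], 1e-300))
            return total

        # truth restricted to the fitted support for a fair comparison
        Qres = self.QTRUE * model.allowed_mask
        np.fill_diagonal(Qres, 0)
        Qres -= np.diag(Qres.sum(axis=1))
        assert model.loglik >= loglik_at(Qres) - 1e-6

    def test_min_transition_rule_zeroes_rare_transitions(self):
        # two states only ever move A->B; the reverse must stay excluded
        seqs = {
            f"s{i}": [("A", 0), ("B", 28), ("B", 56)] for i in range(5)
        }
        model = v.fit_ctmc(seqs, states=["A", "B"], min_transitions=4, seed=0)
        assert model.Q0[1, 0] == 0.0
        assert model.allowed_mask[0, 1] and not model.allowed_mask[1, 0]

    def test_no_allowed_transitions_rejected(self):
        seqs = {"s0": [("A", 0), ("A", 28)]}
        with pytest.raises(ValueError, match="restriction"):
            v.fit_ctmc(seqs, states=["A", "B"], seed=0)

    def test_covariate_free_pooling_nests(self):
        """A zero covariate column reproduces the pooled covariate-free fit."""
        seqs = simulate_panel(self.QTRUE, self.STATES3, 40,
                              list(range(0, 200, 28)), seed=17)
        pooled = v.fit_ctmc(seqs, states=self.STATES3, seed=0)
        cov = {s: 0.0 for s in seqs}
        with_cov = v.fit_ctmc(seqs, covariate=cov, states=self.STATES3, seed=0)
        np.testing.assert_allclose(with_cov.Q0, pooled.Q0, atol=5e-4)

    def test_recovery_error_shrinks_with_sample_size(self):
        """More subjects give a tighter intensity reconstruction."""
        errs = {}
        for n in (50, 400):
            seqs = simulate_panel(self.QTRUE, self.STATES3, n,
                                  list(range(0, 240, 28)), seed=18)
            model = v.fit_ctmc(seqs, states=self.STATES3, seed=0)
            mask = model.allowed_mask
            errs[n] = np.median(np.abs(
                np.log(model.Q0[mask]) - np.log(self.QTRUE[mask])))
        assert errs[400] < errs[50]

    def test_outcome_covariate_shifts_fitted_intensities(self, default_cohort,
                                                         qc_table, qc_records):
        calls = v.assign_vagitypes(qc_table)
        seqs = v.build_state_sequences(calls, qc_records)
        cov = {s: 1.0 if o == "PTB" else 0.0 for s, o in
               qc_records.groupby("subject_id")["outcome"].first().items()}
        model = v.fit_ctmc(seqs, covariate=cov, seed=0)
        pi_tb = v.stationary_distribution(model, z=0.0)
        pi_ptb = v.stationary_distribution(model, z=1.0)
        i_lc = model.states.index("Lactobacillus_crispatus_cluster")
        i_bv = model.states.index("Lachnospiraceae_BVAB1")
        assert pi_tb[i_lc] > pi_ptb[i_lc]
        assert pi_ptb[i_bv] > pi_tb[i_bv]


def test_per_group_counting_is_stricter_than_pooled():
    """Demanding the min count inside every group can only shrink the mask."""
    states = ["A", "B", "C"]
    Qtrue = np.array([[-0.012, 0.008, 0.004],
                      [0.006, -0.010, 0.004],
                      [0.003, 0.009, -0.012]])
    seqs = simulate_panel(Qtrue, states, 40, list(range(0, 200, 28)), seed=19)
    cov = {s: float(i % 2) for i, s in enumerate(seqs)}
    pooled = count_transitions(seqs, states)
    per_group = count_transitions(seqs, states, covariate=cov)
    assert np.all(per_group <= pooled)
    model = v.fit_ctmc(seqs, covariate=cov, states=states,
                       pool_counts=False, seed=0)
    assert model.allowed_mask.sum() <= (pooled >= 4).sum()
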