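"""Simulation-loop tests against independent hand-rolled oracles."""

import numpy as np
import pytest

from cctd import (
    ExperimentDesign, GroupSpec, ITISpec, ModelParameters, PhaseSpec, Placement,
    Simulator, StimulusSpec, TrialTemplate, expand_design, run_experiment,
)
from conftest import make_design


def csc_td_oracle(trials, alphas, p):
    """Independent plain-CSC TD recursion (no configurations).

    ``trials``: list of (placements, us_onset, us_dur, total_steps) with
    placements as (name, onset, dur).  Returns weights dict keyed
    (stimulus, component).
    """
    V: dict[tuple, float] = {}
    E: dict[tuple, float] = {}
    y_prev = 0.0
    for placements, us_on, us_dur, total in trials:
        for t in range(total):
            active = [(s, t - o) for (s, o, d) in placements if o <= t < o + d]
            us = p.lambda_us if us_on is not None and us_on <= t < us_on + us_dur else 0.0
            y = sum(V.get(k, 0.0) for k in active)
            delta = us + p.gamma * max(0.0, y) - max(0.0, y_prev)
            beta = p.beta_plus if us else p.beta_minus
            for k, e in E.items():
                if e:
                    V[k] = V.get(k, 0.0) + beta * alphas[k[0]] * delta * e
            for k in list(E):
                E[k] *= p.rho * p.gamma
            for k in active:
                E[k] = min(1.0, E.get(k, 0.0) + 1.0)
            y_prev = max(0.0, y)
    return V


class TestAgainstHandRolledRecursion:
    def test_first_trials_match_stepwise_oracle(self):
        """Two delay-conditioning trials, compared component by component."""
        p = ModelParameters()
        d = make_design(
            [StimulusSpec("A", 0.1, duration_s=3)],
            [TrialTemplate("A+", [Placement("A")], True)],
            [("A+", 2)], iti_s=12, form_simultaneous=False,
        )
        res = run_experiment(d, seed=1)["G"]
        oracle = csc_td_oracle(
            [([("A", 0, 3)], 3, 1, 16)] * 2, {"A": 0.1}, p
        )
        for j in range(3):
            assert res.weights["A"][j] == pytest.approx(oracle[("A", j)], abs=1e-12)

    def test_configuration_free_run_equals_plain_csc_td(self):
        """With configurations disabled, a compound design reduces to plain
        component-level TD (independent recursion, machine precision)."""
        p = ModelParameters()
        d = make_design(
            [StimulusSpec("A", 0.2, duration_s=4), StimulusSpec("B", 0.1, duration_s=6)],
            [TrialTemplate("AB+", [Placement("A", 1), Placement("B", 0)], True,),
             TrialTemplate("B-", [Placement("B")])],
            [("AB+", 5), ("B-", 5)], iti_s=20, form_simultaneous=False,
        )
        sched = expand_design(d, seed=3)["G"]
        res = Simulator(d).run(sched, seed=3, group="G")
        oracle = csc_td_oracle(
            [(t.placements, t.us_onset, t.us_duration, t.total_steps) for t in sched],
            {"A": 0.2, "B": 0.1}, p,
        )
        for (stim, comp), v in oracle.items():
            assert res.weights[stim][comp] == pytest.approx(v, abs=1e-12)


class TestRescorlaWagnerLimit:
    def test_single_step_stimuli_reduce_to_trial_level_delta_rule(self):
        """One-step CSs, US on the following step, gamma=0: per-trial weight
        changes equal the trial-level delta rule exactly."""
        p = ModelParameters(gamma=0.0)
        d = make_design(
            [StimulusSpec("A", 0.3, duration_s=1), StimulusSpec("B", 0.2, duration_s=1)],
            [TrialTemplate("AB+", [Placement("A"), Placement("B")], True),
             TrialTemplate("A-", [Placement("A")]),
             TrialTemplate("B+", [Placement("B")], True)],
            [("AB+", 25), ("A-", 10), ("B+", 5)],
            params=p, iti_s=5, form_simultaneous=False,
        )
        res = run_experiment(d, seed=2)["G"]
        va = vb = 0.0
        for tr in res.trials:
            present = {s for s, _, _ in tr.placements}
            y = (va if "A" in present else 0.0) + (vb if "B" in present else 0.0)
            lam = p.lambda_us if tr.us_onset is not None else 0.0
            beta = p.beta_plus if lam else p.beta_minus
            delta = lam - y
            if "A" in present:
                va += beta * 0.3 * delta
            if "B" in present:
                vb += beta * 0.2 * delta
        assert res.weights["A"][0] == pytest.approx(va, abs=1e-12)
        assert res.weights["B"][0] == pytest.approx(vb, abs=1e-12)


class TestStepInvariants:
    def test_empty_trial_changes_nothing(self):
        d = make_design(
            [StimulusSpec("A", 0.1, duration_s=3)],
            [TrialTemplate("none", [Placement("A", 0, 3)])],
            [("none", 4)], iti_s=10,
        )
        res = run_experiment(d, seed=1)["G"]
        assert np.all(res.weights["A"] == 0)  # no US ever: nothing to learn
        assert np.all(res.strength == 0)

    def test_full_determinism(self):
        from cctd import response_table, run_fixture
        a = run_fixture("second_order", seed=4, scale=0.1)
        b = run_fixture("second_order", seed=4, scale=0.1)
        for g in a:
            assert np.array_equal(a[g].strength, b[g].strength)
        assert response_table(a).to_csv() == response_table(b).to_csv()

    def test_asymptote_ladder(self, delay_design):
        """Acquisition drives the prediction k steps before the US onset to
        gamma**k * lambda (k=0 at the final CS step)."""
        p = ModelParameters()
        res = run_experiment(delay_design(400), seed=1)["G"]
        last = res.trials[-1]
        pred = res.strength[last.start:last.start + 10]
        expect = p.lambda_us * p.gamma ** np.arange(9, -1, -1)
        assert np.max(np.abs(pred - expect)) < 0.01


class TestConfiguralLearning:
    def test_serial_cues_are_order_specific(self):
        d = make_design(
            [StimulusSpec("A", 0.2, duration_s=5), StimulusSpec("B", 0.2, duration_s=5)],
            [TrialTemplate("A>B+", [Placement("A", 0), Placement("B", 6)], True)],
            [("A>B+", 30)], iti_s=60,
            serial_configs=[("A", "B"), ("B", "A")],
        )
        res = run_experiment(d, seed=1)["G"]
        assert np.sum(np.abs(res.weights["q(A>B)"])) > 0.05
        assert "q(B>A)" not in res.weights or np.all(res.weights["q(B>A)"] == 0)

    def test_negative_patterning_cue_turns_inhibitory(self):
        d = make_design(
            [StimulusSpec("A", 0.3, duration_s=5), StimulusSpec("B", 0.3, duration_s=5)],
            [TrialTemplate("A+", [Placement("A")], True),
             TrialTemplate("B+", [Placement("B")], True),
             TrialTemplate("AB-", [Placement("A"), Placement("B")])],
            [("A+", 60), ("B+", 60), ("AB-", 120)], iti_s=40,
        )
        res = run_experiment(d, seed=5)["G"]
        assert np.sum(res.weights["q(A+B)"]) < 0

    def test_context_loses_strength_across_the_iti(self):
        d = make_design(
            [StimulusSpec("A", 0.2, duration_s=5)],
            [TrialTemplate("A+", [Placement("A")], True)],
            [("A+", 30)], iti_s=120, context_alpha=0.2,
        )
        res = run_experiment(d, seed=1)["G"]
        tr = res.trials[-1]
        iti = res.strength[tr.start + tr.span:tr.start + tr.span + tr.iti_steps]
        early, late = iti[: len(iti) // 4], iti[-(len(iti) // 4):]
        assert early.mean() > late.mean()
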