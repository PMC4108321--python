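"""Design language: expansion, sampling bounds, scaling, serialization,
common-element augmentation and configural learning-rate assignment."""

import numpy as np
import pytest

from cctd import (
    DesignError, ExperimentDesign, GroupSpec, ITISpec, ModelParameters, PhaseSpec,
    Placement, StimulusSpec, TrialTemplate, add_common_elements,
    assign_configural_alphas, design_from_yaml, design_to_yaml, expand_design,
    get_fixture, scaled_count, schedule_table,
)
from conftest import make_design


def simple_delay_design(n=40, iti=ITISpec(fixed_s=100)):
    return ExperimentDesign(
        name="d",
        stimuli={"T": StimulusSpec("T", 0.1, duration_s=10)},
        templates={"T+": TrialTemplate("T+", [Placement("T")], True)},
        groups=[GroupSpec("G", [PhaseSpec([("T+", n)], iti)])],
        params=ModelParameters(),
    )


class TestExpansion:
    def test_delay_conditioning_layout(self):
        sched = expand_design(simple_delay_design(), seed=3)["G"]
        assert len(sched) == 40
        for tr in sched:
            assert tr.placements == [("T", 0, 10)]
            assert tr.us_onset == 10 and tr.us_duration == 1
            assert tr.span == 11 and tr.context_period == 11

    def test_variable_iti_bounds(self):
        iti = ITISpec(var_mean_s=792, var_halfrange_s=402)
        sched = expand_design(simple_delay_design(60, iti), seed=5)["G"]
        samples = np.array([t.iti_steps for t in sched])
        assert samples.min() >= 390 and samples.max() <= 1194
        assert samples.std() > 0

    def test_variable_iti_default_halfrange(self):
        lo, hi = ITISpec(var_mean_s=120).bounds_s()
        assert (lo, hi) == (60, 180)

    def test_zero_trial_phase(self):
        d = simple_delay_design(0)
        assert expand_design(d, seed=1)["G"] == []

    def test_exponential_durations_at_least_one_step(self):
        d = ExperimentDesign(
            name="v",
            stimuli={"V": StimulusSpec("V", 0.1)},
            templates={"V+": TrialTemplate("V+", [Placement("V", 0, exp_mean_s=3)], True)},
            groups=[GroupSpec("G", [PhaseSpec([("V+", 200)], ITISpec(fixed_s=20))])],
            params=ModelParameters(),
        )
        durs = [t.placements[0][2] for t in expand_design(d, seed=2)["G"]]
        assert min(durs) >= 1 and len(set(durs)) > 3

    def test_random_order_is_permutation_of_multiset(self):
        d = make_design(
            [StimulusSpec("A", 0.1, duration_s=5), StimulusSpec("B", 0.1, duration_s=5)],
            [TrialTemplate("A+", [Placement("A")], True), TrialTemplate("B-", [Placement("B")])],
            [("A+", 12), ("B-", 7)],
        )
        labels = [t.label for t in expand_design(d, seed=9)["G"]]
        assert sorted(labels) == ["A+"] * 12 + ["B-"] * 7
        assert labels != ["A+"] * 12 + ["B-"] * 7  # actually interleaved

    def test_unknown_stimulus_rejected(self):
        with pytest.raises(DesignError):
            ExperimentDesign(
                name="bad",
                stimuli={"A": StimulusSpec("A", 0.1, duration_s=5)},
                templates={"B+": TrialTemplate("B+", [Placement("B")], True)},
                groups=[GroupSpec("G", [PhaseSpec([("B+", 1)], ITISpec(fixed_s=10))])],
                params=ModelParameters(),
            )


class TestScaling:
    @pytest.mark.parametrize("n,scale,expect", [
        (700, 0.1, 70), (40, 0.1, 4), (28, 0.1, 4), (8, 0.1, 4),
        (2, 0.1, 2), (1, 0.1, 1), (40, 1.0, 40),
    ])
    def test_scaled_count(self, n, scale, expect):
        assert scaled_count(n, scale) == expect

    def test_fixed_sequences_preserved_verbatim(self):
        d = get_fixture("occasion_setting")
        sched = expand_design(d, seed=1, scale=0.1)
        for g in ("Sim", "SimC"):
            p4 = [t.label for t in sched[g] if t.phase == 3]
            assert p4 == ["N-", "LNsim-", "LNsim-", "N-", "LNsim-", "N-", "N-", "LNsim-"]
        p4 = [t.label for t in sched["Ser"] if t.phase == 3]
        assert p4 == ["N-", "L>N-", "L>N-", "N-", "L>N-", "N-", "N-", "L>N-"]


class TestRoundTrip:
    def test_yaml_round_trip_gives_identical_schedule(self):
        d = get_fixture("summation")
        d2 = design_from_yaml(design_to_yaml(d))
        t1 = schedule_table(expand_design(d, seed=11, scale=0.1))
        t2 = schedule_table(expand_design(d2, seed=11, scale=0.1))
        assert t1.equals(t2)

    def test_schedule_table_round_trip(self, tmp_path):
        tbl = schedule_table(expand_design(simple_delay_design(5), seed=1))
        f = tmp_path / "sched.csv"
        tbl.to_csv(f, index=False)
        import pandas as pd
        assert pd.read_csv(f).equals(tbl)


class TestCommonElements:
    def base(self):
        return make_design(
            [StimulusSpec("A", 0.3, duration_s=10), StimulusSpec("B", 0.2, duration_s=10)],
            [TrialTemplate("AB+", [Placement("A"), Placement("B")], True),
             TrialTemplate("A-", [Placement("A")])],
            [("AB+", 2), ("A-", 2)],
        )

    def test_each_presentation_gains_coextensive_x(self):
        d = add_common_elements(self.base(), alpha=0.05)
        assert d.common_element == "X"
        ab = d.templates["AB+"]
        xs = [p for p in ab.placements if p.stimulus == "X"]
        assert len(xs) == 1 and xs[0].onset_s == 0 and xs[0].duration_s == 10
        a = d.templates["A-"]
        assert sum(p.stimulus == "X" for p in a.placements) == 1

    def test_single_stimulus_design_unchanged(self):
        d = make_design(
            [StimulusSpec("A", 0.3, duration_s=10)],
            [TrialTemplate("A+", [Placement("A")], True)],
            [("A+", 2)],
        )
        assert add_common_elements(d, alpha=0.05) is d

    def test_variable_durations_sampled_independently(self):
        d = ExperimentDesign(
            name="v",
            stimuli={"A": StimulusSpec("A", 0.1), "B": StimulusSpec("B", 0.1, duration_s=5)},
            templates={"A+": TrialTemplate("A+", [Placement("A", 0, exp_mean_s=20)], True),
                       "B-": TrialTemplate("B-", [Placement("B")])},
            groups=[GroupSpec("G", [PhaseSpec([("A+", 100)], ITISpec(fixed_s=20))])],
            params=ModelParameters(),
        )
        d = add_common_elements(d, alpha=0.05)
        sched = expand_design(d, seed=4)["G"]
        pairs = [(dict(((s, (o, du)) for s, o, du in t.placements))["A"],
                  dict(((s, (o, du)) for s, o, du in t.placements))["X"]) for t in sched]
        diffs = [a[1] != x[1] for a, x in pairs]
        assert any(diffs)  # durations differ trial by trial
        # and the US tracks the nominal stimulus, not the common element
        for t in sched:
            a_off = dict(((s, o + du) for s, o, du in t.placements))["A"]
            assert t.us_onset == a_off


class TestConfiguralAlphas:
    def test_serial_interference_counts_from_declared_set(self):
        d = get_fixture("serial_structure")
        alphas = assign_configural_alphas(d)
        # every pair shares a stimulus with 5 of the other 7 sequences and
        # has no unique CS: 0.1*0.1 / 5
        assert alphas["q(A>B)"] == pytest.approx(0.002)
        assert len(alphas) == 8
        assert all(a == pytest.approx(0.002) for a in alphas.values())

    def test_isolated_serial_pair(self):
        d = make_design(
            [StimulusSpec("A", 0.1, duration_s=5), StimulusSpec("B", 0.1, duration_s=5)],
            [TrialTemplate("A>B+", [Placement("A", 0), Placement("B", 6)], True)],
            [("A>B+", 1)],
            serial_configs=[("A", "B")],
        )
        # 2 unique CSs, no sharing configurations: 0.01 * 2 / 1
        assert assign_configural_alphas(d)["q(A>B)"] == pytest.approx(0.02)


class TestFixtureCatalog:
    def test_parameter_overrides(self):
        assert get_fixture("blocking").params.timestep_s == 0.05
        assert get_fixture("timing").params.rho == 0.989
        assert get_fixture("timing").params.gamma == 0.989
        assert get_fixture("occasion_setting").params.rho == 0.995
        base = get_fixture("generalization").params
        assert (base.rho, base.gamma, base.timestep_s) == (0.97, 0.97, 1.0)
        assert (base.beta_plus, base.beta_minus, base.decision_B) == (0.5, 0.495, 0.985)

    def test_full_scale_trial_counts_conserved(self):
        sched = expand_design(get_fixture("blocking"), seed=1)
        labels = [t.label for t in sched["Blocking"]]
        assert labels.count("T+") == 700 and labels.count("TL+") == 500
        assert labels.count("L-") == 30 and labels.count("L+") == 500
        assert len(sched["Naive"]) == 500

    def test_catalog_complete(self):
        from cctd import fixture_catalog
        cat = fixture_catalog()
        assert sorted(cat) == [
            "blocking", "generalization", "occasion_setting", "patterning",
            "renewal", "second_order", "serial_structure", "summation", "timing",
        ]
        for d in cat.values():
            d.validate()
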