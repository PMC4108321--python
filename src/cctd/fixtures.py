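"""The catalog of nine classical-conditioning experiment designs.

Each builder returns a complete :class:`~cctd.design.ExperimentDesign`
(stimuli, trial templates, groups/phases, ITI distributions, learning
rates, parameter overrides).  Wherever two or more nominal CSs occur in a
design, a shared common element ``X`` accompanies every CS presentation.
Reduced-scale variants for fast testing divide trial counts by 10
(never below 4 trials) via the ``scale`` argument of the runner.

Design notes
------------
* Reinforced templates use delay conditioning (US at the latest CS offset,
  one-timestep US) unless the procedure dictates otherwise (the
  second-order study delivers a 2 s US 10 s into a 12 s light).
* "Variable" ITIs with only a mean stated are sampled uniformly on
  [0.5*mean, 1.5*mean]; stated half-ranges are used verbatim.
"""

from __future__ import annotations

from .design import (
    ExperimentDesign, GroupSpec, ITISpec, PhaseSpec, Placement, StimulusSpec,
    TrialTemplate, USSpec, add_common_elements,
)
from .params import ModelParameters

BASE = ModelParameters()  # lambda=1, rho=gamma=0.97, beta+=0.5, beta-=0.495, B=0.985, 1 s steps


def _stim(name, alpha, dur=None, **kw):
    return StimulusSpec(name=name, alpha=alpha, duration_s=dur, **kw)


def second_order() -> ExperimentDesign:
    """Second-order conditioning: first-order light training, then a click
    serially paired with the light (PP), vs unpaired controls (UP, PU)."""
    stimuli = {
        "L": _stim("L", 0.1),
        "C": _stim("C", 0.1),
        "ctx": _stim("ctx", 0.001, is_context=True),
    }
    templates = {
        "L+": TrialTemplate("L+", [Placement("L", 0, 12)], True, USSpec(onset_s=10, duration_s=2)),
        "L12-": TrialTemplate("L12-", [Placement("L", 0, 12)]),
        "US": TrialTemplate("US", [], True, USSpec(onset_s=10, duration_s=2)),
        "C>L-": TrialTemplate("C>L-", [Placement("C", 0, 10), Placement("L", 10, 10)]),
        "C-": TrialTemplate("C-", [Placement("C", 0, 10)]),
        "L-": TrialTemplate("L-", [Placement("L", 0, 10)]),
    }
    iti = ITISpec(fixed_s=665)
    groups = [
        GroupSpec("PP", [PhaseSpec([("L+", 84)], iti, "ctx"),
                         PhaseSpec([("C>L-", 16)], iti, "ctx")]),
        GroupSpec("UP", [PhaseSpec([("L12-", 84), ("US", 84)], iti, "ctx"),
                         PhaseSpec([("C>L-", 16)], iti, "ctx")]),
        GroupSpec("PU", [PhaseSpec([("L+", 84)], iti, "ctx"),
                         PhaseSpec([("C-", 16), ("L-", 16)], iti, "ctx")]),
    ]
    d = ExperimentDesign(
        name="second_order", stimuli=stimuli, templates=templates, groups=groups,
        params=BASE, serial_configs=[("C", "L")],
        notes={"readout": "C", "readout_phase": 1},
    )
    return add_common_elements(d, alpha=0.001)


def blocking() -> ExperimentDesign:
    """Blocking in eye-blink conditioning (50 ms timesteps): tone pre-training
    blocks the light during compound training; Phase-4 reacquisition."""
    params = BASE.replace(timestep_s=0.05)
    stimuli = {
        "T": _stim("T", 0.025, 0.45),
        "L": _stim("L", 0.025, 0.45),
        "ctx": _stim("ctx", 0.00025, is_context=True),
    }
    us = USSpec(duration_s=0.05)
    templates = {
        "T+": TrialTemplate("T+", [Placement("T")], True, us),
        "TL+": TrialTemplate("TL+", [Placement("T"), Placement("L")], True, us),
        "L-": TrialTemplate("L-", [Placement("L")]),
        "L+": TrialTemplate("L+", [Placement("L")], True, us),
    }
    iti = ITISpec(var_mean_s=30, var_halfrange_s=5)
    groups = [
        GroupSpec("Blocking", [PhaseSpec([("T+", 700)], iti, "ctx"),
                               PhaseSpec([("TL+", 500)], iti, "ctx"),
                               PhaseSpec([("L-", 30)], iti, "ctx"),
                               PhaseSpec([("L+", 500)], iti, "ctx")]),
        GroupSpec("Control", [PhaseSpec([], iti, "ctx"),
                              PhaseSpec([("TL+", 500)], iti, "ctx"),
                              PhaseSpec([("L-", 30)], iti, "ctx"),
                              PhaseSpec([("L+", 500)], iti, "ctx")]),
        GroupSpec("Naive", [PhaseSpec([], iti, "ctx"),
                            PhaseSpec([], iti, "ctx"),
                            PhaseSpec([], iti, "ctx"),
                            PhaseSpec([("L+", 500)], iti, "ctx")]),
    ]
    d = ExperimentDesign(
        name="blocking", stimuli=stimuli, templates=templates, groups=groups,
        params=params, notes={"readout": "L"},
    )
    return add_common_elements(d, alpha=0.00025)


def timing() -> ExperimentDesign:
    """Fixed vs variable CS duration (within-subjects): fixed and variable
    reinforced CSs plus a non-reinforced control, at 30 s and 60 s means.

    The common element is kept out of configuration formation here: its
    sampled duration differs from the nominal stimulus trial by trial.
    """
    params = BASE.replace(rho=0.989, gamma=0.989)
    stimuli = {
        "F": _stim("F", 0.125),
        "Vs": _stim("Vs", 0.125),
        "Cc": _stim("Cc", 0.125),
        "ctx": _stim("ctx", 0.001, is_context=True),
    }

    def tpls(mean):
        return {
            "F+": TrialTemplate("F+", [Placement("F", 0, mean)], True),
            "V+": TrialTemplate("V+", [Placement("Vs", 0, exp_mean_s=mean)], True),
            "Cf-": TrialTemplate("Cf-", [Placement("Cc", 0, mean)]),
            "Cv-": TrialTemplate("Cv-", [Placement("Cc", 0, exp_mean_s=mean)]),
        }

    # both duration conditions are groups of one design; templates therefore
    # get a per-group suffix
    templates = {}
    for mean, suffix in ((30, "30"), (60, "60")):
        for k, t in tpls(mean).items():
            templates[k + suffix] = TrialTemplate(
                k + suffix, t.placements, t.reinforced, t.us
            )
    iti30 = ITISpec(fixed_s=60, var_mean_s=30)
    iti60 = ITISpec(fixed_s=90, var_mean_s=60)
    groups = [
        GroupSpec("G30", [PhaseSpec([("F+30", 90), ("V+30", 90), ("Cf-30", 45), ("Cv-30", 45)],
                                    iti30, "ctx")]),
        GroupSpec("G60", [PhaseSpec([("F+60", 90), ("V+60", 90), ("Cf-60", 45), ("Cv-60", 45)],
                                    iti60, "ctx")]),
    ]
    d = ExperimentDesign(
        name="timing", stimuli=stimuli, templates=templates, groups=groups,
        params=params, common_in_configs=False,
        notes={"sessions": 5},
    )
    return add_common_elements(d, alpha=0.00065)


def generalization() -> ExperimentDesign:
    """Shape discrimination: reinforced circle vs non-reinforced square,
    generalization carried by a strong common element."""
    stimuli = {
        "circle": _stim("circle", 0.25, 10),
        "square": _stim("square", 0.25, 10),
        "ctx": _stim("ctx", 0.003, is_context=True),
    }
    templates = {
        "A+": TrialTemplate("A+", [Placement("circle")], True),
        "B-": TrialTemplate("B-", [Placement("square")]),
    }
    groups = [GroupSpec("D", [PhaseSpec([("A+", 33), ("B-", 33)], ITISpec(var_mean_s=120), "ctx")])]
    d = ExperimentDesign(
        name="generalization", stimuli=stimuli, templates=templates, groups=groups,
        params=BASE,
    )
    return add_common_elements(d, alpha=0.2)


def renewal() -> ExperimentDesign:
    """ABA renewal: conditioning in context A, extinction in B, test in A;
    responding is carried by the context+CS configuration."""
    stimuli = {
        "T": _stim("T", 0.25, 10),
        "ctxA": _stim("ctxA", 0.0375, is_context=True),
        "ctxB": _stim("ctxB", 0.0375, is_context=True),
    }
    templates = {
        "T+": TrialTemplate("T+", [Placement("T")], True),
        "T-": TrialTemplate("T-", [Placement("T")]),
        "US": TrialTemplate("US", [], True, USSpec(onset_s=10)),
    }
    iti = ITISpec(var_mean_s=792, var_halfrange_s=402)
    groups = [
        GroupSpec("ABA", [PhaseSpec([("T+", 40)], iti, "ctxA"),
                          PhaseSpec([("T-", 28)], iti, "ctxB"),
                          PhaseSpec([("T-", 24)], iti, "ctxA")]),
        GroupSpec("AAA", [PhaseSpec([("T+", 40)], iti, "ctxA"),
                          PhaseSpec([("T-", 28)], iti, "ctxA"),
                          PhaseSpec([("T-", 24)], iti, "ctxA")]),
        GroupSpec("Control", [PhaseSpec([("T-", 40), ("US", 40)], iti, "ctxA"),
                              PhaseSpec([("T-", 28)], iti, "ctxB"),
                              PhaseSpec([("T-", 24)], iti, "ctxA")]),
    ]
    return ExperimentDesign(
        name="renewal", stimuli=stimuli, templates=templates, groups=groups,
        params=BASE, context_in_configs=True, notes={"readout": "T"},
    )


def patterning() -> ExperimentDesign:
    """Concurrent positive (AB+, A-, B-) and negative (CD-, C+, D+)
    patterning vs a biconditional discrimination (AB+, CD+, AC-, BD-)."""
    stimuli = {s: _stim(s, 0.1, 30) for s in "ABCD"}
    stimuli["ctx"] = _stim("ctx", 0.001, is_context=True)

    def tpl(label, names, plus):
        return TrialTemplate(label, [Placement(n) for n in names], plus)

    templates = {
        "AB+": tpl("AB+", "AB", True), "A-": tpl("A-", "A", False), "B-": tpl("B-", "B", False),
        "CD-": tpl("CD-", "CD", False), "C+": tpl("C+", "C", True), "D+": tpl("D+", "D", True),
        "CD+": tpl("CD+", "CD", True), "AC-": tpl("AC-", "AC", False), "BD-": tpl("BD-", "BD", False),
    }
    iti = ITISpec(fixed_s=120)
    groups = [
        GroupSpec("Patterning", [PhaseSpec(
            [("AB+", 800), ("A-", 400), ("B-", 400), ("CD-", 800), ("C+", 400), ("D+", 400)],
            iti, "ctx")]),
        GroupSpec("Biconditional", [PhaseSpec(
            [("AB+", 800), ("CD+", 800), ("AC-", 800), ("BD-", 800)], iti, "ctx")]),
    ]
    d = ExperimentDesign(
        name="patterning", stimuli=stimuli, templates=templates, groups=groups, params=BASE,
    )
    return add_common_elements(d, alpha=0.02)


def summation() -> ExperimentDesign:
    """Summation test: AD+, BC+, AB- training, then CD probes; elemental
    summation predicts more responding to CD than to the trained compounds."""
    stimuli = {s: _stim(s, 0.1, 30) for s in "ABCD"}
    stimuli["ctx"] = _stim("ctx", 0.001, is_context=True)

    def tpl(label, names, plus):
        return TrialTemplate(label, [Placement(n) for n in names], plus)

    templates = {
        "AB-": tpl("AB-", "AB", False), "AD+": tpl("AD+", "AD", True), "BC+": tpl("BC+", "BC", True),
        "CD-": tpl("CD-", "CD", False), "C-": tpl("C-", "C", False), "D-": tpl("D-", "D", False),
    }
    iti = ITISpec(var_mean_s=120)
    day = [("AB-", 8), ("AD+", 8), ("BC+", 8)]
    groups = [GroupSpec("S", [
        PhaseSpec([("AB-", 176), ("AD+", 176), ("BC+", 176)], iti, "ctx"),
        PhaseSpec(day + [("CD-", 4)], iti, "ctx", ordering="random_tests_last",
                  test_labels=("CD-",)),
        PhaseSpec([("AB-", 16), ("AD+", 16), ("BC+", 16)], iti, "ctx"),
        PhaseSpec(day + [("CD-", 2), ("C-", 1), ("D-", 1)], iti, "ctx",
                  ordering="random_tests_last", test_labels=("CD-", "C-", "D-")),
    ])]
    d = ExperimentDesign(
        name="summation", stimuli=stimuli, templates=templates, groups=groups, params=BASE,
    )
    return add_common_elements(d, alpha=0.02)


def occasion_setting() -> ExperimentDesign:
    """Simultaneous vs serial feature-negative discrimination (conditioned
    suppression): N+, LN- with the light-noise compound either simultaneous
    or serial, retardation test (L+) and summation test."""
    params = BASE.replace(rho=0.995, gamma=0.995)
    stimuli = {
        "N": _stim("N", 0.495, 60),
        "L": _stim("L", 0.495, 60),
        "ctx": _stim("ctx", 0.0055, is_context=True),
    }
    templates = {
        "N+": TrialTemplate("N+", [Placement("N")], True),
        "N-": TrialTemplate("N-", [Placement("N")]),
        "LNsim-": TrialTemplate("LNsim-", [Placement("L"), Placement("N")]),
        "L>N-": TrialTemplate("L>N-", [Placement("L", 0, 60), Placement("N", 60, 60)]),
        "L-": TrialTemplate("L-", [Placement("L")]),
        "L+": TrialTemplate("L+", [Placement("L")], True),
    }
    iti = ITISpec(var_mean_s=780)

    def seq(neg):  # Phase-4 fixed order: N, LN, LN, N, LN, N, N, LN
        order = ["N-", neg, neg, "N-", neg, "N-", "N-", neg]
        return PhaseSpec([(l, order.count(l)) for l in dict.fromkeys(order)],
                         iti, "ctx", ordering="sequence", sequence=order)

    groups = [
        GroupSpec("Sim", [PhaseSpec([("N+", 4)], iti, "ctx"),
                          PhaseSpec([("N+", 12), ("LNsim-", 36)], iti, "ctx"),
                          PhaseSpec([("L+", 8)], iti, "ctx"), seq("LNsim-")]),
        GroupSpec("SimC", [PhaseSpec([("N+", 4)], iti, "ctx"),
                           PhaseSpec([("N+", 12), ("L-", 36)], iti, "ctx"),
                           PhaseSpec([("L+", 8)], iti, "ctx"), seq("LNsim-")]),
        GroupSpec("Ser", [PhaseSpec([("N+", 4)], iti, "ctx"),
                          PhaseSpec([("N+", 48), ("L>N-", 144)], iti, "ctx"),
                          PhaseSpec([("L+", 8)], iti, "ctx"), seq("L>N-")]),
        GroupSpec("SerC", [PhaseSpec([("N+", 4)], iti, "ctx"),
                           PhaseSpec([("N+", 48), ("L-", 144)], iti, "ctx"),
                           PhaseSpec([("L+", 8)], iti, "ctx"), seq("L>N-")]),
    ]
    d = ExperimentDesign(
        name="occasion_setting", stimuli=stimuli, templates=templates, groups=groups,
        params=params, serial_configs=[("L", "N")], notes={"readout": "N"},
    )
    return add_common_elements(d, alpha=0.055)


def serial_structure() -> ExperimentDesign:
    """Serial structural discrimination: the same four stimuli in eight
    ordered pairs, reinforcement determined solely by order."""
    stimuli = {s: _stim(s, 0.1, 10) for s in "ABCD"}
    stimuli["ctx"] = _stim("ctx", 0.001, is_context=True)
    pos = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
    neg = [("B", "A"), ("C", "B"), ("D", "C"), ("A", "D")]
    templates = {}
    for a, b in pos + neg:
        plus = (a, b) in pos
        label = f"{a}>{b}" + ("+" if plus else "-")
        # 10 s stimuli with a 1 s gap between them
        templates[label] = TrialTemplate(
            label, [Placement(a, 0, 10), Placement(b, 11, 10)], plus
        )
    iti = ITISpec(var_mean_s=84)
    groups = [GroupSpec("S", [PhaseSpec([(l, 210) for l in templates], iti, "ctx")])]
    d = ExperimentDesign(
        name="serial_structure", stimuli=stimuli, templates=templates, groups=groups,
        params=BASE, serial_configs=pos + neg,
    )
    return add_common_elements(d, alpha=0.02)


FIXTURES = {
    "second_order": second_order,
    "blocking": blocking,
    "timing": timing,
    "generalization": generalization,
    "renewal": renewal,
    "patterning": patterning,
    "summation": summation,
    "occasion_setting": occasion_setting,
    "serial_structure": serial_structure,
}


def fixture_catalog() -> dict[str, "ExperimentDesign"]:
    """All nine designs, freshly built."""
    return {name: build() for name, build in FIXTURES.items()}


def get_fixture(name: str) -> ExperimentDesign:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}") from None
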