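import numpy as np
import pytest

from cctd import (
    ExperimentDesign, GroupSpec, ITISpec, ModelParameters, PhaseSpec, Placement,
    StimulusSpec, TrialTemplate,
)


@pytest.fixture
def params():
    return ModelParameters()


def make_design(
    stimuli,
    templates,
    phase_trials,
    *,
    params=None,
    iti_s=50,
    serial_configs=(),
    context_alpha=None,
    form_simultaneous=True,
    name="test",
):
    """Small single-group design builder used across the suite."""
    stim = {s.name: s for s in stimuli}
    ctx = None
    if context_alpha is not None:
        ctx = "ctx"
        stim[ctx] = StimulusSpec("ctx", context_alpha, is_context=True)
    return ExperimentDesign(
        name=name,
        stimuli=stim,
        templates={t.label: t for t in templates},
        groups=[GroupSpec("G", [PhaseSpec(list(phase_trials), ITISpec(fixed_s=iti_s), ctx)])],
        params=params or ModelParameters(),
        serial_configs=list(serial_configs),
        form_simultaneous=form_simultaneous,
    )


@pytest.fixture
def delay_design():
    """Single 10 s CS, delay conditioning, one-step US at CS offset."""
    def build(n_trials=100, alpha=0.1, iti_s=150, p=None):
        return make_design(
            [StimulusSpec("A", alpha, duration_s=10)],
            [TrialTemplate("A+", [Placement("A")], True)],
            [("A+", n_trials)],
            params=p,
            iti_s=iti_s,
        )
    return build
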