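"""Running fixtures and turning run results into behavioural measures.

The readout entity for every measure is the clamped aggregate US
prediction: during a compound or a configuration this automatically equals
the summed strengths of the active constituents, their configural cue, and
the context.  Rates reported here are the deterministic expectation of the
response decision rule (``cap * min(1, s/B)``); the stochastic rule lives
in :mod:`cctd.responses`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .engine import RunResult, TrialRecord, run_experiment
from .fixtures import get_fixture
from .responses import expected_rate, smooth_running_mean, suppression_ratio

#: default seed battery for seed-averaged directional assertions
DEFAULT_SEEDS = (1, 2, 3, 4, 5)


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def stimulus_window(result: RunResult, trial: TrialRecord, stimulus: str | None = None,
                    pre: bool = False) -> tuple[int, int] | None:
    """Global-step window of one stimulus in one trial (or of the whole
    nominal compound when ``stimulus`` is None).  ``pre=True`` returns the
    immediately preceding window of equal length (the preCS period)."""
    if stimulus is None:
        spans = [(o, o + d) for (s, o, d) in trial.placements]
    else:
        spans = [(o, o + d) for (s, o, d) in trial.placements if s == stimulus]
    if not spans:
        return None
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    if pre:
        lo, hi = max(0, lo - (hi - lo)), lo
        if hi <= lo:
            return None
    return lo, hi


def trial_rate(result: RunResult, trial: TrialRecord, stimulus: str | None = None,
               pre: bool = False) -> float | None:
    w = stimulus_window(result, trial, stimulus, pre=pre)
    if w is None:
        return None
    return expected_rate(result.strength[w[0]:w[1]], result.params)


def rates(result: RunResult, phase: int | None = None, labels=None,
          stimulus: str | None = None, pre: bool = False) -> np.ndarray:
    """Expected response rate per matching trial, in schedule order."""
    vals = []
    for tr in result.trials_matching(phase, labels):
        r = trial_rate(result, tr, stimulus, pre=pre)
        if r is not None:
            vals.append(r)
    return np.asarray(vals)


def elevation_scores(result: RunResult, phase=None, labels=None, stimulus=None) -> np.ndarray:
    cs = rates(result, phase, labels, stimulus)
    pre = rates(result, phase, labels, stimulus, pre=True)
    n = min(len(cs), len(pre))
    return cs[:n] - pre[:n]


def suppression_ratios(result: RunResult, phase=None, labels=None, stimulus=None) -> np.ndarray:
    return np.array([
        suppression_ratio(r, result.params) for r in rates(result, phase, labels, stimulus)
    ])


def within_cs_profile(result: RunResult, labels, stimulus: str, n_seconds: int,
                      trial_slice: slice = slice(None), smooth_s: int = 5) -> np.ndarray:
    """Mean expected rate per second from CS onset, averaged over the
    selected trials (trials shorter than a given second simply stop
    contributing), smoothed with a centred running mean."""
    p = result.params
    per_sec = max(1, int(round(1.0 / p.timestep_s)))
    acc = np.zeros(n_seconds)
    cnt = np.zeros(n_seconds)
    for tr in result.trials_matching(labels=labels)[trial_slice]:
        w = stimulus_window(result, tr, stimulus)
        if w is None:
            continue
        seg = result.strength[w[0]:w[1]]
        for sec in range(min(n_seconds, len(seg) // per_sec)):
            chunk = seg[sec * per_sec:(sec + 1) * per_sec]
            acc[sec] += p.rpm_cap * min(1.0, float(np.mean(np.clip(chunk, 0, None))) / p.decision_B)
            cnt[sec] += 1
    prof = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    prof = prof[cnt > 0]
    return smooth_running_mean(prof, smooth_s) if len(prof) else prof


# ---------------------------------------------------------------------------
# multi-seed orchestration and tabular output
# ---------------------------------------------------------------------------

def run_fixture(name_or_design, seed: int, scale: float = 1.0) -> dict[str, RunResult]:
    design = name_or_design if isinstance(name_or_design, ExperimentDesign) else get_fixture(name_or_design)
    return run_experiment(design, seed=seed, scale=scale)


def run_battery(name_or_design, seeds=DEFAULT_SEEDS, scale: float = 1.0
                ) -> dict[int, dict[str, RunResult]]:
    return {seed: run_fixture(name_or_design, seed, scale) for seed in seeds}


def response_table(results: dict[str, RunResult], stimulus: str | None = None) -> pd.DataFrame:
    """Tidy per-trial response table across groups."""
    rows = []
    for group, res in results.items():
        for tr in res.trials:
            r = trial_rate(res, tr, stimulus)
            rows.append(dict(group=group, trial=tr.index, phase=tr.phase,
                             label=tr.label, rpm=np.nan if r is None else r))
    return pd.DataFrame(rows, columns=["group", "trial", "phase", "label", "rpm"])


def write_run(results: dict[str, RunResult], outdir: str | Path) -> None:
    """Write per-trial response tables (CSV) plus a metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tbl = response_table(results)
    tbl.to_csv(outdir / "responses.csv", index=False)
    any_res = next(iter(results.values()))
    meta = {
        "design": any_res.design_name,
        "seed": any_res.seed,
        "scale": any_res.scale,
        "params": any_res.params.to_dict(),
        "groups": sorted(results),
        "entities": {g: sorted(r.alphas) for g, r in results.items()},
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    strengths = {
        g: pd.DataFrame({"t": np.arange(len(r.strength)), "strength": r.strength,
                         "us": r.us})
        for g, r in results.items()
    }
    for g, df in strengths.items():
        df.to_csv(outdir / f"strength_{g}.csv", index=False)
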