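"""Shared fixtures: canonical synthetic pulses, records and component draws."""

from __future__ import annotations

import numpy as np
import pytest

from wristpwv import synth, wpd
from wristpwv.preprocessing import PulseCycle

FS = 256.0


@pytest.fixture(scope="session")
def template_cycle() -> PulseCycle:
    """One clean default-template pulse as a screened cycle (M = 213)."""
    M = 213
    tpl = synth.DEFAULT_TEMPLATE
    comps = synth.ComponentSet.from_arrays(
        tpl["alpha"], [b * M for b in tpl["beta_frac"]], [g * M for g in tpl["gamma_frac"]]
    )
    pulse = synth.synth_pulse(comps, M, FS)
    return PulseCycle(pulse, M, 1.0 / FS, onset_index=1000, r_index=820)


@pytest.fixture(scope="session")
def clean_record() -> synth.SignalRecord:
    """Noise-free 10-beat record at 72 bpm with ground-truth annotations."""
    return synth.synth_record(synth.RecordConfig(n_beats=10, seed=0))


def draw_inbounds_components(
    rng: np.random.Generator, M: int
) -> synth.ComponentSet:
    """Random component set strictly inside the default WPD boxes, ordered."""
    lo, hi = wpd.default_bounds(np.ones(M), M)
    betas, prev = [], 0.0
    for j in range(5):
        l = max(lo[5 + j] + 2.0, prev + 8.0)
        h = hi[5 + j] - 2.0
        betas.append(float(rng.uniform(l, h)) if h > l else l)
        prev = betas[-1]
    alphas = rng.uniform(0.15, 1.0, 5)
    gammas = rng.uniform(5.0, 28.0, 5)
    return synth.ComponentSet.from_arrays(alphas, betas, gammas)


def jittered_template_cycle(rng: np.random.Generator) -> PulseCycle:
    """A physiologically-jittered default-template cycle of random length."""
    M = int(rng.integers(170, 260))
    tpl = synth.DEFAULT_TEMPLATE
    alphas = [a * (1 + rng.uniform(-0.15, 0.15)) for a in tpl["alpha"]]
    betas = np.sort([b * (1 + rng.uniform(-0.08, 0.08)) for b in tpl["beta_frac"]])
    gammas = [g * (1 + rng.uniform(-0.12, 0.12)) for g in tpl["gamma_frac"]]
    comps = synth.ComponentSet.from_arrays(
        alphas, [b * M for b in betas], [g * M for g in gammas]
    )
    return PulseCycle(synth.synth_pulse(comps, M), M, 1.0 / FS, onset_index=1000, r_index=820)
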