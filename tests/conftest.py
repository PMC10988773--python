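"""Shared fixtures: small stimulus sets, montage, noiseless recordings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fpvs import NoiseSpec, plan_sequence, standard_montage
from fpvs.design import StimulusItem, StimulusSet, demo_stimulus_sets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_set(n: int, category: str = "word", prefix: str = "s",
             attributes=None) -> StimulusSet:
    return StimulusSet(
        [StimulusItem(f"{prefix}{i:03d}", category, 5, attributes)
         for i in range(n)],
        set_id=f"{prefix}{n}",
    )


@pytest.fixture(scope="session")
def stimuli():
    return demo_stimulus_sets(seed=0)


@pytest.fixture(scope="session")
def montage68():
    return standard_montage()


@pytest.fixture(scope="session")
def default_plan(stimuli):
    words, nw = stimuli[("NWW", "set_size")]
    return plan_sequence(words, nw, "set_size", seed=1)


@pytest.fixture(scope="session")
def silent_noise():
    return NoiseSpec(pink_scale=0.0, white_scale=0.0, alpha_amp=0.0)


@pytest.fixture(scope="session")
def short_plan():
    """A 6-s plan at the standard rates: 60 presentations, 12 deviants."""
    dev = make_set(6, "word", "w")
    base = make_set(6, "nonword", "n")
    return plan_sequence(dev, base, "set_size", duration_s=6.0, seed=0,
                         fade_in_s=0.5, fade_out_s=0.5)


def brute_force_bin_stats(amps: np.ndarray, tb: int):
    """Independent recomputation of SNR/corrected/z from raw bin lists."""
    snr_win = [amps[i] for i in range(tb - 10, tb + 11) if i != tb]
    snr = amps[tb] / np.mean(snr_win)
    cand = [i for i in range(tb - 12, tb + 13) if abs(i - tb) >= 2]
    vals = [amps[i] for i in cand]
    cand.pop(int(np.argmin(vals)))
    vals = [amps[i] for i in cand]
    cand.pop(int(np.argmax(vals)))
    win = np.array([amps[i] for i in cand])
    corrected = amps[tb] - win.mean()
    z = corrected / win.std(ddof=1)
    return snr, corrected, z
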