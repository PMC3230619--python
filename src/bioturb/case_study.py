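"""Reference parameterisation: *Hediste diversicolor* gallery bioturbation.

The worked example the framework was built around: pink luminophores
deposited on estuarine mud reworked by the ragworm *Hediste diversicolor*,
imaged through an aquarium wall at 73 um/pixel every 5 minutes. The
fitted behavioural parameters for that experiment are activity = 0.674
(probability of displacement per particle per 5-min step),
distance = 4.30 layers (= 0.314 mm mean displacement), symmetric vertical
direction (downwards = 0.5), full-depth reworking (range_frac = 1) and a
tracer selection weight tracerdif = 0.929 during passive relocation.

The observation grid is 149 layers x 2980 particles wide with the
uppermost 20 layers initially tracer, observed over 24 five-minute steps.
Calibration conventionally simulates one tenth of the width (w = 298) and
rescales counts by 10, since the same mixing events occur across the
whole width.

`synthetic_hediste_dataset` forward-simulates this parameterisation to
produce a synthetic stand-in for the experimental profile series, with
the generating truth attached.
"""

from __future__ import annotations

from dataclasses import replace

from .data_io import SyntheticDataset, generate_synthetic
from .model import ModelParams, SimConfig

__all__ = [
    "HEDISTE_PARAMS",
    "HEDISTE_CONFIG_FULL",
    "HEDISTE_CONFIG_FIT",
    "WIDTH_FACTOR",
    "SANN_START",
    "synthetic_hediste_dataset",
]

#: Fitted behavioural parameters of the ragworm experiment.
HEDISTE_PARAMS = ModelParams(
    activity=0.674,
    distance=4.30,
    downwards=0.5,
    range_frac=1.0,
    tracerdif=0.929,
)

#: Full observation grid: 149 layers (73 um each) x 2980 particles wide,
#: tracer in the top 20 layers, 24 steps of 5 minutes.
HEDISTE_CONFIG_FULL = SimConfig(
    d=149, w=2980, d_lum=20,
    layer_height_mm=0.073, dt_min=5.0, n_steps=24, seed=0,
)

#: Calibration runs at one tenth of the width and rescales by 10.
WIDTH_FACTOR = 10
HEDISTE_CONFIG_FIT = replace(HEDISTE_CONFIG_FULL, w=HEDISTE_CONFIG_FULL.w // WIDTH_FACTOR)

#: Conventional starting point for annealing: distance = 5, tracerdif = 0.9.
SANN_START = replace(HEDISTE_PARAMS, distance=5.0, tracerdif=0.9)


def synthetic_hediste_dataset(
    seed: int = 0, *, p_detect: float | None = None
) -> SyntheticDataset:
    """Synthetic full-width profile series from the reference parameters."""
    return generate_synthetic(
        HEDISTE_PARAMS, replace(HEDISTE_CONFIG_FULL, seed=seed), p_detect=p_detect
    )
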