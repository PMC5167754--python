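"""Configuration files and named experiment presets.

Configurations are flat YAML/JSON mappings using the model's standard
parameter names (p, TH, RP, AP, g, M, L, gap, g_e ...).  Presets encode
the canonical grid-experiment conditions: a 50x50 torus of p=0.05,
TH=50, RP=50, AP=200 units with unit excitatory weights, six-spike
signatures (ISIs uniform on 2..12), driven by tonic period-100 inputs,
with the intra-unit parameters (M, L) selecting the memory and
competition regimes.
"""

from __future__ import annotations

from typing import Any, Dict, Mapping, Optional

import yaml

from .core_model import NeuronParams
from .network_sim import SimulationConfig, StimulusEntry
from .plasticity import PlasticityParams

__all__ = [
    "PRESETS",
    "get_preset",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "save_config",
]

#: Default external weight: equal to the firing threshold, so each tonic
#: pulse drives the stimulated unit straight over threshold and the unit
#: follows the stimulus outside its refractoriness.
DEFAULT_GE = 50

_STIM_KEYS = {"period", "cell", "t_start", "t_end", "g_e"}

_TOP_KEYS = {
    "preset",
    "duration",
    "seed",
    "rows",
    "cols",
    "p",
    "TH",
    "RP",
    "AP",
    "g",
    "M",
    "L",
    "gap",
    "signature_spikes",
    "isi_range",
    "v0_range",
    "stimuli",
}


def _ten_stimuli(**kw) -> list:
    """Ten tonic inputs at distinct rates (periods 60..150), seeded cells."""
    return [
        {"period": 60 + 10 * k, "cell": None, "g_e": DEFAULT_GE, **kw}
        for k in range(10)
    ]


#: Named experiment presets (flat parameter mappings).  A stimulus
#: ``t_end`` of "mid" is resolved to duration // 2 so the second half of
#: the run observes the reverberation after data offset.
PRESETS: Dict[str, Dict[str, Any]] = {
    # autonomous network generating spontaneous bursting wave fronts
    "autonomous": {"M": 400, "L": 4, "stimuli": []},
    # one cell driven by a period-100 tonic input for the whole run
    "single_stimulus": {
        "M": 400,
        "L": 4,
        "stimuli": [{"period": 100, "cell": None, "g_e": DEFAULT_GE}],
    },
    # ten simultaneous tonic inputs at different rates
    "ten_stimuli": {"M": 400, "L": 4, "stimuli": _ten_stimuli()},
    # single input active for the first half of the run; (M, L) select
    # the memory regime of the fingerprint dimension
    "memory_long_term": {
        "M": 500,
        "L": 5,
        "stimuli": [
            {"period": 100, "cell": None, "g_e": DEFAULT_GE, "t_end": "mid"}
        ],
    },
    "memory_short_term": {
        "M": 400,
        "L": 4,
        "stimuli": [
            {"period": 100, "cell": None, "g_e": DEFAULT_GE, "t_end": "mid"}
        ],
    },
    "memory_short_term_small_window": {
        "M": 350,
        "L": 4,
        "stimuli": [
            {"period": 100, "cell": None, "g_e": DEFAULT_GE, "t_end": "mid"}
        ],
    },
    # competition among ten propagating fingerprints
    "competition_localized": {"M": 400, "L": 4, "stimuli": _ten_stimuli()},
    "competition_winnerless": {"M": 350, "L": 4, "stimuli": _ten_stimuli()},
    "competition_alternating": {"M": 500, "L": 5, "stimuli": _ten_stimuli()},
    "competition_winner_take_all": {
        "p": 0.08,
        "M": 350,
        "L": 3,
        "stimuli": _ten_stimuli(),
    },
}


def config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    """Build and validate a :class:`SimulationConfig` from a flat mapping.

    Unknown keys are rejected; missing keys take the standard defaults.
    """
    d = dict(d)
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "duration" not in d or "seed" not in d:
        raise ValueError("configuration must define 'duration' and 'seed'")
    duration = int(d["duration"])

    neuron = NeuronParams(
        p=float(d.get("p", 0.05)),
        TH=int(d.get("TH", 50)),
        RP=int(d.get("RP", 50)),
        AP=int(d.get("AP", 200)),
    )
    signature_spikes = int(d.get("signature_spikes", 6))
    plasticity = PlasticityParams(
        M=int(d.get("M", 400)),
        L=int(d.get("L", 4)),
        gap=int(d.get("gap", 24)),
        pattern_len=signature_spikes - 1,
    )
    stimuli = []
    for s in d.get("stimuli", []) or []:
        unknown = set(s) - _STIM_KEYS
        if unknown:
            raise ValueError(f"unknown stimulus keys: {sorted(unknown)}")
        t_end = s.get("t_end")
        if t_end == "mid":
            t_end = duration // 2
        stimuli.append(
            StimulusEntry(
                period=int(s["period"]),
                cell=None if s.get("cell") is None else int(s["cell"]),
                t_start=int(s.get("t_start", 1)),
                t_end=None if t_end is None else int(t_end),
                g_e=int(s.get("g_e", DEFAULT_GE)),
            )
        )
    config = SimulationConfig(
        duration=duration,
        seed=int(d["seed"]),
        rows=int(d.get("rows", 50)),
        cols=int(d.get("cols", 50)),
        neuron=neuron,
        plasticity=plasticity,
        g=int(d.get("g", 1)),
        signature_spikes=signature_spikes,
        isi_range=tuple(d.get("isi_range", (2, 12))),
        v0_range=tuple(d.get("v0_range", (0, 40))),
        stimuli=tuple(stimuli),
    )
    config.validate()
    return config


def config_to_dict(config: SimulationConfig) -> Dict[str, Any]:
    """Flat mapping representation; round-trips through
    :func:`config_from_dict`."""
    return {
        "duration": config.duration,
        "seed": config.seed,
        "rows": config.rows,
        "cols": config.cols,
        "p": config.neuron.p,
        "TH": config.neuron.TH,
        "RP": config.neuron.RP,
        "AP": config.neuron.AP,
        "g": config.g,
        "M": config.plasticity.M,
        "L": config.plasticity.L,
        "gap": config.plasticity.gap,
        "signature_spikes": config.signature_spikes,
        "isi_range": list(config.isi_range),
        "v0_range": list(config.v0_range),
        "stimuli": [
            {
                "period": s.period,
                "cell": s.cell,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "g_e": s.g_e,
            }
            for s in config.stimuli
        ],
    }


def get_preset(
    name: str, duration: int, seed: int, **overrides: Any
) -> SimulationConfig:
    """Instantiate a named preset with the given run length and seed.

    Keyword overrides use the same flat keys as configuration files
    (e.g. ``L=5, M=500``).
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    d: Dict[str, Any] = {"duration": duration, "seed": seed}
    d.update(PRESETS[name])
    d.update(overrides)
    return config_from_dict(d)


def load_config(path) -> SimulationConfig:
    """Load a YAML/JSON configuration file (optionally preset-based)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict) or not d:
        raise ValueError(f"configuration file {path} is empty or not a mapping")
    preset = d.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        merged: Dict[str, Any] = dict(PRESETS[preset])
        merged.update(d)
        d = merged
    return config_from_dict(d)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
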