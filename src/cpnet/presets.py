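"""Named experiment presets bundling network, stimulus and protocol options.

Each preset reproduces one study condition.  Presets are expressed as
deviations from a base configuration, so they can be materialized either at
full scale (`reduced=False`) or on the quarter-scale calibrated network
(`reduced=True`) used by the test suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .config import NetworkConfig, StimulusConfig

__all__ = ["ExperimentPreset", "PRESETS", "get_preset"]


@dataclass
class ExperimentPreset:
    name: str
    network: NetworkConfig
    stimulus: StimulusConfig
    mode: str = "non-replicate"
    n_stimuli: int = 0  # replicate-bank size when mode == "replicate"
    heterogeneous: bool = False
    notes: str = ""
    deviations: dict = field(default_factory=dict)


# deviations from the default condition; "g_ff_factor" scales the base
# feedforward efficacy (slower decision dynamics)
_SPECS = {
    "fig1": dict(net={"b_fb": 0.0}, stim={"sigma": 1.0},
                 notes="single-trial phenomenology, no top-down feedback"),
    "fig2_bottomup": dict(net={"b_fb": 0.0}, stim={"sigma": 1.0},
                          notes="bottom-up CP only: non-replicate, b_FB=0"),
    "fig2_topdown": dict(net={"b_fb": 1.0}, stim={"sigma": 1.0},
                         mode="replicate", n_stimuli=100,
                         notes="top-down CP only: replicate stimuli, "
                               "global background, b_FB=1"),
    "fig3_combined": dict(net={"b_fb": 1.0}, stim={"sigma": 1.0},
                          notes="combined condition: non-replicate, b_FB=1"),
    "fig3_slow": dict(net={"b_fb": 1.0, "g_ff_factor": 0.75},
                      stim={"sigma": 1.33},
                      notes="slower decision dynamics: g_FF x 0.75, "
                            "sigma=1.33"),
    "fig5_heterogeneous": dict(net={"b_fb": 1.0}, stim={"sigma": 1.0},
                               heterogeneous=True,
                               notes="four stimulus/top-down input groups"),
    "fig7_bounds": dict(net={"b_fb": 0.0}, stim={"sigma": 2.7},
                        notes="bound-crossing analysis; compare b_FB 0 vs 4"),
    "fig7_sweep": dict(net={"b_fb": 0.0}, stim={"sigma": 2.7},
                       notes="stability-accuracy sweep over "
                             "b_FB in {0, 1.5, 3, 4.5, 6}"),
}


def get_preset(name: str, reduced: bool = False, **net_overrides
               ) -> ExperimentPreset:
    """Materialize a named preset.

    reduced=True builds it on the quarter-scale calibrated network.
    Extra keyword arguments override network-config fields (e.g. b_fb for
    sweep presets, master_seed).
    """
    try:
        spec = _SPECS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(_SPECS)}") from None
    base = NetworkConfig.reduced() if reduced else NetworkConfig()
    net_kw = dict(spec.get("net", {}))
    factor = net_kw.pop("g_ff_factor", None)
    if factor is not None:
        net_kw["g_ff"] = base.g_ff * factor
    net_kw.update(net_overrides)
    network = base.replace(**net_kw)
    stimulus = StimulusConfig(**spec.get("stim", {}))
    return ExperimentPreset(
        name=name, network=network, stimulus=stimulus,
        mode=spec.get("mode", "non-replicate"),
        n_stimuli=spec.get("n_stimuli", 0),
        heterogeneous=spec.get("heterogeneous", False),
        notes=spec.get("notes", ""),
        deviations={"network": net_kw, "stimulus": spec.get("stim", {}),
                    "reduced": reduced})


PRESETS = dict.fromkeys(_SPECS)  # names; materialize via get_preset
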