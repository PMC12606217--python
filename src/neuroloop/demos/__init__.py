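"""Packaged desk-scale demo pipelines.

Each demo reproduces one of the five end-to-end experiments on synthetic
data: streaming LNP characterization, behavior-video regression, Bubblewrap
trajectory prediction, closed-loop Bayesian stimulus optimization, and
adaptive photostimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources


@dataclass
class DemoSpec:
    name: str
    config: str  # packaged YAML file name
    frames: int | None = None  # source step budget (None: sources self-stop)
    scale_overrides: dict = field(default_factory=dict)  # scale -> actor -> params


DEMOS: dict[str, DemoSpec] = {
    "fig2_lnp": DemoSpec(
        name="fig2_lnp",
        config="fig2_lnp.yaml",
        scale_overrides={
            "small": {"source": {"n_frames": 600, "n_neurons": 10}},
            "full": {"source": {"n_frames": 3000, "n_neurons": 20}},
        },
    ),
    "fig3_behavior": DemoSpec(
        name="fig3_behavior",
        config="fig3_behavior.yaml",
        scale_overrides={
            "small": {"source": {"n_frames": 400}},
            "full": {"source": {"n_frames": 1200}},
        },
    ),
    "fig4_bubblewrap": DemoSpec(
        name="fig4_bubblewrap",
        config="fig4_bubblewrap.yaml",
        scale_overrides={
            "small": {"source": {"n_frames": 2000}},
            "full": {
                "source": {"n_frames": 10000},
                "bubblewrap": {"horizons": [1, 2, 3, 4, 5, 10, 25, 50, 100]},
            },
        },
    ),
    "fig5_bo": DemoSpec(
        name="fig5_bo",
        config="fig5_bo.yaml",
        frames=20000,  # closed loop: bound the presenter's idle spinning
        scale_overrides={
            "small": {
                "presenter": {"n_neurons": 30},
                "bo": {"n_neurons": 30},
            },
            "full": {
                "presenter": {"n_neurons": 200},
                "bo": {"n_neurons": 200},
            },
        },
    ),
    "fig6_photostim": DemoSpec(
        name="fig6_photostim",
        config="fig6_photostim.yaml",
        scale_overrides={
            "small": {"source": {"n_rois": 15}},
            "full": {"source": {"n_rois": 40, "repetitions": 3}},
        },
    ),
}


def demo_config_text(name: str) -> str:
    spec = DEMOS[name]
    return (resources.files(__package__) / spec.config).read_text()
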