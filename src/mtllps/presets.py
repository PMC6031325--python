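"""Named deterministic simulation scenarios with expected outcome classes.

Each preset is a JSON spec (shipped as package data) that regenerates
bit-identically from its stored seed.  The presets model the qualitative
regimes the assay distinguishes, not any specific protein pair:

* ``same_protein``     — both channels report the same protein; no
                         compartment should be detected.
* ``strong_demix``     — immiscible pair (e.g. TDP-43 vs G3BP1-like):
                         many compartments, median enrichment above 100%.
* ``partial_mix``      — partially miscible pair (TDP-43 vs FUS-like):
                         compartments poorly enriched, median below 50%.
* ``reduced_self``     — a partner with little self-attraction: sparse
                         compartments caused mostly by *exclusion* of the
                         coexisting protein rather than self-enrichment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .datatypes import TwoChannelImage
from .simulate import (
    GroundTruth,
    PlantedCompartment,
    SimulationSpec,
    make_network,
    render_scene,
)

__all__ = ["ScenarioPreset", "list_presets", "get_preset", "load_preset"]


@dataclass
class ScenarioPreset:
    name: str
    spec: SimulationSpec
    planted: list[PlantedCompartment]
    expected: dict

    def render(self) -> tuple[TwoChannelImage, GroundTruth]:
        paths = make_network(self.spec)
        return render_scene(paths, self.planted, self.spec)


def _data_dir():
    return resources.files("mtllps") / "presets_data"


def list_presets() -> list[str]:
    return sorted(p.name[:-5] for p in _data_dir().iterdir() if p.name.endswith(".json"))


def get_preset(name: str) -> ScenarioPreset:
    path = _data_dir() / f"{name}.json"
    if not path.is_file():
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(list_presets())}"
        )
    d = json.loads(path.read_text())
    return ScenarioPreset(
        name=d["name"],
        spec=SimulationSpec.from_dict(d["spec"]),
        planted=[PlantedCompartment(**c) for c in d["planted"]],
        expected=d["expected"],
    )


def load_preset(name: str) -> tuple[TwoChannelImage, GroundTruth]:
    """Render the named scenario deterministically from its stored seed."""
    return get_preset(name).render()
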