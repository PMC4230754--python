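"""Loading of the versioned model parameter files bundled with the package."""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Any

_DATA_FILES = ("muscles", "curves", "neuron", "feedback", "spindle",
               "motorunits", "protocol_runs")


@lru_cache(maxsize=None)
def load(name: str) -> dict[str, Any]:
    """Return the parsed parameter file ``name`` (without extension)."""
    if name not in _DATA_FILES:
        raise KeyError(f"unknown parameter file {name!r}; have {_DATA_FILES}")
    ref = resources.files("stancesim.data").joinpath(f"{name}.json")
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def muscle_names() -> tuple[str, ...]:
    return tuple(load("muscles")["muscles"].keys())
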