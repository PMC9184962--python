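"""Versioned parameter fixtures and figure-level scenarios.

Every figure-level computation in the package is reproducible by name: a
:class:`ScenarioConfig` bundles a model, its parameter set (with per-value
provenance), the analysis to run and the projection plane.  Parameter values
are shipped as structured-text fixtures under ``mitoclock/data`` so that
each number traces to a citable location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .models import CheckpointScenario, ModelDefinition, ParameterSet, get_model

__all__ = [
    "ScenarioConfig",
    "table1_parameters",
    "parameter_provenance",
    "figure_scenario",
    "list_scenarios",
    "SCENARIO_IDS",
]


def _load_yaml(name: str) -> dict:
    with resources.files("mitoclock.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def _parameter_table() -> dict:
    return _load_yaml("parameters.yaml")


@lru_cache(maxsize=None)
def _scenario_table() -> dict:
    return _load_yaml("scenarios.yaml")


def table1_parameters(model_id: int | str) -> ParameterSet:
    """Reference parameter set for one model, caption constants included.

    ``model_id`` may be 1-4 or 'model1'...'model4'.  The returned set is
    immutable; use :meth:`ParameterSet.replace` for overrides.
    """
    key = f"model{model_id}" if isinstance(model_id, int) else model_id
    table = _parameter_table()
    if key not in table:
        raise KeyError(f"unknown model id {model_id!r}; known: {sorted(table)}")
    return ParameterSet(**{k: v["value"] for k, v in table[key].items()})


def parameter_provenance(model_id: int | str) -> dict[str, str]:
    """Citable source label for every parameter of one model's fixture."""
    key = f"model{model_id}" if isinstance(model_id, int) else model_id
    return {k: v["source"] for k, v in _parameter_table()[key].items()}


@dataclass(frozen=True)
class ScenarioConfig:
    """A named, fully specified figure-level computation."""

    id: str
    model: ModelDefinition
    params: ParameterSet
    analysis: str                       # simulate|cycle|nullclines|arrest|branch|sizecycle
    x0: np.ndarray
    plane: tuple[str, ...] = ()
    checkpoint: CheckpointScenario | None = None
    nullclines: tuple[dict, ...] = ()
    description: str = ""
    anchor: str = ""
    extra: dict = field(default_factory=dict)


def figure_scenario(scenario_id: str) -> ScenarioConfig:
    """Build the runnable configuration for a named scenario.

    Running the configured analysis regenerates the computational content
    of the corresponding figure (time courses, pseudo-nullclines, arrest
    states, branch diagrams); plot aesthetics are out of scope.
    """
    table = _scenario_table()
    if scenario_id not in table:
        raise KeyError(f"unknown scenario {scenario_id!r}; "
                       f"known: {sorted(table)}")
    raw = table[scenario_id]
    model = get_model(raw["model"])
    params = table1_parameters(raw["model"])
    checkpoint = None
    if "checkpoint" in raw:
        checkpoint = CheckpointScenario(kind=raw["checkpoint"]["kind"],
                                        overrides=raw["checkpoint"]["overrides"])
        params = checkpoint.apply(params)
    extra = {k: raw[k] for k in ("mu", "v0", "entry_threshold",
                                 "exit_threshold", "n_cycles", "free_param",
                                 "range", "envelope_values") if k in raw}
    return ScenarioConfig(
        id=scenario_id,
        model=model,
        params=params,
        analysis=raw["analysis"],
        x0=np.zeros(len(model.state_names)),
        plane=tuple(raw.get("plane", ())),
        checkpoint=checkpoint,
        nullclines=tuple(raw.get("nullclines", ())),
        description=" ".join(str(raw.get("description", "")).split()),
        anchor=raw.get("anchor", ""),
        extra=extra,
    )


def list_scenarios() -> list[dict[str, str]]:
    """Manifest of scenario ids with their descriptions and anchors."""
    return [{"id": sid,
             "model": raw["model"],
             "analysis": raw["analysis"],
             "anchor": raw.get("anchor", ""),
             "description": " ".join(str(raw.get("description", "")).split())}
            for sid, raw in _scenario_table().items()]


SCENARIO_IDS = tuple(_scenario_table())
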