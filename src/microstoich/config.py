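"""Parameter-file loading, validation and round-tripping.

Scenario configuration is one human-readable YAML file whose keys mirror
:class:`~microstoich.core_model.SimulationParams`, plus an optional
``groups`` section (trait table) and fixed ``component_cn`` block.
Structural constants of the model (grid 100x100, 3-h step, invasion
probability 0.01, constitutive enzyme fraction 0.1, component C:N 15/150/5)
are flagged *paper-fixed*: a config that changes them is rejected unless the
override flag is set explicitly.

Trait tables can also be loaded from delimited text with the Table-1 style
columns (name, component fractions, MCS, colony size, enzyme investment and
allocation).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .core_model import (
    ComponentStoichiometry,
    ConfigurationError,
    FunctionalGroup,
    SimulationParams,
)

__all__ = [
    "default_params",
    "load_config",
    "dump_config",
    "load_traits_table",
    "PAPER_FIXED",
]

#: structural constants and their fixed values
PAPER_FIXED: dict[str, float] = {
    "grid_size": 100,
    "step_hours": 3.0,
    "invade_prob": 0.01,
    "constitutive_fract": 0.1,
}
PAPER_FIXED_COMPONENT_CN = {"dom": 15.0, "mrc": 150.0, "mrn": 5.0}

_SCHEMA = "microstoich-params-v1"
_PARAM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)} - {"comps"}
_META_KEYS = {"schema", "component_cn", "groups", "allow_fixed_override"}

_default_cache: SimulationParams | None = None


def _params_from_mapping(data: dict, source: str,
                         allow_fixed_override: bool = False) -> SimulationParams:
    unknown = set(data) - _PARAM_FIELDS - _META_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown parameter key(s) in {source}: {sorted(unknown)}"
        )
    if data.get("schema", _SCHEMA) != _SCHEMA:
        raise ConfigurationError(f"unsupported schema {data.get('schema')!r}")
    allow = allow_fixed_override or bool(data.get("allow_fixed_override", False))
    if not allow:
        for key, fixed in PAPER_FIXED.items():
            if key in data and float(data[key]) != float(fixed):
                raise ConfigurationError(
                    f"{key} is paper-fixed at {fixed}; set allow_fixed_override "
                    f"to change it (got {data[key]})"
                )
    comp = {**PAPER_FIXED_COMPONENT_CN, **(data.get("component_cn") or {})}
    if not allow and comp != PAPER_FIXED_COMPONENT_CN:
        raise ConfigurationError(
            "component_cn is paper-fixed at 15/150/5; set allow_fixed_override"
        )
    kwargs = {k: v for k, v in data.items() if k in _PARAM_FIELDS}
    for key in ("vmax", "km"):
        if key in kwargs:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    comps = ComponentStoichiometry(
        cn_dom_component=comp["dom"], cn_mrc=comp["mrc"], cn_mrn=comp["mrn"]
    )
    return SimulationParams(comps=comps, **kwargs)


def default_params() -> SimulationParams:
    """The shipped default parameter set (from ``data/default_params.yaml``)."""
    global _default_cache
    if _default_cache is None:
        ref = importlib.resources.files("microstoich") / "data" / "default_params.yaml"
        data = yaml.safe_load(ref.read_text())
        _default_cache = _params_from_mapping(data, "default_params.yaml")
    return dataclasses.replace(_default_cache)


def load_config(
    path: str | Path, allow_fixed_override: bool = False
) -> tuple[SimulationParams, list[FunctionalGroup]]:
    """Load and validate a scenario configuration file.

    Returns ``(params, groups)``; ``groups`` is empty when the file has no
    ``groups`` section.  Unknown keys, out-of-range values and unflagged
    changes to paper-fixed constants all raise
    :class:`~microstoich.core_model.ConfigurationError`.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    params = _params_from_mapping(data, str(path), allow_fixed_override)
    groups = [_group_from_mapping(g, params) for g in data.get("groups", [])]
    return params, groups


_GROUP_KEYS = {
    "name", "f_dom", "f_mrc", "f_mrn", "mcs", "max_cells_per_site",
    "enz_fract", "enz_ratio", "mortality_prob",
}


def _group_from_mapping(g: dict, params: SimulationParams) -> FunctionalGroup:
    unknown = set(g) - _GROUP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown trait key(s): {sorted(unknown)}")
    kwargs = dict(g)
    if "enz_ratio" in kwargs:
        kwargs["enz_ratio"] = tuple(float(x) for x in kwargs["enz_ratio"])
    return FunctionalGroup(comps=params.comps, **kwargs)


def dump_config(
    params: SimulationParams,
    path: str | Path,
    groups: list[FunctionalGroup] | None = None,
) -> None:
    """Write a parameter set (and optional trait table) back to YAML.

    ``load_config(dump_config(...))`` round-trips every field exactly.
    """
    data: dict = {"schema": _SCHEMA}
    for f in dataclasses.fields(SimulationParams):
        if f.name == "comps":
            continue
        val = getattr(params, f.name)
        data[f.name] = list(val) if isinstance(val, tuple) else val
    data["component_cn"] = {
        "dom": params.comps.cn_dom_component,
        "mrc": params.comps.cn_mrc,
        "mrn": params.comps.cn_mrn,
    }
    if groups:
        data["groups"] = [
            {
                "name": g.name, "f_dom": g.f_dom, "f_mrc": g.f_mrc,
                "f_mrn": g.f_mrn, "mcs": g.mcs,
                "max_cells_per_site": g.max_cells_per_site,
                "enz_fract": g.enz_fract, "enz_ratio": list(g.enz_ratio),
                **({"mortality_prob": g.mortality_prob}
                   if g.mortality_prob is not None else {}),
            }
            for g in groups
        ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_traits_table(
    path: str | Path, comps: ComponentStoichiometry | None = None
) -> list[FunctionalGroup]:
    """Load functional groups from a delimited trait table.

    Expected columns: ``name, f_dom, f_mrc, f_mrn, mcs, max_cells_per_site,
    enz_fract, enz_plant, enz_mrc, enz_mrn`` (tab or comma separated).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"name", "f_dom", "f_mrc", "f_mrn", "mcs", "max_cells_per_site",
                "enz_fract", "enz_plant", "enz_mrc", "enz_mrn"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"trait table missing column(s): {sorted(missing)}")
    comps = comps or ComponentStoichiometry()
    return [
        FunctionalGroup(
            name=str(row["name"]), f_dom=row["f_dom"], f_mrc=row["f_mrc"],
            f_mrn=row["f_mrn"], mcs=row["mcs"],
            max_cells_per_site=int(row["max_cells_per_site"]),
            enz_fract=row["enz_fract"],
            enz_ratio=(row["enz_plant"], row["enz_mrc"], row["enz_mrn"]),
            comps=comps,
        )
        for _, row in df.iterrows()
    ]
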