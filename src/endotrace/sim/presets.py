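"""Named default parameter sets for the simulators.

Presets live in ``presets.yaml`` (data, not code). Each event preset
pairs mean trapezoid kinetics with an event-to-event variability block;
:func:`sample_event_kinetics` draws one event's kinetics from that
distribution.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from endotrace.binding import CaTitrationModel, SequentialBindingModel
from endotrace.sim.models import CameraModel, EventKinetics, SingleMoleculeKinetics


@lru_cache(maxsize=1)
def _load() -> dict:
    text = resources.files("endotrace.sim").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def list_presets() -> dict[str, list[str]]:
    """Names of all shipped presets, grouped by kind."""
    data = _load()
    return {
        kind: sorted(data[kind])
        for kind in ("events", "two_color", "titrations", "transients")
    } | {"single_molecule": ["single_molecule"], "cameras": sorted(data["cameras"])}


def _lookup(kind: str, name: str) -> dict:
    data = _load()
    try:
        return data[kind][name]
    except KeyError:
        known = ", ".join(sorted(data.get(kind, {})))
        raise KeyError(f"unknown {kind} preset {name!r}; available: {known}") from None


def preset(name: str) -> dict:
    """Raw preset dictionary for ``name``, searched across all kinds."""
    data = _load()
    for kind in ("events", "two_color", "titrations", "transients"):
        if name in data[kind]:
            return {"kind": kind, **data[kind][name]}
    if name == "single_molecule":
        return {"kind": "single_molecule", **data["single_molecule"]}
    all_names = sorted(
        set().union(*(data[k] for k in ("events", "two_color", "titrations", "transients"))) | {"single_molecule"}
    )
    raise KeyError(f"unknown preset {name!r}; available: {', '.join(all_names)}")


def camera_preset(name: str) -> CameraModel:
    return CameraModel(**_lookup("cameras", name))


def excitation_scale() -> float:
    """Illumination ratio between measurement and calibration scenes."""
    return float(_load()["calibration"]["excitation_scale"])


def event_kinetics_preset(name: str) -> EventKinetics:
    """Mean (variability-free) kinetics of an event preset."""
    return EventKinetics(**_lookup("events", name)["kinetics"])


def event_camera(name: str) -> CameraModel:
    return camera_preset(_lookup("events", name)["camera"])


def sample_event_kinetics(name: str, rng: np.random.Generator) -> EventKinetics:
    """Draw one event's kinetics from the preset's variability model.

    Peak molecule count and the two rates vary multiplicatively (Gaussian
    CVs), the plateau duration additively (Gaussian SD); all quantities
    are truncated away from zero so every draw is a valid trapezoid. The
    scission offset, when present, is Gaussian with a hard minimum.
    """
    spec = _lookup("events", name)
    kin = spec["kinetics"]
    var = spec.get("variability", {})
    peak_cv = var.get("peak_cv", 0.0)
    rate_cv = var.get("rate_cv", 0.0)
    plateau_sd = var.get("plateau_sd", 0.0)

    peak = kin["peak_molecules"] * max(0.1, 1.0 + rng.normal(0.0, peak_cv)) if peak_cv else kin["peak_molecules"]
    rise = kin["rise_rate"] * max(0.1, 1.0 + rng.normal(0.0, rate_cv)) if rate_cv else kin["rise_rate"]
    fall = kin["fall_rate"] * max(0.1, 1.0 + rng.normal(0.0, rate_cv)) if rate_cv else kin["fall_rate"]
    plateau = max(0.5, kin["plateau_duration"] + rng.normal(0.0, plateau_sd)) if plateau_sd else kin["plateau_duration"]

    scission_offset = kin.get("scission_offset")
    if scission_offset is not None and var.get("scission_sd", 0.0) > 0:
        scission_offset = max(
            var.get("scission_min", 0.5), scission_offset + rng.normal(0.0, var["scission_sd"])
        )
    return EventKinetics(
        rise_rate=rise,
        peak_molecules=peak,
        plateau_duration=plateau,
        fall_rate=fall,
        scission_mode=kin.get("scission_mode", "none"),
        scission_offset=scission_offset,
    )


def single_molecule_preset() -> tuple[SingleMoleculeKinetics, CameraModel]:
    spec = _load()["single_molecule"]
    camera = camera_preset(spec["camera"])
    kin = SingleMoleculeKinetics(
        on_rate_density=spec["on_rate_density"],
        off_rate=spec["off_rate"],
        diffusion_coefficient=spec["diffusion_coefficient"],
    )
    return kin, camera


def titration_preset(name: str):
    """Binding model and acquisition grid of a titration preset.

    Returns ``(model, x_values, noise_cv)`` where ``model`` is a
    :class:`SequentialBindingModel` for binding titrations or a
    :class:`CaTitrationModel` for the pCa preset.
    """
    spec = _lookup("titrations", name)
    if "pca_values" in spec:
        model = CaTitrationModel(**spec["model"])
        return model, np.asarray(spec["pca_values"], dtype=float), spec.get("noise_cv", 0.0)
    model = SequentialBindingModel(**spec["model"])
    return model, np.asarray(spec["ligand_concentrations"], dtype=float), spec.get("noise_cv", 0.0)


def transient_preset(name: str) -> dict:
    return dict(_lookup("transients", name))


def two_color_preset(name: str) -> dict:
    return dict(_lookup("two_color", name))
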