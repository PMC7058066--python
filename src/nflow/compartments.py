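"""Compartment registry for the coupled human-natural urban N system.

The system boundary encloses 12 subsystems arranged in four process groups:

* production  - farmland, urban green, livestock, forest, aquaculture, industry
* consumption - human
* treatment   - sewage disposal, garbage disposal
* environment - atmosphere, surface water, ground water

External compartments (world trade, the ocean, the surrounding atmosphere and
the notional fixation source feeding BNF/HBNF/fossil fixation) sit outside the
boundary; fluxes touching them are the system's boundary-crossing inputs and
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnknownCompartmentError

GROUPS = ("production", "consumption", "treatment", "environment", "external")


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str
    group: str
    within_boundary: bool

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown process group {self.group!r}")


def _c(cid: str, name: str, group: str, within: bool = True) -> Compartment:
    return Compartment(cid, name, group, within)


REGISTRY: dict[str, Compartment] = {
    c.id: c
    for c in (
        # production group
        _c("farmland", "Farmland", "production"),
        _c("urban_green", "Urban green", "production"),
        _c("livestock", "Livestock", "production"),
        _c("forest", "Forest", "production"),
        _c("aquaculture", "Aquaculture", "production"),
        _c("industry", "Industry", "production"),
        # consumption group
        _c("human", "Human", "consumption"),
        # treatment group
        _c("sewage_disposal", "Sewage disposal", "treatment"),
        _c("garbage_disposal", "Garbage disposal", "treatment"),
        # environment group
        _c("surface_water", "Surface water", "environment"),
        _c("ground_water", "Ground water", "environment"),
        _c("atmosphere", "Atmosphere", "environment"),
        # external world
        _c("world_trade", "World trade", "external", within=False),
        _c("ocean", "Ocean", "external", within=False),
        _c("surrounding_atmosphere", "Surrounding atmosphere", "external", within=False),
        _c("fixation_source", "N fixation source", "external", within=False),
    )
}

#: The 12 within-boundary subsystems, in registry order.
SUBSYSTEMS: tuple[str, ...] = tuple(c.id for c in REGISTRY.values() if c.within_boundary)

#: External compartment ids.
EXTERNAL: tuple[str, ...] = tuple(c.id for c in REGISTRY.values() if not c.within_boundary)

#: Within-boundary process groups -> member ids.
GROUP_MEMBERS: dict[str, tuple[str, ...]] = {
    g: tuple(c.id for c in REGISTRY.values() if c.within_boundary and c.group == g)
    for g in ("production", "consumption", "treatment", "environment")
}


def get(cid: str) -> Compartment:
    try:
        return REGISTRY[cid]
    except KeyError:
        raise UnknownCompartmentError(
            f"unknown compartment id {cid!r}; known ids: {sorted(REGISTRY)}"
        ) from None


def is_internal(cid: str) -> bool:
    return get(cid).within_boundary
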