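"""Digital twin of a PDMS lifting-gate valve optofluidic chip.

The chip is modeled as an undirected graph of nodes: pneumatic valves,
fluidic reservoirs (inlet wells and outlet/waste wells) and one passive
*detection node* feeding the optical detection channel. Lifting-gate
semantics, in the parcel/ledger model used here:

* **Opening** a valve (negative pressure lifts the PDMS membrane) creates
  an exchange volume; if the valve sits under a loaded inlet reservoir it
  draws fluid from the well, up to its free capacity.
* **Closing** a valve (positive pressure) expels its contained parcel
  toward adjacent open nodes — open valves, reservoirs and the detection
  channel — split *equally by volume* among them, composition traveling
  with each share. Closing with no open neighbour traps the parcel
  (flagged in an audit field with a warning; a real device would
  back-pressure).

Parcels merge volume-additively with volume-weighted composition
averaging; mixing is instantaneous and perfect. There is no pressure or
flow physics, no diffusion, no channel geometry — this is a conservative
state machine whose invariant is exact per-reagent volume conservation:

    on-chip + trapped + in reservoirs  ==  total loaded   (within 1e-9 rel.)

The default topology is a schematic stand-in for a 15-valve, 6-reservoir
chip: three inlet valves under inlet wells, three central mixing valves, a
transport chain to the detection channel, and a waste arm. It is a
schematic, not a map of any specific physical chip; any alternative
architecture can be supplied as a YAML/JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .interpreter import ExecutionTrace, Mode, run_script
from .script import Script, validate_script

__all__ = [
    "ChipTopology",
    "FluidParcel",
    "ChipState",
    "ProtocolConfig",
    "VirtualChip",
    "FluidicsError",
    "default_topology",
    "default_protocol",
    "reference_staining_script",
    "wash_script",
    "load_topology",
    "run_protocol",
]

REL_TOL = 1e-9  # conservation tolerance, relative to total loaded volume


class FluidicsError(ValueError):
    """Structural misuse of the chip model (unknown node, bad load...)."""


@dataclass(frozen=True)
class ChipTopology:
    """Valve/reservoir adjacency graph of one chip architecture."""

    n_valves: int
    reservoirs: dict[str, str]              # reservoir id -> role ("INLET"|"OUTLET")
    adjacency: dict[str, frozenset[str]]    # node id -> neighbours (undirected)
    detection_node: str
    valve_capacity_nl: float = 10.0
    name: str = "chip"

    @property
    def valves(self) -> set[str]:
        return {f"v{i}" for i in range(1, self.n_valves + 1)}

    def valve_node(self, valve_id: int) -> str:
        if not (1 <= valve_id <= self.n_valves):
            raise FluidicsError(f"valve {valve_id} outside range 1..{self.n_valves}")
        return f"v{valve_id}"

    def validate(self) -> None:
        nodes = self.valves | set(self.reservoirs) | {self.detection_node}
        for a, nbrs in self.adjacency.items():
            if a not in nodes:
                raise FluidicsError(f"adjacency lists unknown node {a!r}")
            for b in nbrs:
                if b not in nodes:
                    raise FluidicsError(f"adjacency lists unknown node {b!r}")
                if a not in self.adjacency.get(b, frozenset()):
                    raise FluidicsError(f"edge {a}-{b} is not symmetric")
        for role in self.reservoirs.values():
            if role not in ("INLET", "OUTLET"):
                raise FluidicsError(f"unknown reservoir role {role!r}")
        # connectivity and inlet -> detection reachability (BFS)
        if self._reachable(next(iter(nodes))) != nodes:
            raise FluidicsError("topology graph is not connected")
        for rid, role in self.reservoirs.items():
            if role == "INLET" and self.detection_node not in self._reachable(rid):
                raise FluidicsError(f"detection node unreachable from inlet {rid}")

    def _reachable(self, start: str) -> set[str]:
        seen = {start}
        frontier = [start]
        while frontier:
            n = frontier.pop()
            for m in self.adjacency.get(n, frozenset()):
                if m not in seen:
                    seen.add(m)
                    frontier.append(m)
        return seen


@dataclass
class FluidParcel:
    """A volume of fluid with a reagent composition (fractions sum to 1)."""

    volume_nl: float = 0.0
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume_nl < 0:
            raise FluidicsError("parcel volume must be non-negative")
        if self.volume_nl == 0 and self.composition:
            raise FluidicsError("empty parcel cannot carry a composition")

    def is_empty(self) -> bool:
        return self.volume_nl == 0.0

    def merge(self, other: "FluidParcel") -> "FluidParcel":
        """Volume-additive merge with volume-weighted composition average."""
        v = self.volume_nl + other.volume_nl
        if v == 0:
            return FluidParcel()
        comp: dict[str, float] = {}
        for parcel in (self, other):
            for reagent, frac in parcel.composition.items():
                comp[reagent] = comp.get(reagent, 0.0) + frac * parcel.volume_nl
        return FluidParcel(v, {r: m / v for r, m in comp.items()})

    def split(self, k: int) -> list["FluidParcel"]:
        """k parcels of volume V/k, identical composition."""
        share = self.volume_nl / k
        return [FluidParcel(share, dict(self.composition)) for _ in range(k)]

    def reagent_volumes(self) -> dict[str, float]:
        return {r: f * self.volume_nl for r, f in self.composition.items()}


@dataclass
class ChipState:
    """Mutable fluidic state of one chip: valve states, parcels, ledgers."""

    topology: ChipTopology
    valve_open: dict[str, bool] = field(default_factory=dict)
    contents: dict[str, FluidParcel] = field(default_factory=dict)
    reservoir_loaded: dict[str, dict[str, float]] = field(default_factory=dict)
    reservoir_inflow: dict[str, dict[str, float]] = field(default_factory=dict)
    trapped: dict[str, FluidParcel] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in self.topology.valves:
            self.valve_open.setdefault(v, False)

    # -- bookkeeping -------------------------------------------------------

    def parcel_at(self, node: str) -> FluidParcel:
        return self.contents.get(node, FluidParcel())

    def total_loaded(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for per_reagent in self.reservoir_loaded.values():
            for r, v in per_reagent.items():
                out[r] = out.get(r, 0.0) + v
        return out

    def total_on_system(self) -> dict[str, float]:
        """Per-reagent volume everywhere: nodes, trapped audit, reservoirs."""
        out: dict[str, float] = {}
        for parcel in list(self.contents.values()) + list(self.trapped.values()):
            for r, v in parcel.reagent_volumes().items():
                out[r] = out.get(r, 0.0) + v
        return out

    def conservation_error(self) -> float:
        """Max relative per-reagent imbalance vs. everything ever loaded."""
        loaded = self.total_loaded()
        held = self.total_on_system()
        worst = 0.0
        for r in set(loaded) | set(held):
            total = loaded.get(r, 0.0)
            diff = abs(held.get(r, 0.0) - total)
            worst = max(worst, diff / total if total > 0 else diff)
        return worst

    def to_json(self) -> str:
        return json.dumps(
            {
                "topology": self.topology.name,
                "valve_open": {k: self.valve_open[k] for k in sorted(self.valve_open)},
                "contents": {
                    n: {"volume_nl": p.volume_nl, "composition": p.composition}
                    for n, p in sorted(self.contents.items())
                    if not p.is_empty()
                },
                "trapped": {
                    n: {"volume_nl": p.volume_nl, "composition": p.composition}
                    for n, p in sorted(self.trapped.items())
                },
                "reservoir_loaded": self.reservoir_loaded,
                "reservoir_inflow": self.reservoir_inflow,
                "warnings": self.warnings,
            },
            indent=2,
        )


@dataclass(frozen=True)
class ProtocolConfig:
    """Reagent loading plan and incubation time for one experiment."""

    inlet_loads: tuple[tuple[str, str, float], ...]  # (reservoir, reagent, volume µL)
    incubation_ms: int = 20 * 60 * 1000

    def __post_init__(self) -> None:
        if self.incubation_ms < 0:
            raise FluidicsError("incubation time must be non-negative")


# ---------------------------------------------------------------------------
# operations on chip state


def load_inlet(state: ChipState, reservoir: str, reagent: str, volume_nl: float) -> ChipState:
    """Credit an inlet well with a reagent volume (nanoliters).

    The fluid sits in the well until an adjacent valve opens and draws it.
    Sequential loads accumulate; loading an outlet well or a non-positive
    volume is an error. Mutates and returns ``state``.
    """
    role = state.topology.reservoirs.get(reservoir)
    if role is None:
        raise FluidicsError(f"unknown reservoir {reservoir!r}")
    if role != "INLET":
        raise FluidicsError(f"reservoir {reservoir} has role {role}, cannot be loaded")
    if volume_nl <= 0:
        raise FluidicsError("load volume must be positive")
    state.reservoir_loaded.setdefault(reservoir, {})
    state.reservoir_loaded[reservoir][reagent] = (
        state.reservoir_loaded[reservoir].get(reagent, 0.0) + volume_nl
    )
    state.contents[reservoir] = state.parcel_at(reservoir).merge(
        FluidParcel(volume_nl, {reagent: 1.0})
    )
    return state


def open_valve(state: ChipState, valve_id: int) -> ChipState:
    """Lift the valve membrane: mark open and draw from adjacent inlet wells.

    The draw is capped at the valve's free capacity; the well keeps the
    remainder. Opening an already-open valve is a no-op.
    """
    node = state.topology.valve_node(valve_id)
    if state.valve_open[node]:
        return state
    state.valve_open[node] = True
    # reclaim any parcel trapped here by an earlier dead-end close
    if node in state.trapped:
        state.contents[node] = state.parcel_at(node).merge(state.trapped.pop(node))
    _draw_from_inlets(state, node)
    return state


def _draw_from_inlets(state: ChipState, node: str) -> None:
    cap = state.topology.valve_capacity_nl
    for nbr in sorted(state.topology.adjacency.get(node, frozenset())):
        if state.topology.reservoirs.get(nbr) != "INLET":
            continue
        well = state.parcel_at(nbr)
        if well.is_empty():
            continue
        free = cap - state.parcel_at(node).volume_nl
        if free <= 0:
            break
        take = min(free, well.volume_nl)
        drawn = FluidParcel(take, dict(well.composition))
        remaining = well.volume_nl - take
        state.contents[nbr] = (
            FluidParcel(remaining, dict(well.composition)) if remaining > 0 else FluidParcel()
        )
        state.contents[node] = state.parcel_at(node).merge(drawn)


def close_valve(state: ChipState, valve_id: int) -> ChipState:
    """Collapse the valve membrane: expel its parcel to open neighbours.

    The parcel splits equally by volume among adjacent open nodes (open
    valves, reservoirs, the detection channel). With no open neighbour the
    parcel is trapped — audited, warned about, conserved. Closing an
    already-closed or empty valve moves no fluid.
    """
    topo = state.topology
    node = topo.valve_node(valve_id)
    was_open = state.valve_open[node]
    state.valve_open[node] = False
    parcel = state.parcel_at(node)
    if parcel.is_empty():
        return state
    if not was_open:
        # closed valve already holds only trapped fluid; nothing to expel
        return state

    open_nbrs = sorted(
        n
        for n in topo.adjacency.get(node, frozenset())
        if _node_is_open(state, n)
    )
    state.contents[node] = FluidParcel()
    if not open_nbrs:
        state.trapped[node] = state.trapped.get(node, FluidParcel()).merge(parcel)
        state.warnings.append(
            f"closing {node} with no open neighbour: {parcel.volume_nl:.3g} nL trapped"
        )
        return state

    for nbr, share in zip(open_nbrs, parcel.split(len(open_nbrs))):
        state.contents[nbr] = state.parcel_at(nbr).merge(share)
        if nbr in topo.reservoirs:
            inflow = state.reservoir_inflow.setdefault(nbr, {})
            for r, v in share.reagent_volumes().items():
                inflow[r] = inflow.get(r, 0.0) + v
        elif nbr in topo.valves:
            cap = topo.valve_capacity_nl
            if state.parcel_at(nbr).volume_nl > cap * (1 + 1e-12):
                state.warnings.append(
                    f"valve {nbr} over capacity: "
                    f"{state.parcel_at(nbr).volume_nl:.3g} nL > {cap:.3g} nL"
                )
    return state


def _node_is_open(state: ChipState, node: str) -> bool:
    """Reservoir wells and the detection channel are always open ends."""
    if node in state.topology.reservoirs or node == state.topology.detection_node:
        return True
    return state.valve_open.get(node, False)


# ---------------------------------------------------------------------------
# backend adapter


class VirtualChip:
    """Chip state machine wrapped as an interpreter device backend."""

    def __init__(self, topology: ChipTopology | None = None):
        self.topology = topology or default_topology()
        self.topology.validate()
        self.state = ChipState(topology=self.topology)
        self.elapsed_ms = 0

    @property
    def n_valves(self) -> int:
        return self.topology.n_valves

    def set_valve(self, valve_id: int, open: bool) -> None:
        if open:
            open_valve(self.state, valve_id)
        else:
            close_valve(self.state, valve_id)

    def advance_time(self, ms: int) -> None:
        # incubation affects only the clock: mixing is already perfect
        self.elapsed_ms += ms

    def state_ref(self) -> str:
        return f"{self.topology.name}@{self.elapsed_ms}ms"

    def apply_protocol_loads(self, protocol: ProtocolConfig) -> None:
        for reservoir, reagent, volume_ul in protocol.inlet_loads:
            load_inlet(self.state, reservoir, reagent, volume_ul * 1000.0)

    def delivered(self) -> FluidParcel:
        return self.state.parcel_at(self.topology.detection_node)


def run_protocol(
    script: Script,
    topology: ChipTopology | None = None,
    protocol: ProtocolConfig | None = None,
) -> tuple[ChipState, ExecutionTrace, FluidParcel]:
    """Run a staining/mixing script on a freshly loaded virtual chip.

    Validates the script, applies the protocol's inlet loads, executes in
    virtual time, and reports ``(final state, trace, parcel delivered to
    the detection node)``.
    """
    chip = VirtualChip(topology)
    protocol = protocol or default_protocol()
    errors = [d for d in validate_script(script, chip.topology) if d.severity.value == "ERROR"]
    if errors:
        raise FluidicsError(
            "script failed validation:\n" + "\n".join(d.format() for d in errors)
        )
    chip.apply_protocol_loads(protocol)
    trace = run_script(script, chip, Mode.VIRTUAL)
    return chip.state, trace, chip.delivered()


# ---------------------------------------------------------------------------
# bundled defaults and config I/O


def _data_text(name: str) -> str:
    return resources.files("liftgate.data").joinpath(name).read_text(encoding="utf-8")


def default_topology() -> ChipTopology:
    """The bundled 15-valve, 6-reservoir schematic topology."""
    return topology_from_dict(yaml.safe_load(_data_text("default_topology.yaml")))


def default_protocol() -> ProtocolConfig:
    """Reference staining loads: 2 µL bacteria, 2 µL dye, 5 µL buffer."""
    raw = yaml.safe_load(_data_text("default_protocol.yaml"))
    return protocol_from_dict(raw)


def reference_staining_script() -> str:
    """Source of the bundled bacteria-staining script (20 min incubation)."""
    return _data_text("staining.loc")


def wash_script() -> str:
    """Source of the bundled post-experiment wash template."""
    return _data_text("wash.loc")


def topology_from_dict(raw: dict) -> ChipTopology:
    adjacency: dict[str, set[str]] = {}
    for a, b in raw["edges"]:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    topo = ChipTopology(
        n_valves=int(raw["n_valves"]),
        reservoirs={k: str(v).upper() for k, v in raw["reservoirs"].items()},
        adjacency={k: frozenset(v) for k, v in adjacency.items()},
        detection_node=raw["detection_node"],
        valve_capacity_nl=float(raw.get("valve_capacity_nl", 10.0)),
        name=raw.get("name", "chip"),
    )
    topo.validate()
    return topo


def protocol_from_dict(raw: dict) -> ProtocolConfig:
    return ProtocolConfig(
        inlet_loads=tuple(
            (str(l["reservoir"]), str(l["reagent"]), float(l["volume_ul"]))
            for l in raw["inlet_loads"]
        ),
        incubation_ms=int(raw.get("incubation_ms", 20 * 60 * 1000)),
    )


def load_topology(path: str) -> ChipTopology:
    """Read a topology from a YAML or JSON config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return topology_from_dict(yaml.safe_load(fh))


def load_protocol(path: str) -> ProtocolConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return protocol_from_dict(yaml.safe_load(fh))
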