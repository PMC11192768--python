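"""Script execution against a pluggable device backend.

The interpreter turns a validated :class:`~liftgate.script.Script` into a
sequence of valve actuations on a *backend* — anything that honours the
small :class:`DeviceBackend` contract (the virtual chip, a hardware
transport adapter, a test spy). Execution is strictly sequential: one
instruction at a time, ``call`` bodies inlined, no concurrency.

Two clock modes exist. ``VIRTUAL`` advances a virtual clock instantly, so
a 20-minute staining protocol executes in milliseconds of wall time;
``REALTIME`` sleeps through each wait, for driving real hardware.
"""

from __future__ import annotations

import enum
import json
import time
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

from .script import Instruction, InstructionKind, Script

__all__ = [
    "Mode",
    "ActuationEvent",
    "ExecutionTrace",
    "DeviceBackend",
    "ExecutionAborted",
    "expand_calls",
    "run_script",
    "dry_run",
    "DryRunSummary",
]


class Mode(enum.Enum):
    REALTIME = "realtime"
    VIRTUAL = "virtual"


@dataclass(frozen=True)
class ActuationEvent:
    """One valve actuation on the virtual clock."""

    t_ms: int
    action: InstructionKind  # OPEN or CLOSE
    valve_id: int
    origin: str = "main"          # enclosing function ('main' for top level)
    line_no: int | None = None    # source line of the instruction


@dataclass
class ExecutionTrace:
    events: list[ActuationEvent] = field(default_factory=list)
    total_duration_ms: int = 0
    final_state_ref: str | None = None

    def action_sequence(self) -> list[tuple[str, int]]:
        """The ordered (action, valve) pairs — the contract hardware sees."""
        return [(e.action.value, e.valve_id) for e in self.events]

    def to_tsv(self) -> str:
        lines = ["t_ms\taction\tvalve_id\torigin"]
        for e in self.events:
            lines.append(f"{e.t_ms}\t{e.action.value}\t{e.valve_id}\t{e.origin}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_duration_ms": self.total_duration_ms,
                "final_state_ref": self.final_state_ref,
                "events": [
                    {
                        "t_ms": e.t_ms,
                        "action": e.action.value,
                        "valve_id": e.valve_id,
                        "origin": e.origin,
                        "line_no": e.line_no,
                    }
                    for e in self.events
                ],
            },
            indent=2,
        )


@runtime_checkable
class DeviceBackend(Protocol):
    """Contract an execution target must honour.

    ``set_valve`` must be idempotent at the contract level: asking an open
    valve to open (or a closed one to close) is a legal no-op, because the
    underlying solenoids are level-driven, not edge-driven.
    """

    @property
    def n_valves(self) -> int: ...

    def set_valve(self, valve_id: int, open: bool) -> None: ...

    def advance_time(self, ms: int) -> None: ...


class ExecutionAborted(RuntimeError):
    """Backend rejected an actuation; the partial trace is attached."""

    def __init__(self, message: str, trace: ExecutionTrace):
        super().__init__(message)
        self.trace = trace


def expand_calls(script: Script) -> list[Instruction]:
    """Inline every ``call`` with its function body, recursively.

    Returns the flat instruction list with source order preserved.
    Assumes the script passed validation; an unresolved target or a cycle
    here is an internal error.
    """
    out: list[Instruction] = []

    def emit(body, stack: tuple[str, ...]) -> None:
        for instr in body:
            if instr.kind is InstructionKind.CALL:
                name = instr.function_name
                if name in stack:
                    raise RuntimeError(f"internal error: recursive call to {name!r}")
                if name not in script.functions:
                    raise RuntimeError(f"internal error: unresolved call to {name!r}")
                emit(script.functions[name], stack + (name,))
            else:
                out.append(instr)

    emit(script.main, ())
    return out


def _walk(script: Script):
    """Yield (instruction, origin) over the call-expanded program."""

    def gen(body, origin: str, stack: tuple[str, ...]):
        for instr in body:
            if instr.kind is InstructionKind.CALL:
                name = instr.function_name
                if name in stack:
                    raise RuntimeError(f"internal error: recursive call to {name!r}")
                if name not in script.functions:
                    raise RuntimeError(f"internal error: unresolved call to {name!r}")
                yield from gen(script.functions[name], name, stack + (name,))
            else:
                yield instr, origin

    yield from gen(script.main, "main", ())


def run_script(
    script: Script,
    backend: DeviceBackend,
    mode: Mode = Mode.VIRTUAL,
) -> ExecutionTrace:
    """Execute a validated script on a backend; return the actuation log.

    Each OPEN/CLOSE is forwarded to ``backend.set_valve`` and logged with
    its virtual-clock timestamp; each WAIT advances the clock (and in
    ``REALTIME`` mode sleeps). If the backend raises, the run aborts with
    :class:`ExecutionAborted` carrying the partial trace — no rollback.
    """
    trace = ExecutionTrace()
    t_ms = 0
    for instr, origin in _walk(script):
        if instr.kind is InstructionKind.WAIT:
            ms = instr.duration_ms
            try:
                backend.advance_time(ms)
            except Exception as exc:  # pragma: no cover - backends rarely fail here
                trace.total_duration_ms = t_ms
                raise ExecutionAborted(str(exc), trace) from exc
            if mode is Mode.REALTIME:
                time.sleep(ms / 1000.0)
            t_ms += ms
        else:
            try:
                backend.set_valve(instr.valve_id, instr.kind is InstructionKind.OPEN)
            except Exception as exc:
                trace.total_duration_ms = t_ms
                raise ExecutionAborted(
                    f"backend rejected {instr} at t={t_ms} ms: {exc}", trace
                ) from exc
            trace.events.append(
                ActuationEvent(t_ms, instr.kind, instr.valve_id, origin, instr.line_no)
            )
    trace.total_duration_ms = t_ms
    trace.final_state_ref = getattr(backend, "state_ref", lambda: None)()
    return trace


@dataclass
class DryRunSummary:
    """Static execution analysis: what a run *would* do, backend untouched."""

    total_duration_ms: int
    actuation_counts: dict[int, int]          # valve id -> number of o/c actuations
    peak_open_valves: int                     # max simultaneously open valves
    wait_subtotals: dict[str, int]            # origin (function or 'main') -> wait ms
    longest_wait_ms: int
    n_actuations: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_duration_ms": self.total_duration_ms,
                "n_actuations": self.n_actuations,
                "actuation_counts": {str(k): v for k, v in sorted(self.actuation_counts.items())},
                "peak_open_valves": self.peak_open_valves,
                "wait_subtotals": self.wait_subtotals,
                "longest_wait_ms": self.longest_wait_ms,
            },
            indent=2,
        )


def dry_run(script: Script, topology=None) -> DryRunSummary:
    """Analyse a validated script without driving any backend.

    Reports total duration (equal to ``run_script``'s VIRTUAL
    ``total_duration_ms``), per-valve actuation counts, the peak number of
    simultaneously open valves, and wait-time subtotals per enclosing
    function — the subtotal of an incubation function is how long the
    protocol actually incubates.
    """
    total = 0
    counts: dict[int, int] = {}
    waits: dict[str, int] = {}
    longest = 0
    open_set: set[int] = set()
    peak = 0
    n_act = 0
    for instr, origin in _walk(script):
        if instr.kind is InstructionKind.WAIT:
            total += instr.duration_ms
            waits[origin] = waits.get(origin, 0) + instr.duration_ms
            longest = max(longest, instr.duration_ms)
        else:
            n_act += 1
            counts[instr.valve_id] = counts.get(instr.valve_id, 0) + 1
            if instr.kind is InstructionKind.OPEN:
                open_set.add(instr.valve_id)
            else:
                open_set.discard(instr.valve_id)
            peak = max(peak, len(open_set))
    return DryRunSummary(
        total_duration_ms=total,
        actuation_counts=counts,
        peak_open_valves=peak,
        wait_subtotals=waits,
        longest_wait_ms=longest,
        n_actuations=n_act,
    )
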