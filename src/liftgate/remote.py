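"""Message-driven remote control of a chip device.

Mirrors the three operation modes of an internet-connected instrument
front end: (1) manual actuation of an individual valve, (2) selection and
execution of a script saved on the device, (3) upload of a new script for
future use. Commands and status reports travel as topic-addressed
messages over a publish/subscribe bus with MQTT-style semantics
(hierarchical topics, ``+``/``#`` wildcards, per-topic FIFO delivery).

The bundled :class:`MessageBus` is in-process — no broker, no network —
which keeps the whole control loop testable on a desk. An adapter for a
real MQTT broker can implement the same two-method surface (``publish``,
``subscribe``) and drop in unchanged. Authentication is out of scope and
is a deployment concern.

Topic layout (payloads are JSON-serializable dicts)::

    device/<id>/command/valve    {action: "open"|"close", valve_id: int}
    device/<id>/command/run      {name: str}
    device/<id>/command/upload   {name: str, source: str}
    device/<id>/command/list     {}
    device/<id>/status           {msg_id, status, detail, ...}

Every command message yields at least one status message carrying the
command's ``msg_id`` — acknowledged or error-reported, never dropped.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .chip import VirtualChip
from .interpreter import Mode, dry_run, run_script
from .script import ScriptSyntaxError, parse_script, validate_script

__all__ = [
    "Message",
    "MessageBus",
    "ScriptStore",
    "ChipDevice",
    "RemoteClient",
]

_msg_counter = itertools.count(1)


@dataclass(frozen=True)
class Message:
    topic: str
    payload: dict
    msg_id: str = field(default_factory=lambda: f"m{next(_msg_counter)}")
    timestamp: float = field(default_factory=time.time)

    def to_json(self) -> str:
        return json.dumps(
            {"topic": self.topic, "payload": self.payload,
             "msg_id": self.msg_id, "timestamp": self.timestamp}
        )


def topic_matches(pattern: str, topic: str) -> bool:
    """MQTT-style matching: ``+`` one level, ``#`` all remaining levels."""
    p_parts = pattern.split("/")
    t_parts = topic.split("/")
    for i, p in enumerate(p_parts):
        if p == "#":
            return True
        if i >= len(t_parts):
            return False
        if p != "+" and p != t_parts[i]:
            return False
    return len(p_parts) == len(t_parts)


class MessageBus:
    """In-process pub/sub bus; synchronous, per-topic FIFO delivery."""

    def __init__(self) -> None:
        self._subs: list[tuple[str, object]] = []
        self.log: list[Message] = []

    def subscribe(self, pattern: str, callback) -> None:
        self._subs.append((pattern, callback))

    def publish(self, message: Message) -> None:
        self.log.append(message)
        for pattern, callback in list(self._subs):
            if topic_matches(pattern, message.topic):
                callback(message)


class ScriptStore:
    """Named script templates saved on the device.

    Scripts are re-parsed at store time: a template that does not parse is
    refused, so everything in the store is at least syntactically sound.
    Optionally persists each script as ``<name>.loc`` in a directory.
    """

    def __init__(self, directory: str | Path | None = None):
        self._scripts: dict[str, str] = {}
        self._dir = Path(directory) if directory else None
        if self._dir is not None:
            self._dir.mkdir(parents=True, exist_ok=True)
            for path in sorted(self._dir.glob("*.loc")):
                self._scripts[path.stem] = path.read_text(encoding="utf-8")

    def add(self, name: str, source: str) -> None:
        parse_script(source, source_path=name)  # raises ScriptSyntaxError if bad
        self._scripts[name] = source
        if self._dir is not None:
            (self._dir / f"{name}.loc").write_text(source, encoding="utf-8")

    def get(self, name: str) -> str:
        return self._scripts[name]

    def names(self) -> list[str]:
        return sorted(self._scripts)

    def __contains__(self, name: str) -> bool:
        return name in self._scripts


class ChipDevice:
    """The laboratory side: a chip backend listening for commands on a bus."""

    def __init__(
        self,
        bus: MessageBus,
        device_id: str,
        backend: VirtualChip | None = None,
        store: ScriptStore | None = None,
        progress_every: int = 0,
    ):
        self.bus = bus
        self.device_id = device_id
        self.backend = backend or VirtualChip()
        self.store = store or ScriptStore()
        self.progress_every = progress_every
        bus.subscribe(f"device/{device_id}/command/#", self._on_command)

    # -- helpers -----------------------------------------------------------

    def _status(self, msg_id: str, status: str, **detail) -> None:
        self.bus.publish(
            Message(f"device/{self.device_id}/status",
                    {"msg_id": msg_id, "status": status, **detail})
        )

    # -- command dispatch --------------------------------------------------

    def _on_command(self, msg: Message) -> None:
        kind = msg.topic.rsplit("/", 1)[-1]
        handler = {
            "valve": self._cmd_valve,
            "run": self._cmd_run,
            "upload": self._cmd_upload,
            "list": self._cmd_list,
        }.get(kind)
        if handler is None:
            self._status(msg.msg_id, "rejected", detail=f"unknown command {kind!r}")
            return
        try:
            handler(msg)
        except Exception as exc:  # every command is acknowledged, even on bugs
            self._status(msg.msg_id, "error", detail=str(exc))

    def _cmd_valve(self, msg: Message) -> None:
        action = msg.payload.get("action")
        valve_id = msg.payload.get("valve_id")
        if action not in ("open", "close") or not isinstance(valve_id, int):
            self._status(msg.msg_id, "rejected", detail="need action open|close and integer valve_id")
            return
        if not (1 <= valve_id <= self.backend.n_valves):
            self._status(
                msg.msg_id, "rejected",
                detail=f"valve {valve_id} outside range 1..{self.backend.n_valves}",
            )
            return
        already = self.backend.state.valve_open.get(f"v{valve_id}", False) == (action == "open")
        self.backend.set_valve(valve_id, action == "open")
        self._status(
            msg.msg_id, "ok",
            valve_id=valve_id, valve_state=action, no_op=already,
            detail=f"valve {valve_id} {action}{' (no-op)' if already else ''}",
        )

    def _cmd_run(self, msg: Message) -> None:
        name = msg.payload.get("name")
        if name not in self.store:
            self._status(msg.msg_id, "error", detail=f"no saved script named {name!r}")
            return
        self._execute(msg.msg_id, self.store.get(name), name=name)

    def _cmd_upload(self, msg: Message) -> None:
        name, source = msg.payload.get("name"), msg.payload.get("source")
        if not name or source is None:
            self._status(msg.msg_id, "rejected", detail="need name and source")
            return
        try:
            script = parse_script(source, source_path=name)
        except ScriptSyntaxError as exc:
            self._status(
                msg.msg_id, "rejected",
                diagnostics=[d.format(name) for d in exc.diagnostics],
                detail="script failed to parse",
            )
            return
        errors = [d for d in validate_script(script, self.backend.topology)
                  if d.severity.value == "ERROR"]
        if errors:
            self._status(
                msg.msg_id, "rejected",
                diagnostics=[d.format(name) for d in errors],
                detail="script failed validation",
            )
            return
        self.store.add(name, source)
        self._status(msg.msg_id, "ok", name=name, detail=f"script {name!r} stored")

    def _cmd_list(self, msg: Message) -> None:
        self._status(msg.msg_id, "ok", scripts=self.store.names())

    def _execute(self, msg_id: str, source: str, name: str) -> None:
        script = parse_script(source, source_path=name)
        errors = [d for d in validate_script(script, self.backend.topology)
                  if d.severity.value == "ERROR"]
        if errors:
            self._status(msg_id, "error",
                         diagnostics=[d.format(name) for d in errors],
                         detail="script failed validation")
            return
        if self.progress_every > 0:
            backend = _ProgressBackend(self, msg_id, self.backend, self.progress_every)
        else:
            backend = self.backend
        try:
            trace = run_script(script, backend, Mode.VIRTUAL)
        except Exception as exc:
            partial = getattr(exc, "trace", None)
            self._status(
                msg_id, "failed", detail=str(exc),
                partial_actuations=len(partial.events) if partial else None,
            )
            return
        self._status(
            msg_id, "completed",
            name=name,
            n_actuations=len(trace.events),
            total_duration_ms=trace.total_duration_ms,
            final_state_ref=trace.final_state_ref,
        )


class _ProgressBackend:
    """Wraps the real backend to stream batched progress reports."""

    def __init__(self, device: ChipDevice, msg_id: str, inner, every: int):
        self._device, self._msg_id, self._inner, self._every = device, msg_id, inner, every
        self._count = 0

    @property
    def n_valves(self) -> int:
        return self._inner.n_valves

    def set_valve(self, valve_id: int, open: bool) -> None:
        self._inner.set_valve(valve_id, open)
        self._count += 1
        if self._count % self._every == 0:
            self._device._status(self._msg_id, "progress", actuations_done=self._count)

    def advance_time(self, ms: int) -> None:
        self._inner.advance_time(ms)

    def state_ref(self):
        ref = getattr(self._inner, "state_ref", None)
        return ref() if ref else None


class RemoteClient:
    """The remote side: publishes commands, collects matching statuses."""

    def __init__(self, bus: MessageBus, device_id: str, timeout_statuses: bool = True):
        self.bus = bus
        self.device_id = device_id
        self._inbox: list[Message] = []
        bus.subscribe(f"device/{device_id}/status", self._inbox.append)

    def _command(self, kind: str, payload: dict) -> list[Message]:
        msg = Message(f"device/{self.device_id}/command/{kind}", payload)
        before = len(self._inbox)
        self.bus.publish(msg)
        replies = [m for m in self._inbox[before:] if m.payload.get("msg_id") == msg.msg_id]
        if not replies:
            # nobody answered: no such device on this bus
            timeout = Message(
                f"device/{self.device_id}/status",
                {"msg_id": msg.msg_id, "status": "timeout",
                 "detail": f"no response from device {self.device_id!r}"},
            )
            self._inbox.append(timeout)
            replies = [timeout]
        return replies

    def manual_valve_command(self, action: str, valve_id: int) -> Message:
        """Mode 1: actuate one valve by hand; returns the status reply."""
        return self._command("valve", {"action": action, "valve_id": valve_id})[-1]

    def run_saved_script(self, name: str) -> list[Message]:
        """Mode 2: run a script stored on the device; returns all statuses
        (progress stream, if any, ending in a completion/error report)."""
        return self._command("run", {"name": name})

    def upload_script(self, name: str, source: str) -> Message:
        """Mode 3: store a new script on the device for future use."""
        return self._command("upload", {"name": name, "source": source})[-1]

    def list_scripts(self) -> list[str]:
        reply = self._command("list", {})[-1]
        return reply.payload.get("scripts", [])
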