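"""Valve-control scripting language: parse, validate, serialize.

The language drives pneumatically actuated lifting-gate valves on a
lab-on-a-chip device. It is deliberately minimal so that users with no
programming background can read and write protocols:

* three single-character commands — ``o <valve>`` opens a valve,
  ``c <valve>`` closes it, ``w <ms>`` waits for a period in milliseconds;
* ``call <name>`` invokes a user-defined function;
* a script is a ``main:`` block followed by zero or more
  ``def <name>:`` blocks, each terminated by ``end``;
* ``#`` starts a comment; blank lines are ignored.

Valve numbering is 1-based (valves ``1..N``), matching how laboratories
label pneumatic lines. There are no variables, loops or conditionals, and
``call`` may not recurse — a script always expands to a finite,
straight-line actuation sequence.

Grammar (EBNF)::

    script    = { blank | comment } main_block { func_block } ;
    main_block= "main" ":" NEWLINE { line } "end" NEWLINE ;
    func_block= "def" name ":" NEWLINE { line } "end" NEWLINE ;
    line      = ( instr | blank | comment ) NEWLINE ;
    instr     = "o" int | "c" int | "w" int | "call" name ;
    name      = letter { letter | digit | "_" } ;
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "InstructionKind",
    "Instruction",
    "Script",
    "Severity",
    "Diagnostic",
    "ScriptSyntaxError",
    "parse_script",
    "validate_script",
    "serialize_script",
]


class InstructionKind(enum.Enum):
    OPEN = "o"
    CLOSE = "c"
    WAIT = "w"
    CALL = "call"


class Severity(enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


#: Closed set of diagnostic codes emitted by the parser and validator.
DIAGNOSTIC_CODES = {
    # parse-time
    "E_UNKNOWN_COMMAND": "line does not start with a known command",
    "E_BAD_PARAM": "command parameter missing, extra, or of the wrong type",
    "E_BLOCK": "malformed block structure (main/def/end)",
    "E_DUP_FUNC": "function defined more than once",
    "E_NO_MAIN": "script has no main block",
    # validation-time
    "E_VALVE_RANGE": "valve id outside the topology's valve range",
    "E_UNDEF_FUNC": "call target is not defined",
    "E_RECURSION": "call graph contains a cycle",
    "E_EMPTY_MAIN": "main block contains no instructions",
    "W_UNUSED_FUNC": "function is defined but never called",
}


@dataclass(frozen=True)
class Instruction:
    """One line of a script: exactly one parameter field is set, per kind."""

    kind: InstructionKind
    valve_id: int | None = None       # OPEN / CLOSE
    duration_ms: int | None = None    # WAIT
    function_name: str | None = None  # CALL
    line_no: int | None = None        # 1-based source line, if parsed

    def __post_init__(self) -> None:
        expected = {
            InstructionKind.OPEN: self.valve_id,
            InstructionKind.CLOSE: self.valve_id,
            InstructionKind.WAIT: self.duration_ms,
            InstructionKind.CALL: self.function_name,
        }[self.kind]
        if expected is None:
            raise ValueError(f"{self.kind.name} instruction missing its parameter")
        populated = sum(
            x is not None for x in (self.valve_id, self.duration_ms, self.function_name)
        )
        if populated != 1:
            raise ValueError("exactly one parameter field must be populated")
        if self.duration_ms is not None and self.duration_ms < 0:
            raise ValueError("wait duration must be non-negative")

    def __str__(self) -> str:
        if self.kind in (InstructionKind.OPEN, InstructionKind.CLOSE):
            return f"{self.kind.value} {self.valve_id}"
        if self.kind is InstructionKind.WAIT:
            return f"w {self.duration_ms}"
        return f"call {self.function_name}"


def open_(valve_id: int, line_no: int | None = None) -> Instruction:
    return Instruction(InstructionKind.OPEN, valve_id=valve_id, line_no=line_no)


def close(valve_id: int, line_no: int | None = None) -> Instruction:
    return Instruction(InstructionKind.CLOSE, valve_id=valve_id, line_no=line_no)


def wait(duration_ms: int, line_no: int | None = None) -> Instruction:
    return Instruction(InstructionKind.WAIT, duration_ms=duration_ms, line_no=line_no)


def call(function_name: str, line_no: int | None = None) -> Instruction:
    return Instruction(InstructionKind.CALL, function_name=function_name, line_no=line_no)


@dataclass(frozen=True)
class Script:
    """A parsed program: a main instruction list plus named function bodies."""

    main: tuple[Instruction, ...]
    functions: dict[str, tuple[Instruction, ...]] = field(default_factory=dict)
    source_path: str | None = None

    def __eq__(self, other: object) -> bool:
        # structural equality ignores source line numbers and provenance
        if not isinstance(other, Script):
            return NotImplemented
        return _strip(self.main) == _strip(other.main) and {
            k: _strip(v) for k, v in self.functions.items()
        } == {k: _strip(v) for k, v in other.functions.items()}


def _strip(body: tuple[Instruction, ...]) -> tuple[Instruction, ...]:
    return tuple(replace(i, line_no=None) for i in body)


@dataclass(frozen=True)
class Diagnostic:
    severity: Severity
    line_no: int
    code: str
    message: str

    def __post_init__(self) -> None:
        if self.code not in DIAGNOSTIC_CODES:
            raise ValueError(f"unknown diagnostic code {self.code!r}")

    def format(self, path: str = "<script>") -> str:
        return f"{path}:{self.line_no}: {self.severity.value} {self.code} {self.message}"


class ScriptSyntaxError(ValueError):
    """Parse failure; carries the diagnostics that explain it."""

    def __init__(self, diagnostics: list[Diagnostic], source_path: str | None = None):
        self.diagnostics = diagnostics
        self.source_path = source_path
        path = source_path or "<script>"
        super().__init__("\n".join(d.format(path) for d in diagnostics))


_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")
_INT_RE = re.compile(r"[+-]?\d+\Z")


def _parse_int(token: str) -> int | None:
    return int(token) if _INT_RE.match(token) else None


def parse_script(source: str, source_path: str | None = None) -> Script:
    """Parse script text into a :class:`Script`.

    Every source line is classified as an instruction, a block delimiter,
    a comment, or blank; anything else raises :class:`ScriptSyntaxError`
    with line-numbered diagnostics. Instruction order is preserved and
    ``call`` targets are recorded verbatim (resolution happens in
    :func:`validate_script`).
    """
    diagnostics: list[Diagnostic] = []
    main: list[Instruction] | None = None
    functions: dict[str, list[Instruction]] = {}
    current: list[Instruction] | None = None  # body being filled
    in_block = False
    seen_main = False

    def err(line_no: int, code: str, message: str) -> None:
        diagnostics.append(Diagnostic(Severity.ERROR, line_no, code, message))

    for line_no, raw in enumerate(source.splitlines(), start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue  # blank or comment-only
        tokens = text.split()
        head = tokens[0]

        if head in ("main", "main:"):
            # allow "main:" and "main :" headers, nothing else on the line
            ok = (head == "main:" and not tokens[1:]) or (head == "main" and tokens[1:] == [":"])
            if not ok:
                err(line_no, "E_BLOCK", "expected 'main:'")
                continue
            if seen_main:
                err(line_no, "E_BLOCK", "duplicate main block")
                continue
            if in_block:
                err(line_no, "E_BLOCK", "block opened inside another block")
                continue
            seen_main = True
            in_block = True
            main = []
            current = main
            continue

        if head == "def":
            rest = tokens[1:]
            name = None
            if len(rest) == 1 and rest[0].endswith(":"):
                name = rest[0][:-1]
            elif len(rest) == 2 and rest[1] == ":":
                name = rest[0]
            if name is None or not _NAME_RE.match(name):
                err(line_no, "E_BLOCK", "expected 'def <name>:'")
                continue
            if in_block:
                err(line_no, "E_BLOCK", "block opened inside another block")
                continue
            if not seen_main:
                err(line_no, "E_BLOCK", "function defined before the main block")
            if name in functions:
                err(line_no, "E_DUP_FUNC", f"function {name!r} defined more than once")
                current = []  # parse but discard the duplicate body
                in_block = True
                continue
            functions[name] = []
            current = functions[name]
            in_block = True
            continue

        if head == "end":
            if tokens[1:]:
                err(line_no, "E_BAD_PARAM", "'end' takes no parameter")
                continue
            if not in_block:
                err(line_no, "E_BLOCK", "'end' outside any block")
                continue
            in_block = False
            current = None
            continue

        # instruction lines
        if head in ("o", "c"):
            if len(tokens) != 2 or (vid := _parse_int(tokens[1])) is None:
                err(line_no, "E_BAD_PARAM", f"'{head}' needs one integer valve number")
                continue
            kind = InstructionKind.OPEN if head == "o" else InstructionKind.CLOSE
            instr = Instruction(kind, valve_id=vid, line_no=line_no)
        elif head == "w":
            if len(tokens) != 2 or (ms := _parse_int(tokens[1])) is None or ms < 0:
                err(line_no, "E_BAD_PARAM", "'w' needs one non-negative integer (milliseconds)")
                continue
            instr = Instruction(InstructionKind.WAIT, duration_ms=ms, line_no=line_no)
        elif head == "call":
            if len(tokens) != 2 or not _NAME_RE.match(tokens[1]):
                err(line_no, "E_BAD_PARAM", "'call' needs one function name")
                continue
            instr = Instruction(InstructionKind.CALL, function_name=tokens[1], line_no=line_no)
        else:
            err(line_no, "E_UNKNOWN_COMMAND", f"unknown command {head!r}")
            continue

        if current is None:
            err(line_no, "E_BLOCK", "instruction outside any block")
            continue
        current.append(instr)

    last_line = max(1, source.count("\n") + 1)
    if in_block:
        err(last_line, "E_BLOCK", "unterminated block (missing 'end')")
    if not seen_main:
        err(last_line, "E_NO_MAIN", "script has no main block")

    if diagnostics:
        raise ScriptSyntaxError(diagnostics, source_path)

    return Script(
        main=tuple(main or ()),
        functions={k: tuple(v) for k, v in functions.items()},
        source_path=source_path,
    )


def validate_script(script: Script, topology=None, *, n_valves: int | None = None) -> list[Diagnostic]:
    """Static checks against a chip topology; diagnostics are the result.

    An empty return value means the script is runnable: valve ids lie in
    ``[1, n_valves]``, every ``call`` resolves, and the call graph is
    acyclic. Defined-but-never-called functions are flagged as warnings.

    ``topology`` may be any object with an ``n_valves`` attribute (e.g. a
    :class:`~liftgate.chip.ChipTopology`); alternatively pass ``n_valves``.
    """
    if topology is not None:
        n_valves = topology.n_valves
    diags: list[Diagnostic] = []

    def walk(body: tuple[Instruction, ...], origin: str) -> None:
        for instr in body:
            ln = instr.line_no or 0
            if instr.kind in (InstructionKind.OPEN, InstructionKind.CLOSE):
                if n_valves is not None and not (1 <= instr.valve_id <= n_valves):
                    diags.append(
                        Diagnostic(
                            Severity.ERROR, ln, "E_VALVE_RANGE",
                            f"valve {instr.valve_id} outside range 1..{n_valves} (in {origin})",
                        )
                    )
            elif instr.kind is InstructionKind.CALL:
                if instr.function_name not in script.functions:
                    diags.append(
                        Diagnostic(
                            Severity.ERROR, ln, "E_UNDEF_FUNC",
                            f"call to undefined function {instr.function_name!r} (in {origin})",
                        )
                    )

    walk(script.main, "main")
    for name, body in script.functions.items():
        walk(body, name)

    if not script.main:
        diags.append(Diagnostic(Severity.ERROR, 0, "E_EMPTY_MAIN", "main block is empty"))

    # cycle detection over the call graph (iterative DFS, three colors)
    edges = {
        name: [i.function_name for i in body if i.kind is InstructionKind.CALL]
        for name, body in script.functions.items()
    }
    color: dict[str, int] = {}  # 0 absent, 1 in progress, 2 done

    def dfs(node: str, stack: list[str]) -> None:
        color[node] = 1
        for nxt in edges.get(node, ()):
            if nxt not in edges:
                continue  # undefined: already reported
            if color.get(nxt, 0) == 1:
                cycle = " -> ".join(stack + [node, nxt])
                diags.append(
                    Diagnostic(Severity.ERROR, 0, "E_RECURSION",
                               f"recursive call chain: {cycle}")
                )
            elif color.get(nxt, 0) == 0:
                dfs(nxt, stack + [node])
        color[node] = 2

    for name in edges:
        if color.get(name, 0) == 0:
            dfs(name, [])

    # unused-function warnings (reachability from main)
    reachable: set[str] = set()
    frontier = [i.function_name for i in script.main if i.kind is InstructionKind.CALL]
    while frontier:
        f = frontier.pop()
        if f in reachable or f not in script.functions:
            continue
        reachable.add(f)
        frontier.extend(edges.get(f, ()))
    for name in script.functions:
        if name not in reachable:
            diags.append(
                Diagnostic(Severity.WARNING, 0, "W_UNUSED_FUNC",
                           f"function {name!r} is never called")
            )

    return diags


def serialize_script(script: Script, indent: str = "    ") -> str:
    """Render a :class:`Script` back to source text.

    Round-trip contract: ``parse_script(serialize_script(s)) == s``
    structurally (comments and whitespace are not preserved).
    """
    lines = ["main:"]
    lines += [indent + str(i) for i in script.main]
    lines.append("end")
    for name, body in script.functions.items():
        lines.append("")
        lines.append(f"def {name}:")
        lines += [indent + str(i) for i in body]
        lines.append("end")
    return "\n".join(lines) + "\n"
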