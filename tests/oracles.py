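"""Independent reference implementations used as test oracles.

These deliberately avoid the package's execution machinery: the naive
executor interprets a script lazily with a plain recursive loop (no call
expansion pass, no backend, no trace objects), so agreement with
``run_script``/``expand_calls`` is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

from liftgate.script import Instruction, InstructionKind, Script


def naive_execute(script: Script) -> tuple[list[tuple[str, int]], int]:
    """Reference executor: ordered (action, valve) pairs + total wait ms."""
    seq: list[tuple[str, int]] = []
    total = 0

    def run(body) -> None:
        nonlocal total
        for ins in body:
            if ins.kind is InstructionKind.OPEN:
                seq.append(("o", ins.valve_id))
            elif ins.kind is InstructionKind.CLOSE:
                seq.append(("c", ins.valve_id))
            elif ins.kind is InstructionKind.WAIT:
                total += ins.duration_ms
            else:
                run(script.functions[ins.function_name])

    run(script.main)
    return seq, total


def naive_tally(script: Script) -> dict[int, int]:
    """Brute-force per-valve actuation counts."""
    seq, _ = naive_execute(script)
    counts: dict[int, int] = {}
    for _, vid in seq:
        counts[vid] = counts.get(vid, 0) + 1
    return counts


def random_script(rng: np.random.Generator, n_valves: int = 15,
                  max_functions: int = 4, max_body: int = 8) -> Script:
    """Draw a random valid script: acyclic calls, in-range valves.

    Function ``f_i`` may only call ``f_j`` with ``j > i``, which makes the
    call graph a DAG by construction.
    """
    n_funcs = int(rng.integers(0, max_functions + 1))
    names = [f"f{i}" for i in range(n_funcs)]

    def body(caller_idx: int | None) -> tuple[Instruction, ...]:
        out = []
        lo = 0 if caller_idx is None else caller_idx + 1
        callable_names = names[lo:]
        for _ in range(int(rng.integers(1, max_body + 1))):
            kinds = ["o", "c", "w"] + (["call"] if callable_names else [])
            k = kinds[int(rng.integers(len(kinds)))]
            if k == "o":
                out.append(Instruction(InstructionKind.OPEN,
                                       valve_id=int(rng.integers(1, n_valves + 1))))
            elif k == "c":
                out.append(Instruction(InstructionKind.CLOSE,
                                       valve_id=int(rng.integers(1, n_valves + 1))))
            elif k == "w":
                out.append(Instruction(InstructionKind.WAIT,
                                       duration_ms=int(rng.integers(0, 2000))))
            else:
                target = callable_names[int(rng.integers(len(callable_names)))]
                out.append(Instruction(InstructionKind.CALL, function_name=target))
        return tuple(out)

    functions = {name: body(i) for i, name in enumerate(names)}
    return Script(main=body(None), functions=functions)
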