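"""Parse the bundled staining script and analyse it without any device.

The dry run expands all function calls and reports what a real run would
do: how long it takes, which valves actuate how often, and how much wait
time each function schedules — the `incubate` subtotal is the staining
incubation itself.
"""

import liftgate as lg
from liftgate.interpreter import dry_run

script = lg.parse_script(lg.reference_staining_script())
print(f"main has {len(script.main)} instructions; "
      f"functions: {', '.join(script.functions)}")

diags = lg.validate_script(script, lg.default_topology())
print(f"validation diagnostics: {len(diags)} (empty means runnable)")

summary = dry_run(script)
print(f"total scheduled time : {summary.total_duration_ms / 60000:.1f} min")
print(f"valve actuations     : {summary.n_actuations}")
print(f"peak open valves     : {summary.peak_open_valves}")
for origin, ms in summary.wait_subtotals.items():
    print(f"  wait in {origin:10s}: {ms} ms")
# The 1200000 ms under `incubate` is the 20-minute dye incubation.
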