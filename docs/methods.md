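# Methods

This note records the models behind each layer of `liftgate`, the
parameters that matter, and where the design was genuinely open.

## The scripting language

The language is intentionally tiny: `o`/`c`/`w` with one integer
parameter each, `call` with a function name, a `main:` block and
function blocks after it. Instrument languages of this class fix the
command set but rarely a concrete line and block syntax, so the grammar
here is this package's own concretization,
chosen to make the "functions are defined after main" rule statically
checkable: explicit `main:`/`def name:` headers, an `end` terminator,
`#` comments, whitespace-separated tokens, case-sensitive lowercase
commands. An EBNF sketch lives in the `liftgate.script` module
docstring.

Safety posture: unknown commands are hard parse errors (this text drives
a physical device); `w` takes only non-negative integer milliseconds;
recursion through `call` is prohibited and detected statically by
depth-first search over the call graph, so every valid script denotes a
finite actuation sequence. Validation returns diagnostics from a closed
code set (`E_VALVE_RANGE`, `E_UNDEF_FUNC`, `E_RECURSION`, …;
defined-but-unused functions are warnings, not errors).

## Interpreter

Execution is single-threaded and strictly sequential, with `call`
bodies inlined. Whether calls are expanded ahead of time or interpreted
lazily is unobservable from outside; the tested contract is the ordered
(action, valve) sequence, which is cross-checked against an independent
naive recursive executor on 1000 randomly generated scripts per run.

Two clock modes: `VIRTUAL` advances a virtual clock instantly (a
20-minute incubation costs no wall time — this is what makes the whole
stack testable at desk scale), `REALTIME` sleeps. Re-opening an open
valve or re-closing a closed one is forwarded and logged but is not an
error: solenoid drives are level-triggered and tolerate it. On a backend
rejection the partial trace is preserved and attached to the exception;
there is no rollback, matching how a physical run fails.

`dry_run` walks the same expansion without any backend and reports total
duration, per-valve actuation counts, peak simultaneously-open valves,
and per-function wait subtotals. The subtotal of the staining script's
`incubate` function is the scheduled incubation time (1 200 000 ms).

## Virtual chip

The fluid model is a discrete parcel/ledger state machine, not
hydrodynamics. Nodes are valves, reservoir wells and one passive
detection channel; state is per-valve open/closed plus one fluid parcel
(volume in nL, reagent fractions summing to 1) per node.

Rules, in order of application:

* **Open** (membrane lifted): the valve becomes an exchange volume. If
  an adjacent inlet well holds fluid, the valve draws from it up to its
  free capacity; the well keeps the remainder. On the bench, reagents
  pipetted onto an inlet well preload into the first valve when it
  lifts, but how much enters is set by geometry we do not model; capping
  the draw at the valve capacity is this package's choice and keeps
  volumes physical. A
  reopened valve also reclaims any parcel trapped at that node.
* **Close** (membrane pressed down): the valve's parcel is expelled and
  split **equally by volume** among adjacent open nodes — open valves,
  wells, and the detection channel, all of which count as open ends.
  Equal splitting is the symmetric choice; the real partition depends on
  channel impedances, which are out of scope. With zero open neighbours
  the parcel is recorded as *trapped* with a warning rather than
  destroyed: conservative, and conservation-preserving (a real device
  would back-pressure).
* **Merge**: parcels combine volume-additively with volume-weighted
  composition averaging — mixing is instantaneous and perfect.
  Incubation time advances only the clock; diffusion kinetics are not
  modeled.

Valve capacity defaults to 10 nL; exceeding it (e.g. pooling three 5 nL
half-parcels into one mixing valve, as the reference script does) emits
a warning, never an error — real valve capacity varies with fabrication,
and the reference protocol legitimately runs with these warnings.

The default topology (YAML, `liftgate/data/default_topology.yaml`) is a
schematic stand-in, *not* a reconstruction of any specific physical
chip's adjacency: three inlet valves under inlet
wells, three central mixing valves, a seven-valve transport chain, a
waste valve feeding two outlet wells, and a detection-feed valve ahead
of the passive detection channel and its outlet. Any other architecture
drops in as a config file; the topology validator enforces symmetry,
connectivity and inlet→detector reachability.

Invariants tested: per-reagent conservation (< 1e-9 relative, measured
at ~1e-16 in practice), composition normalisation after every
operation, exact V/k equal splits, and idempotence of open-on-open and
close-on-closed.

## Synthetic fluorescence video and detection

The generator emulates stained bacteria crossing the excitation volume
of a waveguide-illuminated channel as seen by a high-frame-rate camera:
each particle is a 2-D Gaussian spot (PSF σ = 1.5 px) whose brightness
follows a Gaussian temporal envelope (dwell σ = 1 ms, i.e. FWHM ≈
2.4 ms, matched to the 5 ms confirmation window) while its centre sweeps
the ROI at constant velocity; a constant background (10 counts/px) and
Poisson camera noise are added. Amplitudes may be log-normal to mimic
staining variability. All randomness sits behind one integer seed; the
same spec yields a bitwise-identical stack. What it does **not**
emulate: motion blur within a frame, defocus, bleaching, spectral
response of the dye, autofluorescent debris, or particle coincidence in
the detection volume — so passing benchmarks bound performance on clean
single-particle traffic, not on real water samples.

Defaults, and why: frame rate 2000 Hz (unstated for the real camera;
chosen so the 5 ms window spans exactly 10 frames), ROI 32×32 px, event
window 5 ms, threshold `k = 5` robust SDs (median/MAD thresholding is
used because the baseline and noise scale must be insensitive to the
bursts themselves), minimum peak
separation 2 ms. Windows are centered on the peak frame and truncate —
flagged — at trace edges rather than pad.

The benchmark condition is 100 particles in a 4 s acquisition on a
jittered even grid (spacing 40 ± 10 ms), peak amplitude ≈ 26× the
trace's robust noise scale. Sparsity matters: the median/MAD estimates
assume bursts occupy a minority of frames, and at ≳50 % occupancy the
noise scale inflates and recall collapses — a documented limitation of
robust-baseline detection, not of the generator.

## Remote control

The bus is an in-process publish/subscribe object with MQTT topic
semantics (`+`/`#` wildcards, per-topic FIFO); payloads are
JSON-serializable dicts under a small documented schema. No broker or
network is involved; a real-MQTT adapter only needs the same
`publish`/`subscribe` surface. The acknowledged-delivery contract —
every command's `msg_id` answered by at least one status — is enforced
by a catch-all error path in the device dispatcher. Saved scripts are
re-parsed at store time so the store never holds syntactically broken
templates. Authentication and user management are deployment concerns,
out of scope.

## Problem sizes and numerics

The acceptance workload uses 1000 random scripts (≤ 4 functions, bodies
≤ 8 instructions), 1000 random actuation storms of 10–60 operations,
and one 8000-frame 32×32 synthetic acquisition; together they complete
in a few seconds. Volumes are double-precision nL; conservation is
checked relative to total loaded volume; equal splits use one floating
division so `V/k` shares are exactly equal to each other. Ties in peak
calling fall to `scipy.signal.find_peaks` semantics (larger peaks
suppress smaller ones within the separation distance).
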