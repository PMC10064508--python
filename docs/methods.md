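# Methods

## Model and conventions

Every rendered curve is the four-parameter Hill equation

    y(x) = s0 + (s_inf − s0) / (1 + 10^( h · (logAC50 − x) ))

evaluated at log10-molar concentration `x`.  Curve-fitting packages differ
in the sign convention of the slope; this package fixes the form above, so
with `h > 0` the curve runs from `s0` at low concentration to `s_inf` at
high concentration, which makes the parameter names match the zero- and
infinite-concentration asymptotes.  Useful consequences used as test
oracles: the response at `x = logAC50` is exactly `(s0 + s_inf)/2`; the
curve is point-symmetric about that midpoint; and it is monotone between
the asymptotes with direction `sign(h)·sign(s_inf − s0)`.

The exponent `h·(logAC50 − x)` is clamped to ±300 before exponentiation so
that absurd (but finite) concentrations return the appropriate asymptote
instead of overflowing; 10^±300 is still representable in float64.

Responses are treated as already-normalized percent activity.  No
normalization, imputation or fitting happens in the plotting pipeline:
input files carry fitted parameters, and missing response cells are simply
skipped pointwise.  Curve lines are drawn over the tested concentration
range only — extrapolating a sigmoid beyond the titration would invent
plateaus the assay never observed.

## Curve-class surrogate

Published qHTS curve-classification systems use multi-level criteria
(fit quality, asymptote coverage, efficacy tiers) that are out of scope
here.  The package instead assigns one of four documented labels, in this
rule order:

1. `inactive` — no complete parameter set, or |efficacy| < `min_efficacy`;
2. `complete` — the log AC50 lies at least `plateau_margin` log units
   inside *both* grid extremes, so both plateaus are covered by the
   titration;
3. `partial` — the AC50 is inside the tested range but a plateau is not
   bracketed;
4. `low_efficacy` — |efficacy| ≤ `low_efficacy_cap` with the midpoint
   outside the tested range.

A strong response (|efficacy| > cap) whose AC50 falls outside the grid
matches none of the rules above; it is labeled `partial`, reading it as an
incomplete but real response.  Defaults: `min_efficacy = 25 %`,
`low_efficacy_cap = 50 %`, `plateau_margin = 1` log unit.  These are
exposed knobs (CLI: `--min-efficacy`, `--low-efficacy-cap`,
`--plateau-margin`), chosen as round numbers a screening triage would
recognize, not a claim of fidelity to any center's scheme.

## Ordering

The plot preserves input row order by construction; every sort is a stable
sort so ties (and the empty spec) fall back to file order.  Multi-key specs
are applied as successive stable sorts from the least-significant key.
`ac50` sorts on `log_ac50_m` directly (monotone in AC50); records without
parameters sort last under both directions, implemented by negating numeric
keys for descending order rather than reversing the comparison.

## Scene construction

Axis convention: x = compound slot, y = log10 molar concentration,
z = % response.  Each visible record contributes at most one markers trace
and, if `Fit_Output = 1` with complete parameters, one line trace sampled
at `points_per_curve` (default 64) evenly spaced concentrations.  By
default records sharing a `Comp_ID` collapse onto one x slot so
coincidence-reporter readouts (e.g. FLuc/NLuc) overlay; `--slot-per-record`
gives one slot per row instead.  Slots are consecutive integers in layout
order over the *plotted* records.

Color resolution, highest priority first: user override for the record's
group label, user override for its readout, palette color of the group,
palette color of the readout.  The built-in palette uses the conventional
red/yellow/green/gray for curve classes and blue/red for gain/loss.

Datasets larger than `decimation_threshold` records (default 20,000) have
the titration points of point-only (inactive) records thinned to every
k-th point, k = ceil(n_records / threshold), to keep interactive files
tractable at full-library scale; fitted records are never decimated, and
line sampling is unaffected.

## Rendering backends

HTML output is a single self-contained document: the scene serialized as
JSON inside a `<script type="application/json">` element plus a small
vanilla-JavaScript orthographic canvas renderer (drag = rotate, wheel =
zoom, shift-drag = pan).  No external resources are referenced, so files
archive and email cleanly.  PNG output draws the same traces on a
matplotlib 3D axes at 1600×1200 px.  The scene itself is
backend-agnostic and JSON-serializable, which is how structural tests
check plots without a graphics stack.

## Synthetic data generator

The generator emulates a screening export end-to-end: an 11-point
titration over log10 M −9..−4 (5 log units, the typical qHTS span), a
Bernoulli(active_fraction) active/inactive split, gain/loss polarity
Bernoulli(gain_fraction) among actives, and one record per (compound,
readout) with coincidence readouts sharing the compound's true curve but
carrying independent noise.  Active draws: logAC50 ~ U(range shrunk 0.5
log from each end), Hill slope ~ U(0.5, 3), s0 ~ U(−5, 5) (responses are
normalized, so the baseline sits near 0 %), |efficacy| ~ U(50, 100) signed
by polarity.  Responses are the noiseless curve plus additive Gaussian
noise (default sd 5 % activity, a realistic well-level CV for a behaved
reporter assay); inactives are pure noise about 0 %.  One `numpy`
`default_rng(seed)` drives every draw, so a spec is fully reproducible
down to written file bytes.

What the generator does **not** emulate: plate positional artifacts and
edge effects, compound-concentration pipetting error, heteroscedastic or
correlated noise, structure–activity correlation, bell-shaped or biphasic
responses, and fit-quality failures.  Passing tests therefore demonstrate
the pipeline's bookkeeping, numerics and format fidelity — not robustness
to pathological real-world plates.

`fit_hill` is a verification oracle only (the tool never fits user data):
a bounded trust-region least-squares refit (scipy `curve_fit`, slope
bounded to [0.05, 10], asymptotes to ±250 %, AC50 to the grid ±3 logs)
with tight tolerances.  On noiseless draws it recovers the generating
parameters to ~1e−15 relative; at 5 % noise over 11 points the median
|logAC50| recovery error across 200 actives is ≈ 0.05–0.06 log units
(recomputed by `scripts/acceptance.py`), comfortably identifiable.
Non-convergence returns a flagged result so calibration loops can skip
the draw.

## Problem sizes and numerical choices

The test suite and acceptance script use seeded campaigns of 20–1,000
compounds for functional checks, 200 compounds × 2 readouts for the
round-trip check, 1,000 random parameter draws for the Hill identities,
200 actives for noisy recovery, and one 51,441-record campaign as the
full-library scale check — sizes chosen to exercise every code path while
keeping a complete run comfortable on a single CPU.  Floats are written to
CSV at full `repr` precision, so a CSV round-trip is bit-exact; `.xlsx`
numeric cells round-trip to ~16 significant digits (one write/read cycle
is a fixed point of the codec, and the package guarantees 12 significant
digits).  Empty cells, `NA` and `NaN` (any case) read as missing; only the
empty cell is written.  Header matching is case-insensitive and trimmed;
canonical names are written back.

## Known limitations

Only the `generic_qhts` dialect is parsed; the NCATS-internal export
dialect is detected and rejected with a pointer to the generic layout.
Single global concentration grid per file.  No curve fitting of raw user
data, no 5PL/biphasic models, no confidence bands, no SMILES-aware
clustering (SMILES is an opaque annotation; pre-sort the file for
chemotype grouping), and no vector (SVG/PDF) export.
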