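# qhtsplot

3-axis **waterfall plots** for quantitative high-throughput screening (qHTS)
concentration–response data.

In qHTS, every compound of a chemical library — routinely 10⁴–10⁵
compounds — is tested over a titration spanning 4–5 log units of
concentration, and each titration is summarized by a four-parameter Hill
concentration–response curve (CRC) fit.  Standard two-axis plots cannot show
thousands of CRCs at once; a waterfall plot puts compounds on one axis,
log₁₀ molar concentration on a second, and % response on the third, so
library-wide pharmacology (potency spread, gain- vs loss-of-signal,
reporter artifacts) is visible in a single interactive view.

`qhtsplot` is for screening scientists, chemical biologists and
informaticians who have per-compound CRC fit parameters and titration
responses — their own or downloaded from public repositories — and want an
overview plot without commercial software.

## The model

Each record's curve is the four-parameter Hill equation

```
y(x) = S₀ + (S∞ − S₀) / (1 + 10^( h · (log AC₅₀ − x) ))
```

with `x` the log₁₀ molar concentration, `S₀` / `S∞` the response asymptotes
at zero / infinite concentration (% activity), `AC₅₀` the half-maximal
concentration, and `h` the Hill slope.  The signed span `S∞ − S₀`
(*efficacy*) separates gain-of-signal (positive, drawn blue) from
loss-of-signal (negative, drawn red) responses.  A simplified, fully
documented curve-class surrogate (`complete` / `partial` / `low_efficacy` /
`inactive`, see `docs/methods.md`) supports class-wise grouping and the
conventional red/yellow/green/gray coloring.

## Input format

Plain `.csv` or `.xlsx` in the `generic_qhts` layout: a `Format` tag cell,
a per-row `Fit_Output` flag (1 = draw the fitted curve, 0 = points only),
`Comp_ID`, `Readout`, the four fit-parameter columns (`Log_AC50_M`, `S_0`,
`S_Inf`, `Hill_Slope`), then a `Log_Conc_M` tag followed by a contiguous
`Data0..DataN` block whose header row carries the log₁₀ molar
concentrations.  Record order in the file is the plot order — pre-sort your
file (or use `--sort-by`) to group by class, potency, readout or chemotype.
Extra columns (names, SMILES) travel along as opaque annotations.

## Worked example

```
$ qhtsplot example --output sample.csv --n-compounds 8 --seed 42 --active-fraction 0.5
INFO file written: sample.csv (16 records)

$ qhtsplot validate --input sample.csv
OK: 0 error(s), 0 warning(s)

$ qhtsplot plot --input sample.csv --output waterfall.html \
      --sort-by curve_class --sort-by ac50:desc --color-by curve_class
INFO records read: 16 (11 concentrations) from sample.csv
INFO traces built: 20 (16 markers, 4 lines)
INFO file written: waterfall.html (21968 bytes)
```

The synthetic campaign has 8 compounds × 2 coincidence readouts
(FLuc/NLuc) = 16 records; 4 records are active, so the scene holds one
markers trace per record plus one curve line per fitted record
(16 + 4 = 20 traces).  `waterfall.html` is fully self-contained: drag to
rotate, wheel to zoom, shift-drag to pan.  The same inputs from Python:

```python
import qhtsplot as q

ds = q.read_generic_qhts("sample.csv")
fitted, points_only = q.partition_records(ds)   # -> 4 fitted, 12 points-only
p = ds.records[fitted[0]].params
q.hill_response(p.log_ac50_m, p)   # 44.52  (% activity at the AC50 = (S0+S_inf)/2)
q.efficacy(p)                      # 91.63  (gain-of-signal)
q.polarity(p)                      # 'gain'

order = q.order_records(ds, q.OrderingSpec([("curve_class", "asc"), ("ac50", "desc")]))
scene = q.build_scene(ds, order, q.PlotConfig(show_inactive=False))
q.render_scene(scene, "waterfall.png")          # static raster
```

An empty `OrderingSpec` keeps file order exactly; all sorts are stable, so
ties never reshuffle rows.

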