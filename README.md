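# wheatdyn

Sowing-date analysis of winter wheat growth dynamics: logistic modelling
of per-stem dry-matter (DMA) and nitrogen (NA) accumulation, closed-form
fast-accumulation-phase eigenvalues, thermal-time phenology summaries,
and yield-loss / yield-threshold statistics.

## Who this is for

Agronomists and crop modellers analysing sowing-date field trials —
typically rice–wheat rotation systems where late rice harvest pushes
wheat sowing past its optimum — who want a tested, scriptable pipeline
instead of spreadsheet post-processing. The package ships the summary
tables of a two-season trial on the Jianghan Plain (middle-lower Yangtze
River Basin, cv. Zhengmai 9023; sowing dates 28 Oct, 5 Nov, 13 Nov,
21 Nov in 2018–2019 and 2019–2020) as a reference dataset, and a
ground-truthed synthetic experiment generator so every pipeline stage is
testable without field data.

## The model

Per-stem accumulation (DMA in g stem⁻¹, NA in mg stem⁻¹) over time `T`
(days after sowing) follows the three-parameter logistic curve

    W(T) = W_max / (1 + a·e^(−k·T))

Setting the second and third derivatives to zero gives closed forms for
the fast accumulation phase:

    Tm = ln(a)/k                inflection; W(Tm) = W_max/2
    T1 = ln(a/(2+√3))/k         onset of the fast phase
    T2 = ln(a/(2−√3))/k         end of the fast phase
    T  = T2 − T1 = 2·ln(2+√3)/k
    Vm = k·W_max/4              peak rate
    Vt = (W2−W1)/(T2−T1) = W_max/(√3·T)   mean rate over the phase

Around these sit the agronomic statistics: thermal time (growing degree
days, base 0 °C) from sowing to the wintering onset (first run of ≥ 3
days below 10 °C), phase-duration contrasts across sowing dates, percent
yield loss `(Y_ns − Y)/Y_ns × 100` versus the normal date, and
per-season linear regressions of grain yield on the mature/jointing
accumulation ratios (M_D/J_D, M_N/J_N) solved for the ratio sustaining a
target yield (default 6000 kg ha⁻¹).

## Worked example

```python
from wheatdyn import LogisticParams, eigenvalues, threshold_from_lines
from wheatdyn import datasets

# DMA curve of the early (28 Oct) sowing in 2018-2019
params = LogisticParams(w_max=3.6217, a=4101240.31, k=0.0976)
ev = eigenvalues(params)
print(f"fast phase: T1={ev.t1:.1f} d, T2={ev.t2:.1f} d, duration={ev.duration:.1f} d")
print(f"inflection: Tm={ev.tm:.1f} d, Vm={ev.vm:.3f} g/stem/d, Vt={ev.vt:.3f} g/stem/d")

thr, per_season = threshold_from_lines(datasets.ratio_regression_lines("dma"), target=6000.0)
print(f"DMA mature/jointing ratio sustaining 6000 kg/ha: {thr:.2f}")
```

prints

```
fast phase: T1=142.5 d, T2=169.5 d, duration=27.0 d
inflection: Tm=156.0 d, Vm=0.088 g/stem/d, Vt=0.077 g/stem/d
DMA mature/jointing ratio sustaining 6000 kg/ha: 4.06
```

The stem needs 142.5 days after sowing to enter its fast dry-matter
accumulation phase, accumulates fastest at day 156 (88 mg stem⁻¹ d⁻¹),
and exits the phase 27 days after entering it. Averaged over the two
seasons' regression lines, a mature-to-jointing DMA ratio of 4.06 keeps
the stand at or above 6000 kg ha⁻¹.

## Command line

```sh
wheatdyn simulate --seed 42 --out sim/          # synthetic experiment + truth.json
wheatdyn fit --growth sim/growth.csv --out fits.csv
wheatdyn eigen --coeffs fits.csv --out eigen.csv --printed-precision
wheatdyn report --config run.json --out report/  # full pipeline
```

`report` consumes a JSON run configuration (paths to the weather,
phenology, growth and yield CSVs, the reference sowing-date label, base
temperature, wintering threshold/run, target yield) and writes fit,
eigenvalue and thermal-summary tables plus contrast and yield-analysis
reports in CSV/JSON/markdown.

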