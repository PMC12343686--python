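# ringfrap

FRAP turnover analysis for reconstituted FtsZ rings and filaments, plus an
NADH-coupled GTPase rate module.

## The problem

Chloroplast division is driven by a ring of two tubulin-like GTPases (FtsZ2
and FtsZ1 in plants; FtsZA and FtsZB in red algae) whose subunit turnover
remodels the ring as it constricts. Turnover is measured *ex vivo* by
fluorescence recovery after photobleaching (FRAP): a 20-pixel-diameter spot
on a fluorescently tagged ring reconstituted in yeast is photobleached, and
refilling by unbleached subunits is followed for 260 s at 10 s intervals,
after three pre-bleach control frames. Because such slowly exchanging
structures rarely recover far enough for a half-time, the field's summary
statistic is **R₁₃₀ — the percent of fluorescence recovered 130 s after
photobleaching**, averaged over cells (mean ± SE).

`ringfrap` implements that pipeline end to end for people analysing
time-lapse stacks or pre-extracted ROI traces: trace extraction, correction
and normalization, model fitting, R₁₃₀, condition comparison, and the
companion GTPase activity assay. A synthetic-data generator emulates the
full acquisition protocol with known ground truth, so every stage is
testable without recorded data.

## The model

Recovery is fit to a two-binding-state exchange model

```
f(t) = (1 − r) · (1 − C_eq1 · e^(−koff1·t) − C_eq2 · e^(−koff2·t))
```

where `C_eq1`, `C_eq2` are the equilibrium fractions of molecules in each
bound state, `koff1 ≥ koff2` are the dissociation rate constants (s⁻¹), and
`r` absorbs incomplete recovery (`1 − r` is the mobile fraction). Raw ROI
traces are double-normalized first — background-subtracted bleach signal
over background-subtracted reference signal, rescaled to a pre-bleach mean
of 1 — which cancels acquisition photobleaching, then full-scale rescaled
so recovery is measured from the bleach floor. The model is fit to the
cross-cell averaged curve by bounded multi-start least squares.

The GTPase module converts the decline of A₃₄₀ in an NADH-coupled
regeneration assay (one NAD(P)H oxidized per GTP regenerated) into a
turnover rate: `rate = −slope / (ε · l) / [FtsZ]` in GTP FtsZ⁻¹ min⁻¹, with
ε(NAD(P)H, 340 nm) = 6220 M⁻¹cm⁻¹.

## Worked example

```python
from ringfrap import (SimulationConfig, simulate_condition, correct_and_normalize,
                      average_traces, fit_two_state, compute_r130, welch_t_test,
                      r130_per_cell)

def condition(**kw):
    cfg = SimulationConfig(**kw)                     # 12 cells, default protocol
    exps, _ = simulate_condition(cfg)
    traces = [correct_and_normalize(e) for e in exps]
    fit = fit_two_state(average_traces(traces))
    return traces, fit, compute_r130(traces, fit)

slow, fit_s, r_s = condition(seed=1)                 # slow ring (koff2 = 2e-4 /s)
dyn,  fit_d, r_d = condition(seed=2, koff2=0.003)    # more dynamic ring
print(f"slow ring:    R130 = {r_s.r130_empirical_pct:.1f} +/- {r_s.se_pct:.1f}% "
      f"(n={r_s.n_cells}), model {r_s.r130_model_pct:.1f}%")
print(f"dynamic ring: R130 = {r_d.r130_empirical_pct:.1f} +/- {r_d.se_pct:.1f}% "
      f"(n={r_d.n_cells}), model {r_d.r130_model_pct:.1f}%")
a = [v for _, v in r130_per_cell(slow)]
b = [v for _, v in r130_per_cell(dyn)]
w = welch_t_test(a, b, "slow", "dynamic")
print(f"Welch t = {w.statistic:.2f}, p = {w.p_value:.2e}")
```

prints

```
slow ring:    R130 = 9.3 +/- 1.7% (n=12), model 9.2%
dynamic ring: R130 = 35.1 +/- 1.6% (n=12), model 35.0%
Welch t = -10.96, p = 2.27e-10
```

i.e. the slow ring recovered 9.3% of its bleached fluorescence by 130 s and
the faster-exchanging ring 35.1% (both as per-cell means ± SE over 12 cells,
with the fitted curve's value alongside), a difference the Welch test calls
highly significant. The GTPase side works the same way:

```python
from ringfrap import simulate_gtpase_trace, analyze_gtpase
trace = simulate_gtpase_trace(0.39, ftsz_conc_molar=5e-6, noise_sd_AU=0.002, seed=4)
res = analyze_gtpase(trace, ftsz_conc_molar=5e-6)
print(f"slope = {res.slope_AU_per_min:.5f} AU/min over {res.window_min} min, "
      f"turnover = {res.rate_turnover:.3f} GTP FtsZ^-1 min^-1")
# slope = -0.01211 AU/min over (0.0, 30.0) min, turnover = 0.389 GTP FtsZ^-1 min^-1
```

A `ringfrap` command line wraps the same stages (`simulate`, `extract`,
`normalize`, `fit`, `r130`, `compare`, `gtpase`, `run-all`, `validate`)
around one YAML config; see `examples/config.yaml` and `ringfrap --help`.
Model and estimator details are in `docs/methods.md`.

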