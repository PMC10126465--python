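# sporekit

Quantitative analysis of bacterial spore phenotyping assays, built for
researchers studying spore germination and resistance (e.g. *Bacillus
subtilis* inner-membrane proteins such as YetF, YdfS and 2Duf).

The package covers four measurement pipelines plus the synthetic-data
generators needed to validate them end to end:

- **Single-spore germination kinetics** — locate spores in phase-contrast
  time-lapse stacks, extract 20×20-pixel mean-intensity traces,
  endpoint-normalize them (first frame → 1, recording tail → 0), and fit a
  continuous four-phase piecewise-linear model to recover, per spore, the
  lag time T<sub>lag</sub>, the CaDPA-release completion time
  T<sub>release</sub>, the cortex-lysis completion time T<sub>lys</sub>,
  the derived intervals ΔT<sub>release</sub> = T<sub>release</sub> −
  T<sub>lag</sub> and ΔT<sub>lys</sub> = T<sub>lys</sub> −
  T<sub>release</sub>, and the normalized intensities I<sub>lag</sub> and
  I<sub>release</sub>. Breakpoints are SSE-optimal over an exhaustive (or
  coarse-then-refined) search, exactly checkable against brute-force
  enumeration.
- **Population germination** — Tb-DPA fluorescence curves from a plate
  reader reduced to maximum germination rate, plateau, and release extent
  (% of the boiled-control CaDPA signal); selection of the optimal
  heat-activation time; relative CaDPA content per spore.
- **Survival analysis** — viable titers reconstructed from serial-dilution
  duplicate 10 µL spot counts, and the first-order inactivation fit
  log₁₀ N(t) = log₁₀ N₀ − t/D, giving the decimal reduction time D and
  rate constant k = ln(10)/D.
- **Homolog census** — Duf421-family proteins classified as YetF-like
  (210–253 aa, Duf421 domain only) or 2Duf-like (285–290 aa, Duf421 +
  Duf1657) from sequence length, with global-alignment identity/coverage
  against reference prototypes, hit filtering (coverage > 85%, E-value <
  1e−30 when supplied), and per-species count/best-hit tables.

See `docs/methods.md` for the models, their assumptions and limitations.

## Worked example

Simulate a recording of 60 spores (90% germinating, pixel noise 40 counts),
extract traces, and fit kinetics — via the CLI:

```sh
cat > cfg.json <<'EOF'
{"population": {"n_spores": 60, "frac_germinating": 0.9},
 "imaging": {"width": 600, "height": 400, "duration": 45.0, "noise_sd": 40.0}}
EOF
sporekit simulate --kind stack --config cfg.json --seed 7 --out sim
sporekit extract --stack sim/stack.npz --out traces.csv
sporekit kinetics --traces traces.csv --out kin
```

which prints

```
wrote stack (181 frames) and roster for 60 spores
detected 60 spores (0 edge-clipped discarded); wrote traces to traces.csv
fit 60 spores, 54 germinated (90.0%)
```

and writes per-spore kinetics (`kin/kinetics.csv`) plus a population
summary (`kin/summary.json`) whose parameter table reads:

```
                   mean     sd
t_lag             9.759  2.783
t_release        11.787  2.766
t_lys            17.843  3.170
delta_t_release   2.028  0.576
delta_t_lys       6.056  1.788
i_lag             0.957  0.031
i_release         0.394  0.081
```

All 60 rendered spores were detected, the 6 non-germinators were correctly
excluded by the endpoint-drop rule (germinated fraction 0.90), and the
recovered means match the generator's sampling distributions: lag times
~10 min, rapid CaDPA release lasting ~2 min, cortex lysis ~6 min, and a
mean I<sub>lag</sub> near 0.96 reflecting the small lag-phase leak.

The same steps are available as library calls
(`sporekit.generate_truth` / `render_stack` / `detect_spores` /
`extract_all_traces` / `fit_kinetics` / `summarize_population`), and the
other pipelines as `sporekit simulate --kind plate|survival|proteins`,
`sporekit population`, `sporekit survival` and `sporekit census`.

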