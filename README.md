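# shipstrike

A probabilistic simulator of lethal vessel strikes on North Atlantic right
whales (*Eubalaena glacialis*), for conservation scientists and managers who
need to estimate annual strike mortality by vessel size class and evaluate
speed-restriction policies.

## The model

Vessel traffic is summarised as transit segments, each crossing one
10 × 10 km grid cell. For transit *k* in cell *j* during month *i*, annual
mortality is the triple sum

```
M_year = Σ_i Σ_j Σ_k  strike_ijk · (1 − avoid_ijk) · lethal_ijk · N_w(i, j)
```

where each factor is one stochastic replicate of:

- **strike** ~ Bernoulli( clamp(λₑ·t · p_strike_depth · c, 0, 1) ), with
  λₑ·t the 2-D random-movement (ideal-gas) encounter expectation at a
  13.5 m detection radius (one whale body length),
  λₑ = (2R/A)·(u² + 3v²)/(3v); *t* is the cell-crossing time,
  p_strike_depth the regional tag-derived proportion of time above 5 m
  (vessels < 350 ft) or 15 m (ocean-going vessels, OGVs), and *c* an
  AIS-undercount correction (Small/Medium class only);
- **avoid** — a whale starting at a uniform random depth dives at a uniform
  random descent rate (0.81–2.0 m/s) from a uniform random reaction
  distance (10–1200 m); it escapes iff it is below the strike zone
  (draft × propeller-suction scalar; 2× for OGVs) when the vessel arrives
  *and* the bottom leaves room: bottom > strike zone + 3 m whale height.
  OGVs (30 m strike zone) are therefore unavoidable in water < 33 m;
- **lethal** ~ Bernoulli of a logistic in vessel speed, size class, species
  and speed × species (coefficients are config inputs; shipped defaults are
  documented qualitative placeholders);
- **N_w** — the expected whale count in the cell that month, so
  contributions are real-valued.

A bootstrap (default 1000 iterations) yields mean/sd/median annual
mortality per size class (Small/Medium 26–65 ft, Large 65–350 ft,
OGV > 350 ft), a per-cell-month risk surface, and risk apportionment. The
**slow-all** counterfactual caps every non-exempt transit over 10 kn at
Uniform(9.5, 10) kn with all other random draws held equal, isolating the
effect of speed on avoidance, lethality, and exposure time.

A synthetic-scenario generator (shelf bathymetry, seasonally shifting
density hotspots scaled to a 350-whale population, class-specific traffic)
exercises the full pipeline with no external data.

## Worked example

```
shipstrike synth --seed 7 --out-dir data
# cfg.yaml:  n_iterations: 1000
#            seed: 7
shipstrike run      --config cfg.yaml --transits data/transits.csv --density data/density.csv \
                    --bathy data/cells.csv --profiles data/depth_profiles.csv --out real
shipstrike slow-all --config cfg.yaml --transits data/transits.csv --density data/density.csv \
                    --bathy data/cells.csv --profiles data/depth_profiles.csv --out slow
shipstrike compare real slow
```

prints

```
wrote scenario (41129 transits) to data

SmallMedium: mean annual mortality 11.235 (70.90% of risk)
Large: mean annual mortality 1.677 (10.58% of risk)
OGV: mean annual mortality 2.933 (18.51% of risk)

 size_class  mean_real  mean_slow  decrease_pct
SmallMedium  11.234552   5.270150     53.089813
      Large   1.676544   1.497702     10.667317
        OGV   2.933459   2.722854      7.179416
risk-share-weighted overall decrease: 40.10%
```

Reading: on this synthetic coast the three classes together kill ~15.8
whales/yr in expectation; Small/Medium vessels dominate because the
generator routes them through the nearshore density hotspot with the 3.5×
AIS-undercount correction applied, and they benefit most from slowing
(steep lethality-speed response). OGV decreases are smallest: their strikes
are near-certainly lethal at any speed, and slowing lengthens cell-crossing
time. `real/` contains `summary.csv`, per-iteration totals, and the
per-cell-month mean risk surface.

`shipstrike sensitivity` runs one-at-a-time parameter sweeps (e.g.
`avoidance_enabled: [false]` bounds mortality with no avoidance behaviour).

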