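# Methods

## Model structure

The simulator estimates annual lethal-vessel-strike mortality of North
Atlantic right whales on a planar 10 × 10 km grid. The unit of computation
is one transit segment — one vessel track crossing one cell in one month.
Each bootstrap iteration evaluates, per transit, a chain of four factors
(encounter, depth exposure, avoidance, lethality) and multiplies the binary
outcome by the cell's expected whale count N_w. Annual totals per vessel
size class are the sum over months, cells, and transits; with several years
of traffic, each iteration reports the across-year mean.

Contributions are deliberately real-valued (indicator × N_w) rather than
integerised: N_w comes from a density surface and is itself an expectation,
so totals are expected mortalities, not realised integer body counts. This
makes expected mortality exactly linear in N_w, which the tests exploit.

### Encounter

Both whale and vessel are treated as randomly moving points in the cell
(area A, default 10⁸ m²). The encounter rate uses the Gerritsen–Strickler
swept-path form λₑ = (2R/A)·ṽ with ṽ = (u² + 3v²)/(3v) for vessel speed
v ≥ whale speed u, R = 13.5 m (one adult body length). λₑ·t over the
cell-crossing time t is an expected count; it is clamped to [0, 1] only at
the point where it is consumed as a Bernoulli probability. For u → 0 the
kernel reduces exactly to the swept strip 2RL/A. The antecedent literature
for this model family does not fix a unique ṽ convention, so the form is
isolated behind a single function and validated against a brute-force
moving-points Monte-Carlo oracle (toroidal cell, closed-form minimum
distance over linear relative motion, adaptive periodic-image lattice);
agreement is within 3 Monte-Carlo standard errors on all tested parameter
sets.

The whale swim speed u is not constrained by the source material; the
default is 1.0 m/s (typical right whale travel speed) and configurable. At
transit speeds it contributes only a (1 + u²/3v²) factor, so results are
insensitive to it.

### Depth exposure

The probability that the whale occupies the hazardous upper water column is
read from regional tag-derived profiles: proportion of time above 5 m for
vessels under 350 ft, above 15 m for OGVs. Shipped defaults
(duration-weighted means from 146 depth-recording tags): Northeast
(0.392, 0.587), Cape Cod Bay (0.910, 0.953), Mid-Atlantic (0.876, 0.969),
Southeast (0.564, 0.930) as (above 5 m, above 15 m). Profiles are inputs;
recomputing them from raw tag records is out of scope. The exposure depth
is tied to the size class, not the individual imputed draft, because the
empirical profiles exist only at those two depths.

### Avoidance

Vertical dive avoidance: whale depth at vessel arrival is
start + rate · distance / v, with start ~ U(0, class max draft), rate ~
U(0.81, 2.0) m/s, distance ~ U(10, 1200) m, drawn independently. The source
ranges come with no distributional shape, so independent uniforms are the
least-assumption default; all three ranges are configurable. Escape
requires (strictly) depth > strike zone and bottom > strike zone + 3 m
whale height; ties count as struck (conservative). Strike zone = class
draft × suction scalar (Small/Medium and Large: draft 5 m, scalar 1; OGV:
draft 15 m, scalar 2 → 30 m, hence a 33 m unavoidable-zone threshold).
Class drafts, not per-vessel imputed drafts, define both the strike zone
and the start-depth bound — AIS drafts are mostly missing in practice, and
this matches the empirical basis of the exposure profiles. Lateral
avoidance is intentionally absent (no empirical support).

### Lethality

P(death | strike) is a logistic in vessel speed (kn), size class
(categorical), a humpback/other-species indicator, and speed × species.
The fitted coefficients of the underlying strike-database regression are
not public; they are therefore required config inputs. The shipped defaults
— intercept −4.0, speed +0.35/kn, Large +1.0, OGV +4.0, species terms 0,
indicator fixed at the non-humpback level — are explicitly labelled
placeholders, calibrated qualitatively: lethality rises steeply with speed
for sub-350-ft classes, and OGV strikes are highly likely lethal (> 0.9)
at all observed transit speeds while retaining a mild speed response, so
slowing an OGV is never counterproductive. Quantitative work must supply
fitted coefficients (YAML block or CSV).

### Small/Medium correction factor

Most vessels under 65 ft carry no AIS. A class-level scalar (default 3.5,
derived as total registered / total AIS-observed unique vessels across
categories) multiplies the Small/Medium encounter expectation before
clamping — equivalent in expectation to replicating transits, but cheaper.
It assumes observed Small/Medium traffic is spatially representative.

### Randomness and pairing

Iteration *i* uses one PCG64 generator seeded SeedSequence([seed, i]).
Every transit consumes exactly five uniforms (strike, start depth, descent
rate, reaction distance, lethality) in sorted-transit_id order, whether or
not a strike occurs. Because the slow-all transform preserves transit
identities, the real-world and counterfactual runs share every random input
except the speeds themselves — a common-random-numbers design that makes
scenario differences near-noiseless. The scalar `simulate_transit` consumes
the same five-uniform block, so a Python loop reproduces the vectorised
engine bit-for-bit (tested).

### Slow-all counterfactual

Non-exempt transits over 10 kn get speed ~ U(9.5, 10.0) kn. Elapsed
cell-crossing time is recomputed from the segment length by default: a
slower vessel is easier to avoid and less lethal but spends longer in the
cell, and the model must capture that trade-off. Whether the original
analysis held elapsed time fixed is not documented, so
`recompute_elapsed=False` is available. Since λₑ·t at fixed path length is
nearly speed-independent, the choice is second-order.

## Synthetic scenarios

The generator emulates the structure of the real inputs, not their
geography:

- **Bathymetry**: depth = 1 + 199·(x/(nx−1))^1.5 m across the default
  20-column grid — a concave shelf whose nearshore columns exercise the
  < 3 m removal filter and populate the 3–8 m (Small/Medium-unavoidable)
  and < 33 m (OGV-unavoidable) bands.
- **Density**: two Gaussian hotspots with opposing monthly amplitudes — a
  southern one peaking in winter (calving grounds) and a northern one in
  summer (foraging grounds). Each monthly surface is normalised to
  350 whales × an in-domain fraction (0.9 Nov–Apr, 0.4 Jun–Sep),
  reflecting seasonal migration beyond the modelled domain. Mass is placed
  only on retained cells.
- **Traffic**: per-cell-month Poisson counts; OGVs in a lane crossing the
  shelf (2/cell-month), Large broadly over the shelf (4), Small/Medium
  nearshore with a 4× summer peak (3). Speeds Normal per class (OGV 13,
  Large 9.5, Small/Medium 17 kn, sd 3–6) clipped to the valid 0.2–50 kn
  range; 5% of transits flagged exempt. The default scenario yields
  ~41,000 transits/yr and ~16 expected mortalities/yr — the order of
  magnitude a coastwide analysis scaled to a 350-whale population produces.

What passing tests on synthetic data show: the stochastic composition,
conservation, pairing, and counterfactual machinery are correct. What they
do not show: fidelity of any absolute mortality number to the real coast —
that depends on real density surfaces, real AIS traffic, and fitted
lethality coefficients supplied by the user.

## Numerical choices and problem sizes

- Filter boundaries are strict as worded: speeds > 50 and < 0.2 kn dropped
  (0.2 and 50 retained); cells < 3 m removed (3.0 m retained); avoidance
  inequalities strict. Length 65 ft classes as Large; > 350 ft as OGV;
  < 26 ft (below the smallest class) dropped on load.
- Region assignment: first containing polygon in the fixed order Southeast,
  Mid-Atlantic, Cape Cod Bay, Northeast (southernmost wins boundary ties);
  a cell outside every region is an error, never silently defaulted.
- Density aggregation from a 5 km grid sums exact 2 × 2 blocks; non-nesting
  shapes are an error.
- Missing length/draft are imputed by uniform draws from same-category
  donor records (transit-level, as the table carries no vessel identity);
  missing speed or elapsed time is a filter failure, never imputed.
- Test problem sizes: the encounter oracle uses 10⁵ placements per
  parameter set; the engine expectation check integrates the avoidance
  draws on a 400² midpoint grid and compares 2000 bootstrap iterations on a
  3-cell scenario; the paired slow-all ordering is asserted over 100
  scenarios × 400 iterations on a 12 × 12 grid. All randomness is seeded,
  so every test is deterministic.

## Known limitations

- Dive behaviour is static per region: no monthly, behavioural-state, or
  life-history variation in the exposure profiles.
- Avoidance is purely vertical and always attempted; the true frequency of
  avoidance behaviour is unknown, so `avoidance_enabled: false` in a
  sensitivity sweep gives the no-avoidance upper bound.
- One strike-zone scalar per class; real propeller-suction effects vary
  continuously with vessel size and type.
- The planar grid ignores geodesic distortion; cell area is nominal 10⁸ m².
- The correction factor is a single class-level scalar assuming spatial
  representativeness of observed small-vessel traffic.
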