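# Methods

## Model

A fibre is a one-dimensional segment of length *L* (µm) with uniform
wall properties.  Impacts during free-fall mixing are idealised as
three-point bending of a simply supported beam: supports at the fibre
ends, a transverse force *P* at a random position.  For a load at
relative position *x′* the bending-moment diagram is triangular; the
envelope over all load positions is the parabola *M*(x′) = *P·L·x′(1−x′)*,
which dominates the central-load triangle and touches it at mid-span
(*P·L*/4).  The fibre breaks only where the envelope reaches the failure
moment *M_u*.  Since forces in free-fall mixing are taken as constant,
only the ratio *M_u/P* enters; it has units of length and is carried in
µm.  The probable failure region (PFR) is the central interval where
breakage is possible; its relative extent is *e* = √(1 − 4·(*M_u/P*)/*L*)
and its boundary lies at least *M_u/P* from either fibre end, so no
break can create a fragment shorter than *M_u/P* (provable from the
envelope: at distance *d* < *M_u/P* from an end, *M* ≤ *P·d* < *M_u*).

### Simulation step

Per step, each active fibre is processed independently, in input order,
consuming one uniform variate from a single seeded generator:

1. if *L* < 4·*M_u/P* (ratio of failure to peak central moment > 1) the
   fibre is **retired**: it can never break at this or any later
   strength (strength only decreases) and is permanently excluded from
   the breakage loop.  Retired fibres remain part of the material and
   of every reported distribution;
2. otherwise a candidate break point *p* = *u·L* (*u* uniform on [0, 1))
   is drawn.  If *p* lies in the closed PFR interval the fibre is
   **broken** into fragments *p* and *L − p*; else it is **passed**
   unchanged.  Break probability therefore equals the PFR extent *e*.

Equality at the threshold (*L* = 4·*M_u/P*) counts as breakable but has
zero break probability (the PFR is a point), so the boundary needs no
special-casing.  The extent is computed as √(max(0, 1 − ratio)) so
roundoff at the threshold cannot produce a negative sqrt argument.

Enzymatic weakening: *M_u/P* at step *k* is
max(floor, initial·decay^(k−1)); defaults 400 µm, 0.75, 40 µm.  The
geometric sequence never hits the floor exactly, so "until it reached
40" is implemented as a clamp held for all later steps (first clamped
step under defaults: step 10).  The stop rule is checked before each
step: the run ends when fewer than `min_active_to_continue` (default
100) fibres would enter it, counting both halves of every broken fibre.
Termination is only almost-sure, so a `max_steps` cap (default 500)
backstops the loop; the trajectory records which condition ended it.

### Null model

Random segmentation splits *every* fibre at a uniform point in *every*
step: counts double and the mean length halves exactly each step, with
no lower threshold.  Because the stored trajectory grows as
*n*·2^(steps+1) values, runs whose storage would exceed ~2·10⁸ numbers
are refused with an explanatory error; the null model's binned
distribution does not depend on the population size, so smaller samples
serve for distribution-level comparisons at longer horizons.

## Parameters

| parameter | unit | default | meaning |
|---|---|---|---|
| `initial_mu_over_p` | µm | 400 | failure moment / impact force at step 1; minimum breakable length 1.6 mm |
| `decay_factor` | — | 0.75 | per-step strength decay from enzymatic weakening |
| `floor_mu_over_p` | µm | 40 | terminal strength; minimum breakable length 0.16 mm |
| `min_active_to_continue` | count | 100 | stop rule on fibres forwarded to a step |
| `max_steps` | count | 500 | safety cap on step count |
| bin edges | mm | 0, 0.25, 0.5, 3, 7 | length classes; 0.25 mm is a package choice for the interior split of the sub-0.5 mm range |

The µm reading of *M_u/P* is a convention: 400 µm → 40 µm makes the
breakable-length threshold run from 1.6 mm to 0.16 mm, consistent with
3–7 mm starting segments and stabilisation of the sub-0.5 mm classes.

## Synthetic populations

The generator emulates a pre-hydrolysis flax sample: a binomially sized
fraction (default 80 %) of intact segments uniform on 3–7 mm, plus
fines — short fragments from cutting and handling — log-normal with
median 0.5 mm and log-sd 0.8, resampled above 7 mm.  Defaults
(10,000 fibres) give a population whose length-weighted share is ~97 %
in the 3–7 mm class, matching a freshly cut sample measured by
automated image analysis.  The generator does not emulate measurement
artefacts (resolution floor of the imaging instrument, width/curl), nor
any correlation between fibre length and strength; passing tests
therefore validate the simulator's mechanics and bookkeeping on
realistic length scales, not agreement with any particular measured
sample.

## Reported statistic

Distributions are length-weighted: the share of *total fibre length*
per class, computed with half-open bins [a, b), a closed last bin, and
lengths above the top edge folded into the last bin (flagged).
Number-weighted shares are available as an option and coincide with
length-weighted shares when all fibres are equal.  Distribution series
are compared by total-variation distance (½·Σ|Δshare|), chosen because
it is bounded, defined for empty classes and reads as "fraction of
length misallocated".  Stagnation is declared at the first entry from
which every consecutive pair over a patience window (default 2) differs
by less than a tolerance; the patience guards against one-step
coincidences.

## Calibration

`calibrate_schedule` is a direct grid search: each candidate schedule
is simulated with a small number of replicate seeds (derived
deterministically from one master seed), binned at the observed edges,
aligned to the observed series by index — the model has no mapping from
steps to hours, a known gap — with excess steps truncated and missing
steps padded with the terminal distribution, and scored by mean
total-variation distance.  Invalid grid corners (floor above initial)
are skipped.  On self-generated data the generating schedule
(400/0.75/40) is recovered from a 3×3×3 grid of decoys.

## Behaviour under defaults

On the default synthetic population the mechanical run realises ~60–70
steps, with a long tail in which under 2 % of the material is still
active; the binned distribution stops changing (TV < 0.01 sustained)
around step 14 while ~36 % of total length persists above 0.25 mm —
stagnation without collapse.  The null model's shortest-bin share rises
monotonically; by ~13 doubling steps essentially *all* its length lies
below 0.25 mm, at which point its binned series necessarily stops
changing too.  The two models are therefore distinguishable in binned
terms over the horizon where the null still has mass above the
shortest class (roughly 12 steps), or at any horizon by the end state:
the mechanical model freezes into a non-degenerate distribution, the
null into the degenerate shortest-class corner.  The mechanical/null
contrast in the examples uses a 12-step window for this reason.

## Numerical choices and limitations

* Splits conserve length exactly per fibre (*p* and *L − p*); sums over
  populations are float64 and tested to ≤1e-9 relative error.
* Runs are bit-reproducible: one `numpy` generator seeded from the
  config, one draw per entering fibre in stable input order; trajectory
  JSON is byte-identical across repeated runs.
* Time is abstract: steps do not map to hydrolysis hours.  Enzyme
  kinetics, mass loss, fibre diameter and spatial mixing are out of
  scope; strength is uniform along and across fibres (the weakening
  schedule can also be read as a spread of per-fibre strengths, but no
  explicit strength distribution is modelled).
* Problem sizes in the test and acceptance runs (10,000 fibres, ten
  seeds; 1,000-fibre null samples; 3×3×3 calibration grids with two
  replicates) are the package's default study conditions and complete
  in well under a minute each on one CPU.
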