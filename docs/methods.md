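# Methods

## The model

`pursuitkit` studies the attack phase of terrestrial (cursorial)
predator–prey pursuit on a flat, homogeneous plane, isolating one variable:
body mass. Two physical laws carry all of the mass dependence.

**Maximum running speed.** Mammalian top speed follows a quadratic
log–log allometry,

    log10 Vmax[km/h] = a0 + a1·log10 M + a2·(log10 M)²,

with default coefficients (1.478, 0.2589, −0.0623) and M in kg. The law is
unimodal: speed rises with mass up to a vertex near 120 kg
(`10^(−a1/2a2)`) and falls beyond it. Over 0.05–5000 kg the max/min ratio
is ≈ 5.14 — mass changes top speed by less than a factor of six.
`speed_factor` evaluates the analytic vertex in addition to its log-spaced
grid, so the interior maximum is found at any grid density.

**Strength-limited turning.** Under geometric similarity an animal of mass
M and density ρ has characteristic length `L = (M/ρ)^(1/3)`; the force its
limbs can transmit scales with cross-section as `k·L²` (k in N/m², a
material property of muscle, tendon and bone), while holding a circular
path of radius r at speed v demands centripetal force `M·v²/r`. Equating
the two gives the minimum turn radius

    r_min(v) = ρ·L·v²/k .

Demand scales as mass¹, supply as mass^(2/3), so `r_min ∝ M^(1/3)` at any
common speed: heavier animals are faster but clumsier. The default
k = 3100 N/m² is calibrated from a single reference turn — a 30 kg cursor
turning with r = 40 m at 20 m/s — and ρ = 1000 kg/m³ is the density that
makes that triple self-consistent (and is close to tissue density). Both
are exposed parameters. Elastic-similarity or posture corrections,
friction-limited turning and bone safety factors are deliberately outside
the model.

During a shared turn of angle φ at common speed v each party covers
`φ·r_min`, so the predator's extra distance is `φ·(r_pred − r_prey)`, with
sign fixed by the masses alone. A 250 kg predator runs farther than prey
of 3–200 kg in any 90° turn; a 30 kg predator out-turns the three heavier
of those five prey but not the two lighter ones.

## The chase simulator

The chase has two stages. In stage 1 the predator accelerates from
concealment toward a (near-)stationary prey under a speed-dependent
tangential-acceleration law `a(v) = c1·v^c2` (default (47.041, −0.945),
measured for a ~30 kg sprinter at ≈ 90 W/kg); when the gap falls to the
prey's reaction distance the prey flees directly away — any other heading
closes the gap faster while the predator is distant. The bearing change
the predator sees after its reaction time follows planar sine-rule
geometry, `sin ϕ = (s_prey/D)·sin θ`. (The transposed form
`sin ϕ = (D/s_prey)·sin θ` that one might write from the same triangle is
inconsistent — it exceeds 1 whenever D > s_prey — so the geometrically
consistent form is used.)

In stage 2 both parties run at constant top speed (the default; an
accelerating mode exists) and the prey executes a turn policy: at each
trigger distance (or time) it turns a given angle on its own minimum
radius at its current speed. The predator, after its reaction time
`t_react` (default 0.3 s), first turns toward the prey on *its* minimum
radius until its velocity vector points at the prey, then reverts to pure
pursuit — heading at the prey's current position each step, with heading
rate capped at `v/r_min`. Predictive strategies (constant bearing, CATD)
are out of scope; terrestrial pursuers are well described by pure pursuit.

Numerics: fixed-step explicit integration, default dt = 0.01 s, with a
midpoint-heading position update (second-order accurate on circular arcs);
halving dt changes the final separation of the canonical scenario by
≈ 0.7%. The acceleration power law diverges at v = 0 and is frozen below
0.1 m/s. Radii below 1e−9 m are treated as instantaneous heading changes,
which recovers the ideal pursuit-curve limit. Heading is CCW radians from
+x, positions Cartesian metres, time from predator launch. Everything is
deterministic; stochastic components elsewhere take explicit seeds.

**Classifying the response.** Each predator response is classified by
comparing the path it ran over its response window (prey-turn onset →
realignment end, i.e. reaction segment + realignment arc) against the path
the prey ran during its turn arc: shorter ⇒ `corner_cut`, longer ⇒
`overshoot`, equal within one integration step of path ⇒ `matched`. The
signed difference (`path_excess`) is the overshoot magnitude used in the
sensitivity grid; it grows with reaction time and predator speed and
shrinks with trigger distance, reproducing the model's three headline
sensitivities on a 3×3×3 grid (reaction 0.3–0.9 s, trigger 6–14 m,
predator 18–20 vs prey 15 m/s).

**Termination.** Capture when D ≤ capture radius (default 0.2 m). The
model has no natural escape condition at constant speeds, so escape is a
convention: D exceeding `escape_factor` (default 2) times its value at the
most recent prey-turn onset, or an optional predator energy budget
running out. Escape is never declared while a predator response is still
in progress — a long-reaction overshoot transiently doubles the gap before
the predator realigns, and aborting there would leave the manoeuvre
unclassified mid-swing. The sensitivity battery disables escape entirely
so every cell runs to a classified response.

**Energetics.** Mass-specific power is `intercept + slope·v` on straight
segments (the linear cost-of-transport law; defaults 2 W/kg and
4 J/kg/m) plus a turning surcharge proportional to the centripetal-work
proxy `v²·|ω|` (dimensionless coefficient, default 1). No published
surcharge value exists for this setting, so the energetics are
qualitative: they order scenarios (an overshooting predator spends
markedly more over its turn-response window than a corner-cutting one on
the same prey path) but calibrate to no species. Window-based comparison
matters here: at constant speed a whole-chase comparison is dominated by
the terminal phase, where pure pursuit with a finite turn radius settles
into an orbit around a prey it cannot reach, accruing surcharge
indefinitely.

## Turn detection from collar accelerometers

Cornering shows up as a departure of the mediolateral acceleration
magnitude from 1 g. The chain mirrors standard bio-logging practice:
vectorial sum √(heave² + sway²) (insensitive to collar rotation, which
redistributes gravity arbitrarily between the two lateral axes); a
centred 2 s running mean to isolate the static component (60 samples at
the 30 Hz default rate); a second 0.5 s running mean to suppress the
residual bounding-gait waveform; then peak detection on the departure
from 1 g. Defaults: peak threshold 0.1 g, onset threshold 0.05 g,
gait-peak exclusion window 0.4 s — none of these has a published value;
all are exposed on the CLI. Edge policy: windows shrink symmetrically at
the record ends. Departure is absolute by default (a signed mode exists).
The exclusion rule keeps peaks greedily by height and discards lower
peaks within the window of a retained one. A turn's onset is the last
upward crossing of the onset threshold before its peak, falling back to
the preceding local minimum when the smoothed series never dips below
the onset level; duration is onset-to-peak. Chase windows are taken as
given — segmenting chases out of day-long logs is out of scope.

## The performance surface

Over a log-spaced mass grid (default 60×60, 0.05–5000 kg) the surface
holds `vratio = Vmax_pred/Vmax_prey` and `tratio = Tmin_prey/Tmin_pred`,
each Tmin evaluated at that animal's own allometric top speed. Since
`Tmin ∝ M^(1/3)·Vmax(M)²`, k and ρ cancel whenever both parties share
them, and swapping the parties inverts both ratios exactly. Species mass
pairs are placed by direct evaluation (no interpolation) and flagged
inside the predator-advantage region when tratio ≥ 1 — a documented
convention; the region has no published quantitative boundary. A
common-speed sensitivity mode reduces tratio to the pure `(M_prey/M_pred)^(1/3)`
ratio. The computed maximum turn-radius ratio over the full range is
≈ 591; the surface reports its own computed spread rather than asserting
any external figure.

## Synthetic data

The generators define the study conditions; all are pure functions of
(recipe, seed).

*Accelerometer traces* (default 20 s at 30 Hz): the static lateral
magnitude is 1 g plus Gaussian cornering bumps (default peak 0.3 g, σ
0.4 s, four per trace), projected onto heave/sway through a collar angle
doing a slow Gaussian random walk (σ 0.02 rad/sample) — emulating a
partially rotating collar that makes the two axes interchangeable. A
gait sinusoid (3 Hz, 0.5 g — plausible for a galloping cursor; no
published values) rides along the instantaneous collar direction, and
white noise (σ 0.05 g) is added per channel. Ground truth is the exact
bump peak times; overlapping bumps are refused (truth would be
ambiguous). The detector scores recall and precision 1.00 on the default
benchmark (100 seeded traces, 4 random turns each, matched within
0.5 s). What this does *not* show: real chases have speed-varying gait
frequency, surge/pitch cross-talk, impacts and genuinely ambiguous
compound turns, so field performance will be lower than the synthetic
ceiling; the benchmark demonstrates the chain's correctness, not a field
error rate.

*Species tables*: predator masses log-uniform (default 1–300 kg, n = 54),
prey mass = predator mass × a log-normal ratio (default median 1.0, log-σ
0.5, straddling the agility-parity boundary).

*Scenario batteries*: Cartesian products over reaction time, trigger
distance and speed pairs, each an equal-mass single-turn gambit at fixed
overridden speeds.

## Known limitations

Constant-speed stage 2 means no speed modulation in turns, although real
pursuers slow before cornering; the optional accelerating mode does not
couple speed to commanded radius by default. Pure pursuit with a hard
radius cap produces a terminal orbit instead of capture when the prey
sits inside the predator's turning circle — real predators decelerate or
lunge. The energetics surcharge is uncalibrated. The allometric laws are
cross-species trends; individual species deviate widely from geometric
similarity. Problem sizes throughout (grid extents, 100-trace benchmark,
dt = 0.01 s) are the package's standard analysis settings and run in
seconds on one core.
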