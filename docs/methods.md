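# Methods

This note documents the models, estimators and numerical choices behind
`infoflow`, in the order data flows through the pipeline, and states what
the synthetic-data validation does and does not demonstrate.

## Tracks, projection and pairing

Tracks are 5 Hz position series. Geographic input is projected to planar
metres with an azimuthal-equidistant mapping about the home loft, built on
Vincenty geodesics (WGS84). Any locally distance-preserving projection
would do at homing scales (<50 km); this one makes distances measured from
the loft exact by construction and is invertible to ~1e-6 degrees. The
projection is cross-checked in the tests against independently computed
geodesic distances and bearings.

Pair members are resampled to a shared 0.2 s grid by nearest-sample
matching with a 0.1 s tolerance (loggers are not synchronised to the
sample). Grid points with no sample within tolerance on either track are
masked, never interpolated: entropy estimates are counts of observed
symbols, and interpolation would fabricate rotations. Pairs whose mean
inter-bird distance exceeds 250 m are excluded — birds that far apart are
effectively flying solo. Flights with less than 60 s of overlap are
rejected outright.

## Rotation encoding

The symbol at index i compares the motion vector from position i to i+1
with the one from i+1 to i+2: positive planar cross product →
counterclockwise (1), negative → clockwise (0). Encoding at a coarser
sampling period subsamples positions first, so larger periods measure
coarser turning. Exact zero cross products (collinear motion) carry the
previous symbol forward — a third alphabet symbol would leave the binary
model, and dropping ties would desynchronise the two birds' series — and
are flagged in a tie mask so the tie fraction can be audited per flight.
On real 5 Hz data exact zeros are measure-zero events; they matter only
for synthetic straight-line edge cases.

The signed front/back distance `d_EN` projects the E−N separation onto the
normalised sum of the two unit velocity vectors (the bisector of the two
headings). Degenerate samples (a stationary bird, or exactly opposed
headings at equal speed) are masked.

## Plug-in information estimators

All entropies are plug-in estimates from one flight's own transition
counts; nothing is pooled across flights. Transfer entropy with target
history k is the difference of two conditional entropies computed from the
same joint count table, which guarantees 0 ≤ TE ≤ H(next | past) exactly,
and the local (per-transition) series averages to the TE estimate exactly
(same counts — asserted to 1e-9 in the tests). Transitions touching masked
or tie-degenerate samples are dropped from the counts, not imputed.

No bias correction is applied by default: estimates are interpreted
against a surrogate null that carries the same bias, which is how the
study design intends them to be read. A Miller–Madow-style correction is
available behind a flag.

**Choosing k and the period.** The default analysis configuration is
k = 10 at 0.2 s. Note the plug-in bias scale: with binary symbols and
history k there are ~2^(k+2) count cells, so a single ~2,600-sample flight
at k = 10 carries a bias of order 0.1–0.5 bits per direction. That washes
out in real-vs-surrogate contrasts over hundreds of flights, but in
desk-scale colonies of 10–20 simulated flights the k = 10 bias swamps a
~0.03-bit coupling signal. The surrogate-comparison validations therefore
run at k = 5 (32 contexts), where the bias is negligible at these flight
lengths; k is an analysis setting, and the contrast being validated does
not depend on its exact value.

**Predictive power.** TE is reported as a percentage of
H(next | past k) — the uncertainty that remains after the bird's own past
is accounted for — since TE is defined as the reduction of exactly that
quantity. The marginal-entropy denominator is available behind a flag.

**Local TE by distance.** Each counted transition contributes its local TE
to the d_EN bin at its time; per-bin means get flight-level bootstrap 95%
CIs (1000 resamples by default). Fixed-width binning replaces smoothed
conditional means because it is deterministic and testable. Two
resolvability limits are built into how results should be read: (i) by
exchangeability the E→N and N→E curves cross at d_EN = 0, so narrow bins
straddling zero carry a near-zero contrast by construction; (ii) a bin
mean of local TE has SE ≈ 0.5/√n bits, so bins holding less than ~1% of
transitions cannot resolve the ~0.02-bit front/back contrast. The
validation suite treats a bin as "populated" at the 1% occupancy level and
uses 10 m bins.

## Surrogate null

Surrogates cross-pair the experienced-role track of each pair with the
naive-role track of every other pair sharing no subject, in both role
orderings, by default within the same release index. Tracks are aligned on
elapsed time from release (all birds start at the same site) and truncated
to the shorter flight. The comparison statistic is per-flight total TE
(both directions summed), tested by two-sided Mann–Whitney. On fully
uncoupled synthetic colonies the resulting p-values are uniform across
replicate colonies (null calibration); on coupled colonies the real arm
separates at p < 0.01 with 20 flights.

## Leadership segments and durations

Leadership is positional: maximal constant-sign runs of d_EN. Exact zeros
and masked samples extend the incumbent's run — the front/back assignment
has metre-scale GPS noise near zero, so a sign flip, not a missing or zero
sample, is the only evidence of a leadership change. An optional hysteresis
band (|d_EN| < 1.69 m keeps the incumbent) is off by default. Durations are
fit by maximum likelihood to log-normal and exponential families, compared
by AIC and KS distance; this stands in for a fuller model-selection
procedure and is labelled as such in reports.

## Exploration and exploitation

A focal sample is exploring when its minimum distance to the baseline
trajectory exceeds 300 m, the threshold below which an established bird
stays on its idiosyncratic route; equality counts as exploitation
("remains within"). Distances are vertex-to-vertex (at 5 Hz and ~20 m/s
the ~4 m spacing is negligible against 300 m). Baselines: model A uses the
previous release (generation boundary: last release of the previous
generation); model B uses the last release of the previous generation for
the whole generation, isolating the information available to the
experienced bird at the generation start. Paired flights are represented
by the pair-mean trajectory on both sides. The first release of
generation 1 has no baseline and is excluded.

Phase-transition initiators are attributed to the front bird at the first
sample of the new phase (the front bird is the more informative one at
short range, so it is the proximate driver); masked or abreast onsets fall
back to the nearest preceding valid sample. A majority-over-1 s variant is
available behind a flag. Initiation asymmetry is tested with the exact
two-sided binomial test.

## The paired-flight simulator

Two birds move at constant speed (20 m/s — a conventional cruise speed;
the sampling step is 0.2 s) with headings updated as normalised weighted
sums of unit vectors (never raw angle averages, which wrap). One bird is
the latent leader: it blends heading persistence with the bearing to its
goal (weight `beta_home = 0.2`), the goal being home or, during an
exploration bout, an off-route waypoint. The follower blends persistence,
the leader's heading `tau` steps earlier (`w_couple`), and attraction to
the partner beyond a cohesion radius (`alpha_attract`, radius `r_coh`;
inside the radius the attraction weight reverts to persistence so the
blend stays convex). Wrapped-Gaussian heading noise
(`sigma_heading = 0.12` rad/step by default) perturbs every step. Leader
identity flips per-step with probability `q_switch` (geometric run
lengths; a log-normal run-length mode exists so the duration-fit machinery
can be validated against both families). All randomness for one flight
flows from a single seeded generator; runs are bit-for-bit reproducible.

Route fidelity defaults (`beta_home = 0.2`, `sigma_heading = 0.12`) keep
an established flight's lateral spread about its corridor at ~40 m median,
~100 m 95th percentile — comfortably inside the 300 m labelling envelope,
as established real birds are. Exploration bouts are near-perpendicular
darts: a waypoint 300–1000 m lateral to the current along-track position
(400–1000 m in the validation chains), then re-entry towards a corridor
point ~150 m ahead, ending within 150 m of the corridor. The dart shape is
deliberate: it guarantees bouts cross the 300 m threshold, and it keeps a
baseline flight's own bout from leaving a kilometre-scale hole in its
coverage of the corridor, which would otherwise mislabel the next flight's
corridor-following as exploration. Transmission-chain flights truncate on
arrival at the loft, as real GPS tracks do.

Ground truth records three per-step channels: the latent leader, the
mechanistic in-bout flag, and a geometric exploration state (farther than
300 m from the ideal release–home corridor, on the pair midpoint for pairs
or the bird itself for solos). The geometric state is the labelling
oracle: a distance-threshold labeller cannot attribute boundary-transit
time, so the mechanistic flag would make any labeller look wrong at the
edges of every bout.

Transmission chains: generation 1 is 12 solo releases of the founding
bird; each later generation pairs the previous naive bird (now
experienced) with a fresh naive bird whose bout-start probability is
elevated early in the generation (×(1 + 5·exp(−(r−1)/2.5))) and decays to
baseline — newly introduced birds drive early exploration. Route memory
beyond the shared corridor (e.g. following the precise previous GPS track)
is not modelled. The base bout rate in the validation chains (2×10⁻⁴ per
step, ~0.7 bouts per flight) matches the "occasional bout" regime the
labeller is meant to segment.

**Coupling timescales.** With heading-level blending, the follower's
heading relaxes towards the leader's over ~1/(1−persistence) steps, so at
moderate coupling (w = 0.6) the symbol-level information transfer spreads
over ~2 samples and a period scan peaks at 0.4 s rather than the coupling
delay itself. Only at strong coupling (w ≥ 0.8) does the transfer
concentrate at the sample scale; the period-scan validations use such
colonies. This is a property of the generative model, worth keeping in
mind when interpreting scan results on data simulated at weaker coupling.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that every stage recovers known ground truth
under the generator's assumptions: closed-form TE on analytic channels,
coupling direction and monotonicity in coupling strength, front-bird
dominance of local TE, null-calibrated surrogate comparison, geometric
run-length statistics, and ≥0.8 Jaccard recovery of exploration bouts.
Real data differ in ways the generator does not emulate: GPS noise and
dropouts, wind and terrain steering, route memory of idiosyncratic
(non-beeline) corridors, speed variation, and leadership that responds to
position rather than an autonomous Markov chain. Results on real tracks
therefore inherit the method's assumptions (binary symbolisation, per-
flight plug-in estimation, positional leadership), not the generator's.

## Problem sizes

The validation suite and the reproduction script run on desk-scale
problems chosen to make each effect statistically resolvable at comfortable
margins: 10⁵-symbol analytic channels; 20-seed directionality replicates at
20,000 steps; a 64-pair colony (3,000 steps each) for the local-TE-by-
distance profile; 30–50 replicate 6-pair colonies for null calibration;
and 3-generation × 12-release chains at 3,600 steps for the labelling
checks.
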