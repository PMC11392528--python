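# Methods

This note documents the models, rules and numerical choices behind
`flockgaze`, the assumptions they rest on, and what the synthetic-data
validation does and does not establish.

## Head frame, pose fitting and egocentric projection

The head-local frame is anchored to three calibration keypoints expressed
in the head-marker cluster frame: the two eye centers and the beak tip.
X is the unit vector from the left to the right eye; the beak principal
axis (eye midpoint → beak tip, orthogonalized against X) is rotated upward
about X by exactly 30° to give the forward axis Y, because a standing
pigeon carries its beak about 30° below its visual horizon; Z = X × Y.
The rotation is a proper orthonormal matrix by construction, and the
construction is equivariant under rigid motions of its inputs (tested).

Per-frame head pose is an orthogonal-Procrustes (Kabsch) fit of the
4-marker template to the observed markers, all visible markers weighted
equally. Frames with fewer than three finite markers are *missing*, not
errors — dropouts are routine in marker tracking. The full-frame case is
vectorized (batched SVD); partial frames fall back to a scalar path.

Egocentric angles use the signed convention azimuth = atan2(x, y)
(0 = straight ahead, positive to the animal's right) and
elevation = atan2(z, √(x²+y²)). Azimuth sign is a package convention — it
follows from the right-handed frame with X = right; nothing downstream
depends on the sign, and mirror symmetry (reflection about the sagittal
plane swaps the eyes' verdicts exactly) is enforced by test.

**Foveal region.** Each fovea projects at ±75° azimuth, 0° elevation. The
foveation test is *rectangular* in angle space — |azimuth ∓ 75°| ≤ 10° and
|elevation| ≤ 10°, inclusive — matching how visual-field heatmap cells are
scored, rather than a great-circle cone; `offset_from_fovea` provides the
great-circle distance separately for diagnostics. An object is foveated
when its sphere *center* satisfies the test for either eye; the
angular-radius overlap alternative was considered and rejected as the
default because it makes the verdict depend on distance in a way the
rectangular region does not. Eyes are not distinguished in any output
(a foveation by either eye counts), since the downstream statistics never
separate them. Default object radii — monitor 0.35 m, hiding table 0.65 m,
conspecific 0.15 m — are scene-config values chosen from the physical
dimensions of the equipment and of a pigeon; only sphere centers enter the
default test.

## Preprocessing

Sampling is 60 Hz throughout. Gap filling interpolates positions linearly
and orientations by slerp across gaps of at most 0.2 s (12 frames); longer
gaps stay missing, and observed frames are never altered. Smoothing is a
zero-phase centered moving average (default window 0.1 s) with window
shrinkage at the ends; orientations are averaged as sign-aligned
quaternions and renormalized, which is accurate for the small within-window
rotations of a head-pose stream. Implausible-motion removal masks frames
reached at > 20 m/s translation or > 3000 °/s rotation — far beyond pigeon
kinematics, so only tracking glitches are caught; the thresholds are
config-exposed. These three steps are a deliberately simple, transparent
substitute for vendor-specific mocap filtering chains whose exact dialects
vary between labs; all parameters sit in `RunConfig`.

**Saccades.** Angular speed is the geodesic angle between successive
orientations times the rate, assigned to the transition's first frame. A
saccade is a maximal run of transitions above 60 °/s lasting at least
50 ms whose *net* start-to-end rotation exceeds 5°. Net displacement, not
cumulative path, is used for the amplitude: "a head movement larger than
5°" reads most naturally as displacement, and the two differ only for
curved saccades (a sensitivity flag would swap one line of code).
Fixations are the complementary intervals, so saccades and fixations
partition valid frames exactly.

## Ethogram

All rules are simple thresholds on 3D posture; the constants sit in
`RunConfig` with these defaults:

| rule | definition |
|---|---|
| head_down | head centroid strictly below the body centroid (6 cm below the back-cluster center) |
| pecking | beak < 4 cm above ground and pitch > −100°; event at the beak-height minimum of each low run (earliest frame on ties) |
| feeding | any time between two pecks ≤ 6 s apart |
| grooming | back-preen: head-direction vs body→head angle > 60° and beak-to-body < 0.10 m, or > 40° with the head above the body; breast-preen: pitch < −100°, or pitch < −80° with angle > 60°; scratch: \|roll\| > 50° with the head < 3 cm above the body |
| courting | ≥ 2 bows in any 8 s window, within 0.6 m of a neighbor faced within 120°; episodes < 1 s dropped |
| running_away | speed > 0.6 m/s and d/dt(distance to monitor) > 0.2 m/s, not courting; runs < 70 ms dropped |
| flying | speed > 2 m/s; runs < 70 ms dropped |
| head_up | residual valid frames |

Pitch is the elevation of the head's forward axis extended past ±90° by the
dorsal axis (atan2 of forward-z over dorsal-z), so a breast-preening head
tipped "upside-forward" reads below −90°, as the −100° threshold requires;
range (−180°, 180°].

**Bows.** The courting rule needs a bow definition the source rules leave
open. A bow here is a pitch dip ≥ 25° below the bird's rolling median
(10 s window) that returns within 2 s, and — because bowing is a display
performed down-and-back-up from an upright stance — the rolling baseline
and the median pitch in the half-second before and after the dip must all
be upright (> −30°). Without the upright conditions, pecking dips from a
head-down foraging posture satisfy the depth criterion and feeding birds
standing near a neighbor would be classified as courting. The "courted"
partner is identified from the courter's orientation cone only (the
nearest eligible neighbor), not mutual orientation.

**Radial speed** for the running rule is a 0.25 s centrally differenced
distance-to-monitor series; a single-frame derivative at 60 Hz is too noisy
to hold a 0.2 m/s threshold. Which monitor is "the" monitor follows the
event timeline (the most recently presented side).

**Precedence.** Co-firing rules resolve as
flying > running_away > courting > grooming > feeding > head_down > head_up.
Locomotor escape dominates so that escape latencies can never be masked by
a concurrent feeding or grooming label; head_up is defined as the residual.

## Gaze events and latencies

Foveation events are maximal runs of foveated frames *after* saccade-frame
removal — a saccade crossing a long foveation splits it, and each half is
measured against the 300 ms minimum on its own (300 ms ≈ the lower end of
pigeon intersaccadic intervals; shorter crossings are chance alignments).
Latency to foveate is the start of the first qualifying foveation on a cue
object (the active monitor or its hiding table) at or after 200 ms past
loom onset — pigeon reaction times exceed 200 ms, so earlier "responses"
mean the gaze was already there. If the first qualifying cue foveation
begins only after the looming stimulus ended, the observation is excluded
(returned as missing): that gaze targets the model predator, not the cue.

Escape latencies are the onsets of the first running-away and flying
intervals after loom onset; escape-before-offset is true when the earlier
of the two precedes the loom offset. The response delay is
t_fly − t_foveate. Visual-field heatmaps bin the object direction into
5° × 5° cells (azimuth bins left-closed from −180°, boundary angles to the
higher bin, the 180°/90° edges folded into the last bin) over the window
from loom onset to the first escape response of *either* kind (run or
fly — the earlier one truncates, since either ends "pre-escape" viewing);
counts are unit-sum normalized and the summed frequency in the two foveal
rectangles is clipped to [1e-4, 1−1e-4] before the logit.

Before-cue metrics summarize the 120 s before loom onset: proportion of
valid frames head-up, pecks/s, saccades/s, and proportions of time
foveating any monitor and any conspecific (qualifying foveation events
clipped to the window).

## Contagion permutation test

Within an event with n ≥ 2 responders, the statistic is the mean of the
n − 1 successive gaps of the sorted latencies. Events are paired within
session and presentation side across the two flocks (each event in exactly
one pair; unmatched events are reported). For a pair, the pooled latencies
are reassigned uniformly at random between the two events with group sizes
preserved; the pair statistic — observed and per permutation — is the
gap-count-weighted mean over the two events. Aggregation over pairs pools
gap sums and counts, with each pair permuted independently from one seeded
stream. The p-value is the raw proportion of permuted statistics ≤ the
observed one: ties count as extreme (conservative for a "smaller than"
alternative), and no +1 smoothing is applied by default (a `smoothed` flag
adds it). Degenerate pooling (all latencies identical) warns and yields
p = 1. Birds without the response are simply absent from that event's
latency set.

The distance-overlap control intersects the two flocks' distance-to-monitor
ranges ([max of minima, min of maxima], inclusive) and keeps only birds
inside it; pairs with disjoint ranges, or where a filtered event retains
fewer than two birds, are dropped and reported.

Per-pair permutation with a pooled statistic (rather than one global
permutation across all pairs) is the implemented variant: it preserves each
pair's group sizes and keeps latencies exchangeable only within their
matched pair, which is the exchangeability the matching is meant to buy.

## Synthetic flock generator

The generator is first-class, tested code; its defaults are the study
conditions it emulates.

*Design*: 20 birds, 6 sessions, two flocks of 10 per session, every pair of
birds sharing a flock at least once (greedy randomized search over
candidate splits with restarts), two events per flock session with North /
South order counterbalanced within session — 12 flock sessions, 24 events,
240 bird × event observations.

*Scene*: a 15 × 7 × 4 m room; monitor-on-table assemblies at two opposite
corners (> 12 m apart), sphere radii 0.35 m (monitor) and 0.65 m (table);
a central feeding area equidistant from both monitors.

*Behavior*: each bird walks a correlated random walk at ~0.1 m/s inside the
feeding area, alternating pecking bouts (inter-peck 0.9–1.6 s, beak dipping
to ~2 cm), head-up scanning (fixations 300–800 ms, saccades 10–60° at
100–400 °/s), and occasional breast-preening bouts. Scan headings are drawn
so that neither monitor enters the foveal azimuth band before the scripted
detection — otherwise chance foveations would corrupt the known detection
times that make latency recovery testable. At each event the bird saccades
onto the active monitor at its drawn detection time (lognormal, median 3 s,
clipped inside the loom), holds it foveated (≥ 0.55 s), runs away at
1 m/s after a lognormal delay (median 5 s), flies at 3 m/s at the time
given by the contagion model, lands, and walks back to forage. Flight
times are kept exactly as the contagion model draws them; the run onset is
pulled earlier if needed, so the coupling structure the permutation test
must detect is never distorted.

*Contagion model*: with coupling c = 0, flight latencies are i.i.d.
lognormal (median 12 s, σ = 0.4 — flights cluster after the model predator
appears). With c > 0, every bird other than the earliest flyer flies at the
first flight time plus an Exp(0.3/c s) lag, truncated at its own
independent draw. The lognormal/exponential forms are generator choices
(real latency histograms are empirical); all parameters are config-exposed.

*Markers*: 4 head markers on a ~3 cm cluster (calibration keypoints in a
deliberately rotated/translated cluster frame, so the axes construction is
exercised nontrivially) and 4 back markers on a 7 × 3.5 cm plate following
the body heading; isotropic Gaussian noise, default SD 1 mm. Identical
seeds reproduce byte-identical CSVs; each trial renders from its own seeded
substream.

*Ground truth* applies the behavior definitions to the scripted, noise-free
kinematics (head/body heights, scripted peck times chained by the 6 s rule,
scheduled locomotion intervals, the grooming posture rules on scripted
pitch/roll), with the classifier's precedence. The pipeline route —
noisy markers → Procrustes → conditioning → detectors — is what validation
exercises against it.

**What passing these checks shows — and does not.** The generator produces
piecewise-scripted kinematics with clean transitions, stationary noise,
no marker identity swaps, no occlusion structure correlated with behavior
(real head-data loss concentrates in self-occluding grooming), no eye
movements, and behavior frequencies that are plausible but not fitted to
any recording. Recovery therefore demonstrates internal consistency and
correctness of the geometry, detectors and statistics — not field accuracy
of the thresholds on real birds, which the original validation against
human raters addresses.

## Numerical and scale choices

- Durations are counted in transitions (run length / rate) with a 1e-9
  tolerance at rule boundaries; inclusive boundaries are used wherever a
  printed rule says "within".
- Per-transition speeds are assigned to the transition's first frame, so
  detected locomotion onsets can lead scripted onsets by one frame;
  foveation latency recovery is exact to one frame (1/60 s) at zero noise
  with smoothing off, and degrades to a few frames with 1 mm noise and the
  0.1 s smoothing window (the window smears the saccade landing).
- Permutations are vectorized (argsort of uniforms); a permutation row's
  gap sum telescopes to max − min per group, but the implementation sorts
  and differences to keep the statistic's definition literal.
- Tests and the acceptance script run the generator with shortened feeding
  periods (30 s before-cue and inter-event instead of 120 s) and, for
  recovery checks, two 10-bird sessions; these are problem-size choices
  that leave every rule and threshold at its default. The permutation
  calibration uses 500 replicate designs at 1,000 permutations; the
  package default for analyses is 10,000 permutations.
- The pipeline-recovery checks disable smoothing because their input is
  noise-free; smoothing exists to suppress marker noise and only blurs
  scripted transitions there.

## Known limitations

- The rectangular-versus-conical foveal test is a genuine open point of the
  underlying definitions; the rectangle was chosen for consistency with the
  heatmap scoring, and `offset_from_fovea` supports re-analysis.
- Courting detection depends on the bow definition above; birds that bow
  from a non-upright posture would be missed.
- The distance-overlap control can cut deep when two paired flocks occupy
  different distance bands (e.g. one flock's event follows a recent
  regrouping); pairs reduced below two responders per event are dropped
  rather than imputed.
- Orientation averaging by quaternion mean is a small-angle approximation;
  at the 0.1 s default window and 60 Hz it is indistinguishable from the
  exact Karcher mean.
- No eye-in-head movement is modeled; the ±10° margin absorbs it by
  design.
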