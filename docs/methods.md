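# Methods

This note documents the models, procedures and numerical choices behind
`flysocial`. It is the package's own account of its science; every number
shown here is computed by the test suite or the analysis scripts.

## The system being modelled

Groups of ~50 walking flies (body length 2.5–3.3 mm) in a circular arena
of 90 mm internal diameter spontaneously aggregate into a single ordered
cluster with near-crystalline local spacing (~4.7 mm between contiguous
neighbours, bodies never closer than ~2.5 mm). The package quantifies that
aggregation at three levels: static spatial statistics of one snapshot,
tessellation-based cluster structure, and the trajectory-level dynamics
(dyadic encounters and nascent clusters) through which the cluster grows.

## Synthetic worlds

All testing runs against generated scenes whose structure is known
exactly.

**Clustered configurations.** Seeded growth on a triangular lattice of
pitch `spacing` (default 4.7 mm): the *n* lattice sites closest to a
cluster centre are taken in radius-then-angle order, each perturbed by
isotropic Gaussian jitter (default sd 0.5 mm) and re-drawn (bounded
retries) until no pair violates the contact floor (default 2.5 mm). The
cluster centre is drawn uniformly over positions where the lattice fits,
because real clusters nucleate anywhere in the dish — this matters for the
"random flies" null, which only de-correlates positions if the source
clusters do not all sit in the same place. Ground truth marks all flies as
one cluster.

**Dispersed configurations.** The hard-core sampler (below) dressed with
fly bodies. An optional `margin` keeps centres away from the wall when
whole bodies must fit inside the dish (used by the imaging tests, where a
body clipped by the arena rim would bias its centroid).

**Body sizes.** Lengths ~ Normal(2.8, 0.2) mm truncated to [2.5, 3.3];
widths ~ Normal(1.0, 0.08) truncated to [0.8, 1.2]; orientations uniform.
The source study gives no per-fly size distribution, only the 2.5–3.3 mm
range ("5 mm ≈ 1.5–2 body lengths"), so the distribution shape is a
package choice.

**Scripted trajectories.** Walkers move on constant-speed (5 mm/s)
straight segments; everything else is stationary. Each scripted encounter
gets a "station" on a 12-slot ring at r = 30 mm: the interactee sits at
the station, the interactor approaches from 10 mm along the inward radial
corridor so the pair separation crosses 1.5 × mean body length exactly at
the scripted time, dwells 0.6 s at 2 mm, then both flies realise their
scripted stay/move outcomes (a moving interactor retraces its corridor; a
moving interactee leaves at 135° from the interactor so its walk never
faces it). Station geometry guarantees that no mover ever passes within
contact distance of an unrelated fly, so the scripted event list is
exactly the set of events a correct detector can find. Pairs may meet
repeatedly at their station when the previous event left it clear.
Unrealisable scripts (events before the recording starts, a station still
occupied, a fly scripted with two partners) raise a script error rather
than producing quietly wrong ground truth.

**Cluster assembly scenes.** Flies walk from a start ring to triangular
lattice slots at 3 mm pitch (inside the 1.5-body-length proximity
threshold) at scripted join times, optionally dispersing later; arrival
and departure frames form the ground-truth event log.

What the generators do **not** emulate: gait, grooming, wing posture,
heading fluctuation of standing flies, photorealistic texture, identity
swaps or missing detections. A green test therefore establishes that the
analysis recovers the stated structure from idealised kinematics and
rendering — not that it is robust to tracking noise in real video.

## Detection

Background = per-pixel maximum over the stack (dark flies vanish wherever
they move; the minimum is used for bright flies). A fly that never moves
survives into the background and is invisible to subtraction — an inherent
limitation, kept and tested. Segmentation thresholds |background − frame|
inside the arena mask (Otsu on the masked difference when "auto"),
labels 8-connected components, and drops components below 25% of the
median component area (noise rejection without a hand-set constant; both
the threshold rule and the blob floor are package decisions, not source
facts). Each component is reduced to its moment-equivalent ellipse:
centroid, axis lengths 4·√(eigenvalues of the second central moments)
— exact for a filled ellipse — and major-axis orientation in [0, 180).
Touching flies are not split; merged blobs are flagged by a fill-factor
test (pixel count vs moment-ellipse area outside [0.85, 1.15]).
At 10 px/mm the render-and-recover error is < 0.05 mm in centroid and
< 2° in orientation (acceptance suite).

## Tessellation and clusters

Residing areas are computed as the generalised Voronoi diagram of the
body silhouettes: silhouettes are rasterised (default 10 px/mm; bulk test
sweeps use 5 px/mm), and every interior pixel joins the nearest silhouette
via a distance-transform label propagation. This is declared equivalent to
the morphological Euler-preserving shrink that motivated it: both produce
the partition of the arena into cells nearest each fly, and the pixel
partition conserves the masked arena area exactly. Pixels equidistant from
two silhouettes follow the distance transform's deterministic internal
tie-break (measure-zero effect). Contiguity uses 8-neighbour pixel
adjacency between cells; `touches_edge` marks cells reaching the arena
rim. On random point patterns the contiguity graph agrees with an
arena-restricted Delaunay oracle on ≥ 95% of edges; disagreements are
confined to ridges barely clipped by the rim and to near-degenerate
quadrilaterals.

Cluster reconstruction: basic clusters are contiguity-connected components
of flies whose cell is below the area threshold; the expansion loop adds
any fly whose centre-to-centre distance to a member is below the distance
threshold, iterated to a fixpoint (a fly reachable from two clusters joins
the nearest member's cluster; ties go to the lower cluster label).
Clusters below 5 members are discarded — the source defines no floor for
"formed a cluster", and 5 matches the small-cluster floor used by the
dynamics stage; it is configurable. Insiders are members whose contiguous
neighbours all belong to the same cluster and whose cell avoids the edge.
Relaxing SF enlarges both thresholds, so membership grows monotonically
from CSC 1 to CSC 5 (asserted on 100 configurations).

DCN (distance of contiguous neighbours) spread is reported per inner fly
(cell not touching the edge) as the standard deviation of its link
lengths. The arena-level "more clustered subset" filter keeps inner flies
below the arena median spread — an interpretation of a loosely specified
secondary filter, flagged as such.

## Spatial statistics

Distances are centre-to-centre throughout. NND ties resolve to the lower
fly id; SSI bins are half-open. Surround profiles superimpose each fly as
the reference by translation only (no rotation or heading alignment).
Edge correction is per annulus: each reference's count in an annulus is
multiplied by full-annulus area / in-arena annulus area, the latter from
differences of the closed-form circle–circle ("lens") intersection between
the arena disc and the measuring circle. Density uses cumulative counts
over cumulative in-arena area, averaged across references (the cumulative
rather than per-annulus normalisation is a package choice; the per-annulus
quantity is recoverable from the tidy output). Annuli with zero in-arena
area contribute nothing.

## Null models

**Random dots.** Sequential inhibition: points placed one at a time,
uniform in the disc, rejecting candidates within the hard-core distance of
accepted points (10⁴ attempts per point, then an infeasible-packing error
reporting the achieved count). Hard-core 0 reduces to binomial CSR, which
passes a quadrat chi-square against uniformity and matches the Poisson
NND law on an edge-free torus variant (mean NND = 1/(2√λ), G(d) = 1 −
exp(−λπd²)). Note that sequential inhibition and Matérn type-II thinning
have different n-point distributions even though the two labels are often
conflated; the sequential form is implemented because it is the stated
construction, and the torus sampler exposes the same inhibition rule
without edge effects.

**Random flies.** Records pooled across source arenas are taken in seeded
random order at their original coordinates; a candidate whose body ellipse
(32-vertex polygon intersection, via shapely) overlaps an accepted fly is
discarded; an insufficient-pool error is raised if the pool runs out.

## Force field

Profiles are exponential: attraction amplitude 1 at scale 20 mm, repulsion
amplitude 50 at scale 2 mm (C factor 50). The true profile shapes are not
recoverable from the source text, so the functional form and defaults are
package choices with the stated qualitative structure (broad weak
attraction, local strong repulsion); everything is parameterised. For a
single source the net radial force crosses zero at
ln(C)/(1/s_r − 1/s_a) = ln 50/0.45 ≈ 8.69 mm, and the crossing survives
scaling C by 0.1–10×. The walker is overdamped: step = gain × net force
(gain 2, capped at 1 mm) plus isotropic noise; it settles when its
distance to the nearest set fly drifts less than max(0.02 mm, noise sd)
over a 50-step window, and the settle distance is that window's mean. The
set is static (an established small cluster is assumed unaffected by one
approaching fly); there is no many-body simulation and no fitting of the
profiles to data.

## Dynamics

Speeds come from boxcar-smoothed positions (5 frames) and centred
differences at the 50 frames/s default rate; headings from the smoothed
velocity. "Stationary" is speed < 0.5 mm/s sustained over 0.5 s — a
package definition, well below walking speeds. The encounter predicate
(per ordered pair and frame): distance ≤ 1.5 × mean pair body length,
interactor above and interactee below the stationary threshold, interactee
bearing within ±90° of the interactor heading. Qualifying runs merge
across gaps < 0.25 s. Outcomes use net displacement over 2 s after offset
against a threshold of 1 body length (both windows are package choices;
the source states stay/move without thresholds). The paired net-outcome
statistic is %both-stay − %both-move.

Small clusters are per-frame proximity components of ≥ 5 flies linked
across frames by member-set Jaccard ≥ 0.5 (greedy best match; a chain with
no match terminates). Lifetime boundaries are honoured exactly: < 5 s
discarded, [5 s, 60 s] transient, > 60 s mini. NSI is the signed ratio
(size at onset+60 s − size at onset)/size at onset, computed at the last
frame and flagged when the event is shorter (the source names the index
but not its formula; the signed ratio is switchable). Stage summaries
count encounters in the [5,10), [10,15), [15,20) minute windows and read
first-crossing times for sizes {10, 25, 45} off the growth curve.
Whether "1.5 body lengths" means the approacher's, the target's or the
mean body length is unstated; the mean is used everywhere.

## Known limitations

- No identity tracking across frames: trajectories must arrive with ids.
- Touching flies are segmented as one blob (flagged, not split).
- The tessellation needs disjoint silhouettes; overlap raises an error
  listing the offending flies rather than guessing.
- Background estimation cannot see a fly that never moves.
- The force-field profiles are a stated-structure stand-in, not a fit.
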