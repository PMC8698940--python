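# Methods

## The measurement problem

Neonatal rodent prostate lobes cultured on filters branch over a few days,
and the branching pattern is lobe-specific: the ventral prostate (VP)
grows 3–5 long main ducts and ramifies to the fourth branch generation,
while the lateral prostate (LP) grows 5–6 shorter ducts and stops at the
second; the LP1 sub-lobe produces long original ducts with only
first-generation branches, LP2 a compact bush reaching the third
generation. Quantifying this requires (i) a skeletal map of every duct at
every imaging time point, (ii) branch-generation labels defined by
descent — primary buds emerging from the urogenital sinus (UGS) are the
original ducts (generation 0), branches forming off them are generation 1,
and so on, and (iii) a temporal classification of each branching event as
a terminal bifed (a tip splits in two), a terminal trifed (in three), or a
lateral side branch (a new branch from a duct interior, leaving the parent
tip intact). The central methodological point is that the classification
is *temporal*: a static end-point image of three tips clustered at the end
of a duct is compatible with three different histories (trifed,
bifed-then-bifed, bifed-then-lateral), and only sequential imaging can
separate them. `ductmorph` implements that entire measurement chain, plus
a stochastic growth simulator that stands in for the organ-culture imaging
and supplies exact ground truth for validating the chain.

## Growth model

Ductal trees grow in continuous time in a 2-D field:

- **Originals.** `n_original_ducts` buds (fixed or drawn from an inclusive
  range, e.g. 3–5 for VP) start on a vertical UGS anchor line with initial
  length `initial_bud_length_um`, fanned over `±fan_half_angle_rad`.
- **Elongation.** Each free tip advances at `elongation_rate_um_h`
  (optionally scaled per generation; LP1 uses (1.3, 0.8) so its original
  ducts outpace its sparse first-generation branches). Geometry is laid in
  2 µm steps whose direction performs a Gaussian random walk (σ = 0.04 rad
  per step) clamped to ±0.5 rad around the branch's birth direction.
- **Branching.** Every unstalled tip whose segment generation is below
  `max_generation` carries a constant hazard `tip_branch_hazard_per_h`;
  the event type is drawn from `event_type_probs`
  (bifed, trifed, lateral). A drawn "lateral" is re-sited to a uniform
  interior position of the tip's own segment, so laterals emerge from
  mature duct interiors. An optional second channel generates laterals at
  `lateral_hazard_per_h_per_100um` of eligible duct; because eligible
  length grows linearly between events, the integrated hazard is quadratic
  in time and the next event time is solved exactly by inverse transform.
  This channel is off (0) in all lobe presets, so the realized type mix is
  exactly multinomial in `event_type_probs` — matching how the tissue data
  report a single per-event mix (42.3 / 19.7 / 38.0 % for control VP).
- **Terminal vs lateral semantics.** A terminal event consumes the parent
  tip (the 2 or 3 daughters take over); a lateral leaves the parent
  growing. A lateral daughter increments the generation exactly like a
  terminal daughter, because generations count descent, not event type.
- **Collision handling.** An occupancy grid rejects any step that would
  bring a duct within `clearance_um` (18 µm = 2.25 duct widths) of a
  foreign duct, with exemptions inside 40 µm of shared junctions (where
  sisters necessarily start close). A blocked tip retries a fixed fan of
  deflections and then stalls: it stops growing and branching but remains
  a free end. A terminal event whose daughters' very first step would be
  blocked is cancelled and not logged (contact inhibition) — every logged
  event is physically real and in principle visible. Lateral siting draws
  a uniform arc fraction in (0.1, 0.9) and redraws (up to 20 times) any
  position within `min(1.5·w, L/4)` of an existing node — the segment's
  origin, its distal tip, or a prior lateral — so branch points never
  coincide; only segments shorter than ~8 µm have no legal interior.
  These rare discards keep the realized type mix within ±0.01 of
  `event_type_probs` (measured 0.425 / 0.201 / 0.374 against
  0.423 / 0.197 / 0.380 over 4000 events).

Identical configurations (including the seed) give bit-identical trees,
logs and rendered stacks. Configurations whose crude branching-process
bound exceeds `max_events` (default 5000) are rejected as runaway.

### Preset calibration

The tissue study gives no rates or hazards; its curves are measurements,
not model parameters. Presets are therefore calibrated to the *relational*
phenotypes: generation caps (VP 4, LP 2, LP1 1, LP2 3), duct counts and
relative original-duct lengths, VP ≫ LP in tips and length with a contrast
clearly detectable at n = 6 contralateral pairs (VP ≈ 30 vs LP ≈ 10 tips
at 90 h), and LP1 fewer tips / longer originals than LP2. Treatment
multipliers scale (elongation, branching): FGF10 (1.3, 1.8) up;
inhibitors down with ML-7 (0.5, 0.2) strongest, then Y-27632 (0.7, 0.4) ≈
U0126 (0.7, 0.45), and C3 transferase (0.8, 0.6) weakest — reproducing the
reported ordering of inhibitory strength. Mean final tip count is strictly
increasing in the branching multiplier across these presets.

## Imaging and skeletonization

Frames are rendered at 30-min intervals (2 µm/px, ducts as 8-µm tubes,
background 10 / foreground 200 on uint8, optional Gaussian noise).
Rendering is incremental over the monotone growth history, so foreground
never shrinks. Analysis steps:

1. **Binarize** at a given threshold, or the midpoint of the intensity
   range; an empty foreground raises a "no tissue" error.
2. **Thin** with Lee's topology-preserving method. This choice is
   load-bearing: classic two-pass thinning retracts diagonal tube ends by
   an amount that oscillates frame-to-frame by up to ~19 px, which
   destroys tip tracking; Lee's method is stable within ~1 px.
3. **Trace** the skeleton into a measured graph: nodes at pixels of
   skeletal degree ≠ 2 (adjacent node pixels merged, restoring atomic
   trifurcation points), edges carry the ordered pixel path and a length
   (axial step = pixel size, diagonal = √2 × pixel size — transparent and
   bit-reproducible). Endpoints near the anchor line are roots. Cycles up
   to 30 µm (thinning artifacts at thick junction blobs) are collapsed by
   dropping their longest edge; larger cycles (genuinely overlapping
   ducts in 2-D projection) raise an error rather than being guessed at.
4. **Prune** tip-terminated edges shorter than 2 duct widths, protecting
   tips accepted in the previous frame (the tracking hook); idempotent.

## Tracking and event classification

One pass over the frames maintains a track per duct segment. Branch nodes
are matched against a registry of known junctions; a genuinely new
junction is classified through the rooted skeleton: it is a **terminal**
locus of track T if it lies distal of T's tip (or within a 25 µm proximal
allowance — a bifed can be discovered late, after the tip was mistakenly
advanced along one daughter while the other was still buried in the parent
tube), and a **lateral** locus otherwise. A branch appearing within
(w/2 + 2 px) of a junction recorded in the last two frames extends that
event — this is how a trifed whose third daughter protrudes a frame late
is upgraded from the provisional bifed, while a genuine sequential bifed
on a daughter (≳13 µm away at the earliest it can be seen) opens a new
event.

A terminal locus whose distal structure holds three leaves through two
junction clusters separated by `d` is resolved by geometry and time:

- *trifed* is a candidate when `d` ≤ 2 duct widths (thinning can split one
  trifurcation into two nearby junction pixels);
- *bifed-bifed* when the two junctions are distinct (≥ 2 px), the two
  inner branches have equal length (daughters born together grow alike;
  tolerance max(8 µm, 25%)), and the bracketing interval is longer than
  `min_event_separation_h`;
- *bifed-lateral* when the inner branches are clearly unequal (a lateral
  daughter is younger, hence shorter, than the continuing branch).

`min_event_separation_h` (default 0.5 h) encodes the operational
assumption that true events at one locus are separated by at least the
fine imaging cadence — the assumption under which 30-min imaging resolves
event order. At 30-min analysis an interval can hold only one event, so
the structure resolves; at 10-h analysis both trifed and bifed-bifed
survive and the locus is emitted as a single event with `ambiguous=True`
and the candidate set. Ambiguous events are never silently resolved;
morphometry tallies them separately. A first event at a fresh tip locus is
necessarily terminal (there is no interior yet), which is why
lateral-first sequences never appear among candidates.

Track lengths are measured per frame as the geodesic between the nodes
nearest the track's origin and tip. The raw chain-code length of a digital
line overestimates slanted paths by up to 8%, so the geodesic pixel path
is resampled every 4 px before summing. Two end corrections compensate
thinning: +(w/2 − 1 px) per free end (tube-end retraction) and +w/2 at a
daughter's junction origin (its medial axis emerges only outside the
parent tube). With these, per-generation aggregate lengths on clean
rendered stacks agree with ground truth to within ~3.5%.

## Morphometry and statistics

The four kinetics read-outs per sample, time and generation: aggregate
ductal length, cumulative branch events keyed by the parent's generation,
total tip number (degree-1 non-root nodes), and cumulative type counts
with fractions over resolved events (undefined, and flagged, on an empty
log). Morphometry is sampled at 10-h marks by convention while detection
always uses every available frame. Tip conservation —
tips = originals + bifeds + 2·trifeds + laterals — holds exactly on every
simulated run and brackets the observed tip count when ambiguous events
are counted by candidate resolutions.

Group comparisons follow the organ-culture convention: mean ± SEM;
Student's t (paired for contralateral designs, else two-sample with pooled
variance — the era's default, recorded in the output); one-way ANOVA with
Bonferroni-adjusted pairwise post hoc tests against control for ≥ 3
groups. The multiple-testing family is the time grid within one metric,
because significance is reported per time point. Exact ties (zero
variance) are flagged rather than producing NaNs.

## Validation: the clean-separation regime

The simulator's ground truth turns the pipeline into a measurable
instrument. Oracle runs use a sparse configuration (3 original ducts,
hazard 0.012/h, 48 h, 640×640 px) *conditioned* on the clean-separation
regime — the conditions under which sequential imaging is informative, and
a slightly conservative reading of "events at one locus separated beyond
the frame interval", because a newborn daughter is invisible until it
protrudes about one duct width from the parent tube:

- events at one locus (within 80 µm) separated by ≥ 2.5 h;
- laterals ≥ 35 µm behind the parent tip at event time;
- no event within 3 h before a morphometry mark or the end of imaging
  (its daughters would still be invisible at the readout);
- no stalled growth, at least one event.

Under this regime, 50/50 stacks give precision = recall = 1 for event
type, parent and generation; morphometry counts are exact and aggregate
lengths within 5% (observed ≤ 3.5%). Outside the regime the detector
still runs but honestly reports ambiguity or raises (tracks lost, cycles)
rather than guessing.

## Event-sequence enumeration

`enumerate_event_sequences` makes the ambiguity claim exact: it
brute-forces every ordered event sequence up to `max_events` from a single
unbranched duct and counts those whose end state matches a target under
*observational* equality — segments born during the sequence are short on
the scale of a static image, so all structure in the new growth at the
parent's former tip collapses to one distal tip cluster, while laterals on
the pre-existing duct are distinct interior loci. Sequences are counted up
to isomorphism of their construction (a second bifed on either daughter is
one sequence). For the three-tip terminal cluster with `max_events = 2`
the enumeration returns exactly three sequences — bifed-bifed,
bifed-lateral, trifed — and, for example, excludes lateral-then-bifed,
whose end state has an observable interior junction on the original duct.

## Problem sizes

Defaults keep every analysis on one CPU core comfortable: validation
stacks 48 h × 30 min = 97 frames at 640² px (~1.4 s per full round trip);
statistical calibration uses 1000 null replicates of n = 6 paired samples
at 40 h and 100 power replicates at the full 90 h; type-mix recovery pools
≥ 2000 events (~80 VP runs). The full bundled VP-vs-LP experiment
(ground-truth morphometry, n = 5/group, 90 h) runs in seconds; with
imaging enabled it stays within minutes.

## Known limitations

- The simulator and analysis are strictly 2-D; real cultures are
  quasi-2-D and published tip counts labelled "3D analysis" may involve
  reconstruction this package does not model. Overlapping ducts in 2-D
  projection are rejected (cycle error), not resolved.
- Growth is monotone: duct regression, lumenization, mesenchyme and any
  molecular signalling state are out of scope; treatments are pure rate
  multipliers.
- Generation-dependent elongation is exposed but defaults to uniform;
  in vivo rates per generation are not quantified.
- The equal-length test behind bifed-vs-lateral discrimination assumes
  near-uniform elongation across sister branches; strongly heterogeneous
  growth would erode it.
- Classification near the junction-coincidence scale is
  resolution-limited: when two sequential events produce junctions within
  about one duct width of the 2-w coincidence threshold, whether the locus
  is reported resolved or ambiguous can turn on sub-pixel junction
  localization rather than on information content, and the
  refinement-monotonicity property is only meaningful away from that band.
- Event times are reported as bracketing-interval midpoints; detection
  lags truth by the daughter protrusion time (≲ 2 frames at default
  geometry), so kinetics at exactly event-adjacent marks are biased low.
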