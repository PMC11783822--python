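# Methods

## Problem and pipeline

Pelvic ring disruptions are graded with the first-order Tile AO/OTA scheme:
grade A (rotationally and translationally stable), B (rotationally unstable,
translationally stable), C (globally unstable). Radiologists derive the
grade from the pattern of CT findings — pubic symphysis diastasis (PSD),
anteriorly divergent vs. parallel sacroiliac joint diastasis, non-diastatic
and diastatic sacral fractures, ischial spine avulsion, and other pelvic
ring fractures — together with patient age, since fragility in patients of
60 years and over modifies fracture expression. The package mirrors that
workflow: detect findings per 2D slice, aggregate them into robust 3D
findings with uncertainty, then reason over finding presence with an
expert-structured causal model.

## Preprocessing and test-time augmentation

CT volumes in Hounsfield units are windowed to [−10, 1000] (soft tissue
floor to dense cortical bone) and rescaled to 8-bit, v ↦
round_half_up((clip(v) + 10)/1010 · 255). Axial slices are collapsed into
8 mm maximum-intensity-projection slabs (slab size = ceil(8 mm / z-spacing)
slices; the trailing partial slab is kept so no slice is lost). Pelvic
cropping is an optional axial slice range, not an automated cropper.

Self-ensembling inference perturbs the windowed volume over a fixed grid of
intensity shifts {−2, −1, 0, 1, 2} (8-bit units) × contrast factors
{0.8, 0.9, 1.0, 1.1, 1.2}, i.e. K = 25 augmented scans with the identity
cell serving as the original. The perturbations are small by design so that
every fracture's visual pattern is preserved. The contrast operation is not
fully determined by "contrast adjustment" alone; we multiply about mid-gray
(v′ = clip(round_half_up(127.5 + c·(v − 127.5)) + s, 0, 255)), order
contrast → shift → clip, because it is bounded and preserves mid-range
anatomy; both the formula and the grid are configurable. Rounding is
half-up throughout so tests can be bit-exact.

## Detection fusion and the frequency score

Boxes are 0-based, half-open on every axis; a 2D box on slice s occupies
z ∈ [s, s+1). Detector boxes with network score ≤ 0.5 are discarded
(strict >, matching a detector operating point stated as "score > 0.5").
Within one augmented scan, two kept boxes are linked iff they share a
fracture type, their in-plane boxes intersect (any nonempty half-open
overlap — deliberately parameter-free, no IoU threshold), and they lie on
the same or adjacent slices; connected components become 3D fractures
(minimal enclosing cuboid, score = max constituent score). Across the K
scans, 3D fractures of the same type with intersecting cuboids are merged
the same way; a fused finding's confidence is the frequency

P_c(fx) = #{k : scan k contains ≥ 1 constituent} / K,

so several split pieces inside one scan count once. Per-type confidence is
the maximum frequency over that type's findings. Thresholding uses ≥, so a
finding present in all K scans attains the z = 1.0 operating point exactly.
Output ordering is deterministic (type order, then z/y/x of the cuboid).

## The causal network

Nodes are boolean: seven fracture types, age60 (age < 60 → 0, else 1), R
and T. Edges: age60 → R, age60 → T, and R → fx, T → fx for every fracture
type. The generative orientation (instability explains findings) was chosen
because (a) every CPD then has at most four parent configurations, fittable
from a few hundred patients, and (b) it makes observed fractures
informative about one another through their common causes — without which
retrieval of co-occurring findings would be vacuous. The structure is a
config value; the age-blind variant is expressed purely by removing the
age node and its edges, with no code change.

Tile is a deterministic label of (R, T), not a network node: (0,0) → A,
(1,0) → B, and any T = 1 → C. The (R=0, T=1) combination is undefined in
the first-order scheme's text; it maps to C because translational
instability is the hallmark of global instability (configurable).
Evaluation therefore operates on P(R=1|e) and P(T=1|e) directly, with hard
calls at the 0.5 posterior cut.

CPDs are estimated with Laplace smoothing, P(node=1|config) =
(n₁ + α)/(n₁ + n₀ + 2α), default α = 1; never-observed configurations get
0.5. Inference is exact sum-product variable elimination over boolean
factors with greedy min-degree ordering and per-engine memoisation (many
patients share an evidence pattern, and the refinement loop repeats similar
queries). Evidence with zero probability under the model raises an explicit
error rather than returning NaN. The test suite checks inference against an
independent full-joint-enumeration oracle to 1e-9 on random DAGs up to 10
nodes.

## Grading and Bayesian retrieval

Findings with confidence ≥ z_high (default 0.8) form FXhigh; ≥ z_low
(default 0.5) form FXlow ⊇ FXhigh. The initial grade conditions on FXhigh
(detected types 1, all others 0, plus age60). Retrieval then loops:
candidates are FXlow \ positives; each candidate's leave-one-out
conditional q = P(fx=1 | all other fracture states, age) is computed with
the candidate itself unobserved only during its own query; if the largest q
reaches z* (default 0.5; ties broken by the canonical fracture-type order)
that candidate is promoted into the evidence and the loop repeats,
otherwise it stops. Additions are greedy and sequential so each q reflects
previously accepted findings; the loop terminates after at most seven
additions and never removes a high-confidence finding (false positives
propagate — a known limitation, shared with the underlying approach).
A single acceptance rule on the leave-one-out conditional is used (the
candidate threshold in the source procedure is stated ambiguously against
two quantities); per-step q values are exported in the result record so
the decision surface is auditable. With z* > 1 no candidate can ever be
added and the result reduces to the initial grade, the endpoint of the z*
sweep.

## Synthetic cohort and detector

The generator defines the study conditions. Cohorts are ancestrally
sampled: age60 ~ Bernoulli(0.35) (an elderly fraction typical of a mixed
trauma census), R | age and T | age, then each fracture from P(fx | R, T).
Default conditional probabilities encode clinically sensible directions —
PSD and parallel SI diastasis track translational instability, anteriorly
divergent SI tracks isolated rotational instability, diastatic sacral
fracture is a translational hallmark — but they are configuration values,
not fitted clinical estimates. Integer ages are drawn uniformly on 18–59 or
60–95 consistent with the flag.

The detector emulator gives each true fracture a random cuboid in a
96 × 96 × 48 detector frame (8–20 px in-plane, 2–8 slices). Per augmented
scan, a fracture is detected with per-type probability d_t (default 0.85;
the refinement-benefit experiment spreads d_t over 0.5–0.9 across the seven
types to emulate types of varying subtlety); a detected fracture emits one
box per occupied slice, each independently dropped with probability m
(default 0.1) but never all — so d_t alone is the per-scan detection
probability, an identifiability choice — with ±1 px jitter. Poisson(λ)
false positives per scan (default λ = 0.2) get random type and position.
Scores are Beta draws rescaled onto (keep_2d, 1], i.e. conditional on
surviving the operating point: in the noiseless limit (d = 1, m = 0,
λ = 0) the full pipeline then recovers the ground-truth booleans exactly,
and per-slice dropout at m > 0 reproduces the split-fracture mechanism that
cross-scan fusion repairs. All randomness flows from one seed
(per-patient child streams via SeedSequence).

What the simulator does **not** emulate: real CT appearance, correlated
detector errors across augmentations (each augmented scan is an independent
Bernoulli draw, whereas a real detector's errors correlate strongly across
mild augmentations), spatially structured false positives (e.g. at
symmetric anatomy), inter-reader label noise, and site effects. Passing
tests therefore demonstrate the correctness and internal consistency of
the fusion/inference machinery and the qualitative behaviour of refinement
under a matched generative model — not clinical performance; headline
real-data metrics are out of scope because the underlying cohort is
private.

## Evaluation harness

ROC-AUC (rank statistic with midrank ties) and Cohen's kappa
((p_o − p_e)/(1 − p_e); degenerate p_e = 1 returns 1.0 for perfect
agreement and errors otherwise) are computed per instability. Five-fold
cross-validation is patient-level, stratified by the translational truth
label (the rarer instability) when feasible; in each fold CPDs are fit on
the training patients' truth table and the fused detections of held-out
patients are graded. A fold where a metric is undefined (single-class) is
recorded as absent, not fabricated. Threshold sweeps report AUC for three
variants per grid value — LOW (condition on FXlow directly), HIGH (FXhigh
only) and REFINE — along either z_low or z*.

The refinement-benefit check runs 10 cohorts of n = 400 (a scale chosen to
keep the full suite fast while leaving ~60 patients per fold class), K = 25,
d_t ∈ [0.5, 0.9], λ = 0.2, with a 200/200 train/test split per seed, and
requires mean rotational AUC of REFINE to be within 0.01 of (in practice,
slightly above) HIGH, with retrieval strictly additive for every patient.

The CPD-recovery check samples n = 5000 patients from a known network with
near-balanced instability priors so each of the four (R, T) parent
configurations receives ~n/4 samples; every CPD entry then lies ≥ 3.4
binomial standard errors inside the 0.05 recovery band, making the check a
test of the estimator rather than of rare-configuration sampling noise.

## Numerical and interface choices

- Half-up rounding everywhere in imaging; bit-exact contracts in tests.
- Detections are JSON-lines, patients CSV, the fitted model a readable
  YAML of nodes/edges/CPD tables for clinical audit; all artifacts embed
  the config hash and seed that produced them.
- Degenerate inputs error loudly: empty volumes, slab thinner than the
  slice spacing, non-positive contrast, mixed augmentation ids in one
  fusion call, zero-probability evidence, single-class AUC.
- The CLI (`tilegrade simulate|fuse|fit|grade|sweep|evaluate|demo`) is a
  thin layer over the library; flags mirror config keys one-to-one.

## Known limitations

High-confidence false positives are never rejected by refinement. The
network is boolean — fracture displacement, laterality and count are not
modelled. The (R=0, T=1) → C mapping is a convention. The simulator's
independence assumptions make self-ensembling look better-calibrated than
it may be on real scans, where augmentation copies fail together.
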