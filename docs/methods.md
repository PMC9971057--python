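# Methods

## The task and its scoring

An observer recognises a 27×25 grayscale glyph by sequential sampling. A
270×250 canvas (10× upsampling) shows a low-intensity context background —
`background_alpha` (default 0.3) times the mean template of the classes
selected at the previous episode, or of all classes before the first
episode. Each of up to `T = 12` episodes is: click a location, see a 5×5
image-pixel patch of the stimulus (`patch_half = 2`; patches accumulate),
then select a non-empty class set `c_t`. The episode score is
`P_t = 1/|c_t|` if the true class η ∈ `c_t`, else 0; the session total
`h = Σ P_t` lies in `[0, T]`, and equals `T/n` exactly for the policy that
always selects all `n` classes. Sessions are filtered like the human data:
incomplete sessions and sessions whose final episode scored zero are
discarded. Patches are clipped at image borders (a corner patch covers 9
pixels, an interior one 25, i.e. 25/675 ≈ 3.7 % of the image). The
six-minute session time limit is recorded metadata only; the simulator
does not enforce wall-clock behaviour.

Clicks are stored in one canonical space: 0-based (row, col) image
coordinates; canvas clicks are mapped by integer division by
`canvas_scale`.

## The behaviour baseline

**Class prediction.** The belief over classes given the revealed image I′
(stimulus pixels on the union of revealed patches, zero elsewhere) is the
cosine similarity of I′ with each class template `I_i` (the pixelwise mean
of that class's stimuli), normalised across classes to sum to one. It is
invariant to positive rescaling of I′ and undefined for an all-zero I′
(callers use a uniform belief before any evidence). The model's class set
`ĉ_t` is the k most probable classes with k = |c_t|, ties broken toward
the smaller class id for determinism.

**Location prediction.** For every ordered class pair, a saliency map
`D_ij = N(·, σ) * g(I_i, I_j)` scores how strongly an observation at each
pixel supports class i over class j. Two scoring functions `g` are
provided: pixelwise difference `I_i − I_j`, and the regularised pixelwise
KL term `I_i · log(δ + I_i/(I_j + δ))` with `δ = 1e-7` (chosen so the
self-divergence is below 1e-5; configurable). Smoothing uses a 5×5
Gaussian kernel with σ = 6, truncated and renormalised to sum to one —
at this width over a 5×5 support the kernel is nearly uniform, which is
implemented exactly as specified. Convolution uses reflect (edge-repeat)
padding with same-size output. The saliency threshold is global:
`θ = 0.5 × max` over the entire family of maps of a stimulus set,
computed once per set. Candidate next samples form
`Γ = {⟨l̂, i, j⟩ : l̂ ∉ l_{1:t}, D_ij(l̂) > θ, i ∈ c_t or j ∈ c_t}`,
and a participant's next click counts as predicted when some triple
satisfies `‖l̂ − l_{t+1}‖ < ε` (strict), `i ∈ c_{t+1}` and `j ∉ c_{t+1}`,
with ε = 2√2 — the largest centre-to-pixel distance inside a 5×5 patch.

## Synthetic stimuli

The generator emulates the structure that makes glyph recognition by
sequential sampling non-trivial, on a clean 28×28 canvas:

- every class shares a **two-stroke skeleton** (the common structure all
  glyphs of a script share), plus **two distinctive strokes** placed in
  class-specific cells of a 5-px-pitch slot grid, Gaussian-blurred with
  `blur_sd = 0.7`. Shared ink cancels in the pairwise saliency maps, so
  only the distinctive cells are salient — glyphs are told apart by a few
  diagnostic regions;
- a designated **confusable pair** (default classes 1 and 2): the second
  class reuses the first's strokes plus one extra stroke, so the pair's
  templates share most of their support and have by far the highest
  inter-class cosine similarity;
- **intra-class variation** mimics handwriting: each sample redraws the
  strokes with endpoints jittered by ≤ 1 px and perturbs ink intensity on
  the glyph (`noise_sd = 0.08`); the background stays clean, as in real
  scanned digits. Samples are min-max normalised to [0, 1]; with
  `noise_sd = 0` samples are exact prototype copies.

Defaults are `n_classes = 6`, `per_class = 15` (the per-class stimulus
count of the motivating experiments). The class count is deliberately
compact: the mean-probability class-selection rule can only produce a
singleton when every wrong class sits below the belief's mean, a margin
that shrinks as 1/n, and the cosine template posterior is much flatter
than the softmax beliefs of trained attention networks. With six classes
the template-matching observer can recognise within the T = 12 budget,
matching the premise that observers settle on a class within a handful of
samples; with ten or more it cannot, regardless of sampling policy.

The 28×28 → 27×25 crop removes the boundary row/column with the smallest
intensity variance, iteratively, ties broken top, bottom, left, right.
For a stimulus *set* one shared crop window is computed with the variance
pooled across all images, keeping every stimulus pixel-aligned with the
templates (a per-image crop can shift content by up to 3 columns and
silently misalign observations with every template).

**What the generator does not emulate.** Stroke curvature, slant,
per-writer style correlations, centred overlapping glyph layouts, and
inter-class similarity gradations beyond the single confusable pair.
Passing behavioural tests on this testbed therefore shows the machinery
behaves as designed — not that the baseline attains any particular
accuracy on human data or on MNIST/EMNIST images, which the IDX reader
can supply to the same pipeline.

## Simulated participants

Both built-in agents select classes by the mean-probability threshold on
the template-matching belief: classes strictly above the mean probability;
if that set is empty on a non-uniform belief, the argmax class (smallest
id on ties). Before any ink has been revealed the agents entertain **all**
classes, like a participant facing the all-classes context background —
without this, the zero-evidence fallback would register a confident
singleton at episode 1.

- **greedy** clicks the most salient location among maps touching the
  classes it currently entertains (ties: smallest row, then column). While
  any unrevealed location is salient above θ it excludes the whole
  already-revealed patch union — re-sampling revealed ink cannot change
  the belief, and excluding only the exact click pixels would make the
  agent crawl pixel-by-pixel inside one revealed patch. Once nothing
  salient remains unrevealed it clicks the best unvisited pixel even
  inside the revealed area: the forced click of a participant who has
  already made up their mind. It never revisits a clicked location.
- **random** clicks uniformly over unvisited pixels — the null policy.

Episode durations follow `2 + 20·confusion + N(0, 1)` seconds, floored at
0, where confusion is `|c_t|/n`: deliberation grows with the number of
entertained classes, giving the positive confusion-duration association
in expectation. Parameters are configurable; analyses assert only the
sign. Each session draws from a generator seeded by (seed, stimulus
index), so simulations are bit-reproducible.

Because the simulated participants and the baseline share the same
template-matching belief, the baseline's class prediction matches them
exactly (the top-|c_t| classes *are* the above-mean classes); the
class-similarity figures on synthetic sessions are a machinery check, not
an accuracy claim. Location prediction is not circular in the same way —
Γ is built from the participant's class set and θ-thresholded maps, and
its hit rate on greedy sessions stays well below 100 %.

## Evaluation statistics

Class metrics use the Jaccard index `J(X, Y) = |X ∩ Y|/|X ∪ Y|`
(undefined, and an error, for two empty sets): participant accuracy
`J(η, c_t)`, model accuracy `J(η, ĉ_t)`, similarity `J(c_t, ĉ_t)`, and
selection/rejection similarity `J(s_t, ŝ_t)`, `J(r_t, r̂_t)` evaluated
only where `|s_t| > 0` / `|r_t| > 0`.

Fixation maps are normalised click-frequency distributions (no
smoothing). `compare_maps` returns the regularised KL divergence
(reference first; sensitive to zeros in the second argument), the Pearson
correlation CC (an error for a constant map), and the histogram
intersection SIM.

`samples_to_recognition` is, by default, the smallest episode from which
the selection equals {η} and stays so — the strictest reading consistent
with the scoring incentive; `sustained=False` gives the first such
episode ignoring later lapses. When medians are compared across agents, a
session that never recognises is counted as T + 1 (right-censored at the
episode budget).

Scanpath sequence correlations: each session's clicks become sequences of
Euclidean distance and polar angle about the image centre ((13, 12),
0-based; angle measured counter-clockwise from the +x axis, so a click
directly right of centre is 0 and directly above is +π/2). Every
unordered session pair is truncated to its common length; pairs shorter
than 3 or with a constant sequence are skipped; the Pearson correlations
are averaged and reported with standard deviations.

The non-decreasing trend of mean `J(η, c_t)` is asserted against the
paired standard error of the episode-to-episode differences (one-sided,
2 SE) over sessions pooled from three stimulus sets: the claim is about
the expectation, and single-set runs synchronise class cohorts enough to
show noise-level dips.

## Problem sizes and reproducibility

The behavioural analyses and the acceptance script use three stimulus
sets (seeds derived from the run seed), 6 classes × 15 stimuli each — 270
sessions per agent, 540 in total — which keeps a full run in seconds
while leaving ~90 sessions per set for per-episode means. Oracle
equivalence checks run 200 random instances with n ≤ 4 classes on images
up to 10×10 against brute-force reimplementations. All randomness flows
from explicit seeds through `numpy.random.Generator`; no global state.

## Known limitations

- The cosine belief cannot use absence-of-ink evidence: revealing a blank
  patch where a candidate class would have ink does not lower that
  class's probability, which human observers plainly exploit. This is the
  main reason the template-matching observer needs more samples than
  humans and a compact class set.
- `θ` is a single global threshold per stimulus set; per-pair or per-image
  thresholds are not implemented.
- The environment does not render the interactive canvas; background
  composition is provided for completeness and model input, not display.
- Fixation-map KL follows the image-KL convention (reference first); no
  argument-swapped variant is exposed.
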