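# Methods

This note documents the modelling choices behind scrubsight: the
anticipation task, the synthetic cohort that stands in for clinical video,
the temporal networks and their objective, the informed post-processing,
the evaluation scheme, and the numerical decisions that were genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model

Instrument anticipation is posed as causal per-frame classification at
1 fps, separately per working trocar, over an `idle + instruments` label
space (idle at index 0). Every instrument change is anchored at the
last-use time `t0` of the outgoing instrument; the prediction must arrive
by `t_pred = t0 − δ` so the robot has δ seconds to prepare the handover.
With tolerance τ and post-extraction shift σ the prediction window is
`w_p = [t0 − δ − τ, t0 + σ)`; σ extends the window **end** past `t0` (not a
translation of both ends), which is the only reading under which the
default δ = τ = 3 s, σ = 1 s yields the span `[t0 − 6, t0 + 1)`. A resting
window of duration ρ precedes `w_p`; everything else is disregard.

Parameters (all seconds): δ = 3, τ = 3, σ = 1, ρ = 10. ρ is not fixed by
the task itself; 10 s was chosen as comparable to the 7 s default
prediction window and is configurable. Interval membership is half-open
`[start, end)` on a continuous time axis, frames sit at integer seconds —
an unambiguous convention matching 1 fps sub-sampling. Phase annotations
may contain gaps (sampled as "no phase"; such frames are masked out of the
phase loss).

Overlap resolution between consecutive events on one trocar: a resting
window yields to the preceding prediction window (its start is raised to
that window's end); only when two prediction windows themselves collide is
the earlier one truncated, i.e. the imminent change keeps its full label
support. Events whose clipped prediction window is empty are dropped with
a warning; the first insertion of a surgery generates no event (there is
no outgoing instrument to anchor it).

## Synthetic cohort

The simulator emulates the statistical structure of an annotated
laparoscopic-cholecystectomy cohort rather than its pixels:

- **Phases.** 11 ordered phases with truncated-normal durations
  (sd = 0.25 × mean, truncated to [0.3, 2.5] × mean); plan means sum to
  1800 s, so surgeries last about 30 minutes. One action interval per
  phase mirrors the phase segmentation.
- **Left trocar.** The change count is drawn from N(4.13, 0.78), rounded
  and clipped to the number of phase transitions; changes are placed *at*
  phase transitions. The left pool (grasper, irrigator, biopsy forceps) is
  allowed in every phase — left changes are phase-ritualised in practice,
  and this keeps transition-straddling anticipation consistent with the
  compatibility prior.
- **Right trocar.** The change count is drawn from N(20, 3); change times
  are uniform over the surgery with a minimum spacing of 25 s (so
  resting + prediction windows of adjacent events rarely collide). Each
  phase allows a universal instrument (coagulation suction tube) plus two
  rotating phase-specific instruments; an interval's instrument must be
  allowed in *all* phases overlapping `[insertion − 15 s, end]`. The 15 s
  margin makes an instrument compatible not only with the phases it is
  used in but also with the phase in which it is *anticipated* — without
  it, a change shortly after a phase boundary could be vetoed by the
  informed model even when predicted correctly.
- **Features.** The visual embedding (2048-d) is a sum of fixed random
  unit-vector signatures for the current left instrument, right instrument
  and phase, plus i.i.d. Gaussian noise (sd 0.05). Within L = 6 s before
  each extraction (and 2 s after) a *cue* signature of the **next**
  instrument of that trocar is added (strength 1.0) — the minimal
  mechanism that makes anticipation, rather than recognition, learnable;
  the cue lives in V only, so occlusion ablation has a known ground-truth
  ordering. Class probabilities, detection boxes (with `s = w·h` exact)
  and segmentation shape slots are plausible deterministic functions of
  the current frame labels plus noise scaled by the same noise sd, so the
  noiseless, cue-less limit is an exact function of frame labels.

What the simulator does **not** model: appearance, occlusions and detector
failure modes, inter-surgeon stylistic variation, adverse events
(bleeding, smoke) and the resulting unscheduled irrigator use, or any
correlation between feature noise and surgical difficulty. Passing tests
therefore demonstrate that the pipeline recovers anticipation structure
when it exists in the features — not that a real cholecystectomy cohort is
predictable to the same degree.

## Temporal networks

Both backbones are implemented on a small reverse-mode autodiff core
(`scrubsight.autodiff`) over NumPy arrays.

- `causal-tcn`: input 1×1 projection to hidden width H, then n residual
  blocks of dilated causal convolutions (kernel 3, dilation 2^l, left-only
  padding) with 1×1 mixing.
- `causal-ltcontext`: the same dilated convolutions interleaved with
  windowed local self-attention (window 16) and strided long-term-context
  attention (stride 8), all future positions masked with additive −inf.
  The attention output projections are zero-initialised so each attention
  branch starts as the identity; without this the stacked residual
  branches saturate the focal loss at initialisation and gradients vanish
  through the probability clamp.

Causality is exact, not approximate: masked attention weights are exactly
0.0 and convolutions only read the past, so outputs at frame t are
bit-identical under any perturbation of frames > t (tested for both
backbones). Every stage emits all three heads (left, right, phase
distributions via softmax) and enters the per-stage loss; stages beyond
the first consume the previous stage's concatenated head distributions
(a flag allows raw-feature passthrough). The full-scale reference
configuration is 1 stage × 8 layers; the desk-scale default used
throughout the tests is 1 stage × 4 layers, hidden 32.

Inputs are standardized per dimension with training-split statistics
(stored in the checkpoint); the raw feature blocks differ by orders of
magnitude (pixel-scale perimeters vs unit embeddings) and unnormalized
inputs saturate the softmax in float32.

## Objective

Per supervised frame: `scale(t) · (1 − p_y)^γ · (−log p_y)`, with γ = 2 in
resting/prediction windows, γ = 1 in disregard, and the quadratic
`scale(t)` of the task model (1 at `w_p` start falling to β at its end;
β at `w_r` start rising to 1 at its end; μ in `w_d`). β = 0.25 and μ = 0.1
by default — these two are free hyperparameters of the scaling, kept
configurable and logged. Disregard frames supervise towards idle (at
weight μ): spurious robot triggers are discouraged everywhere, cheaply.
The two trocar heads are summed per frame, the phase head adds an
unscaled focal term (γ = 2, weight 1.0), frames are averaged, stages are
averaged. Probabilities are clamped at ε = 1e−12 before the logarithm.

## Training

Full-video batches (batch = one video), Adam with linear warm-up.
Full-scale reference settings: lr 5e−5, 550 epochs, 70 warm-up epochs
(`TrainConfig.full_scale()`). The desk-scale default, used by the test
suite and sized so that the complete experiment (simulate 13 surgeries,
train 50 epochs, evaluate) runs in about two minutes on one CPU: lr 3e−3,
50 epochs, 5 warm-up epochs. Two regularisers compensate for the small
cohort (10 training videos against 2199-dim features): decoupled weight
decay (1e−3, matrices only) and Gaussian input-noise augmentation on the
standardized features (sd 0.3–0.5 of a feature's sd; default 0.5). Without
them the network memorises the training videos (train wAF1 1.0) and loses
roughly ten points of test wAF1. Model selection keeps the epoch with the
best validation weighted F1 when a validation split exists, else the
final epoch. All randomness is seeded; identical seeds give identical
training curves.

Streaming inference re-runs the causal forward pass on the growing frame
prefix, which is exactly prefix-consistent with batch inference (for the
TCN bit-identically; for attention up to BLAS summation order, < 1e−6) at
O(T²) cost — acceptable at 1 fps frame rates, and kept deliberately
simple instead of maintaining per-layer ring buffers.

## Informed model

`B` is binary, phases × (idle + instruments), idle column all ones. The
frame-wise reweighting `a′_λ ∝ i_λ · Σ_α p_α B[α, λ]` marginalises the
compatibility over the phase distribution and renormalises on the simplex;
with a one-hot phase it zeroes exactly the incompatible classes, with an
all-ones `B` it is the identity. When the reweighted mass is zero the
original distribution is kept (the prior never forces a prediction). The
reweighting is applied at inference only, to the final stage; an optional
training loss on the reweighted output is available behind a flag but off
by default. `B` can be supplied (CSV), taken from the simulator's design
matrix, or estimated from timelines as the usage union (instrument ever
in use during a phase); the estimate is monotone in the data and, on
full-length simulated cohorts of a few dozen surgeries, recovers the
design matrix exactly.

## Evaluation

One sequence per event (resting then prediction window); the first
non-idle frame prediction is the sequence's single counted prediction,
disregard frames are never scanned. Counts are one-vs-rest per class
(instrument × trocar), split into prediction-window and resting-window
compartments; precision/recall/accuracy/F1 pool both compartments. A
correct first prediction during the resting window therefore counts as a
(resting-compartment) true positive — the pooled definitions require it —
while the compartment split preserves timely-only reporting. Decisions
that the pooled definitions do not fix, chosen and documented here:
missed sequences are prediction-compartment false negatives (the failure
is the absence of a timely prediction); true negatives are booked in the
compartment of the sequence's first prediction (prediction compartment
when there is none); 0/0 metrics are 0 for classes with sequences, and
zero-support classes are excluded from support weighting. Weighted and
macro averages are taken per video over supported classes and reported as
mean ± sd over videos; first-prediction offsets (seconds relative to the
prediction-window start) are reported per class as diagnostics, and
per-trocar multiclass confusion tables are emitted alongside.

Occlusion ablation zero-fills one feature block (V, D or S) at inference
using the recorded block offsets and reports the drop in weighted F1
against the unperturbed baseline.

## Known limitations

- The synthetic cue is a single additive direction per instrument class;
  real pre-change visual evidence is weaker, compositional and
  surgeon-dependent. Absolute synthetic scores say nothing about clinical
  scores.
- The simulator draws change counts per video independently; it does not
  model the correlation between surgery duration and change count.
- `estimate_compatibility` needs enough surgeries to visit every allowed
  (phase, instrument) pair; on short or few timelines it under-covers the
  design matrix (by construction it never over-covers).
- The attention backbone uses full masked T×T attention; for sequences far
  beyond ~30-minute surgeries at 1 fps a banded implementation would be
  needed.
- Streaming inference is O(T²) overall; adequate at 1 fps, not at video
  rate.
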