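# Methods

`osmlab` models how a population code for a cue–delay–choice task can be
learned from a stream of sensory symbols, and provides the metrics used
to compare learned representations across models and against
calcium-imaging-style data.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not emulate.

## The task

A 230-cm virtual linear track is discretised into 10-cm segments, one
sensory symbol per segment.  An indicator cue at 60–100 cm (symbol 2 on
"near" trials, 3 on "far" trials) predicts which of two visually
identical reward zones pays out: R1 at 130–150 cm or R2 at 180–200 cm.
All remaining segments show featureless grey (symbol 1).  The canonical
7-symbol ("rnn") dialect encodes a trial in 23 steps, e.g. near =
`1,1,1,1,1,1,2,2,2,2,1,1,1,4,6,1,1,1,5,5,1,1,0`; the 8-symbol "cscg"
dialects append a wall symbol and three teleport symbols (26 steps).
Variant dialects permute the rewarded zone's two symbols (water before
the reward visual) or merge them into conjunctive codes; the stretched
variant widens both pre-reward grey gaps from 3 to 8 segments (330-cm
track), placing the near reward where the far reward sits on standard
trials.

Trial types are sampled in runs whose lengths follow a Poisson(0.7)
distribution truncated to [1, 3], alternating between types, so each
type occurs at 50% in the long run and never repeats more than three
times.  Truncation is implemented by rejection so the run-length
distribution is the exact conditional distribution.

The key combinatorial fact of the task is the context-ambiguity
threshold: enumerating all within-trial n-grams shows that contexts of
length ≤ 4 still leave some reward-zone symbol ambiguous between trial
types (e.g. `1,1,1,4` is followed by 6 on near trials and 4 on far
trials), while length-5 contexts reach back to the indicator (or the
preceding reward zone) and disambiguate everything.  The threshold is 4
because the inter-reward grey gap is 3 symbols.  Ambiguity is assessed
only at trial-type-*determined* positions (the reward zones); the
indicator onset and the post-teleport start are irreducibly random and
are excluded.  Contexts never cross the teleport boundary.

## Cloned HMM (CSCG)

The clone-structured causal graph is an HMM in which each hidden state
emits exactly one symbol (p(x=j|z=i) ∈ {0,1}); learning re-estimates
only the S×S transition matrix T and the initial distribution π by
Baum–Welch EM.  With C(j) the clones of symbol j (100 per symbol by
default; S = 800 on the 8-symbol task), the forward/backward messages at
step n have support only on C(x_n), so inference runs in
100×100 blocks.  Scaled (normalised) messages keep the recursion
underflow-safe for sequences of at least 10^4 steps; the log-likelihood
is the sum of log scale factors and matches brute-force path enumeration
to 1e-10 on small instances.

Training follows a batch curriculum: at each training step, 20 trials
are drawn (with replacement) from the session, concatenated into one
sequence — so teleport-to-start transitions are learned and the
transition graph closes into a loop — and 20 EM iterations are run on
that batch.  Within a step the batch log-likelihood is non-decreasing
(EM guarantee, asserted to 1e-8).  A pseudocount of 1e-10 is added to
all transition counts each M-step so no row of T becomes degenerate;
rows that receive no evidence relax toward uniform but such clones are
never visited.  Viterbi refinement re-estimates T from hard state paths
until the joint path probability stops improving; ties in the Viterbi
argmax resolve to the lowest state index.  Transition graphs are
restricted to clones on the Viterbi paths of the supplied trials, with
edges above a probability floor.

Model representations are state-occupancy population vectors: the
posterior γ (positions × states) of a probe trial, one row per track
position (a Viterbi one-hot variant is available).  Because EM converges
quickly on this task — most of the likelihood gain arrives within the
first few training steps — checkpoints can be taken after every EM
iteration ("iteration" cadence), which resolves the decorrelation order
cleanly.  To keep memory flat when checkpointing this finely, fit() can
store probe-PV pairs per checkpoint instead of full model snapshots.

Trained on the standard visual-first dialect, the near/far occupancy
correlation falls to ≈ 0 at both pre-reward regions, and the
time-to-threshold order is off-diagonal ≤ pre-R2 ≤ pre-R1 in nearly all
seeds.  On the water-first dialect (water symbol precedes the reward
visual) the pre-R1/pre-R2 order flips, because the shared water symbol
in the near reward zone forces the model to disambiguate contexts
*after* R1 earlier in learning.

## Spiking Hebbian network

K = 100 recurrently connected spiking neurons receive input from n = 96
Poisson input neurons, 12 per symbol (disjoint groups, so stimuli are
orthogonal at the input).  Filtered spike trains (exponential kernel,
τ = 20 ms, unit jump per spike) drive the membrane potential
u_k = Σ_i w_ki x̄_i + Σ_j v_kj ȳ_j(t−Δt) at Δt = 1 ms resolution;
firing probabilities are a softmax over u (global divisive inhibition —
soft winner-take-all), spikes are Bernoulli draws per step, and a 10-ms
refractory period silences recent spikers.  When neuron k spikes, the
weights onto it update as Δw = α(e^{-w}·trace − 0.1) with α = 0.1, and
all weights are clipped at zero (the excitatory constraint); negative
initial draws (W: N(0, 3.5²), V: N(0, 2.5²)) are clipped the same way.
Plasticity reads the traces as they stood before the triggering spike's
own contribution.

Two presentation parameters are not dictated by the learning rule and
matter enormously: the input Poisson rate and the duration each symbol
is presented.  The defaults are 50 Hz and 30 ms per symbol.  At much
higher input rates the feedforward term dominates the membrane potential
(the trace fixed point w* = ln(trace/0.1) grows with the rate on both
factors), the same winners fire for both trial types in the grey
regions, and context never separates the trial types; at 30 ms per
symbol (≈ 1.5 trace time constants) filtered activity bridges adjacent
symbols, so recurrent chains carry the indicator identity through the
grey gaps.  With these defaults the near/far correlation at both
pre-reward regions falls below 0.3 in 5/5 probe seeds after ~400 trials
of passive exposure, with no error signal or task objective anywhere.
Representation PVs are trial-averaged spike counts per position from
probe trials run with plasticity frozen; the correlation of an all-zero
PV pair is defined as 0 and flagged.

## Gradient-trained predictors

Rate RNNs (h_t = act(W_in x_t + W_rec h_{t−1} + b)), single-layer LSTMs
and a small decoder-only transformer are all trained with Adam under
cross-entropy next-symbol prediction on one-hot 7-symbol inputs, with
half of a sampled session for training and half held out.  The rate-RNN
activations include two soft-WTA variants — exponential softmax and
polynomial softmax a_i = |u_i|^8 / Σ|u_j|^8 — plus ReLU and sigmoid.
Rate-RNN input/recurrent weights start at sd 0.001 and the output layer
at sd 0.1; the LSTM uses standard 1/√H fan-in scaling (with tiny
initialisation its gates receive no usable gradient).  The transformer
follows the GPT recipe (learned positional embeddings, pre-norm blocks,
causal attention, GELU MLP); representations are read from the pre-logit
layer (final layer norm), with each trial position evaluated under its
trailing context window.  All gradients come from a small reverse-mode
autodiff engine on numpy arrays, validated against finite differences.

All families learn the prediction task (reward-zone accuracy ≈ 1 with
full context; ≈ the 0.5 Bayes rate at the trial-type-ambiguous positions
when the context window is ≤ 4).  The scientific contrast is in the
hidden representations: softmax-activation RNNs orthogonalize the
near/far representations; ReLU/sigmoid RNNs, standard LSTMs and
transformers keep them highly correlated while solving the task, because
prediction only requires orthogonality in the low-dimensional read-out
subspace.  An optional correlation penalty (λ · mean squared Pearson r
between paired near/far hidden states, λ = 1, zero-variance vectors
contributing 0) makes the LSTM orthogonalize; L1 and dropout variants
are also provided.

## Representation metrics

A population vector (PV) is the activity of all units at one position
bin: state occupancies, network hidden states, or mean ΔF/F per 5-cm
bin for calcium data (frames with speed > 5 cm/s only).  The near×far
cross-correlation matrix holds the Pearson r between every pair of
positions; zero-variance PVs yield r = 0 and are flagged.  Named track
regions (initial, indicator, pre-R1, R1, pre-R2, R2, end) are averaged
as region×region blocks of this matrix; the off-diagonal grey statistic
averages all ordered pairs of distinct grey regions.  PV angles are
arccos of the cosine similarity of the raw vectors, so orthogonal
nonnegative codes sit at 90°; for mean-centred PVs r = cos(angle).

Decorrelation trajectories track region means over training checkpoints.
The time to threshold (0.3, the conventional value) is the first
downward crossing, linearly interpolated between checkpoints, on a time
axis normalised to [0, 1] by checkpoint index; a region that never
crosses is flagged and fails any order comparison.  The discriminating
statistic is the crossing order off-diagonal ≤ pre-R2 ≤ pre-R1 (ties
allowed), which the CSCG reproduces robustly and the other learners are
not required to.

## Calcium metrics

F0 is estimated per cell by Gaussian smoothing (the "5 s" filter is
interpreted as a full width of ~5 s, σ = 1.25 s ≈ 12 frames at 10 Hz)
followed by a rolling minimum then rolling maximum (window 30 s).
ΔF/F = (F − F0)/F0.  Baseline noise σ is the sd of ΔF/F over all frames
of the quietest quarter of 5-s bins (bins ranked by mean fluorescence);
keeping whole quiet bins avoids the ~3× downward bias of keeping only
each bin's lowest frames, which would turn noise wiggles into spurious
"transients".  Significant transients start when ΔF/F exceeds 5σ and end
on return within 1σ.  The maximin baseline tracks slow drift but leaves
curvature-scale residuals; on drifting noise-only traces ΔF/F stays
small but may still graze 5σ of a very quiet cell — a property of the
method, not a bug.

Place fields: candidate fields are contiguous 5-cm bins of the
trial-averaged tuning curve above 25% of (peak − lower-quartile
baseline), between 15 and 120 cm wide, with in-field/out-field mean
ratio ≥ 4 and significant transients covering ≥ 20% of in-field frames.
Tuning uses active trials only (≥ 1 lick in either reward zone) and
running frames.  Significance: the activity (and its transient mask) is
cut into 10-s blocks, block order is permuted against position, and the
whole detection re-runs; a cell is significant if fewer than 5% of
shuffles produce a passing field (1,000 shuffles at full scale; tests
use a few hundred and say so).  On noise-only cells the false-positive
rate is ≤ 5% by construction of the permutation null.

Single-cell phenotypes: r = Pearson correlation of the near and far
tuning curves, D = |A_near − A_far| / max(A_near, A_far) with A the
curve peaks.  Thresholds r = 0.2, D = 0.5 partition cells into place
(r ≥ 0.2, D < 0.5), splitter (D ≥ 0.5) and remapping-splitter (r < 0.2,
D < 0.5) responses — a partition that is exhaustive and mutually
exclusive, with silent cells excluded.  Population classification first
drops cells whose peak does not exceed 2 sd above the mean (computed
from the ΔF/F trace when available, otherwise from the curves).  The
spatial dispersion index is the Shannon entropy (bits) of the
area-normalised tuning curve: 0 for a single bin, log2(46) ≈ 5.52 for
uniform tuning over a 230-cm track at 5-cm bins.  The stretched-trial
analysis pairs per-cell peak locations between standard and stretched
tuning curves; cells lacking a peak in either condition are excluded and
counted.

## Behaviour metrics

Lick density (licks per trial per 10-cm bin, by trial type and session
half) is regressed on four strategy basis functions, each nonnegative
and unit-area over its (near, far) support: random (uniform),
both-rewards (both zones on both types), lick-stop (both zones on far
trials, only the near zone on near trials — licking stops after the
reward), and expert (correct zone only).  Reward-zone supports include a
20-cm anticipatory lead-in.  The coefficient of partial determination is
CPD_i = (SSE_−i − SSE_full)/SSE_−i from nested ordinary least squares;
the dominant strategy per session half is the argmax.  No intercept is
included: the random-licking regressor is itself constant over the
track, and an intercept would be exactly collinear with it and absorb
its contribution.  SSEs below 1e-12 of the total sum of squares are
treated as perfect fits (CPD 0 for the removed regressor) to avoid
ratios of numerical dust.  Trial accuracy is binary — licked in the
correct zone and nowhere in the wrong zone — and the expert criterion is
accuracy ≥ 75% in three consecutive sessions.

## Synthetic data

The generator produces position/speed/lick traces and calcium-like
fluorescence with a known ground truth, so every analysis has a recovery
test without any external data.  Behaviour: runs at 30 cm/s with jitter,
slow-downs inside licking zones, 2-s teleport gaps; licks drawn from the
active strategy's zones plus a 5% uniform noise floor.  Neural activity:
per-cell tuning → Poisson events → difference-of-exponentials calcium
kernel (rise 50 ms, decay 700 ms, GCaMP6f-like) → per-cell event
amplitude → Gaussian noise (sd 0.03 ΔF/F) on a baseline of 100, at
10 Hz.

Representation stages plant the learning course: stage 0 (unstructured,
firing at five scattered locations, shared across trial types), stage 1
(sensory: grey-tuned cells respond across all four grey regions with a
mild home preference; indicator cells split from the start because the
cue itself differs; reward-cue cells respond at both visually identical
zones), stage 2 (grey cells collapse to their home region, still shared
across types), stage 3 (cells before/at the far reward become
trial-type-specific), expert (fully split, with a planted 60/30/10%
splitter/place/remapping-splitter mixture; place cells concentrate at
the track start and end).  This plants the decorrelation order
off-diagonal → pre-R2 → pre-R1 with the start/end regions staying
correlated, and the licking strategies advance random → both-rewards →
lick-stop → expert across the same sessions.

Two generator features deserve emphasis because they were forced by the
ΔF/F pipeline itself.  First, cross-region PV correlation is carried by
per-cell *event amplitude* diversity (lognormal, σ = 1.1), not by firing
-rate diversity: the baseline division normalises a cell's rate gain
away, but its fluorescence-per-event survives.  Second, early-stage
multi-region activity is *time-sparse* — each firing location is
expressed on only ~65% of trials — because a cell elevated most of the
session saturates the rolling-minimum baseline and its sustained
component disappears from ΔF/F, turning broad tuning into spurious
anti-correlations between regions.  Real recordings are sparse in
exactly this sense.

What the generator does not emulate: imaging noise with spatial
structure, neuropil contamination, cell dropout across sessions
(available as an option but off by default), biophysical calcium
dynamics, running-speed modulation of firing, and replay events.
Passing recovery tests therefore show that the analysis chain is
faithful to its own assumptions on data of the intended structure — not
that those assumptions hold in any particular real dataset.

## Problem sizes and numerical choices

Default scales are chosen so a full check of every model family runs on
one CPU core in minutes: CSCG with 100 clones/symbol trained for 20
steps × 20 EM iterations on 20-trial batches (~10 s/seed); Hebbian
network for 400 trials (~15 s/seed); rate RNNs with 200–500 hidden units
for 400–1,200 epochs; LSTMs with 128–800 units for 250 epochs;
transformer with 2–4 layers trained on 100-element chunks of 10-trial
streams.  Hidden sizes and learning rates sit inside the conventional
stable ranges for each family (softmax variants tolerate the largest
rates; sigmoid needs the smallest).  Synthetic sessions use 400–500
cells and 40–60 trials.  All randomness flows through explicit integer
seeds (numpy Generator); identical seeds reproduce identical sessions,
spike histories and fits bit-for-bit, up to floating-point
non-associativity in BLAS reductions.

## Known limitations

The Hebbian network's decorrelation depends on the presentation-rate
balance described above; it demonstrates sufficiency of local plasticity
plus soft WTA, not robustness across all presentation regimes.  The
polynomial-softmax activation uses |u|^8 normalisation, which loses sign
information by construction.  The conjunctive sequence dialect reuses
the water symbol id for the near conjunctive code, so its alphabet
carries nine ids.  The CPD analysis assumes the strategy bases span
licking behaviour up to noise; with heavily collinear bases the
pseudoinverse fit is flagged rather than regularised.  Place-field
significance inherits the known permissiveness of threshold-based field
detection; the shuffle null controls the false-positive rate only under
stationarity of the block structure.
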