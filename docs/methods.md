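# Methods

## The problem

Recurrent classifiers over longitudinal electronic-health-record (EHR)
sequences — one multi-hot vector of diagnosis codes per clinical visit — make
accurate risk predictions but give no account of *which visits* drove a given
patient's score. This package implements visit-level **contextual
decomposition (CD)** for LSTM and bidirectional LSTM classifiers: an exact
additive split of the model's class logit into the contribution of a chosen
subset of visits and the contribution of everything else, plus the experiment
harness needed to validate such attributions when no labelled ground truth
exists.

## Model

A patient is a sequence x_1..x_T with x_t in {0,1}^|D| marking the diagnosis
codes of visit t (|D| is the vocabulary size at the chosen ICD truncation
level: 3-digit categories or 4-digit subcategories). The classifier is a
single-layer LSTM

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    g_t = tanh(W_g x_t + U_g h_{t-1} + b_g)
    c_t = f_t ⊙ c_{t-1} + i_t ⊙ g_t
    h_t = o_t ⊙ tanh(c_t)

with a 2-class softmax head p_j ∝ exp(W_j·h + b_j). The feature vector h is
the hidden state at the true final visit; a BiLSTM concatenates the forward
state at the last visit with the backward state at the first visit, which is
the standard single-vector reading of a bidirectional encoder feeding one
classifier. Sequences are post-padded with zero rows and padded steps copy
the state through unchanged, so padding is inert in predictions, gradients
and decompositions alike (tested by comparing batched and per-patient runs).

Training is cross-entropy with Adam (default learning rate 5e-4) and early
stopping on validation loss: training stops after `patience` consecutive
epochs without improvement and the best-validation weights are returned.
The trainer is plain NumPy backpropagation-through-time, verified against
finite differences; trained weights are exported into inert parameter
containers so the decomposition depends only on weights, never on the
training machinery. Defaults — hidden 64, batch 32, max 50 epochs, patience
5, uniform ±1/sqrt(hidden) seeded initialization — are desk-scale choices;
the experiment harness uses max 20 epochs with patience 3, which suffices on
the synthetic cohorts below.

## Contextual decomposition

For a subset S of visit indices, every hidden and cell state is split as
h_t = beta_t + gamma_t, c_t = beta^c_t + gamma^c_t, where beta collects all
terms traceable solely to visits in S. At each step the gate pre-activation
splits into three summands — relevant (U·beta_{t-1}, plus W·x_t when t∈S),
irrelevant (U·gamma_{t-1}, plus W·x_t when t∉S), and the bias — and the gate
nonlinearity is **Shapley-linearized**: each summand's contribution to
sigma(total) or tanh(total) is its marginal effect averaged over all
orderings of the summands (full permutation averaging, chosen over
reduced-ordering shortcuts for symmetry). The activation-at-zero offset
(sigma(0)=1/2) is assigned to the bias summand, or to the irrelevant summand
when no bias participates.

The cell update keeps in beta^c_t the terms (f_rel+f_bias)⊙beta^c_{t-1} +
(i_rel+i_bias)⊙g_rel + i_rel⊙g_bias, plus the bias-bias interaction
i_bias⊙g_bias only at steps t∈S; gamma^c_t is the exact remainder
c_t − beta^c_t, with c_t computed by the undecomposed forward recursion. The
output gate is left undecomposed; tanh(c_t) is split over the two summands
(beta^c, gamma^c) and beta_t = o_t ⊙ L_tanh(beta^c_t). The *relevant score*
of S for class j is W_j·beta_T (W_j·[beta_fwd, beta_bwd] for a BiLSTM, with
the backward recursion run on the reversed true sequence and S mapped through
the reversal).

Because gamma is always defined as an exact remainder, additivity

    score_relevant + score_irrelevant + b_j = logit_j

holds to floating-point precision for every S — the suite checks 1e-10
relative on hundreds of random models, and a hand-expanded scalar oracle
reproduces the full recursion at hidden size 1. Two structural consequences
are also tested: S=∅ forces a zero relevant score, and S covering all visits
with all biases zeroed forces an empty irrelevant stream. By default the
scored class is j=1 (the outcome class); any class index can be passed.
Non-contiguous S is accepted by the engine even though the window search only
generates contiguous candidates, since nothing in the definition requires
contiguity. Requesting S outside the true length is an error — the
decomposition never touches padding.

## Most predictive subset of visits

`find_predictive_subset` slides windows of each width w in W (default
{1..min(5,T)}) with step s (default 1) across the true visits, scores every
window by its CD relevant score, and returns the argmax; candidate counts
equal Σ_w ⌊(T−w)/s⌋+1. Ties break toward the smaller window, then the
earlier start (the most parsimonious, earliest explanation). This is an
exhaustive search; with tens of visits per patient it is cheap.

## Synthetic cohorts and the validation experiments

Real pediatric EHR extracts of this kind are access-restricted, so all
experiments run on synthetic cohorts shaped like them: 5–12 visits per
patient (mean ≈ 8.5), 1–3 codes per visit (mean ≈ 2), a Zipf(1.0) background
over a 100-code vocabulary, strictly increasing ages with uniform gaps, and
2000 patients with a 50% case fraction in the standard configuration. Cases
(75%) and controls (25%) carry a planted signal visit consisting of the three
*rarest* vocabulary codes, giving the model a moderate, non-degenerate signal
(test AUCs around 0.8, comparable to realistic code-based risk models). The
signal codes are deliberately rare: a "planted" visit made of the commonest
codes also arises as background noise and stops being a pattern. The
generator can plant multi-visit signal blocks (consecutive visits splitting
the signal codes) for subset-search experiments. What these cohorts do *not*
emulate: code co-occurrence structure, comorbidity progression, visit-rate
heterogeneity, censoring. Passing validations therefore show that the
decomposition finds patterns a model has learned — not that real clinical
sequences contain such clean patterns.

**Artificial-visit validation.** A visit bearing a single code outside the
real vocabulary is added to cases with probability p_art and to controls with
probability 1−p_art, at a seeded random position or appended. At p_art=1 the
visit separates the classes perfectly, so a trained model should predict
every case and CD should give the artificial visit the maximal per-visit
score; at p_art=0.5 it carries no information and should essentially never
win. Attribution accuracy is measured over test cases bearing the artificial
visit; a patient counts as correctly attributed only if it is also predicted
class 1, so the class-1 prediction accuracy over the same patients is an
upper bound by construction. The packaged experiment reproduces the expected
endpoints (100% attribution and class-1 accuracy at p_art=1, 0% attribution
at 0.5 for both LSTM and BiLSTM) and a monotone decline across
p_art = 1.0 → 0.5 (Kendall trend over the 6-point grid, 3 seeds; interior
grid points use 1200-patient cohorts, endpoints 2000).

**Logistic-regression ground truth.** A logistic model on per-patient binary
code-presence aggregates (counts are deliberately not used; presence is the
simplest temporal-order-free summary) yields per-code odds ratios. Codes
with Wald p ≤ 0.05 and OR > 1 are sorted by OR and split into four contiguous
quartile groups scoring 4..1 (remainder codes go to the top groups); all
other codes score 0. Visit scores are sums of their codes' scores; the top
three visits per patient (recency breaking ties, since later pre-outcome
visits are clinically the more plausible attribution) are the ground truth,
and matching accuracy@k asks whether the top-CD visit is among the top-k.
Degenerate all-present columns are dropped from the fit and score 0. A
non-identifiable fit (perfect or quasi-complete separation) raises an error
naming the offending codes rather than reporting unstable coefficients; the
detection is post-fit (|coef| > 15 for a one-class code, or non-convergence)
because a hard pre-check on one-class presence alone would reject harmless
rare background codes.

**Pattern mining.** Among test cases predicted as cases, the visit (or
consecutive visit pair) with the maximal positive CD score contributes its
sorted code set (pair of code sets) to a tally; tables report the top-10
patterns with counts and percentages of contributing patients. On planted
cohorts the planted visit tops the table, mirroring how the dominant
clinical patterns surface on real data.

## Visualization

`render_timeline` writes a self-contained static HTML timeline: one row of
squares per model, labelled with visit ordinal and age, codes in a hover
tooltip, colors on a symmetric blue-white-red ramp normalized per row by the
maximal |score| (so rows are comparable in shape, not in magnitude), and the
most predictive subset outlined in yellow. Rendering is deterministic.

## Numerical choices and limitations

- All computation is float64; CD additivity is exact to ~1e-12 and asserted
  at 1e-5 relative in the acceptance checks.
- Training determinism: a single seeded NumPy generator drives
  initialization and batch shuffling; identical seeds give identical models.
- Model files are JSON with repr-precision floats and round-trip bit-exactly.
- The label rule for the school-age-asthma cohort uses strict age
  inequalities (symptom visit before age 5, more than two visits before 5,
  asthma code after 6; controls asthma-free on (6, 9) and observed to ≥ 9).
- The train/validation/test split is 55/15/30, stratified per class with
  per-class rounding, so class proportions are preserved to rounding.
- Known limitations: single-layer recurrences only; no code-level (within-
  visit) decomposition; pattern frequencies and matching percentages on
  synthetic cohorts are properties of the generator, not clinical findings;
  the CD conventions (full-permutation Shapley averaging, bias-bias term
  assignment, undecomposed output gate) are one principled fixing of the
  decomposition — other published variants differ in these details while
  preserving additivity.
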