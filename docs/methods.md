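# Methods

`olbac` jointly learns to *predict* ligand bioactivity and to *optimize*
ligands by a single-atom element substitution, exploiting the structure of
activity cliffs: pairs of near-identical molecules with very different
potency. This note describes the model, the design choices that were
genuinely open, the synthetic study system, and the limits of what the
accompanying tests demonstrate.

## Model

**Encoder.** Molecules are heavy-atom graphs. Atom features are a 16-way
element one-hot (B, C, N, O, F, Si, P, S, Cl, As, Se, Br, Te, I, At, plus a
catch-all "other"), degree, formal charge, aromaticity and implicit-H
count; bond features are order one-hot, conjugation and ring membership.
An attentive message-passing encoder (L = 2 rounds of neighbor attention
followed by a GRU state update) produces atomic embeddings h_i ∈ R^D and
the molecular embedding f = Σ_i h_i. The plain-sum readout is load-bearing:
the decoder's first step divides a (possibly perturbed) molecular embedding
back onto atoms, which presumes f is an atomic aggregate. D = 64 by
default.

**Predictor.** N(f₁, f₂) is a two-layer feed-forward network on the
concatenation [f₁ ∥ f₂]. Ordinary prediction evaluates N(f, f); the
two-slot form exists so that perturbed embeddings can sit in the second
slot, N(f, f + d).

**Adversarial perturbation.** A Gaussian probe r with ‖r‖ = ε (ε = 0.01)
perturbs the second slot; the gradient of the squared prediction
discrepancy D = (N(f,f) − N(f,f+r))² with respect to r, rescaled to norm η,
is the adversarial perturbation d. It is the direction in embedding space
along which the prediction moves fastest — exactly the direction that
separates the two sides of an activity cliff locally. d is one-step (no
inner ascent loop) and is treated as a constant wherever it is consumed:
the stabilization loss D(N(f,f), N(f,f+d)) trains the predictor to be
locally smooth, and the decoder receives d as data. The squared difference
was chosen as D because it is smooth, symmetric, nonnegative and zero only
at agreement; on classification tasks it acts on logits.

Because the probe is random, the raw d carries a random sign. At
optimization time the package orients d so that the predictor's output
rises along +d; "+d" is then the activity-raising direction by construction
and "−d" its reverse. Training uses the raw, unoriented d (only the
magnitude of the discrepancy matters there).

**Decoder.** The graph reconstruction network maps {f_in, H} to per-atom
element probabilities (and, optionally, bond features), where
f_in = f + s·d with s ∈ {+1, 0, −1}:

1. *Decomposition:* responsibilities γ_i = softmax_i⟨f_in, h_i⟩ apportion
   the molecular embedding to atoms.
2. *Molecule-to-atom:* g_i = γ_i·f_in + h_i, then T rounds of a
   relationship network (elu) + GRU (T = 1 by default).
3. *Atom-to-atom:* L rounds of neighbor attention over directed edge
   states with a second GRU; edge states start from the sending atom's
   state and are updated each round.
4. *Generation:* a 16-way softmax per atom; bond heads (order softmax +
   per-flag sigmoids) exist but are off in the default loss, which focuses
   on the atom symbols the optimization scheme consumes.

With s = 0 the decoder reconstructs the input (â); with s = ±1 it produces
the optimization posteriors (ã). Zero perturbation makes the branches
bit-identical by construction.

**Reconstruction loss.** Per molecule, (1/N_a) Σ_i w_i · CE(â_i, a_i) with
w_i = 1 − N_{K_i}/N_a, the share of the molecule *not* made of atom i's
element. Carbon, which dominates organic molecules, is down-weighted;
heteroatoms — the substitution sites that matter — dominate the loss. The
weighted cross-entropy is implemented as a nonnegative weighted negative
log-likelihood (a loss to be minimized must be bounded below; a sign-literal
reading of the weighted-CE formula would be unbounded).

**Selection rule.** From the two posterior tables P_f(k|i) = â and
P_{f±d}(k|i) = ã, the key atom is
i\* = argmax_i max_{k∉K_i} P_{f±d}(k|i), where K_i = {k : P_f(k|i) ≥ P₀} is
the set of elements the reconstruction already finds plausible at site i
(the original element and anything confusable with it). The replacement is
the most confident candidate k\* with P_{f±d}(k\*|i\*) ≥ P₀ and
k\* ≠ original. P₀ = 0.5 by default — "confident" taken literally. Ties
break to the lowest index, making selection deterministic. A molecule is
emitted only if (i\*, k\*) exists and passes the chemical validity check,
so the generated count can fall below the anchor count.

**Validity.** Val(k|i) = 1 when placing element k at atom i, keeping all
bonds, is chemically unsound. The check is a neutral-atom valence
arithmetic (aromatic bonds count 1.5, rounded up) whose positive verdicts
are confirmed by full RDKit sanitization of the substituted molecule; a
relabel that would force bond-order re-perception (e.g. breaking an
aromatic ring) is invalid. This makes "valid ⇒ sanitizes" hold by
construction. The placeholder element "other" is never a valid target.
During training, an invalid selected pair incurs −log(1 − P_{f+d}(k\*|i\*)):
the model is pushed to withdraw confidence from impossible substitutions.
The penalty is applied to the single selected pair (the summand of the
written validity objective does not depend on the summation index; we read
the 1/N_a Σ_i as selecting that one term).

**Objective.** L_Bio + λ₁·L_AFSE + λ₂·(L_Recon + L_Val) with λ₁ = 0.6,
λ₂ = 0.3. L_Bio is MSE on the pActivity scale (regression) or logit
cross-entropy (classification). Adam, base rate 3·10⁻³, batch 32, 100
epochs, linear warm-up over the first 10% of steps then linear decay to
zero. The base rate is higher than the 10⁻³ conventional for small graph
networks because the decoder otherwise underfits at the data scales this
package targets (it plateaus predicting carbon everywhere); 3·10⁻³ with
D = 64 fits reconstruction cleanly.

The best model is the epoch checkpoint maximizing reconstruction rate +
validity rate on the training set (ties to the earliest epoch);
reconstruction rate is the fraction of molecules with every atom symbol
recovered exactly, validity rate the fraction of selected substitutions
passing the valence check among molecules where one was selected.

## The perturbation size η

η is the main user knob: it is the distance traveled in embedding space,
i.e. how far from the anchor the decoder is asked to look.

- *Training* (stabilization loss): η = 1.0, a small perturbation relative
  to typical embedding norms, consistent with a smoothness regularizer.
- *Optimization*: `eta="auto"` scans a geometric ladder
  η ∈ ‖f‖·{1/16, 1/8, 1/4, 1/2, 1} and keeps the smallest perturbation
  whose decoded branch proposes a confident substitution. Rationale: the
  embedding displacement of a one-atom change is a property of the trained
  encoder, not a constant; on trained models it is a sizable fraction of
  ‖f‖ (≈ ‖f‖/3 on the study fixture). Taking the smallest effective step
  keeps the proposal as close to the anchor as the decoder allows, which is
  the matched-molecular-pair premise. A fixed numeric η remains available.

One perturbation is drawn per molecule per call with the run's seeded
generator, so results replay exactly from the recorded seed.

## Synthetic study system

The generator emulates a ligand series with activity cliffs. Each scaffold
is a random aliphatic skeleton (chain or ring of 4–12 carbons, up to two
methyl decorations) carrying one marked substitution site — a terminal
heteroatom. Variants place O or S at the site and

    activity = base(scaffold) + effect(element) + N(0, σ),

with base ~ U(5, 7) pActivity, effects {O: 0, S: +2} and σ = 0.2 by
default. The 2-log-unit element effect against 0.2 noise makes every O/S
pair a genuine ≥10-fold cliff; σ is nonzero to avoid degenerate fits.
Scaffolds are deduplicated on their site-masked canonical form, which
guarantees (and tests verify) that two generated molecules differ at
exactly one atom *iff* they are variants of the same scaffold — the
planted cliff list is exhaustive and the miner can be checked against it
exactly at σ = 0.

A scaffold can instead emit a single variant ("singleton"). The study
configuration used by the tests and the acceptance script is 135 scaffolds:
65 paired (130 molecules, 65 cliffs) and 70 singletons, 200 molecules in
all. Singletons matter: in the optimization split every cliff's high member
is held out, so without them the training set would contain no
high-activity S-bearing example and the element effect would be
unlearnable. Real screening libraries always contain such background
actives; the singleton fraction mimics that.

What the generator does **not** emulate: aromatic and fused-ring
chemistry at the site, multi-site structure–activity interactions,
assay heteroscedasticity, scaffold-activity correlation, and any
distribution shift between train and test beyond the cliff split itself.
Passing the fixture tests therefore shows the machinery is correct and the
mechanism works when a single-site element rule dominates; it does not
show the method recovers cliffs in real GPCR data.

## Evaluation protocol

Optimization experiment: mine cliffs, hold out every high member, train on
the rest, run one optimization per anchor (the low members), and count
exact canonical-SMILES matches of emitted molecules against the held-out
highs ("discoveries"). The comparison baseline applies one uniformly random
valid single-atom substitution per anchor — the matched-budget null. The
reverse experiment mirrors the split and decodes f − d instead.

A discovered pair's transformation is "novel" when its key — the
substituted atom's element, its first-shell (neighbor element, bond order)
environment, and the new element — does not occur among the training set's
cliff transformations.

## Numerical choices and degenerate inputs

- All tensors are float64; the autodiff engine is plain NumPy, so results
  are deterministic given the seed up to BLAS reduction order.
- Logarithms in losses clamp their arguments at 1e-12.
- Probe gradients below 1e-12 in norm yield a zero perturbation ("flat
  probe") rather than a division blow-up.
- Single-atom molecules skip neighbor attention; their context vector is
  zero.
- A molecule every atom of which is the same element has zero
  reconstruction-loss weight everywhere; it contributes nothing to
  L_Recon (and cannot, since the weights are the within-molecule element
  shares).
- r² is reported as not-applicable (None) when either vector has zero
  variance; validity rate is None when no substitution was selected —
  never 0/0.
- Dropout (0.1) is active only in training mode; every evaluation,
  rate computation and optimization pass runs with dropout off, so
  (i\*, k\*) is reproducible.
- `TrainConfig.stop_at_reconstruction` optionally ends training once the
  training-set reconstruction rate reaches a target; the learning-rate
  schedule is still laid out for the full epoch budget.

## Known limitations

- The decoder only relabels atoms on a fixed skeleton: no atom insertion
  or deletion, no bond edits, no ring rewiring, one substitution per
  anchor per run.
- Formal charges pass through substitution unchanged and the valence rule
  uses neutral-atom maxima; chemistry where that is wrong is rejected
  rather than modeled.
- Stereochemistry is dropped on parse; discovery matching is
  stereo-agnostic.
- Cross-cliff generalization of the *predictor* (accuracy on held-out
  cliff highs) is weak at this data scale for all objective variants; the
  package's value on the fixture is in recovering the planted
  transformation, which succeeds far above the random baseline, not in
  extrapolating absolute activities across cliffs.
- With the adversarial and reconstruction terms removed (λ₁ = λ₂ = 0) the
  model still predicts, but cannot optimize: the decoder and the
  perturbation are the optimization machinery.
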