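# olbac

Joint **ligand-bioactivity prediction** and **single-atom ligand
optimization** around activity cliffs.

Activity cliffs — pairs of nearly identical molecules with very different
potency against the same target — are the main failure mode of QSAR
models, but they are also a map of exactly which small chemical edit buys a
large activity gain. `olbac` is built for computational chemists who want
both sides of that coin: a graph-based activity model that stays accurate
near cliffs, and a generator that turns the model's own gradients into
concrete one-atom edit proposals (a *matched molecular pair* away from the
anchor).

## Method in brief

A molecule is a heavy-atom graph. An attentive message-passing encoder
yields atomic embeddings h_i and a molecular embedding f = Σ_i h_i; a
predictor N(f, f) maps it to pActivity (−log₁₀ molar potency) or a
classification logit. A random probe r (‖r‖ = ε) in the second slot of N
gives the adversarial perturbation

    d = η·g/‖g‖,   g = ∇_r D(N(f,f), N(f,f+r)),

the embedding direction of fastest prediction change. A graph
reconstruction decoder maps {f + s·d, H} back to per-atom element
probabilities: s = 0 reconstructs the input, s = +1 asks "what would this
molecule look like if its embedding moved toward higher activity?". The
atom whose most confident *non-original* element assignment is strongest
becomes the substitution site i\*, the element k\* is the most confident
candidate above threshold P₀, and the proposal is emitted only if it
passes chemical valence rules. Training jointly minimizes

    L_Bio + λ₁·L_AFSE + λ₂·(L_Recon + L_Val),      λ₁ = 0.6, λ₂ = 0.3

(prediction error, prediction stability under d, element-weighted graph
reconstruction, and a penalty on chemically invalid proposals). See
`docs/methods.md` for the full model and its assumptions.

## Worked example

`examples/03_optimize_ligands.py` builds a synthetic library with a
planted rule (S at a marked site is worth +2 log units over O), hides the
high member of every mined cliff, trains on the rest, and optimizes each
low-activity anchor:

```
135 molecules, 45 cliffs; train 90, held out 45
generated 41 molecules from 45 anchors; 41 are held-out high-activity ligands
random single-substitution baseline: 1 discoveries

example proposal: CC1CC(C)C(O)C1 → CC1CC(C)C(S)C1
  atom 6 (O → S), confidence 0.59
```

Reading this: of 45 anchors, the model proposed a confident, chemically
valid single-atom edit for 41 — and every proposal reproduced, atom for
atom, the real high-activity molecule that had been hidden from training.
A uniformly random valid substitution at the same budget finds 1. The
confidence is the decoder's posterior for the chosen (atom, element) under
the activity-raising perturbation; proposals below P₀ = 0.5 are never
emitted.

The other examples show the pieces in isolation:
`examples/01_simulate_and_mine.py` (library generation and exact MMP-cliff
mining) and `examples/02_train_and_predict.py` (prediction accuracy, r²
and RMSE).

## Command line

Every step is also a subcommand of `olbac`:

```bash
olbac simulate    --config fixture.yaml --seed 1 --out data.csv --truth cliffs.json
olbac mine-cliffs --data data.csv --fold 10 --out cliffs.json
olbac train       --config config.yaml --data train.csv --seed 1 --out run/
olbac optimize    --model run/model.npz --input anchors.csv --direction forward --seed 1 --out results.csv
olbac evaluate    --model run/model.npz --generated results.csv --heldout heldout.csv --out report.json
```

Each run writes a JSON manifest (seed, config hash, vocabulary hash) that
suffices to replay it.

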