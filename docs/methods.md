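# Methods

`spinsys` predicts full NMR spin systems — per-atom chemical shifts (¹H,
¹³C, ppm) and per-pair scalar couplings (¹J_CH, ²J_HH, ³J_HH, ⁴J_HH, Hz) —
from 2D molecular input, with a per-value uncertainty.  This note records
the model, its assumptions, the synthetic study conditions, and the design
choices that were genuinely open.

## Featurization

A molecule (SMILES or SDF, explicit hydrogens added on load) must contain
only H, C, O, N, F, S, P, Cl and at most 128 atoms.  Three feature blocks
are built:

* **Vertex features** `x` (N × 21): element one-hot (8), atomic number
  (scaled by 1/35), default and total valence (scaled by 1/4), formal
  charge, Gasteiger partial charge, aromaticity flag, ring-membership flags
  for ring sizes 3–8, and the hydrogen count on the heavy atom.
* **Adjacency stack** `G_adj` (N × N × 5): any-bond, single, double,
  triple, and bond-order-1.5 slices.  Aromatic bonds populate the 1.5
  slice; no kekulization is applied, so the any-bond slice is the
  elementwise maximum of the class slices.
* **Geometric pair features** `G_feat` (N × N × 22), summarizing a
  distance-geometry conformer ensemble: the Boltzmann-weighted mean
  interatomic distance; a 16-center Gaussian basis expansion of the
  distance distribution (centers evenly spaced 0.75–4.5 Å, shared width
  σ_d = 0.25 Å, each feature the weighted mean over conformers of
  exp(−(d−c)²/2σ_d²) — the 0.25 Å resolution is what lets the network
  recover dihedral-dependent couplings from the vicinal H–H distance
  distribution); for atom pairs sharing a bonded neighbor, the weighted
  mean angle at that neighbor plus a present/absent flag; and, for pairs
  whose shortest bond path has length 3, the weighted mean cos θ and
  cos 2θ of the path torsion plus a flag — the geometric summary vicinal
  couplings depend on through the Karplus relation (the distance
  distribution alone under-determines the dihedral once bond-angle jitter
  is present).  Distance-derived slices have a zeroed diagonal.

Conformers come from the knowledge-based distance-geometry embedder
(ETKDGv3) with a fixed seed (an embedding failure is retried once with
random-coordinate initialization).  Each conformer then receives a single
MMFF94 minimization iteration, and the resulting MMFF energies give
Boltzmann weights w_k ∝ exp(−(E_k − min E)/RT) at T = 298.15 K (the
temperature is a config field; the min-energy shift keeps the exponentials
stable, making weights exactly invariant to a constant energy offset).
The iteration count is a parameter: the default 1 matches the fast
pipeline, while rigid-molecule invariance checks run the same code with a
converged minimization (2000 iterations, force tolerance 1e-8), under
which methane/benzene features agree to 1e-6 regardless of ensemble size.
If MMFF parameters are unavailable the ensemble falls back to uniform
weights and is flagged.  A note on seeding: the embedder treats a seed of
0 degenerately (every conformer identical), so seeds are mapped into
[1, 2³⁰] internally.

Units are Å, radians and kcal/mol throughout featurization.

## Network

Two stacks run on the same inputs.

**Message-passing layers** update vertex states only.  The adjacency stack
is augmented with matrix powers of the any-bond slice (default powers
{2, 3}, kept as raw path-count powers) and an identity slice (self-loops).
Each slice has an independent linear lift of the vertex state; the slice
multiplies its lifted state; per-slice linear collection maps back to the
hidden width, followed by ReLU and per-vertex layer normalization.

**Decode layers** alternate GRU updates of the vertex state and a dense
N × N edge state initialized from [G_adj | G_feat] through a linear lift,
ReLU and layer norm.  The vertex GRU takes the masked mean over the
neighbor axis of the edge state as input (mean is the default aggregation;
sum and max are selectable).  The edge GRU's input is the linear map of
the concatenated endpoint states [x_i | x_j]; because that map and the
GRU's input projection compose linearly, they are parameterized directly
as one learned per-endpoint, per-gate projection evaluated per vertex and
broadcast over pairs — the same function family at ~N× less compute than
materializing per-pair inputs.  After every edge update the state is
symmetrized by transpose-averaging, which together with elementwise heads
makes J(i,j) = J(j,i) hold bitwise.  Both outputs pass through a linear +
ReLU + layer-norm stage.  Padded atoms are masked out of every
aggregation, normalization statistic and loss.

The final vertex representation is the concatenation of the two stacks'
vertex states.  B bootstrap heads (default B = 10; the scaled study uses
4) — each one residual block plus a linear output, evaluated jointly as
batched matrix products over the head axis — map it to per-nucleus shift
channels; the final edge state feeds the analogous coupling heads.  Every
output has two data channels (experimental / ab initio).

The two data channels are tied at the output: the heads emit an ab initio
level and a damped per-atom correction, and the experimental channel is
level + a learned per-class scalar offset + correction.  Tying the
channels this way — sharing everything except a mostly-systematic
correction — is what lets the experimental/ab-initio difference learned on
dual-labeled data transfer to chemistry where only ab initio labels exist;
with fully independent output units per channel the experimental output
simply fails to extrapolate there.  Consequently the two channels share
per-class standardization constants (training mean/std pooled over
channels); predictions are de-standardized at output.  Losses are computed
in standardized units so ¹³C (tens of ppm) does not drown ¹H (a few ppm).

## Bootstrap uncertainty

Each molecule is assigned a fixed subset of heads: head h is included with
probability p_include = 0.5 via a SHA-256 hash of (molecule_id, h, seed),
with the smallest-hash head forced in if the draw is empty.  The training
loss for a molecule uses the mean over its subset, so each head sees a
different slice of the data while the trunk sees everything.  At test time
the prediction is the mean over all heads and the uncertainty the sample
standard deviation (ddof = 1; exactly zero for identical heads, arranged
by computing the mean relative to the first head; B = 1 reduces exactly to
a single-model trainer).  Subsets are fixed per molecule rather than
redrawn per epoch — the simplest scheme that keeps runs reproducible; a
per-epoch redraw would trade head diversity for noise and is left as a
config extension.

## Disagreement regularization

With dual labels ϕ_a (ab initio) and ϕ_e (experimental), the per-atom loss
on the two-channel output is

    L = L_a + [ λ / (|ϕ_a − ϕ_e| + 1 ppm) ] · L_e

with L_a, L_e the base losses (absolute error by default; Huber
selectable) on the respective channels.  When only one channel is labeled
the loss is that channel's base loss.  The 1 ppm denominator offset is
fixed; λ ≥ 0 is the single tunable weight, λ = 0 reduces exactly to
ab-initio-only training on dual-labeled atoms, and the experimental weight
decreases strictly and continuously as the channels disagree.  The weight
is computed from raw (ppm) labels even though the base losses are
standardized, preserving the meaning of the 1 ppm offset.  By default the
rule applies to shift channels; couplings train with a direct per-channel
loss (a Hz-offset disagreement variant is a config toggle).

Training uses Adam (lr 3e-3, cosine-annealed to 5% over the run), batches
of 32 padded to the largest molecule in the (size-sorted) batch, early
stopping on validation MAE with patience 20, and a single seed driving
initialization, shuffling, splits and head assignment; reruns are
bit-identical on one machine.  Non-finite loss aborts with a diagnostic.

## Synthetic study conditions

No public shift/coupling corpus ships with the package; a fixture
generator defines the study conditions instead.  Molecules are assembled
from a fragment grammar over C/O/N/F/Cl: chains of 3–6 heavy atoms with
heteroatom substitutions and short branches; 35% of molecules carry a 3-
or 4-membered ring (region "B", the small-ring analogue); 20% get random
stereocenter assignments.  Fixture ensembles use 16 conformers — a
scale-down from the 50-conformer pipeline default that still averages the
single-step MMFF geometry jitter enough for vicinal couplings (at the
~16 Hz/Å dihedral–distance slope, per-conformer distance noise of ~0.03 Å
costs ~0.5 Hz, and the ensemble average divides it by roughly the square
root of the effective conformer count).

Labels are a smooth deterministic function of graph and geometry:

* ¹H shifts: base by attached heavy atom (C 1.0, O 3.0, N 2.0 ppm) +
  0.7 ppm per β-heteroatom − 0.9 ppm for small-ring attachment (the
  cyclopropane-like upfield shift) + 4·q_Gasteiger + a through-space term
  2·Σ_het exp(−d̄/1.2 Å).
* ¹³C shifts: 25 + 7·(heavy neighbors) + 22·n_O + 12·n_N + 16·n_halogen −
  22·(small ring) + 30·q.
* ³J_HH: the Boltzmann-weighted ensemble average of the Karplus-style
  J(θ) = 7 cos²θ − cos θ + 1.1 Hz over each conformer's H–X–Y–H dihedral —
  the averaged observable NMR measures — so the conformer ensemble
  genuinely carries label-relevant information.
* ¹J_CH: 125 + 38·(small ring) + 9·(heteroatom neighbors) +
  25·(d̄_CH − 1.09); ²J_HH: −12.4 + 1.8·(heteroatom neighbors) +
  5·(d̄_HH − 1.78); ⁴J_HH: 1.3·exp(−d̄_HH/1.1).

The experimental channel adds noise: shifts heteroscedastic (σ = 0.15 ppm
¹H / 1.0 ppm ¹³C, with 25% of molecules at 3× — emulating poorly
referenced user-contributed spectra — and O/N-bound protons at a further
3×, emulating the well-documented extra error on exchangeable protons),
couplings homoscedastic σ_J = 0.5 Hz.  The ab initio channel is the clean value plus a fixed global
offset (0.3 ppm ¹H, 2.0 ppm ¹³C, 0.2 Hz) plus small noise (0.05 ppm /
0.02 Hz).  Everything is deterministic given the generator seed.

What the generator does *not* emulate: real electronic structure (labels
are additive heuristics, not quantum chemistry), solvent/temperature
effects, conformer-dependent shift averaging beyond the through-space
term, misassignment errors (noise is Gaussian, not permutation-valued),
and molecules beyond ~20 atoms.  Passing tests therefore demonstrate that
the architecture, losses and uncertainty machinery work as specified on
data with this statistical structure — not that the shipped weights
predict real spectra.

## Scaled study sizes

The learnability study trains the 2 MP + 2 decode, width-64, B = 4 model
on 2,000 fixture molecules (300 held out) for 18 epochs; its held-out
³J_HH MAE is compared against the aleatoric floor σ_J·√(2/π) ≈ 0.399 Hz
and against the best-constant predictor.  The region experiment trains
four configurations (baseline, experimental control, ab initio control,
disagreement λ = 5) on 600 molecules (ring fraction 0.5, region-stratified
22% held out) for 22 epochs each — long enough that the ab initio
control's systematic offset is exposed rather than masked by underfitting.
DP4 baselines use 5,000 Monte-Carlo trials (random predictor over 8
candidates) and 400 noisy-oracle molecules.
`scripts/acceptance.py` re-runs all of this from scratch and writes the
measured values.

## DP4 stereoisomer identification

Candidates are enumerated over unassigned stereocenters/double bonds
(input structure first, deterministic order, capped at 8).  Per candidate,
errors between (optionally linearly rescaled) predicted and reference
shifts are scored by the Student-t tail probability with the published DP4
parameters (¹H: σ = 0.185 ppm, ν = 14.18; ¹³C: σ = 2.306 ppm, ν = 11.38),
multiplied across nuclei in log space and normalized over candidates.
Linear rescale (fit of prediction on reference, canonical DP4 practice) is
the default; "none" is provided for ablation since the upstream usage is
not specified.  With rescale active, a common additive error leaves the
ranking unchanged.

## Numerical choices and limitations

* The network runs in float32 for training throughput; float64 is a config
  switch (used by the equivariance checks; permutation equivariance then
  holds to ~1e-9).
* The autodiff core is a minimal reverse-mode tape over NumPy arrays,
  gradient-checked against central finite differences.  ReLU and |·| use
  the zero subgradient at their kinks.
* Layer norm uses ε = 1e-5; padded rows are masked after normalization so
  they never contribute.
* Boltzmann weighting shifts by the minimum energy before exponentiating.
* Best-constant baselines use the training median (the L1-optimal
  constant).
* Early-stopping checkpointing keeps the best validation weights.
* Known limitations: dense N² edge states cap practical molecule size well
  below the 128-atom input limit on a single CPU; the bootstrap spread
  captures coverage (epistemic) uncertainty and is only indirectly
  sensitive to label noise; the fixture label model is not transferable to
  real spectra and the shipped defaults should be retrained on measured
  data for any real application.
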