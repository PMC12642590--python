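# Methods

## The prediction problem

A deep mutational scanning (DMS) experiment assigns each protein variant a
functional score, usually a wild-type-centered log2 enrichment of
sequencing reads between an input library and a post-selection pool.  A
supervised variant effect predictor (VEP) maps a variant to that score.
`biovep` studies the regime where prediction must *extrapolate* beyond the
mutations or positions covered by training data, and implements the
hypothesis that per-residue physical features — mutational folding-energy
changes and structural flexibility — carry exactly the information that
sequence-only models lack there.

## Variant encoding

Variants are sets of point substitutions over a 21-symbol alphabet (20
canonical residues plus `*` for stop), validated against a reference
sequence.  A variant is encoded as an `L × D` matrix, row `i` describing
the amino acid present at position `i`:

* **One-hot (21).**  Indicator of the residue at that position.
* **Property PCs (19).**  A 20 × P amino-acid property matrix (AAIndex
  style) is compressed by PCA.  Twenty centered points span at most 19
  dimensions, so 19 components always carry 100% of the variance; each
  component score is then min-max scaled to [0, 1].  Scaling after the PCA
  preserves that variance accounting.  Stop-codon rows get zero property
  PCs, since physicochemical properties are defined only for residues.
* **Energy terms (8, biophysics only).**  A precomputed table holds, for
  every (site, substitution) pair including the wild-type
  self-substitution, the total ΔΔG (= ΔG_wildtype − ΔG_mutant, REU) and
  its per-term components.  The table is produced externally by a
  side-chain-repacking protocol (the shipped tables record repacking
  radius 12 Å, one repacking iteration); generating it is out of scope
  here by design — the package treats it as a resource with a documented
  schema.  Values are squashed (below), the 7 components with largest
  variance are kept next to the always-retained total ΔΔG, and each of
  the 8 features is min-max scaled over the table.  Unmutated rows carry
  the self-substitution entry (zero by construction); stop rows use the
  squash ceiling — a truncation is treated as maximally destabilizing.
  Multi-mutant variants place each mutation's single-mutation entry at
  its own row; additivity across sites is left to the model.
* **RMSF (1, biophysics only).**  Per-residue Cα root-mean-square
  fluctuation, min-max scaled.  It is a property of the wild-type
  structure, identical across variants, and informs which sites can
  absorb mutations.

`D` is 40 without the biophysics blocks and 49 with them.

**Energy squashing.**  Energies above 50 REU come from hard steric
clashes and are not quantitatively meaningful, so they are saturated by
`f(x) = x` for `x ≤ t` and `f(x) = t + t·tanh((x − t)/t)` above, with
`t = 50` REU: continuous with unit slope at the threshold, asymptote
`2t = 100` REU.  The piecewise-tanh form was chosen because it is closed
form and C¹, making its contract (identity below, monotone, bounded)
directly testable.

**Normalization and leakage.**  All min-max normalizers are fitted on the
variant-independent resources (the energy table, the RMSF profile, the PC
scores), which depend only on the wild-type protein — so nothing about
which variants land in a test split can leak through them.  Values
outside a fitted range are clipped to [0, 1] rather than extrapolated.

## Contact graphs

Nodes are residues; an edge joins residues whose representative atoms —
Cβ, or Cα for glycine — lie within a cutoff (7 Å default; 6 Å is
conventional for very large proteins).  Distances are Euclidean in Å.
Graph convolutions use the symmetric-normalized adjacency with self-loops,
`D^(−1/2)(A + I)D^(−1/2)`, the standard spectral propagation rule; on an
edgeless graph it reduces to the identity, so a graph layer degenerates to
a per-residue dense map (a tested property).  The first chain of the first
model of a PDB file is used unless configured; insertion codes are
rejected rather than silently renumbered.

## Split schemes

* **random** — shuffle variants 70/15/15 (floor-sized validation and test,
  remainder to train).
* **mutational** — partition the unique (position, substitution) pairs
  70/15/15; a variant is assigned only if *all* its mutations fall in one
  partition, otherwise it is dropped and logged.
* **positional** — the same over mutated positions.

The all-or-drop rule is the only assignment that guarantees zero shared
mutations (or positions) between partitions; the drop is symmetric (train
loses spanning variants too).  Wild-type records carry no held-out
information and default to train.  Splits are pure functions of
(dataset, fractions, seed).

## Models and training

All four families regress the scalar score from the `L × D` matrix:

* **LR** — affine map on the flattened matrix.
* **NN** — dense layers, leaky ReLU, dropout 0.2, scalar output.
* **CNN** — 1-D convolutions along the residue axis (features as
  channels, stride 1, valid padding, leaky ReLU), then a dense head.
* **GCN** — graph convolutions over the fixed propagation matrix, then a
  dense head.

**Readout head.**  The CNN/GCN head is configurable.  The default
(`head="pool"`) global-averages over positions before the dense layer,
making the whole model position-invariant: weights learned at training
positions apply unchanged at positions never mutated in training, which is
what makes positional extrapolation possible at all, and which realizes
the additivity assumption of the energy encoding.  The alternative
(`head="flatten"`) concatenates positions, giving the readout
position-specific weights — more expressive under random splits, but
measurably unable to extrapolate positionally (its positional-validation
loss never beats the variance baseline on the synthetic world, with or
without weight decay).  The pooled default is the package's deliberate
design choice for the extrapolation problem.

**Optimization.**  MSE loss, Adam (default 5 × 10⁻⁴), batch 64, up to 300
epochs with early stopping (patience 30) on validation loss, best-epoch
weights restored.  Targets are standardized to zero mean / unit variance
on the training split and predictions mapped back, so the output layer's
conditioning does not depend on the score scale.  An optional
reduce-on-plateau schedule exists but is off by default: with the small,
distribution-shifted validation sets of extrapolation splits, plateau
detection is noisy and tends to freeze training early.  Every source of
randomness — initialization, batch order, dropout masks — draws from
generators seeded by the configuration, so training is bit-reproducible.
Default widths (24 filters, kernel 5, one conv layer, dense 64) were
chosen by validation-set comparison; `run_experiment` accepts a config
grid and selects by validation Pearson when asked.

**Evaluation.**  Pearson *r* and Spearman ρ (undefined on constant
vectors and reported as missing, not coerced to 0), MAE, and an MAE
breakdown by mutations-per-variant.  Experiments repeat 5 times; each
repeat redraws the split with its own seed and re-seeds training.
Summaries report medians over repeats.

## Enrichment scores

The two-condition wild-type-centered form
`log2((c_sel + ½)/(c_inp + ½)) − log2((wt_sel + ½)/(wt_inp + ½))`
with pseudocount 0.5.  This is the standard two-timepoint ratio score; the
full weighted-regression machinery of multi-timepoint scoring pipelines is
deliberately out of scope, and scores read from a table are taken as-is.
The simplified form is antisymmetric under swapping variant and wild type
and strictly monotone in each count — both property-tested.

## Read-count resampling experiment

To study how library size and sequencing depth shape VEP accuracy: hold
out a fixed scored test set (default 10,000 variants, truncated to the
dataset); from the left-over pool repeatedly (i) draw a uniform variant
library of a given size (the wild type always rides along for score
centering), (ii) renormalize its input/selected counts into two
multinomial distributions, (iii) split a total read budget between the
conditions in the base pool's input:selected proportion and draw new
counts (drawn reads equal the budget exactly), (iv) recompute enrichment
scores, (v) train the specified model and evaluate on the fixed test set.
Five replicates per grid cell; cells whose library size exceeds the pool
are reported empty.  Within a replicate, all cells share one shuffled pool
permutation, so libraries are *nested* across sizes and identical across
budgets, and training seeds are shared — common random numbers that pair
the cross-cell comparisons and remove library-sampling variance from
them.

A caveat the synthetic experiments surface clearly: test accuracy is
non-decreasing in read budget, and in library size *when per-variant
depth remains adequate* — but at severely read-starved budgets (around
one read per variant) a larger library spreads the budget thinner and
performs *worse* than a smaller one.  The experiment is precisely a
size-versus-depth tradeoff, and the monotone-in-size claim applies on
the adequate-depth side of it.  The shipped checks therefore assert
monotonicity along the grid's informative margins — read budget at the
large library, library size at the deep-read column, and the starved
corner against the best corner — and deliberately do not rank cells
inside the starved corner, where the tradeoff reversal and the variance
of models trained on a few dozen samples dominate.

## Synthetic worlds

The generator produces, from one seed: a random reference sequence; an
idealized α-helix (Cα trace, radius 2.3 Å, 100°/residue, 1.5 Å rise) with
radially offset Cβ atoms, written as a PDB stub whose contact graph at
7 Å is connected; an energy table with 19 REF2015-style term labels whose
per-term scales follow a geometric ladder (so variance-based term
selection has real structure to find), ~1.5% steric-clash entries above
the 50 REU squash threshold on the repulsive term, exact zeros for
self-substitutions, and total ΔΔG equal to the term sum; a smooth
flexibility profile, floppier at the termini; and a low-rank-plus-noise
property matrix with 19 informative PCs.

Ground-truth fitness is a two-state stability-fitness curve,
`F = max_score / (1 + exp((ΣΔΔG − μ)/σ_f))` with midpoint μ = 5 REU,
softness σ_f = 2 REU, max 1, observation noise σ = 0.02 — a logistic
rather than linear link so that nonlinear models have something to gain
over LR.  Selection multiplies input frequencies by `exp(α·F)` (α = 4),
and both pools are sequenced as multinomial draws (default 2 × 10⁶ reads
per condition for 5,000 variants, ~400 reads/variant, in line with deeply
sequenced DMS libraries); scores are then enrichment scores of the drawn
counts — the estimator inverting the generative model.  Default library
composition is 45% single / 40% double / 15% triple mutants, the
single-and-double-dominated shape of real DMS libraries.

Because fitness depends on sequence only through the energy table, the
biophysics features are *sufficient statistics* for fitness, and because
the table entries are independent draws per (site, substitution),
amino-acid identity carries no cross-position signal.  The synthetic
world is therefore a controlled best case: it demonstrates that the
pipeline can exploit energy features where they are informative, and that
sequence-only models are at chance under positional extrapolation.  What
it does **not** show: real Rosetta energies are noisy, correlated across
sites and substitutions, and only partially determine measured function;
real amino-acid substitution effects do share structure across positions
(so real sequence-only baselines sit above chance); and real epistasis
violates the additivity assumption.  Synthetic results bound what the
architecture can do, not what any real protein will yield.

## Known limitations

* Energy tables and RMSF profiles are consumed, never computed; the
  package contains no molecular-mechanics code.
* The enrichment score is the simplified two-condition form, not a full
  multi-timepoint scoring pipeline.
* Multi-mutant energies are strictly additive in the encoding; epistatic
  energy coupling is not represented.
* The NumPy networks are sized for CPU-scale experiments (thousands of
  variants, hundreds of residues), not for half-million-variant datasets.
* Positional numbering offsets between published tables and reference
  sequences must be supplied by the caller (`offset=`); no automatic
  alignment is attempted.
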