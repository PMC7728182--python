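# Methods

## Model

A hidden Potts model (HPM) over a family with M consensus columns consists
of three parts.

**Match emission.** The M match characters are drawn jointly from a Potts
(Markov random field) distribution over the K = 5 alphabet A, C, G, U plus
a deletion character: P(x_m) ∝ exp H(x_m) with
H = Σ_k h_k(x_mk) + Σ_{k<l} e_kl(x_mk, x_ml). The coupling tensor is stored
fully with the symmetry e_kl(a,b) = e_lk(b,a) and zero diagonal blocks;
each pair contributes once (k < l) to the Hamiltonian. The partition
function is intractable at realistic M and is never computed; all scoring
is unnormalized. Deletions are emitted characters, which is what lets a
fixed-topology emission process express variable occupancy of consensus
columns.

**Insert process.** Since every HPM path visits every match node, the
transition model reduces to an insert-only affine process: after node k
(k = 0 is the 5' flank, k = M the 3' flank) an insert run opens with
probability t_open[k] and extends with t_ext[k] (geometric run length).
Insert residues are i.i.d. from a shared 4-letter distribution.

**Null model.** i.i.d. residues at the training background frequency over
the observed length, no length term. Log-odds scores are reported in bits
(base 2); a 2-bit increase is exactly a 4-fold likelihood-ratio factor.
Because P* is unnormalized, bit scores are comparable only within one
model; all benchmark logic uses within-model comparisons only.

## Proposal distribution and importance sampling

The proposal is a *glocal* profile HMM (global to the model, local to the
sequence only through flanking inserts): entry before node 1, exit after
node M, no local begin/end. All nine M/I/D transitions are present,
including D→I. That completeness is load-bearing: a pHMM path maps
bijectively onto an HPM decomposition (D states emit the deletion
character; I runs become insert runs), and without D→I the proposal could
not reach decompositions where an insert run follows a deleted node, which
would make the importance-sampling estimator converge to a strictly
smaller sum than the true marginal. The estimator's unbiasedness is tested
against an exact enumeration oracle on tiny models.

Scoring a sequence costs one O(ML) Forward fill, then R stochastic
tracebacks at O(L + M) each plus an O(M²) Hamiltonian re-scoring per
sample. Tracebacks for all R samples are run in lockstep as vectorized
array operations; Hamiltonians for a batch of R match sequences are one
(R, MK) × (MK, MK) matrix product. Weights are averaged with log-sum-exp;
the effective sample size ESS = (Σw)²/Σw² is reported and a warning is
issued below 100, the regime where the estimate is dominated by a handful
of samples. The default R is 10⁶, matching the scale at which the
estimator is typically stable for benchmark-sized models; tests and the
acceptance script use 10³–10⁵ (stated per experiment below).

## Training

**Profile HMM.** Weighted observed counts along each training sequence's
implied path with a Laplace +1 pseudocount per legal transition and per
match residue; insert emission = background = weighted overall residue
frequency; Henikoff position-based sequence weights, renormalized to sum
to the sequence count (so uniform rescaling is a no-op). No mixture
Dirichlet priors and no entropy weighting — deliberately plain maximum a
posteriori counts, so every number is reproducible from the alignment
alone.

**Potts, pseudolikelihood (PLM).** Weighted negative log-pseudolikelihood
with ridge penalties, minimized by L-BFGS-B from zero initialization
(deterministic), gradient tolerance 1e-5, iteration cap 5000. Couplings
are estimated asymmetrically (one conditional per site) and symmetrized by
averaging, the standard PLM convention. Defaults λ_h = 0.01 and
λ_e = 0.2·(M−1)/2 (length-scaled, in the style of common DCA trainers);
both are configuration surface, not fitted constants.

**Potts, masked (analytic).** For a disjoint set of annotated base pairs:
e_kl(a,b) = log of the Laplace-smoothed (+1 over K² cells) weighted joint
frequency with h_k = h_l = 0 at paired sites; h_k(a) = log smoothed
marginal at unpaired sites, couplings zero. The distribution then
factorizes over pairs and singletons, Z = 1 exactly, and the model's exact
marginals reproduce the smoothed training frequencies — tested to 1e-12.
The nested-only and nested+pseudoknot variants differ only in which
annotated pairs enter the mask.

**Structure input.** Base pairs are read from the Stockholm `#=GC SS_cons`
line (WUSS): matched brackets are nested pairs, uppercase/lowercase letter
pairs are pseudoknots, pairs touching non-consensus columns are dropped,
and coordinates are 0-based indices into the ordered consensus columns.
Consensus columns are those with strictly less than 50% gaps, unweighted.

## Emission (MCMC)

Match sequences are emitted by Metropolis–Hastings: independent chains,
i.i.d.-uniform initialization, one proposal per iteration (uniform site,
uniform character, acceptance min(1, e^ΔH)), state taken after a burn-in
of 5000 proposal iterations (counting proposals, not acceptances). Chains
are advanced in lockstep for speed but share no state. Single-site
marginals from 10⁴ samples match exact enumeration within total-variation
0.02 on tiny models. σ is a random walk over the insert process and insert
residues are i.i.d.; the implied alignment is retained as ground truth.

## Information content

Primary information is the per-column relative entropy (bits) of
Henikoff-weighted residue frequencies over non-gap rows against a uniform
0.25 background, summed over consensus columns; secondary/tertiary
information is the summed mutual information over nested / other disjoint
annotated pairs, computed from rows co-occupied in both columns, with no
pseudocount. Marginals are re-derived from the joint so the decomposition
identity RE(joint) = RE(i) + RE(j) + MI(i,j) holds exactly.

## Contact ranking

Pair score = Frobenius norm of e_kl over the 4×4 residue block (the
deletion row/column is excluded — contacts are residue–residue structural
signal), followed by the average-product correction computed with
full-matrix means (which annihilates a rank-one score matrix exactly).
Top ⌈M/2⌉ pairs are reported.

## Benchmarks

**Splits.** Sequences are clustered by single linkage at 60% pairwise
identity; whole clusters go to train or test, so no test sequence exceeds
60% identity to any training sequence by construction; the test pool is
then greedily thinned (dropping the member with most conflicts, highest
index first) until no pair exceeds 70%. Identity is matches divided by
columns where both rows carry residues, computed on the reference
alignment rows — a convention chosen for reproducibility where curated
benchmarks leave the denominator open. Cluster assignment moves smallest
clusters (seeded shuffle for ties) into the test pool until it reaches a
minimum size (default 5).

**Decoys.** i.i.d. residues from the pooled composition of the positive
test sequences, lengths matched to randomly chosen positives; 200,000 at
full benchmark scale, hundreds to thousands in routine runs (the ROC at
the tested false-positive rates is insensitive to this).

**Scoring.** One Forward fill and one batch of R tracebacks per sequence
are shared across all HPM variants (full PLM, coupling-free, masked
nested, masked pseudoknotted), which differ only in re-weighting; the
profile HMM baseline is its own Forward bit score. ROC threshold sweeps
count ties as "score ≥ threshold" on both axes.

**Alignment accuracy.** A residue is correct iff the predicted and
reference decompositions place it in the same consensus column; insert
placements are not scored. Counts are pooled across sequences ("fraction
of residues in consensus columns aligned correctly"), with a breakdown by
nested-pair, pseudoknot and other columns.

**Recovery experiment.** Train an HPM on a seed alignment (MSA1), emit n
aligned sequences (MSA2, Hamiltonian trace recorded), train a second HPM
on MSA2, emit MSA3, then compare: parameter scatters (h, e), marginal
single-site and pairwise probabilities, per-pair mutual information
(MSA2 vs MSA3), and the accuracy of realigning MSA2's sequences to the
MSA2-trained model against their known true alignment. With the masked
trainer on both ends the construction is closed (probability tables are
re-estimated consistently up to sampling noise); with PLM the couplings
come back positively correlated but shrunken and mutual information is
systematically attenuated — the direction of bias is asserted, not its
magnitude.

## Synthetic family generator

Families are emitted from a ground-truth HPM whose Potts core has the
masked (pair-factorized) form, so the generating distribution and its
marginals are known exactly. Structure: evenly spaced hairpin stems plus
optional pseudoknot pairs connecting loop regions; presets provide a
72-column family with 20 nested pairs (tRNA-sized), a 65-column family
with 12 nested and 2 pseudoknot pairs (twister-ribozyme-sized), and a
108-column family with 24 nested and 4 pseudoknot pairs
(SAM-riboswitch-sized).

Per-column conservation is heterogeneous, as in real alignments: a core
fraction (default 0.4) of sites is strongly conserved (preferred residue
0.95; preferred canonical pair 0.78 with 0.19 spread over the alternative
canonical/wobble pairs), while variable sites draw conservation uniformly
from 0.5–0.8 (unpaired) or preferred-pair mass from 0.35–0.6 (paired, with
most remaining mass compensatory). Deletion rate 0.06 per column, mostly
as joint deletion of both partners at paired sites; insert open 0.03 /
extend 0.4 internally, 0.15 / 0.6 at the flanks. These values were fixed
once to make the emitted families resemble curated structured-RNA
alignments in summed information content and pairwise-identity spread
(means near 50%, maxima near 70%); they are not fitted to any benchmark
outcome. Optional subfamilies re-draw variable-site preferences to emulate
clades.

What the generator does *not* emulate: phylogenetic correlation between
sequences (draws are exchangeable given the subfamily), base triples or
other non-disjoint interactions, position-specific insert composition, and
alignment/annotation errors of curated databases. Tests passing on these
families therefore demonstrate correctness of the machinery and the
qualitative behaviors (coupling utility, PLM attenuation), not performance
on real families.

## Problem sizes used

The test suite runs tiny enumerable models (M ≤ 4, L ≤ 5) for all oracle
comparisons; family-scale tests use 65–108 columns with 30–400 sequences,
R = 300–10⁴ samples per sequence, and MCMC burn-ins of 10³–5·10³. The
acceptance script emits a 300-sequence family, runs the recovery
experiment at n = 200 with R = 10⁴, and the scoring benchmarks with
400–500 decoys at R = 10³–2·10³. These sizes were chosen so the whole
pipeline reruns in minutes on one CPU while keeping every statistical
assertion at its stated tolerance.

## Known limitations

- Scores are unnormalized: no E-values/p-values, no cross-model
  comparison; estimating Z and score statistics is future work.
- Glocal alignment only; no local mode.
- PLM training demonstrably attenuates pairwise correlation (the recovery
  experiment measures this); the masked parameterization sidesteps it only
  for disjoint pair sets.
- ESS can be very small for long sequences under strongly coupled models;
  scores then need large R, and the per-sequence ESS output should be
  monitored.
- The pure-Python/numpy implementation targets desk-scale experiments,
  not database-scale search.
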