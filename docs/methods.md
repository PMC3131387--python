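# Methods

## Scope and design

The package formalizes a two-pronged test for lateral gene transfer (LGT)
into eukaryotes: a topological screen of gene trees for a candidate donor
lineage, and compositional tests of the transfer's age. Every stage is a
library function; the CLI and the `analysis/` drivers are thin callers.
External ML/Bayesian trees can be supplied as Newick with support labels and
enter the screen unchanged; the in-repo tree engine is distance-based (see
below) so the whole chain runs without external binaries.

## Homology search

The pairwise primitive is exact Smith–Waterman local alignment (Biopython's
`PairwiseAligner`, BLOSUM62, affine gaps costing `open + L·extend` with
open 11, extend 1). Significance follows the Karlin–Altschul convention:
`bits = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bits)` with the gapped-BLOSUM62
constants λ = 0.267, K = 0.041. Defaults for the staged gates are
E ≤ 1e−40 (seed search, one best homolog kept per taxon), E ≤ 1e−20
(single-linkage orthogroup clustering over the pairwise-E graph), and
E ≤ 1e−3 (profile expansion). These constants are a stated convention, not
a fitted null; they are appropriate for ungapped-ish strong hits and the
stringent gates used here, where decisions sit many orders of magnitude
from the thresholds.

The profile stage is an ungapped PSSM scan: log-odds columns
`log2((c + w·q)/((N + w)·q))` with pseudocount weight w = 1 and
Robinson–Robinson background; a sequence scores as its best window sum.
Significance is empirical: each database sequence is residue-shuffled
(composition-preserving) `null_shuffles` times, a Gumbel is moment-fitted to
the null scores, and the tail probability uses the empirical survival
function wherever the null sample resolves it, falling back to the Gumbel
only beyond the sampled range (the moment-fitted Gumbel tail is heavier
than the observed max-window tail, so using it throughout would be
conservative by roughly 3× at E ≈ 1). E-values are per-database
(multiplied by database size). Mean hits at E ≤ 1 on pure-null databases
measure 0.7–1.4 across seeds.

## Trimming

Columns are kept when their non-gap fraction is ≥ the gap threshold
(default 0.25). A conservation floor (default 0.50) then guarantees
`ceil(floor · length)` columns survive, re-adding discarded columns by
decreasing coverage (leftmost on ties). The combined rule is deliberately
deterministic and is property-tested against a brute-force restatement.
Residue-similarity trimming is not implemented.

## Tree inference

Distances are p-distances under pairwise deletion with a 20-state Poisson
correction `d = −(19/20)·ln(1 − 20p/19)`; p ≥ 0.95 marks the pair saturated
and aborts tree building (no silent imputation). Trees come from
Saitou–Nei neighbor joining with two deterministic conventions: Q-ties
break by the lexicographically smallest pair of cluster representative
labels, and negative branch-length estimates clamp to 0. Internal edges
whose estimated length is exactly 0 are collapsed into polytomies — an
edge with no estimated length carries no grouping signal, so identical
sequences yield a star rather than an arbitrary tie-broken resolution.
On additive metrics NJ provably recovers the generating tree; the suite
checks 100 random 5–12-taxon cases to 1e−9 and cross-checks topology
against scikit-bio's implementation.

Bootstrap supports resample alignment columns with replacement (seeded),
rebuild the tree, and report the percentage of usable replicates containing
each internal bipartition of the base tree. Degenerate replicates (no
comparable columns for some pair, or saturation) are skipped with the
denominator adjusted. The production default is 1000 replicates; the
benchmark and acceptance runs use 100, which resolves the 50% reporting
threshold comfortably.

Rooting is total: the configured outgroup domain (default Archaea) is used
when present and monophyletic, otherwise the midpoint of the longest
tip-to-tip path. Rerooting preserves each split's support on the
corresponding child edges.

## The screen

Eukaryote monophyly is a bipartition statement on the unrooted tree. When
it fails, inclusion-maximal eukaryote-only sides are analyzed separately
and the family takes the strongest sub-clade call (supported > weak >
patchy > other > unresolved); only if nothing yields a call is the family
`euk_nonmonophyletic`. Sister purity (default threshold 0.8, not 1.0)
tolerates closely related non-donor tips in the sister clade, e.g. sister
groups mixing the donor order with close relatives from the same class.
The donor rank walks rootward from the eukaryote clade collecting newly
introduced prokaryotic groups in order of first appearance (within a step:
descending tip count, then lexicographic). Support thresholds are 50
(report) and 95 (strong) on the bootstrap percent scale; supports given as
fractions in input Newick are rescaled ×100 on read. Classification order:
donor purity first (supported/weak by support), then another group passing
the same supported rule (`other_origin`), then donor-first-in-rank
(`patchy_donor`), else `unresolved`.

## Composition

G+C is computed over A/C/G/T (N excluded). Karlin's codon-usage bias
B(g|C) weights the per-amino-acid L1 distance between synonymous codon
frequencies by the gene's amino-acid frequencies; it lives in [0, 2], is
length-invariant given frequencies, and zero-observation synonymous
families take the uniform distribution (harmless, as their weight is 0).
Only the genome-average reference class is implemented; thresholds default
to 0.08 (|ΔG+C|) and 0.40 (B) and are re-applicable from the report, which
always carries the raw values. The amelioration degree `alpha_hat` is the
grid argmin (step 0.01, ties toward donor) of the L1 distance between the
gene's 61-codon distribution and mixtures α·host + (1−α)·donor; it
requires donor and host profiles to differ by total variation > 0.05.
Reference codon profiles are synthesized from a genome's average G+C by
exponential tilting (P(codon) ∝ exp(β·GC(codon)), β solved by bisection),
which also shifts amino-acid usage toward Ala/Gly/Pro/Arg at high G+C as
real high-G+C genomes do; measured codon-usage tables can be substituted
wherever a `CodonProfile` is accepted.

## Synthetic benchmark

The generator emulates a five-group sampling frame at toy scale — Archaea
4, Alphaproteobacteria 6, Myxococcales 6, OtherBacteria 8, Eukaryota 8 —
with each group monophyletic on a fixed backbone (archaea outgroup;
α-proteobacteria and the donor order as sisters deep in the bacterial
side). `vertical` attaches the eukaryote clade sister to the
α-proteobacteria; `transfer` grafts it onto a random edge inside the donor
clade. Branch lengths (× a global scale, default 1): tips U(0.05, 0.15),
within-group internals U(0.02, 0.10), group stems U(0.25, 0.40), eukaryote
stem 0.30 — a deep-phylogeny regime giving resolvable but unsaturated
signal at the default 300 aa. An optional `graft_edge_length` fixes the
length of the edge subtending the grafted eukaryote+donor split (the
"long graft edge" condition used when measuring support behavior);
by default that edge inherits half of the split donor edge and can be
short, which is exactly why transfer supports vary realistically.

Protein evolution is site-independent WAG (bundled, checksum-verified
published matrix; Poisson equal-rates model as the no-data fallback), root
drawn from equilibrium, per-branch transition matrices via symmetrized
eigendecomposition, optional per-site gamma rate multipliers. Alignments
are indel-free, so the simulated matrix is the true alignment and no
aligner enters the test loop. CDS are i.i.d. codons from the
α-mixture of host and donor profiles (sense codons only; terminal TAA
appended). All draws flow through one seeded numpy Generator per family
with categorical sampling by inverse CDF on the uniform stream, making
every artifact byte-reproducible from its seed.

What the benchmark does **not** emulate: incomplete lineage sorting or
other sources of group non-monophyly, paralogy and gene duplication/loss,
indels and alignment error, rate variation across lineages, and biased
taxon sampling. Passing it therefore shows the machinery is correct and
calibrated under clean conditions, not that real screens are free of those
confounders.

## Problem sizes in the checked runs

The test suite and `scripts/acceptance.py` use: 500 random labeled trees
(≤12 tips) for the screen-extraction oracle; 100 additive metrics for NJ
consistency; 40 families × 300 aa × 100 bootstrap replicates for
end-to-end recovery; 15 long-graft transfer simulations and 5 star
simulations for support behavior; 100 CDS replicates per amelioration
level (500 codons); 1000 random profiles for the Karlin oracle; 1000
random alignments for trimming; 3 × 10 null databases of 40 sequences
(200 shuffles each) for E-value calibration; and a 4-family double run for
bit-level reproducibility.

## Known limitations

- NJ + Poisson distances stand in for ML/Bayesian inference; on short or
  highly heterogeneous alignments real screens should import external
  trees (the screen consumes any Newick with supports).
- Karlin-Altschul constants are not re-fitted for the exact gap scheme;
  the PSSM stage is ungapped; Bayesian posterior probabilities are carried
  for external trees but never produced in-repo.
- One homolog per taxon per cluster: paralog-aware reconciliation is out
  of scope.
- Per-genome codon references are G+C-synthesized unless measured tables
  are supplied; fine-grained codon preferences beyond G+C tilt are not
  modeled.
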