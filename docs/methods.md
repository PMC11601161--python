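# Methods

This note documents the models, parameter choices and numerical conventions
behind factalign, and what the synthetic benchmark does and does not show.

## Residue features

Each Cα is described by nine features, all invariant under rigid motion:

| feature      | type    | meaning                                              |
|--------------|---------|------------------------------------------------------|
| `aa`         | discrete| amino-acid letter (20 states; `X` → letter 0)        |
| `conf_self`  | vector  | pairwise Cα distances in the window i−κ..i+κ         |
| `conf_nen`   | vector  | same window centred at the NEN                       |
| `conf_ren`   | vector  | same window centred at the REN                       |
| `dist_nen`   | scalar  | distance (Å) to nearest Euclidean neighbour          |
| `dist_ren`   | scalar  | distance to the reverse Euclidean neighbour          |
| `nen_offset` | scalar  | signed chain offset to NEN, clipped to ±32           |
| `ren_offset` | scalar  | signed chain offset to REN, clipped to ±32           |
| `dist_n2`    | scalar  | distance to the second-nearest eligible neighbour    |

κ = 3 by default, so each Conf window covers 7 positions and has
C(7,2) − 6 = 15 distances (chain-adjacent pairs are excluded: their distance
is pinned at the ~3.8 Å virtual bond). Neighbour eligibility requires chain
separation |i−j| ≥ 2, excluding the trivially-near i±1. The REN is the
nearest eligible residue on the opposite chain side of i from its NEN.

Conventions the underlying idea leaves open, fixed here:

- **Termini** are mirror-padded (indices reflected across the terminus) so
  Conf vectors have constant dimension; K-means input stays homogeneous.
- **Missing neighbours** (very short chains, terminal REN) record a bounded
  sentinel: distance 20 Å, offset = the clip value, and the residue's own
  window for the neighbour Conf. Sentinels participate in alphabet training,
  so "no neighbour" occupies ordinary bins rather than distorting them.
- **Tied neighbour distances.** Idealised helices and collinear traces
  produce exact ties (i−3 vs i+3) up to float rounding. Candidates within
  1e-6 Å of the minimum are treated as tied and the smallest index wins;
  a hard argmin would let ~1e-15 rounding decide the tie and break rigid-
  motion invariance. Real, noisy structures are essentially never tied.

## Alphabets

Scalar features: equal-frequency binning. Sorted training values are split
into L contiguous bins whose sizes differ by at most one (larger bins first);
the threshold between bins B and B+1 is the mean of the last value of B and
the first of B+1; a value's letter is the number of thresholds strictly below
it. Equal frequencies maximise the alphabet's entropy. Repeated training
values (integer offsets, sentinels) would collapse thresholds, so a
deterministic jitter of 1e-4 × range is added before binning; the strict
trainer refuses genuinely degenerate inputs (< L distinct values).

Vector features: K-means with k-means++ initialisation, 10 restarts,
tolerance 1e-6, max 300 iterations, seeded; a letter is the index of the
nearest centroid (ties to the smaller index). L = 16 for all structural
features by default; alphabets serialise to JSON.

## Scoring

Per-feature log-odds matrices in bits are trained from aligned residue
pairs, counted in both orders (so matrices are exactly symmetric and the
independence case gives the exactly-zero matrix) and smoothed with a
Jeffreys-style pseudocount of 0.5 per cell before normalising — the minimal
fix for sparse counts of rare letter pairs. Marginals are the row sums of
the smoothed joint, which makes Σ p_i p_j M_ij = −KL(p⊗p ‖ P) ≤ 0: random
pairs score non-positive in expectation. Default weights w_f = 1 for all
features; a pair of residues scores the weighted sum of per-feature entries.

## Alignment

Full O(nm) three-state Gotoh dynamic programming (no banding) maximises the
gapped local score with affine penalties; defaults G_open = 3.0,
G_ext = 0.5 bits, chosen on the simulated benchmark and overridable.
Terminal gaps are free by construction of local alignment. Traceback ties
prefer diagonal, then gap-in-target, then gap-in-query; cells whose best
score is ≤ 0 terminate the traceback, so the empty alignment (score 0) is
returned when nothing scores positively. The inner kernel is numba-compiled.

The rigid superposition implied by an alignment is the Kabsch SVD solution
with the standard determinant guard against reflections; inputs with fewer
than 3 points or a collinear configuration (second singular value < 1e-9)
are rejected rather than returning an ill-defined rotation.

## Alignment quality and E-values

LDDT-mu is computed over aligned columns only: reference pairs are pairs of
aligned residues within 15 Å in the reference structure with chain
separation ≥ 2; preservation means |d_Q − d_T| < τ for τ ∈ {0.5, 1, 2, 4} Å,
averaged over the ladder, per column, over both choices of reference
(making the score symmetric, like AQ), and over columns. Columns with no
reference pair contribute 0 (conservative), and the empty alignment scores 0.
This operational definition uses the standard LDDT constants; it is a
documented stand-in for the original's variant, which is specified elsewhere.

The statistic is t = δΔ + (αs − βs_rev)/(L + λ) with L the mean chain
length; the denominator grouping is adopted because λ is meant to damp t
for anomalously short queries, which only that reading achieves. One listed
constant (γ) appears in no formula and is not implemented. The constants
were fixed by a coarse grid search (`quality.tune_quality_params`) on a
development simulated benchmark, maximising the spread-normalised margin
between the 1st-percentile homolog t and the 99th-percentile decoy t:
δ = 1, α = 2, β = 1, λ = 10, and a = 8, b = −2 placing AQ = 0.5 at the
boundary t = 4. Two points deserve note. First, β < α: idealised synthetic
helices are nearly palindromic, so a homolog's s_rev approaches its forward
score and a full-weight reversal correction would cancel genuine signal;
real β would be tuned on real data. Second, the AQ sigmoid is evaluated
with a clipped exponent so extreme t underflows to 0 or 1 instead of
overflowing.

E-values use an empirical null: every query is aligned against the
coordinate-reversed copies of all other database chains, and the decoy AQ
exceedance is fitted as log10 P(AQ′ ≥ q) = intercept + slope·q by least
squares over the upper half of the decoy distribution (≥ 100 decoys
required, ≥ 50 points in the tail, slope must be negative). Below the decoy
median the exceedance is floored at 0.5 — by definition at least half the
null exceeds the median — so E ≥ db_size/2 there. E(q) = db_size · P(q),
clamped to [0, db_size], and scales linearly in database size.

## Benchmarking conventions

Homology is strict same-label (superfamily-level); self-hits are excluded;
sensitivity counts ordered homolog pairs (matching the per-query FPEPQ
normalisation). Hits pass at E < threshold (strict); default sweeps place
thresholds just above each observed E-value so every hit enters the curve.
CatE reports both the fraction of passing queries whose top hit is
homologous (`top_hit_accuracy`) and the fraction of all queries
(`tc_rate`) — the latter is the conventional CatE sensitivity axis — plus
the false-category rate FCR over all queries. Sens(x) reads the CVE step
function at the most permissive threshold with FPEPQ ≤ x, without
interpolation. A small optional k-mer seed prefilter (length-4 words over a
two-feature letter projection) can skip obviously unrelated pairs; it is
plumbing, off by default, and not an accelerated-search implementation.

## Synthetic data: what it emulates and what it does not

The generator produces idealised secondary structure with the correct
~3.8 Å Cα spacing: helices (100°/residue, 1.5 Å rise, 2.3 Å radius),
near-extended zig-zag strands (3.3 Å rise), and self-avoiding random-walk
coil (≥ 3.0 Å clearance). Homologs are derived by single-residue indels
(insertions copy a perturbed midpoint, keeping the ground-truth
correspondence well-defined) followed by isotropic Gaussian jitter.
Families are founder chains with 3–6 random segments (helix 8–16, strand
6–12, coil 3–8 residues, ~25–80 residues total); members are independent
derivations from the founder. Default divergence — jitter σ = 1.0 Å,
indel rate 0.05/residue — yields within-family RMSD ≈ 1.4–2 Å over true
correspondences, a recognisably "homologous but diverged" regime that is
still clearly separated from unrelated chains.

What passing tests on this data show: the factored alphabets carry enough
signal to train dense log-odds tables from small alignment sets; the DP,
statistic and calibration machinery are correct (verified against
enumeration, hand calculation and closed forms); and E-values predict
measured error rates within small factors on a null-matched benchmark.
What they do not show: performance on real protein folds. Synthetic chains
have no Ramachandran statistics, no side-chain packing, no amino-acid/
structure correlation (sequences are uniform random, so the AA matrix
trains toward zero information), no evolutionary indel/substitution
structure, and an unrealistically easy homolog/decoy separation. Benchmark
sensitivities here are properties of the harness, not predictions of
real-data sensitivity; the harness accepts user-supplied SCOP-style sets
for that purpose.

## Problem sizes

Default study sizes, chosen to exercise every code path at desk scale:
training 12 founder/homolog pairs (~1200 residues); benchmark 10 families ×
4 members (40 structures, 120 homologous ordered pairs, 1440 non-homologous);
calibration 1560 reversed-chain decoy comparisons. The full pipeline runs in
a few seconds on one CPU; the test suite in ~10 s.

## Known limitations

- Chain breaks and missing residues in real PDB input are treated as
  consecutive positions; insertion codes are not interpreted.
- The AA log-odds matrix is near-zero when trained on the synthetic data
  (random sequences) and contributes only with real training alignments.
- The reversal-based null slightly underestimates decoy similarity for
  palindromic folds; the tail fit's linear form is an approximation whose
  extrapolation error grows below the ~10⁻³ exceedance quantile.
- One rigid transformation per alignment; flexible multi-segment
  superposition is out of scope.
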