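# Methods

This note records the models, conventions and numerical choices behind
`huihf`, and what its synthetic-data tests do and do not establish about
real data.

## The 90-column core frame

All sequence analysis runs on a fixed 90-column alignment frame covering
the conserved HU/IHF fold (three α-helices, five β-strands). A sequence is
stored as `n_ext + core + c_ext`, where the core is 90 symbols (residue or
`-` for a deleted column) plus an insertion map `{anchor column → residue
run}` with anchors in 1..89. The representation is validated by exact
reconstruction of the raw sequence.

**Core threading.** `align_to_core` threads a raw sequence onto a clade
profile by dynamic programming: global over the 90 columns, free end gaps
on the sequence (the unaligned prefix/suffix become the terminal
extensions at no cost), affine penalties for insertions and deletions
(open 11, extend 1, in score units). Match scores are the profile's
log₂-odds. The original large-scale alignment behind the family frame
used a rate-matrix search procedure; profile–sequence alignment is this
package's reproducible stand-in producing the same 90-column
decomposition.

**Identity with the indel-event rule.** Identity counts columns with equal
non-gap residues; each insertion event (one contiguous run, regardless of
length) not shared identically by both sequences subtracts one, floored at
zero. Deleted columns fail the residue comparison and need no extra term.
On this rule the *E. coli* HUα/HUβ pair scores 62/90 and the IHF α/β pair
24/90.

**Fitch distance.** d = √(1 − s̄), where s̄ is the mean per-column
similarity under the Fitch (1966) residue table, excluding columns where
either sequence has a gap; an all-gap pair is a flagged missing value. The
embedded table (`data/fitch1966_similarity.tsv`) is the binary same-class
indicator over four residue classes — {A,G}, {C,F,I,L,M,V,W,Y},
{D,E,H,K,N,Q,R,S,T}, {P} — matching the `dist.alignment` similarity
convention of the seqinr package; the test suite pins frozen seqinr
reference distances to 12 digits.

**Profiles and classification.** Column frequencies use an additive
pseudocount (default 1) over the 21-symbol alphabet; scores are log₂-odds
against a uniform 1/21 background, so a sequence's profile score is in
bits. Consensus is the modal residue (ties → lexicographically smallest);
conservation is the pseudocount-free modal fraction, with 0.8 the default
threshold for calling a column conserved. Classification takes the
best-scoring profile; the margin (best − second best, bits) below 5 flags
an ambiguous call. Both thresholds are configurable; 5 bits corresponds to
a 32-fold likelihood ratio and is deliberately conservative.

**Embedding.** Default PCA treats each sequence's row of the distance
matrix as its feature vector (the literal protocol behind the family's
published embedding); classical PCoA (double-centred squared distances) is
available via `method="pcoa"`. Component signs are fixed by making the
largest-magnitude loading positive.

**Indel census.** Hotspot regions default to core columns 14–16 (α1–α2
loop), 38–40 (α2–β1 turn) and 60–68 (DNA-binding arm tip); the spans are
calibration data, since secondary-structure block boundaries on the frame
are approximate, and can be overridden. One insertion event = one
contiguous run; one deletion event = one maximal gap run, assigned by its
first column.

## Dimer geometry

Helix axes are total-least-squares lines (principal axis of the centred
Cα cloud, ≥ 5 points), signed toward increasing residue number. Inter-axis
angles are undirected, arccos|a·b| ∈ [0, 90]° — the published fold angles
all fall in this range. Default spans on the core frame: α1 = 2–13 (12
residues), α2 = 17–37 (21 residues), α3 = 84–90, β2 = 48–56, β5 = 73–80;
"helix-2 C-terminus" means the last α2 column, and corresponding residues
of the two chains share a column. Distances are between Cα atoms of
corresponding columns on opposite chains; coordinates are converted Å → nm
on PDB read. A span with fewer than five mapped residues yields a missing
measurement, never a fabricated one. Axis spans shift the absolute angles
by a degree or so, which is why comparisons against externally built
models should be tolerance-based, with spans treated as configuration.

Superposition RMSD uses the Kabsch SVD rotation with a determinant
correction (proper rotations only); the tests check it against an
independent quaternion-based superposition oracle.

## Finite-lattice cooperative binding

A dimer covers n bp of an N-bp lattice; a configuration with k dimers and
j immediately adjacent pairs has weight (K·L)ᵏ ωʲ (L = free protein).
Cooperativity is strictly nearest-neighbour contact, the McGhee–von Hippel
convention; no longer-range terms. Because the weight factorises, the
partition function is the polynomial Z(x) = Σₖ cₖ xᵏ with x = K·L, and the
cₖ are computed once per (n, N, ω) by an O(N·kmax) recursion, in log space
so combinatorially large counts on long lattices stay exact to float
precision. The recursion is verified against exhaustive configuration
enumeration on all lattices up to 15 bp.

The infinite-lattice McGhee–von Hippel isotherm is provided as a closed
form solved for the binding density ν by bracketed root-finding on
[0, 1/n) (Brent, residual ≤ 1e-10), with an analytic ω = 1 branch; it
agrees with the finite lattice at N = 3000 to 1%. For the 20–48-bp oligos
modelled here the finite lattice is the default — end effects are large at
these lengths.

**Depletion.** Experiments run DNA at 200 nM and protein at comparable
concentrations, so free protein is never the total; the free concentration
solves P = L + D·⟨k⟩(L) (monotone; Brent to machine precision). Depletion
correction is always on.

**Titration fitting.** Band k is identified with the exactly-k-dimer
occupancy state; gel smearing and dissociation during electrophoresis are
not modelled. (K, ω) are fit by unweighted least squares in (log₁₀K,
log₁₀ω) between observed and predicted band fractions, with any occupancy
beyond the last observed band aggregated into it. Titrations that never
leave the free state or are fully saturated are rejected as
non-identifiable. The ω confidence interval is a parametric bootstrap
(default 200 resamples, seeded): Gaussian noise at the calibrated raw σ is
added to the fitted predictions, truncated at zero and renormalised per
lane — the same observation process as the generator — and each resample
is refit. The calibration step matters because truncation+renormalisation
shrinks raw noise (~25% under typical conditions); without it the
bootstrap under-covers badly. Even with it, percentile intervals
conditioned on the fitted parameters cover the generating ω in roughly
80–85% of replicates at nominal 95% — ordinary small-sample bootstrap
behaviour that users should keep in mind when reading the CIs. Median
point-estimate recovery is unbiased to within a few percent at 2%
quantification noise.

**Site size.** The ladder estimator fits c(N) = 1 + ⌊(N − offset)/n⌋ to
(length, max-complex-count) data by integer grid search, minimising
mismatches; ties break toward smaller n, then smaller offset, and all
co-optimal pairs are reported. The offset — the minimum duplex length
accommodating the first dimer — is constrained to n ± 2 bp by default,
because that first dimer itself occludes n bp (± end breathing). The
constraint is what makes single-step ladders informative: a pattern with
one count step (two complexes at 21–28 bp, three from 29 bp) is consistent
with every n from 8 to 14 under a free offset, but resolves to the 9/10-bp
ambiguity under the physical one. A free `offset_range` override is
available.

**Single-site Kd.** For the branched constructs (one sharp complex band,
DNA at 10.5 nM) binding is treated as 1:1 with depletion: the complex
concentration is the smaller root of C² − C(P+D+Kd) + PD = 0, and Kd is
fit by least squares in log₁₀Kd. Affinity profiles divide each structure's
Ka by the same protein's dsDNA Ka; the reference row is exactly 1.

Concentrations are molar internally; the CLI accepts nM/µM suffixes.

## Construct assembly

Annealing is exact antiparallel Watson–Crick string matching: repeatedly
pair the longest complementary run ≥ 8 bp between unpaired regions, with
strand order canonicalised (labelled strand first) so the result is
independent of input order. Thermodynamics — melting, mismatches,
hairpins — is deliberately ignored: the oligo sets are designed for unique
pairing, and the assembler is not a general hybridisation predictor.
Structure labels come from the base-pair topology (strand count, pairing
graph, unpaired-run placement). A nick requires zero unpaired bases at the
junction; a 1-nt gap is labelled `unknown`. "Invasion" is detected as a
three-strand path whose centre strand is fully paired while a flanking
strand carries an internal displaced loop — a topological proxy for the
strand-displacement constructs. Every recorded pair is re-verified base by
base as an independent check.

## Synthetic-data generators

All generators are deterministic under a single integer seed.

*Families* mutate a 90-residue base consensus (default: *E. coli* HUα)
i.i.d. per column at rate 1 − identity; insertion events (default rate
0.10 per sequence, 80% single-residue) land in the hotspot regions with
weights 0.34/0.18/0.15/0.33 (loop/turn/tip/elsewhere), deletions (rate
0.034) mostly in the α1–α2 loop — the family-wide census statistics.
Terminal extensions are built to exact length/composition targets (e.g.
the Actinobacteria-like C-terminus: 111 residues, 29 K, 5 R, PAKKA
repeats), with a P-free filler alphabet so the only PAKKA occurrences are
the intact blocks. Columns evolve independently: the generator reproduces
marginal statistics, not phylogenetic correlation, so clade-recovery
results on synthetic families bound what classification achieves when
within-clade diversity is i.i.d. — real families with correlated
substitutions or biased composition may classify better or worse.

*Dimers* are C2-symmetric Cα scaffolds: chain B is chain A rotated 180°
about z, so every inter-chain distance equals twice a radial coordinate
and every distance target is met by construction; helices are ideal
(rise 0.15 nm, radius 0.23 nm, 100°/residue) and placed so their *fitted*
principal axes hit the target angles exactly. Arm residues between the
constrained columns are interpolated placeholders — the scaffold
reproduces the measurement suite, not protein geometry at large, so
round-trip agreement validates the measurement code, not any modelling
pipeline.

*EMSA titrations* draw band fractions from the lattice model at
depletion-consistent free-protein concentrations (by default eight
concentrations spanning 10–90% lattice saturation), add truncated
Gaussian noise and renormalise lanes. *Ladders* report, per duplex length
20–48 bp, the highest complex whose occupancy probability reaches the
detection threshold (default 5% of lane signal — gels do not show
arbitrarily faint bands) at any concentration of a doubling series from
200 nM, mimicking titration to ladder saturation.

## Problem sizes

The test suite and the acceptance script use 100-replicate titration
studies (8 concentrations, 48-bp lattice), 500-sequence families for the
census, 60-sequence families per clade for recovery, and 10–20 seeded
dimer geometries; the full suite runs in about half a minute on one core.

## Known limitations

- The core threading is a profile alignment, not the original rate-matrix
  MSA; column assignments can differ for highly diverged sequences.
- Gel-mobility physics (band compaction from DNA bending) is out of
  scope; band order is assumed to follow stoichiometry.
- Heterodimer statistics, salt dependence and hairpin formation are not
  modelled.
- Bootstrap ω intervals under-cover somewhat (see above); treat them as
  approximate.
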