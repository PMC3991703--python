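# Methods

This note records the models, conventions and design choices behind
`amfassembly`, in the spirit of a statistical appendix: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Data model

Communities are samples × phylotypes matrices of clone counts (or printed
relative abundances), with per-sample metadata (patch, root system,
coordinates). Presence means abundance strictly greater than zero — no
epsilon — for richness, incidence and IndVal fidelity alike.

The packaged field table gives the relative abundance (% of clone numbers)
of 30 AM fungal phylotypes in seven pooled communities: the LD/MD/HD
patches of *Ligularia virgaurea* roots and the Control/LD/MD/HD patches of
neighborhood-plant roots. Direct counting of the table yields 26 phylotypes
in focal roots, 23 in neighborhood roots and therefore 19 shared; the
original text states 18 shared. The fixture follows the printed table and
the discrepancy is documented here rather than resolved.

**Count reconstruction.** The study reports 1184 AM clones over 35 samples
but no per-patch totals, so integer counts are reconstructed under equal
per-patch totals apportioned by sample count: J = round(1184·15/35) = 507
for the focal plant (169/169/169) and J = round(1184·20/35) = 677 for
neighborhood plants (170/169/169/169). Each cell becomes
`round(pct·total/100)` (round-half-even); column sums are *not* forced back
to the requested total, because the printed percentages are already rounded
— the per-column discrepancy is reported instead (−2 clones in each of the
focal MD and HD columns, hence the pooled focal J of 503). Largest-remainder
redistribution would silently fabricate clones of arbitrary phylotypes.

**Diversity and rarefaction.** Shannon diversity uses the natural log
(configurable base). Sample-based rarefaction is the analytical
subset-expectation: τ(h) = S_obs − Σⱼ C(H−Hⱼ, h)/C(H, h), computed in log
space; it equals the brute-force mean over all C(H,h) subsets to 1e-10,
which the tests verify exhaustively for H ≤ 8.

## Neutral model

The local community is modelled by the two-parameter neutral sampling
formula (metacommunity diversity θ; immigration parameter I, equivalently
m = I/(I+J−1)). The likelihood is evaluated exactly: the combinatorial
kernel K(D,A) — a sum over the possible numbers of immigrant ancestors A —
is a product polynomial over species whose coefficients involve unsigned
Stirling numbers of the first kind. Both the Stirling recurrence and the
per-species convolution run in log space, which is stable to at least
J ≈ 700 (validated against a 60-digit arbitrary-precision recomputation and
against exhaustive enumeration: exp(logL) sums to 1 over all abundance
configurations for J ≤ 5, and the I → ∞ limit matches the Ewens sampling
formula). K(D,A) is independent of (θ, I), so it is cached per dataset and
the optimizer pays only a vector logsumexp per evaluation.

**Estimation.** Nelder–Mead on (log θ, log I) from four fixed starts —
derivative-free, unconstrained and deterministic, so fits are bit-for-bit
reproducible without a seed. In calibration runs the optimum always matched
or beat dense log-grid scans. Note the likelihood surface carries the
well-known ridge trading θ against I; with a single community of J = 500
and only ~12 species, single-fit estimates of θ scatter widely (median
relative error around 50–60% in our self-recovery simulations). This is a
property of the estimator at that information content, not of the
implementation; pooled communities with more species constrain θ much
better.

**Simulation and goodness of fit.** The urn scheme builds a community
sequentially: individual k immigrates with probability I/(I+k−1) or copies
an earlier local individual; the a-th immigrant founds a new species with
probability θ/(θ+a−1) or adopts an earlier immigrant's species. Simulated
frequencies match the exact formula at J ≤ 4 within Monte-Carlo error.
Goodness of fit compares the observed Preston octave profile with the mean
profile of 200 simulated communities: χ² over octaves with positive
expectation, df = (such octaves) − 1, plus a two-sample Kolmogorov–Smirnov
test of the observed abundances against the pooled simulated abundances,
reporting Z = D·√(n₁n₂/(n₁+n₂)). The GOF's octave binning defaults to the
classic boundary-splitting convention (a species at an exact power of two
contributes half to each adjacent octave): with hard floor(log₂) bins the
χ² test over-rejects on data truly drawn from the fitted model (~12% at
α = 5%, J = 500) because integer counts pile onto octave boundaries,
whereas split binning calibrates at the nominal level (5.0% in 200
replicates). Plain binning remains available and is the default for
standalone `preston_bin`.

**Relation to the published estimates.** On the reconstruction above, the
exact-likelihood MLE gives θ = 11.7, I = 32.9 (focal; J = 503, S = 26) and
θ = 9.4, I = 29.1 (neighborhood; J = 679, S = 23), with both GOF tests
non-rejecting — the qualitative conclusion (good neutral fit) reproduces.
The originally published parameter pairs (θ = 1.2, I = 7.5; θ = 9.3,
I = 3.8) are not recoverable from the printed table: at θ = 1.2 the model
expects ~4 species in a 507-clone sample, not the 26 observed, and the
likelihood at the published focal pair lies ~41 nats below the MLE. Several
alternative reconstructions (percent-as-integer, sequence-count totals,
per-patch fits) were examined and none yields those values either; the
original fits evidently used inputs that the printed table does not
determine. θ for the neighborhood community agrees to 0.1.

## Phylogenetic structure

Patristic distances come from the supplied newick tree (the tree is an
input, never inferred here). MNTD weights each present taxon's
nearest-co-occurring-taxon distance by its relative abundance. The null
model shuffles taxon labels on the distance matrix over the full tip pool
(the metacommunity), keeping the abundance weights attached to the
community — so neither the distance multiset nor the abundances change.
NTI = −(obs − null mean)/null sd; 999 randomizations by default, with a
degenerate flag when the null spread collapses (e.g. a star tree). Nulls
are seeded per community by stable hashing of the sample id, so pipeline
reports are reproducible sample by sample. Per-patch inference is a
two-tailed one-sample t-test of the NTI values against zero.

## Ordination statistics

NMDS minimizes Kruskal stress-1 by iterative majorization: isotonic (PAVA)
regression of configuration distances on the dissimilarities (ties in the
dissimilarities are pre-ordered by current distance, the primary approach),
then a Guttman transform toward the scaled disparities. Defaults: k = 2,
20 restarts (one metric start from principal coordinates plus random
starts), tolerance 1e-7 on the stress decrease, 500 iterations; the best
restart is returned, centered and rotated to principal axes. Stress traces
are recorded and non-increase is asserted in the tests.

envfit regresses each (centered) variable on the scores; r² is the
coefficient of determination, the arrow is the unit coefficient vector, and
P permutes the variable's values. The Mantel statistic is Pearson r over
lower-triangle entries with simultaneous row/column permutation of the
second matrix, one-tailed. IndVal is specificity × fidelity maximized over
groups, on the 0–1 scale with the strong-indicator threshold at 0.6, and
group labels are permuted without blocking. Every permutation P uses the
(1 + exceedances)/(n_perm + 1) estimator, so P is never zero; type-I error
of Mantel and envfit is verified at 0.05 ± 0.02 over 500 null simulations.
No multiplicity correction is applied across variables or species by
default (mirroring the original protocol); a Holm option exists in the
pipeline.

## Spatial partitioning

PCNM eigenfunctions: Euclidean distances among sample coordinates,
truncation at the longest minimum-spanning-tree edge (override available),
distances beyond it replaced by 4× the threshold, Gower double-centering of
−½D², eigen-decomposition, retaining eigenvalues above 1e-8 of the maximum
and scaling eigenvectors by √eigenvalue. Coincident samples (two root
systems per quadrat) are separated by a deterministic jitter of 1e-6 of the
threshold, with a warning. Redundancy-analysis R² is trace-based
multivariate least squares on the Hellinger-transformed community
(configurable to raw counts), with Ezekiel's adjustment using the rank of
the predictor matrix; aliased columns are dropped with a warning.

Forward selection of spatial predictors uses a permutation F test per step
and the double-stopping safeguard: selection only begins if the full
candidate model is significant at α (without this gatekeeper, picking the
best of many noise candidates inflates type-I error far beyond α), and it
stops once cumulative adjusted R² exceeds the full model's. Variation
fractions solve the three adjusted-R² identities; negative fractions are
reported as computed, and a+b+c+d = 1 holds to 1e-10 by construction. Only
spatial candidates are selected; environmental variables enter unselected.
The published fractions (17.5%/4.4%/16.9%/9.1%) depend on sample
coordinates and environmental measurements that were never published, so
they cannot be recomputed from the printed data; the synthetic studies
verify the machinery instead (environment-only studies yield a pure-spatial
fraction of ~0).

## Synthetic studies

The generator emulates the field design — 4 patches × 5 quadrats × 2 root
systems, 30 phylotypes, 34 clones per root sample (1184/35 rounded), so
pooled root systems land near the real J of ~507/677 — with fully recorded
ground truth. Components and the reasoning behind them:

- **Phylogeny**: pure-birth (Yule) tree, birth rate 1, hand-verified
  ultrametricity and depth expectation.
- **Trait**: Brownian motion on an early-burst clock (edge lengths damped
  by exp(−8·t/T)), standardized to unit variance. The premise being
  operationalized is *strong* niche conservatism; under a plain Brownian
  clock, taxa from different clades too often converge on similar trait
  values, which genuinely breaks the filtering→clustering chain in ~25% of
  realizations.
- **Filtering**: Gaussian trait filter of width 0.2 SD aimed at the mean
  trait of a focal high-trait clade of 4–8 tips — a tolerance that evolved
  once in one lineage — with per-patch offsets (0/0.1/0.2 for LD/MD/HD) and
  quadrat-level noise. The Control patch assembles with no filter.
- **Base abundances**: lognormal(0,1), drawn independently per sample (each
  root sample is its own colonization lottery). This supplies the observed
  single-phylotype dominance (~42–48% per sample in the field data).
  Sharing one lottery across a study correlates samples within patches and
  wrecks the t-test's calibration on random assemblies.
- **Environment and space**: the measured environment tracks the patch-level
  filter optimum plus noise; an *unmeasured* sinusoidal field of
  quadrat-scale wavelength (10 m) perturbs the realized optimum with weight
  0.2, creating a pure-spatial variance component that PCNMs can absorb. A
  patch-coherent (50 m) field would instead shift whole patches off their
  filter target.
- **Neutral mode**: per patch × root system, one urn draw of J = 170 split
  across quadrats by multivariate hypergeometric sampling, so the pooled
  community is an exact draw from the sampling formula.
- **Planted indicators**: optionally one phylotype is confined to the HD
  patch at ~15% abundance — a perfect indicator (IndVal = 1) for power
  checks.

With these defaults, 50 seeded studies give: Control patch phylogenetically
random (t-test non-significant) in 46/50, and LD/MD/HD significantly
clustered in 46–47/50 — the qualitative field pattern, by construction.
What passing these tests does *not* show: real AM communities have
unbalanced phylogenies, traits of unknown conservatism, non-Gaussian
filters, and sequencing noise; the generator demonstrates correctness of
the machinery under a known process, not realism of any particular field
inference.

## Problem sizes and numerical conventions

Test and calibration runs use the study's own scales: J = 500–700 for
neutral fits, 200 goodness-of-fit replicates with 200 simulations each,
999 NTI randomizations, 500 null simulations for permutation calibration
(at 199 permutations per individual test), and 50-study batches for the
patch-pattern and variation-partitioning checks. Log-space arithmetic is
used wherever factorials or Stirling numbers appear; permutation P values
are never zero by construction; optimizer and simulator are reproducible
under explicit seeds, and the pipeline derives per-sample seeds by stable
hashing so reports are bit-for-bit repeatable.

## Known limitations

- Single-community MLE of (θ, I) is weakly identified at low richness; I in
  particular can run to the Ewens ridge (I → ∞). Interpret I from a single
  small community with caution.
- The χ² GOF degrees-of-freedom convention (octaves with positive
  expectation, minus one) is a documented convention; printed df values in
  the original study follow an unknown binning and do not match exactly.
- The taxa-label null draws from the full tip pool; no occupancy-restricted
  null is provided.
- NMDS ties are handled by the primary approach only; no weighted or
  split-by-group stress variants.
- The spatial module implements plain PCNM, not generalized Moran
  eigenvector maps with arbitrary weight matrices.
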