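# Methods

`mppqtl` maps quantitative trait loci (QTLs) in multiparental populations
(MPPs) — diallel, nested association mapping (NAM) and multiparent advanced
generation intercross (MAGIC) designs — by combining founder-origin
(identity-by-descent, IBD) probabilities with variance-component mixed
models. It also ships the simulator that defines the study conditions under
which the method is evaluated.

## 1. Breeding-design simulator

**Genomes and meiosis.** Founders are fully inbred, so one haploid allele
sequence per founder suffices. Offspring genomes are founder mosaics stored
as junction lists (segment end in cM, founder of origin). A meiosis draws a
Poisson number of crossovers per chromosome with mean equal to the map
length in Morgan, places them uniformly, starts from a fair random
haplotype and alternates at every crossover. There is no crossover
interference and no obligate chiasma; a count of zero is allowed.

**Crossing schemes.** A diallel over P founders enumerates all P(P-1)/2
unordered pairs in lexicographic order; NAM crosses a designated central
founder to every other founder; MAGIC runs a balanced funnel (two-way then
four-way crosses for four founders; the construction generalises to any
power of two). Families branch at F2: each line descends from an
independent F2 seed of the family F1 (or the funnel product) and is then
advanced by single seed descent, one selfing per generation, to the final
generation (F6 by default). The F2-branching convention is the standard
recombinant-inbred-line bookkeeping; the residual heterozygosity at F6 is
(1/2)^5 ≈ 3.1% at segregating loci, which the suite verifies against the
Mendelian recursion.

**Default study conditions.** The default map has five chromosomes:
chromosomes 1–4 carry 88 markers each at 1 cM spacing (0–87 cM) and
chromosome 5 carries 110 (0–109 cM), 462 markers in total. Three major
QTLs (additive effect a = 0.4) sit mid-chromosome at 44 cM on chromosomes
1–3. Minor QTLs (b = 0.1) flank each major starting 20 cM above and below
and stepping outward by 10 cM until the chromosome end — six per
chromosome on this map — and chromosome 4 carries six more on a 10 cM
grid (19–69 cM), 24 minors in total. Chromosome 5 carries no QTLs and is
used for false-positive accounting. Chromosome lengths were chosen so that
the stated placement rule yields exactly 24 minors; the 10 cM grid on
chromosome 4 is centred on the chromosome.

**Founder genotypes.** Synthetic founder alleles are i.i.d. Bernoulli(0.5)
per founder per marker. The three major-QTL markers are overwritten with
fixed carrier patterns — the trait-increasing allele is carried by founders
{P1,P2}, {P1} and {P1,P2,P3} respectively — chosen so that, as in the
emulated setup, the three majors segregate in 4/6, 3/6 and 3/6 diallel
families, 2/3, 3/3 and 1/3 NAM families (central founder P1), and have
inbred-limit genotype frequencies 1/2, 1/4 and 3/4 in MAGIC. Minor-QTL
markers are redrawn until polymorphic (a monomorphic "QTL" would simply
not exist). Only the statistical role of the founders matters for the
simulation study, so no real accession data are packaged.

**Phenotypes.** Y = Σ_major a·z + Σ_minor b·z + ε with z = +1/0/−1 for
genotypes 11/12/22 and ε ~ N(0, 1). Only additive effects are simulated.
The expected variance of a QTL with effect a is a²·{E[Z²] − E[Z]²}; in the
inbred limit this is 4a²f(1−f) with f the design-implied frequency of the
increasing homozygote (family-size-weighted across families).

**Observed genotypes** are allele-2 dosages read off the mosaics, masked
missing independently at 5% by default (deliberately pessimistic relative
to practice).

## 2. IBD reconstruction

Each offspring is decoded per family with a hidden Markov model whose
states are the family's founders (two for diallel/NAM families, all
founders for MAGIC). Because F6 offspring are nearly fully inbred, a
single origin state per locus is used; observed heterozygous dosages
(~3% of loci) are treated as missing during decoding, which avoids the
P² paired-origin state space.

**Transition model.** Over a map distance d (Morgan) the state evolves by

    T(i→j) = exp(−ρd)·1{i=j} + (1 − exp(−ρd))·π_j

with π uniform over the family's founders. ρ is the expected junction
density per Morgan of the design, *calibrated by simulation*: the plan's
pedigree is simulated (default 100–200 offspring) and ρ set to the mean
junction count per Morgan, averaging the two haplotypes of each offspring.
Calibrated values: ≈1.0 for F2, ≈1.87 for selfed biparental F6
(approaching the classical limit of 2), ≈2.9 for four-way MAGIC F6. This
continuous-state kernel is a first-order Markov stand-in for an exact
recursive pedigree prior: it is exchangeable across founders and matches
the marginal junction density, but not the non-exponential segment-length
distribution of a single-seed-descent mosaic. Its adequacy is checked
against the simulator truth (≥95% argmax accuracy at 5% missing data, and
progeny-averaged maximum posteriors ≥0.9 at almost all marker positions;
MAGIC chromosome ends occasionally dip a few hundredths below 0.9 at some
seeds — the known cost of the approximation).

**Emissions.** P(obs | origin j) = 1−e if the dosage matches founder j's
homozygote, else e (default e = 0.005, configurable); missing and
heterozygous dosages emit 1 for every state, as does an observation
incompatible with every admissible founder (possible only at e = 0).
Markers with missing founder genotypes are excluded before decoding and
fall back to the family prior. Posteriors come from a scaled
forward–backward pass per chromosome (per-locus normalisation constants,
no underflow at any realistic marker count); the suite verifies exact
agreement (1e−10) with brute-force path enumeration on small problems.

**Predictors.** The genetic predictor matrix at a locus is twice the
posterior origin probability (the expected count of alleles from each
founder in a diploid); rows sum to 2 exactly.

## 3. Kinship

VanRaden genomic relationship: K = WWᵀ / (2Σ p_k(1−p_k)) with W the
dosage matrix centred at twice the pooled sample allele frequency and
missing dosages mean-imputed per marker. Scans use leave-one-chromosome-out
(LOCO) matrices — the scanned chromosome's markers are excluded — to avoid
proximal contamination. An optional ridge (ε·I, default off) is available
for degenerate panels. Allele frequencies are pooled over the whole sample
rather than per family; on the simulated designs, kinship computed from
IBD-expected dosages and from observed IBS dosages correlate above 0.95,
so the cheaper IBS form is used throughout.

## 4. Mixed models and REML

Six models share the fixed part Xβ (family indicators; a single MAGIC
family degenerates to a global intercept):

| model          | predictor | background           | residual        |
|----------------|-----------|----------------------|-----------------|
| `IBD.SQM_U`    | IBD       | —                    | uniform         |
| `IBD.SQM_F`    | IBD       | —                    | family-specific |
| `IBD.MQM_F`    | IBD       | cofactors            | family-specific |
| `IBD.Kin_F`    | IBD       | polygenic (K)        | family-specific |
| `IBD.MQMkin_F` | IBD       | cofactors + K        | family-specific |
| `IBS.Kin`      | IBS       | polygenic (K)        | uniform         |

IBD models treat the P parental effects at the tested locus as
a_q ~ N(0, I_P σ_q²) and likewise each cofactor (a_c ~ N(0, I_P σ_c²));
the polygenic term is g ~ N(0, K σ_g²); the residual is either σ_ε² I or a
direct sum of per-family variances. `IBS.Kin` is the GWAS benchmark with a
fixed bi-allelic substitution effect.

**REML.** The residual log-likelihood (full constant included) is
maximised by average-information (AI) REML: Newton-type updates using the
average of observed and expected information, step halving, box
constraints, and an active set that freezes parameters pinned at the lower
floor with an inward score. A bound-constrained quasi-Newton optimiser on
log-variances polishes the rare fits where AI stalls, and two starting
points guard against local optima. Convergence requires a likelihood change
below 1e−9·(1+|ℓ|) together with the first-order (KKT) conditions on the
scaled score. Two evaluation back-ends produce identical likelihoods,
gradients and AI matrices (verified to 1e−9): a dense Cholesky path for
arbitrary covariance structures, and a Woodbury path for
diagonal-plus-low-rank structures that is an order of magnitude faster.
For kinship models on single-family designs the scan rotates each
chromosome's data into the eigenbasis of its LOCO kinship, making the
polygenic covariance diagonal and every per-marker fit low-rank.

**Boundary handling.** Variances are optimised above a floor
(1e−12·var(y) for genetic terms, 1e−8·var(y) for residual groups — the
latter also prevents degenerate zero-variance families of small size) and
snapped to exactly zero afterwards when this does not reduce the
likelihood, so the LRT has a well-defined point mass at zero.

**Tests.** A QTL variance is tested with LRT = max(0, 2(ℓ_A − ℓ_0))
against the boundary mixture 0.5χ²₀ + 0.5χ²₁ (p = 1 at LRT = 0); both
hypotheses share the fixed part, as REML likelihood comparison requires.
The suite calibrates the null: the rejection rate at nominal 0.05 lies in
[0.03, 0.07] over 2,000 null fits. `IBS.Kin` uses a Wald test of the fixed
marker effect with its GLS variance; monomorphic markers are skipped with
a sentinel p = 1. Model choice uses
BIC = (DF_fixed + DF_var)·ln(n − r + DF_fixed) − 2 ln L_max (smaller is
better; ties break toward fewer variance parameters). Parental effects at
the final QTL candidates are BLUPs from the selected model with all QTLs
fitted jointly.

## 5. Scan procedure

The genome-wide threshold is Bonferroni, T = −log10(α/m); the study runs
use the explicit override T = 4.2 (the emulated analysis used this value
for its 462-marker map even though the formula gives 4.66; both are
implemented, the override reproduces the original runs). Cofactor models
iterate: scan → pick super-threshold peaks greedily with a 20 cM exclusion
radius → rescan with cofactors in the model → stop when the cofactor
configuration stabilises (up to 10 rounds).

Two deliberate conventions:

- **Exclusion radius, not half-width.** The exclusion window is a 20 cM
  *radius* around each cofactor. With a ±10 cM half-width, cofactors
  selected at the minor QTLs flanking a major (14–20 cM away) remain in
  the model when the major itself is tested and absorb its signal through
  linkage (predictor correlation ≈ e^(−ρd) ≈ 0.56 at 20 cM in MAGIC F6),
  driving the multi-QTL model's power *below* the single-QTL model's —
  the opposite of the method's purpose. The 20 cM radius removes this
  proximal contamination. The *success* window for power accounting is a
  separate 20 cM distance and is configured independently.
- **Stabilisation up to jitter.** Rescans move a cofactor by a marker or
  two around the same peak, producing exact-set 2-cycles. The iteration
  stops when consecutive cofactor sets match up to 5 cM positional jitter
  (same per-chromosome cardinality), or when a configuration repeats
  (cycle detection); only genuinely oscillating configurations are flagged
  as non-stabilised.

Inside a cofactor's window, tests run with that cofactor dropped (the
composite-interval-mapping convention, which yields complete profiles); a
strict skip mode (`--skip-in-window`) that performs no test there is
available. The null model is refitted once per chromosome × cofactor
configuration, never per marker; alternative fits warm-start from the null
estimates.

**Detection rule.** A simulated major QTL counts as detected when the
chromosome's profile peak exceeds T and lies within 20 cM of the true
position. Mapping resolution is the mean peak–truth distance; the headline
convention averages successful replicates only (the all-replicates average
is reported alongside). False positives are super-threshold markers on the
QTL-free chromosome in the final profile; their analytical expectation is
m_null · R · 10^(−T), e.g. 110·500·10^(−4.2) = 3.47.

## 6. Problem sizes

Every per-replicate pipeline stage (simulate → decode → kinship → scan)
runs at the full study scale: N = 300, 462 markers. The replication
harness defaults to 100 replicates with 500 available behind a flag. The
packaged test suite uses smaller designs where the check is structural
(toy maps for scan mechanics and enumeration oracles) and runs the
power-trend comparison at 20 MAGIC replicates (full marker density) and 6
replicates each for diallel and NAM with every third marker tested, sizes
chosen to keep a
full run of the suite on one CPU within minutes; the acceptance script
always uses the full study conditions. With ~16-replicate binomials the
trend assertions are deliberately coarse (a one-sided test only flags
reversals well outside sampling noise).

## 7. Known limitations

- The Markov transition kernel only matches the junction density, not the
  full segment-length law of single-seed-descent mosaics; posterior
  confidence at MAGIC chromosome ends sits at the 0.9 quality bound and
  dips slightly below it for some random founder draws.
- Heterozygous offspring populations (e.g. F2 designs) are out of scope:
  decoding assumes one origin state per locus.
- Supported pedigrees are the three named designs; arbitrary pedigrees
  would need an exact recursive prior.
- Synthetic founders are exchangeable Bernoulli draws: real founder panels
  have linkage disequilibrium and allele-frequency structure the simulator
  does not emulate, so passing tests demonstrate correctness of the
  machinery under the stated model, not performance on any real panel.
- The simulator assigns only additive bi-allelic QTL effects — no
  dominance, epistasis or QTL×environment terms; phenotypic inputs to the
  mapping models are assumed to be per-genotype means (BLUEs).
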