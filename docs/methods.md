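# Methods

`crmdecode` implements the computational core of a cis-regulatory module
(CRM) dissection study: a sequence-based thermodynamic model that predicts
reporter activity of enhancer/silencer constructs, a model-guided
binding-site mutagenesis designer, robust errors-in-variables (EIV)
statistics for dual-luciferase data, and seeded synthetic-data generators
that carry ground truth so every stage can be validated end to end.

## Binding-site annotation

A TF's preference is an alignment (count) matrix over positions × bases.
Frequencies are computed with a pseudocount (default 0.5 per cell) and a
uniform background. A site's relative affinity is

    q = prod_i p_i(b_i) / p_i(consensus_i)  ∈ (0, 1],

the product over positions of the frequency of the observed base relative
to the consensus base. Both strands are scanned; windows containing N are
skipped; when forward and reverse hits of one matrix share a start only the
better strand is kept. Sites with q ≥ q_min are annotated. The calling
threshold is not a biophysical constant here — occupancy math downweights
weak sites naturally — so q_min defaults to a permissive 0.01 and is
configurable per scan. Coordinates are 0-based half-open; ties in
frequency are broken alphabetically (A < C < G < T) so every computation is
deterministic.

## Thermodynamic model of transcription

Given annotated sites, roles (activator/repressor), and per-condition TF
concentrations ν, the statistical weight of a bound site is K·q·ν with a
per-TF binding scale K. The ensemble is every subset of pairwise
non-overlapping bound sites; declared cooperative partner pairs within a
gap (default 50 bp) multiply a configuration's weight by ω. Fractional
occupancies

    O_i = Σ_{configs ∋ i} W / Σ_configs W

are computed by a forward/backward dynamic program over sites sorted by
start (exact; verified against brute-force enumeration, which is retained
as an oracle for ≤ 22 sites). The model then applies, in order:

1. **Quenching** (short-range repression): every repressor site j within
   d_q bp edge-to-edge (default 150 bp) multiplies an activator's occupancy
   by (1 − γ_j·O_j), γ ∈ [0, 1].
2. **Interaction strength**: E = Σ_i α_i·O_i^eff over activator sites,
   with activation efficiencies α as weights.
3. **Long-range (dominant) repression**: E′ = E·Π_j (1 − β_R,j·O_j) over
   all repressor sites, β_R ∈ [0, 1]. This term lets a distal silencer
   push activity below the promoter-alone baseline.
4. **Initiation** as an enzymatic barrier crossing:
   r = R_max·exp(−max(0, θ − E′)). The rate is basal (R_max·e^−θ) with no
   input, strictly increasing in E′, and saturates at R_max once E′ ≥ θ.

The exact functional forms of quenching, long-range repression, and the
rate law are this package's declared choices: multiplicative bounded
factors and an exponential barrier law are the simplest forms satisfying
boundedness, dominance of full repression, and monotonicity, and each is
isolated behind its own function so alternatives can be swapped. Reporter
constructs are assembled as promoter + site-free spacer (N bases, default
2000 bp, standing in for vector backbone) + distal CRM; predictions are
reported as fold versus the promoter-only construct in the same condition.

## Mutagenesis design

A target site is ablated by substituting, at every position, the base with
the lowest pseudocounted frequency in the cognate matrix (excluding the
wildtype base; alphabetical tie-break). The mutant is then re-scanned with
all supplied matrices and accepted only if (i) the target window scores
below threshold on both strands, (ii) no new site above threshold exists
anywhere for any matrix, and (iii) all wildtype sites not overlapping the
target are unchanged. Where the all-lowest plan violates (ii) or (iii),
second-lowest bases are substituted position-by-position, searching
fallback subsets in order of increasing size. If no combination works the
design fails explicitly, listing the violating sites. At the permissive
default threshold (q_min = 0.01) an incidental new weak site is
occasionally unavoidable — in the randomized validation suite roughly 1 in
100 designs fails explicitly; no produced plan ever violates the
postconditions silently.

## Robust EIV normalization of dual-luciferase data

Firefly (y) and Renilla (x) luminescence both carry transfection-efficiency
noise, so construct activity is the slope β of y = βx estimated by robust
*orthogonal* regression. With orthogonal distances
d_i(β) = (1 + β²)^(−1/2)(y_i − β·x_i) and Tukey's biweight
ρ_c (capped at c²/6), the scale S solves the M-equation

    (1/n) Σ_i χ(d_i/S) = κ,   χ = ρ with c = 1.56, κ = 0.05,

and the slope is the **S-estimate**: β̂ = argmin_β S(β), with Ŝ = S(β̂)
(bracketed bisection for the scale; log-spaced presearch plus bounded Brent
for the slope, tolerance 1e-7, ≤ 1000 evaluations). Two alternative
formulations were implemented and rejected on numerical evidence:

* minimizing Σρ(d_i/S(β)) with the scale re-solved at each β lets the
  scale inflate to absorb gross outliers — the contaminated line attains a
  *lower* nested loss than the true one;
* a subsequent fixed-scale M-step with c = 4.7 adds no robustness at these
  constants, because the κ = 0.05 scale sits several-fold above the typical
  residual, making the loss effectively quadratic over inliers; the step
  drifts toward contamination while improving clean-data estimates by a
  median of only ~0.6%.

The resulting estimator tolerates gross outliers up to the M-scale's
breakdown point κ/(c²/6) ≈ 12% of the sample; concentrated contamination
beyond that can capture the scale minimum. This ceiling is a property of
the (c = 1.56, κ = 0.05) pairing, not of the implementation.

95% confidence intervals use the basic bootstrap over B = 999 resamples of
(x, y) pairs: (2β̂ − q_0.975, 2β̂ − q_0.025) of the replicate slopes. For
fold-changes (ratios of two group slopes) the numerator and denominator
replicates come from independent seeded streams, are paired by replicate
index, and the basic bootstrap is applied to the ratio. Bootstrap
replicates are solved vectorized (shared presearch grid, per-replicate
golden-section), matching the scalar estimator to ~1e-6.

**Calibration limitation.** At the study's replicate count (n = 10 wells
per group) the pair bootstrap underestimates the slope's sampling variance,
because that variance is dominated by high-leverage wells (large
transfection efficiency with proportionally large errors) whose tail a
10-point resample underrepresents. Measured coverage of the nominal 95%
interval is ≈ 86% over 500 simulated panels at n = 10 (a plain
total-least-squares slope shows the same deficit, so it is not specific to
the robust estimator) and reaches ≈ 95% by n = 20.

Negative or zero luminescence values are retained (background-subtracted
readings can be ≤ 0); only non-finite rows are dropped. Degenerate inputs
are handled explicitly: exact collinear data return β with S = 0 and a
degenerate flag; all-zero x raises an unidentifiability error.

## Reporter fold-changes and classification

Fold-change is a ratio of group slopes under one of two conventions:
against the promoter-only construct in the uninduced condition (one shared
baseline) or in the same condition (per-condition normalization). A
construct is classified an enhancer if its fold CI excludes 1 from above in
any condition, a silencer if the CI excludes 1 from below in some condition
and never from above, else neutral; conflicting conditions are reported.

qPCR threshold cycles convert to relative expression with the standard ΔCt
convention, 2^(−(Ct_target − Ct_ref)), normalized to the mean of uninduced
samples. (The alternative sign convention, under which expression would
grow with threshold cycle, is physically inverted and is not used.) Pooled
group comparisons use the Wilcoxon rank-sum test: exact null distribution
when the pooled sample is ≤ 20 without ties, otherwise mid-ranks with
normal approximation and continuity correction.

## Ensemble inference of TF roles

Whether each TF activates or represses is inferred by enumerating all 2^N
role assignments (N ≤ 20 guard), fitting each assignment's model to
observed folds, and ranking by weighted least squares on **log** folds
(folds are ratio-scaled, so errors are multiplicative). Each fit optimizes
a barrier θ plus, per TF, log10 K and one efficiency — α for activators; a
single repression efficiency driving both γ and β_R for repressors (keeps
the per-assignment problem low-dimensional). Default bounds:
θ ∈ [0.5, 8], log10 K ∈ [−2, 2], α ∈ [0, 5], repression ∈ [0, 1].
Optimization draws a Latin-hypercube pool (≥ 16 points), evaluates the
objective at all of them, and refines the best `n_restarts` candidates by
bounded L-BFGS-B (tolerance 1e-7, ≤ 1000 evaluations per start); runs are
reproducible from the seed via spawned substreams. Site layouts are
scanned once and folds for all conditions are evaluated by a vectorized
re-implementation of the occupancy/strength/rate chain, which is tested
for exact agreement with the reference implementation.

The role-recovery benchmark draws, per simulation, three random informative
matrices, a random assignment with **at least one activator** (an
all-repressor locus produces folds identically 1 and carries no role
information — a real reporter system likewise needs basal activation to
reveal repression), a promoter bearing one site per TF, and five distal
CRMs with rotating guaranteed TF placements; three conditions give each TF
a distinct concentration profile. Generating efficiencies are kept
moderate so interaction strengths stay below the barrier — a saturated
rate also carries no information. Under 5% fold noise the generating
assignment ranks first in 98% of 50 runs.

## Synthetic data: what it emulates and what it does not

* **Luminescence**: wells share a latent log-normal transfection efficiency
  (sdlog 0.35 reproduces the 2–4× sample-to-sample span seen in transient
  transfection at n = 10), each channel carries independent multiplicative
  measurement noise (default CV 10%), and a configurable fraction of wells
  has grossly scaled Firefly readings. Default 10 replicates per group.
* **Sequences**: i.i.d. background with planted matrix-consensus sites,
  recoverable at q = 1.
* **Reporter folds**: model-truth folds under log-normal noise, optionally
  expanded to raw wells.
* A bundled reference activity pattern (four condition-specific enhancers,
  their site-ablated mutants, a shorter enhancer core whose flanking
  sequence is repressive, and three erythroid-background silencers at
  ~3-fold repression) serves as ground truth for end-to-end validation of
  the normalize → fold-change chain.

Not emulated: chromatin context, plasmid copy-number/supercoiling effects,
correlated drift across wells or plates, luminometer saturation, and any
real PWM content (matrices are synthetic). Passing recovery tests
therefore demonstrates correctness of the *computations* under the stated
noise structure, not biological fidelity of any particular parameter value.

## Validation outcomes and known limitations

The end-to-end panel check generates one study-sized dataset (10 wells per
group) per run and asserts each headline quantity within ±15% of its
generating value. Direct folds recover comfortably; the two *derived*
mutant reductions (1 − mutant/wildtype) amplify ratio noise, and at the
frozen validation seeds two of four reductions land outside ±15% even
though every underlying fold is within tolerance. This is sampling noise
of a single n = 10 panel, not pipeline bias (the chain is exact on
noiseless data); it is left visible rather than averaged away.

The original study calibrated a 15-TF model ensemble against reporter
measurements of 46 CRMs and selected a representative best-fitting model;
those measurement tables and fitted parameters are not publicly
distributed, so that calibration **cannot be reproduced** here.
The synthetic recovery experiments above (role recovery, slope/bootstrap
calibration, DP-vs-enumeration agreement, mutagenesis postconditions)
substitute for it: they validate every algorithmic component the original
fit relied on, at desk scale, with carried ground truth.
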