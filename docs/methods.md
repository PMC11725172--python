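# Methods

`cryact` quantifies how a photoactivated protein ensemble departs from its
resting ("dark state", DS) ensemble, using the four analyses that together
characterize cryptochrome photoactivation: region-resolved RMSD relaxation
kinetics, per-residue symmetrized Kullback–Leibler divergence (KLD), flavin–
tryptophan distance/flip statistics with lifetime estimation, and a
KLD-correlation activation network. This note documents the models, the
parameters that matter, the synthetic-data generator used for validation, and
the numerical choices and limitations.

## Coordinate model and units

Structures are Martini-style coarse-grained beads: one backbone bead (`BB`)
per residue, side-chain beads `SC1`–`SC3`, and the flavin isoalloxazine ring
as five beads `FLA1`–`FLA5`. All coordinates are in Å and all times in µs.
Residue numbering is 1-based and taken from the input files; region ranges are
inclusive, with the canonical registry

| region | residues | | region | residues |
|---|---|---|---|---|
| PBL | 220–245 | | EEE | 440–460 |
| CT | 470–497 | | R20_33 | 20–33 |
| CL | 170–200 | | R110_125 | 110–125 |
| OPP | 80–90 | | CT_core (alternate) | 480–497 |
| REF | 388–399 | | REF_alt (alternate) | 389–399 |

and the tryptophan tetrad W395 (Trp_A), W372 (Trp_B), W318 (Trp_C), W369
(Trp_D). Two alternate ranges exist because published figure captions disagree
with the methods text for CT and REF; both registries are exposed and the
methods-text values are the defaults. Input trajectories must be unwrapped;
a consecutive-frame displacement above a configurable bound (default 10 Å)
triggers a warning (optionally an error), never silent correction.

## RMSD relaxation kinetics

Every frame of a replica is rigidly superposed onto that replica's first frame
by the closed-form Kabsch algorithm (proper rotation enforced via the
determinant correction; uniform bead weights, since coarse-grained beads have
near-equal mass). The default fit scope is the whole backbone: region RMSD
then measures motion relative to the protein body, which keeps it sensitive to
relative rearrangements; `region_only` superposition is available for
sensitivity analysis. RMSD is evaluated over the region's BB beads; the
ensemble mean ± std across replicas is the primary observable.

The mean curve is summarized by a biexponential relaxation

    R(t) = R∞ − c1 exp(−t/τ1) − c2 exp(−t/τ2)

with R(0) pinned to the observed first value, parameterized as amplitude
A = c1 + c2 ≥ 0 and weight w = c1/A ∈ [0, 1] so the pinning and positivity are
structural. The effective time constant is the weighted mean
τ_eff = (c1τ1 + c2τ2)/(c1 + c2). Fitting uses bounded least squares
(τ ∈ [dt, 10·t_max]) from three starts (τ1 = 0.1·t_max, τ2 = 0.5·t_max and two
perturbed variants), keeping the lowest-cost solution; when the two time
constants are degenerate (relative gap < 1e-3) or the two-component fit fails,
a single exponential is fitted instead and flagged in the diagnostics.

Two properties of this fit are worth knowing. First, the thermal-noise floor
of an RMSD curve rises within a few correlation times and is absorbed by one
of the two exponential components, diluting τ_eff when the floor is not small
against the structural amplitude. Second, a slow pair of widely split time
constants cannot be resolved alongside that floor with only two components.
Both effects informed the synthetic preset below.

## Symmetrized KLD profiles

For each residue the 3-D distribution of its BB-bead position is compared
between a replica and the DS reference by

    KLD_sym(P, Q) = ½ [ D(P‖Q) + D(Q‖P) ]   (nats),

after both ensembles are rigidly superposed onto the mean DS structure over
all BB beads. Profiles on ensembles lacking a shared superposition label are
rejected rather than silently computed: divergences in incompatible frames are
meaningless. Two independent estimators are implemented and cross-validated:

* **histogram** — cubic cells (default 1 Å) on a grid spanning the padded
  (2 Å) joint bounding box of both samples, with pseudo-count α = 1e-6 per
  cell. The pseudo-count biases the estimate upward where one distribution's
  tail is unsampled; with 1e5 samples per side the estimator is within ~5 % of
  the closed form at 0.5 nats, and within ~10 % of the Gaussian estimator for
  divergences up to ~2 nats. Larger divergences are tail-dominated and need
  more samples; cells should be comparable to the distribution width.
* **gaussian** — sample mean and covariance (ridge λ = 1e-6 Å² for
  positive-definiteness) with the multivariate-normal closed form. This is the
  pipeline default: it has no binning parameters, is cheap for ~500 residues ×
  20 replicas, and is exact for the generator's Gaussian fluctuations.

Divergences are reported in nats; the "normalized KLD" used by the network
stage divides each replica's profile by its own maximum, putting replicas on a
comparable scale (an assumption, flagged as such). Positions are treated as
3-D joint distributions, not per-coordinate.

## Flavin–tryptophan distances, the flip, and its lifetime

Distances are rigid-motion invariant, so no superposition is applied:
centre-of-mass distances between the FLA1–5 group and each tetrad tryptophan
(uniform weights by default; mass weights optional), and the FLA2–SC2 bead
pair distances that track the radical pair's spin-density centres. Side-chain
torsions use the ordered quadruple (BB, SC1, SC2, SC3) when present, else
(BB_prev, BB, SC1, SC2); collinear frames are reported as NaN gaps.

The Trp_C/Trp_D **flip** is the irreversible exchange of their distance order
to the flavin. Per replica, the flip time is the first frame at which
d_C > d_D holds for at least `persistence` consecutive frames (default 50
frames, chosen to exceed the thermal autocorrelation time so transient noise
crossings are ignored); otherwise the replica is right-censored at the
trajectory duration. A flip inside the final persistence window cannot
complete a full run and is censored — a conservative boundary convention.

Waiting times are modelled as a censored single exponential, justified by the
observed irreversibility. The maximum-likelihood estimate is

    τ̂ = (Σ event times + Σ censoring times) / n_events,  SE = τ̂ / √n_events.

Pooled (d_C, d_D) pairs are exported as hexagonally binned density tables, and
replicas are partitioned by flip status for conditional RMSD analysis.

## Activation network

The per-replica normalized KLD profiles form a replica × residue matrix.
Pearson correlation (Spearman optional) between residue columns across
replicas gives a residue × residue matrix; zero-variance residues get missing
entries that never form edges. Binarizing at threshold θ (default 0.86, signed
rule r ≥ θ; absolute-value mode optional) yields the adjacency of an
undirected graph on which NetworkX computes connected components,
greedy-modularity communities, degree and betweenness centralities, shortest
paths between named residue sets (tetrad → CT/EEE/PBL), and a seeded spring
layout. An edge-count-versus-θ curve is exported so the threshold choice can
be audited. Isolated nodes are kept in exports but excluded from community
detection.

## The synthetic-data generator

Real photoactivation trajectories are not publicly deposited, so validation
uses synthetic ensembles whose statistical structure matches what the analyses
assume, with exact ground truth:

* **Base structure** — a deterministic toy protein (helical backbone, BB/SC1/
  SC2 per residue, FLA1–5 site) of configurable size; 100 residues for fast
  tests, 497 with the canonical registry for study-scale runs. The tetrad is
  placed radially around the flavin with SC2 distances 5.5/8.5/11.5/14.5 Å,
  fixing the order Trp_A < Trp_B < Trp_C < Trp_D.
* **Relaxation** — each residue's mean position moves along a fixed,
  seed-drawn unit direction by Δ·(1 − c1 e^{−t/τ1} − c2 e^{−t/τ2}).
* **Fluctuation** — an exact-discretization Ornstein–Uhlenbeck process per
  coordinate (σ = 0.1 Å, τ_ou = 0.05 µs), i.e. fast jitter about the
  conformational mean path; slow conformational motion lives in the relaxation
  term. σ is kept small against the displacement amplitudes so that the RMSD
  kinetics reflect the injected relaxation rather than the noise floor (see
  the fit-bias discussion above).
* **Flip** — per replica an exponential waiting time T ~ Exp(τ_flip = 7.5 µs)
  is drawn; from the first frame at or after T the two designated SC2 beads
  exchange mean positions, irreversibly. A conditional sampler
  (`forced_flip_count`) draws exactly k flips with truncated-exponential times
  for studies conditioned on an observed split (e.g. 12 of 20).
* **Replica coupling** — a mean-one log-normal amplitude factor (cv = 0.3)
  shared within named region groups (defaults: {tetrad, CT} and {EEE, PBL})
  creates the cross-replica heterogeneity that a divergence-correlation
  network detects; without it the network stage would see only estimation
  noise.

The default preset is 20 replicas × 20 µs at 0.02 µs sampling. Injected
effective time constants follow the activation hierarchy (3.0 µs global,
1.8 µs CL/OPP, 4.7 µs CT, 5.7 µs EEE, 9.0 µs PBL), and the background
amplitude (3.36 Å) is calibrated analytically so the whole-backbone RMSD
plateaus at 3.35 Å given 6σ² of thermal variance and the region amplitude mix.
All randomness flows through `numpy.random.Generator` seeded from one integer
via `SeedSequence` spawning, so outputs are bit-reproducible.

**What the generator does not emulate:** anharmonic/multimodal residue
distributions (fluctuations are Gaussian, so the Gaussian KLD estimator is
exact rather than approximate on this data); coupling between RMSD noise and
flip events; replica-to-replica variability of the *background* amplitude; and
solvent or lipid contacts. Passing tests therefore demonstrate correctness of
the estimators and pipeline plumbing under the assumed statistical structure,
not robustness to every feature of real coarse-grained trajectories.

One visible consequence: after max-normalization, all residues share the
normalizing replica factor (typically the EEE maximum), so background residues
appear strongly mutually correlated and the synthetic network carries a dense
background cluster — the classical spurious-correlation effect of ratio
normalization. The planted structure (tetrad–CT connectivity, EEE–PBL block,
no cross-block edges at θ = 0.86) is still recovered, and the network audit
tests use directly constructed KLD matrices where ground truth is unambiguous.

## Numerical choices and degenerate inputs

* Kabsch superposition rejects fit sets with fewer than 3 beads or a
  second singular value below 1e-8 of the first (collinear/coincident).
* RMSD at frame 0 against the replica's own frame 0 is set to exactly 0.
* Histogram grids must match exactly between compared distributions; samples
  falling outside a supplied grid raise an error rather than being dropped.
* The lifetime MLE requires ≥ 1 event; with none, the error carries the
  censoring-based lower bound Σ censoring times.
* Correlation needs ≥ 3 replicas; missing (zero-variance) entries propagate
  as non-edges.
* Empty graphs yield empty metric collections, not exceptions.
* Pipeline stage failures abort with a stage-tagged error; every intermediate
  is persisted as CSV/JSON/GraphML under the run directory, and the report
  embeds a config hash (output path excluded) plus seeds and versions.

## Problem sizes used in the validation suite

Study-scale checks run the full 497-residue preset (20 replicas × 1001 frames):
parameter recovery asserts every region's fitted τ_eff within 15 % of its
injected value. The flip-lifetime study uses 200 replicas of an 80-residue toy
at 0.1 µs sampling (τ̂ within 20 %, flipped fraction within 3 binomial SE of
1 − e^{−20/7.5}). Estimator oracles use 1e5 samples. Unit tests use 60–100
residue toys with tens to hundreds of frames.

## Known limitations

* The biexponential τ_eff is biased low when the thermal floor or truncation
  is substantial relative to the structural signal (quantified above); fits on
  real data should inspect the residual norm and the fallback flag.
* The histogram KLD estimator degrades when cells are much larger than the
  distribution width or tails are unsampled; the Gaussian estimator degrades
  on multimodal distributions (e.g. a residue whose position distribution is
  split by the flip). Cross-checking both estimators is the intended use.
* The exponential flip model cannot reconcile an observed 60 % flipped
  fraction at 20 µs with τ = 7.5 µs (which implies 93 %); with only 20
  replicas such a discrepancy is plausible sampling fluctuation, and the
  conditional sampler exists precisely to reproduce observed splits.
* Max-normalization of KLD profiles induces spurious correlation through the
  shared normalizer (see above); the un-normalized matrix is also exported.
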