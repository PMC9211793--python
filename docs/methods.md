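# Methods

## Scope and model

`ensemblefe` implements the analysis layer of two ensemble binding
free-energy protocols for a congeneric inhibitor series against a kinase
target, together with the network and ranking diagnostics used to judge
them. Molecular dynamics itself is out of scope: the package consumes
per-frame energy tables and per-window ∂U/∂λ samples, and ships a
synthetic generator that emulates those inputs with planted ground truth so
every stage can be verified end to end.

### End-point estimation (1traj, 1traj-ar)

A frame's free energy is the entropy-free MMPBSA sum

    G = E_vdw + E_ele + E_internal + G_PB + G_SA      (kcal/mol).

In the 1traj protocol complex, receptor and ligand conformations all come
from the complex trajectory, so per matched frame

    ΔG_frame = G(complex) − G(receptor) − G(ligand),

and the large internal-energy terms cancel identically. Frames are
averaged within each replica; replicas are averaged with equal weight
(mean-of-replica-means, never pooled frames, so frame-count imbalance
cannot reweight a replica); uncertainty is a bootstrap over replica means
only, because frames within a replica are autocorrelated. Default B = 5000
resamples, seed required. Replica means are sorted before resampling, so
the bootstrap is invariant to replica labelling.

1traj-ar adds a *relative receptor adaptation*: compound i's mean receptor
energy minus the unweighted grand mean over compounds, added to the 1traj
value with SEs combined in quadrature. Two open choices were resolved as
follows and are switchable: the adaptation uses the full MMPBSA receptor
energy by default (`adaptation_energy: total`, `mm_only` available), and
the grand mean weights compounds equally rather than pooling frames.
Relative adaptations sum to zero across the series by construction.
Entropy terms are deliberately absent throughout.

### Ensemble thermodynamic integration

Each alchemical leg (bound, free) is sampled at a λ schedule; the default
13-point schedule {0, 0.05, 0.1, 0.2, …, 0.9, 0.95, 1} densifies the
endpoints where ⟨∂U/∂λ⟩ varies fastest. Window means are
mean-of-replica-means; the leg ΔG is the composite trapezoidal quadrature
(the standard in this family of protocols; the rule is recorded in output
metadata so alternatives can be compared). ΔΔG = ΔG_bound − ΔG_free;
negative values favour the target compound. The bootstrap resamples
replicas independently per window — windows are independent simulations —
and integrates each realisation. Schedules are validated (strictly
increasing, spanning [0, 1]) rather than assumed.

### Network accounting

Transformations form a two-hub perturbation network (parallel edges
allowed). Path composition negates edges traversed backwards and adds SEs
in quadrature. Cycle closure reports the signed calc sum (hysteresis) and
per-leg calc−exp discrepancies; legs above a threshold (default 0.5
kcal/mol, near typical alchemical reproducibility, always stated in
reports) are flagged even when the cycle sum is small, since per-leg errors
can cancel. Cycle discovery enumerates triangles through the two designated
hubs plus any user-specified cycles; exhaustive cycle enumeration is
exponential and deliberately omitted.

Mean signed error (MSE) is ⟨ΔΔG_calc − ΔΔG_exp⟩; negative means the
predicted improvement is overestimated. The common-change offset either
comes from a reference pair that isolates the shared chemical change (the
default, matching how such corrections are motivated in practice) or is
fitted as −MSE; both modes are recorded. MSE after equals MSE before plus
the offset — asserted as an identity — and correlations are unchanged by
any constant shift. Directional agreement excludes edges whose calculated
or experimental ΔΔG is within 1e−12 of zero and reports the exclusion
count; ties are otherwise undefined.

### Series evaluation

Experimental pIC50 converts to ΔG = −RT·ln10·pIC50 with R = 1.9872×10⁻³
kcal/(mol·K), T = 300 K by default (a typical simulation temperature; the
temperature is configurable and recorded). Compounds stratify by net
charge and by modification subgroup: category sets {}, {1}, {2}, {3}, {4},
{3,4}, {1,4} map to codes 0–4, 34, 14, and {1,3,4} maps to 14 when the
category-3 change is a single H→F substitution (too minor to matter); any
other combination is "unclassified" with a warning. Ranking statistics are
Pearson r, Spearman ρ with mid-ranks, Kendall τ-b, and sample covariance
(n−1 denominator, reported on the kcal/mol scale). Strata with fewer than
three members, or constant series, are reported as having no defined
coefficients. Censored compounds (assay floor pIC50 = 5.00) stay in the
headline statistics, with an automatic sensitivity rerun excluding them.

## Synthetic generator

The generator defines the study conditions: 25-replica end-point ensembles
and 5-replica-per-window TI ensembles; a 150-compound series with neutral
subgroup sizes {0: 1, 1: 36, 2: 7, 3: 25, 4: 26, 14: 31, 34: 14}, ten
charged compounds, five censored at the 5.00 floor, and measured pIC50
pinned to the assay range 5.03–8.37 (span 3.34 log units); two hub
compounds L30 (subgroup 0) and L2 (first subgroup-1 member); and the
103-edge two-hub layout (1 hub–hub edge, 17 compounds paired with both
hubs, 68 paired with one).

Key constructions:

- **Quadrature-consistent TI truth.** Each leg's mean ∂U/∂λ profile is a
  quadratic in λ (coefficients ~ N(0, 4)) shifted so its *trapezoidal*
  integral over the requested schedule equals the planted leg ΔG. Noiseless
  data therefore recover the planted ΔΔG to floating precision on any
  schedule, making the planted truth the quadrature-consistent target
  rather than an analytically integrated one. Noise enters as one offset
  per (edge, leg, window, replica) (default SD 0.2 kcal/mol) plus
  per-sample jitter (default SD 0.3 kcal/mol) — values typical of
  well-behaved alchemical windows.
- **Exact single-trajectory decomposition.** Receptor and ligand frames
  are generated first; complex frames are their component-wise sum plus an
  interaction term whose internal-energy component is identically zero.
  Internal-energy streams are snapped to multiples of 2⁻²⁰ (≈1e−6
  kcal/mol, far below any signal), which makes the receptor+ligand sums —
  and hence the 1traj internal-energy cancellation — exact in floating
  point, as they are for real single-trajectory extraction where the
  complex file *is* the sum. The planted interaction+solvation mean is
  split 0.45/0.25/0.25/0.05 across E_vdw/E_ele/G_PB/G_SA. Replica-level
  scatter (default SD 1.0 kcal/mol) sits on the interaction energy;
  per-frame component noise (defaults 0.8/1.5/3.0/1.2/0.3 kcal/mol) affects
  all species but cancels in 1traj except through the interaction term.
- **Planted adaptation.** Receptor adaptation offsets shift each
  compound's receptor internal energy; 1traj-ar recovers them relative to
  the series mean.
- **Linear activity link.** True scores are slope·pIC50 + intercept +
  N(0, σ); the default slope −1.3726 kcal/mol per log unit is −RT·ln10 at
  300 K, so noiseless truth reproduces the experimental free energies.
  `noise_sd_for_pearson` converts a target population correlation into the
  required score scatter; where a planted correlation is meant to survive
  the estimation pipeline, the estimator's own variance (replica offsets
  plus averaged frame noise) is subtracted analytically from the score
  scatter first.
- **Stable streams.** One root seed; child RNG streams are keyed by
  (compound or edge, leg, window, replica) through CRC-hashed
  SeedSequences, so enlarging an ensemble never perturbs existing members,
  and every generator is a pure function of its spec (same seed → same
  bytes).
- **Planted systematic bias.** In the full pipeline, compounds carrying
  the shared hydrophobic-group change are shifted on the calculated side by
  a constant (default −1.28 kcal/mol), so edges that grow the group inherit
  the bias while edges between group-carrying compounds cancel it. This
  reproduces the situation where a single reference-pair discrepancy
  corrects a whole edge subset, and exercises the offset-correction code
  path against known truth.

### What the generator does not emulate

Real trajectories have autocorrelated frames, non-Gaussian and
compound-dependent noise, force-field and sampling bias that varies with
chemistry, slow receptor conformational changes, and finite-sampling
artefacts in the solvation terms. Passing tests therefore demonstrate that
the *estimators and accounting* are correct under the stated noise model —
not that the physical protocols achieve any particular accuracy on real
systems. Published headline correlations for the real series depend on
unreleased simulation energies and are treated as context only.

## Numerical choices

- Trapezoidal quadrature; schedule validated, never assumed.
- Bootstrap B = 5000 by default (smaller in fast demo configs); resampling
  at the replica level; canonical sort before resampling gives
  label-invariance under a fixed seed.
- Sign ties in directional agreement: |ΔΔG| < 1e−12 excluded and counted.
- Energies serialised with six decimals; identical config + seed gives
  byte-identical outputs, checksummed in a run manifest.
- Degenerate inputs fail loudly: mismatched (replica, frame) sets list the
  missing pairs, broken path chains name the gap, constant series and
  n < 3 strata are reported as undefined rather than silently skipped.
- `--discard-frames N` drops the first N frames per replica for inputs
  that include equilibration carry-over; generated data are production-only.

## Problem sizes in the shipped checks

The test suite and the acceptance script scale the study down where full
size adds nothing: TI recovery checks use 5–8 samples per window (noiseless
recovery is exact by construction, so sample count is irrelevant there);
coverage studies use 100 independent seeds; the harmonic oracle uses the
full 13-window × 5-replica × 1000-sample layout; the end-point recovery
check uses the full 25-replica ensemble with 40 frames per replica. These
sizes are the package's own choice of minimal-but-faithful study
conditions.

## Known limitations

- The offset correction assumes a single shared systematic error across
  the tagged subset; heterogeneous biases are not modelled.
- No cycle-consistent weighted least-squares estimation of absolute ΔG
  (out of scope), and no FEP/BAR/MBAR estimators — the TI module consumes
  ∂U/∂λ only.
- Subgroup codes beyond the seven observed combinations are reported as
  "unclassified" rather than inferred.
- The experimental-variability option is a per-compound Gaussian
  (SD 0.12 log units); real assay error is heavier-tailed.
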