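# Methods

`allokit` implements a deep-learning + free-energy-profiling analysis of
boosted (Gaussian-accelerated) molecular-dynamics ensembles of a receptor
simulated with and without an allosteric modulator. This note documents
the models, the synthetic study system, the numerical choices, and what
the tests do and do not establish.

## The analysis

**Contact maps and classification.** Each saved frame is reduced to a
binary residue-contact map: residues i and j are in contact when any pair
of their heavy atoms is within 4.5 Å (inclusive). Receptor-internal pairs
with sequence separation |i−j| < 3 are excluded by default to suppress
trivially permanent backbone-neighbor contacts (configurable down to 0;
pairs involving a ligand or modulator entity are always eligible). Maps
are encoded as single-channel images (contact = maximum intensity),
zero-padded bottom/right to a common size, and split per class 80%/20%
into training/validation sets with a seeded shuffle. A small 2D CNN — two
3×3 stride-2 convolution stages (8 channels each), one 32-unit hidden
dense layer, softmax head — is trained for 15 epochs with Adam (lr 1e-3,
batch 64, cross-entropy, decoupled L2 weight decay 1e-3) to classify
frames by condition (e.g. "Agonist" vs "AgonistPAM"). The net is written
in plain numpy: at contact-image scale CPU training takes seconds, every
operation is deterministic for a fixed seed, and the input gradient
needed for attribution is exact. Weight decay matters beyond
regularization: when several pixels carry equally discriminative signal,
L2 pressure spreads weight across them, which keeps their saliency values
comparable instead of letting one pixel absorb all attribution.

**Saliency and contact selection.** Attribution uses vanilla input
gradients: |∂ logit(target class) / ∂ pixel| evaluated on the contact map
of the most populated conformational cluster's medoid frame, symmetrized
by averaging (i,j) and (j,i), zeroed on the padding, and divided by its
maximum so values lie in [0, 1] — the 0.7 selection threshold presupposes
a normalized scale. A residue pair is a *characteristic contact* when its
normalized gradient is ≥ 0.7 **and** both member residues show a
significant flexibility change upon modulator binding; a pair with a
non-significant member is dropped regardless of gradient (these are
reported separately).

**Flexibility.** Per-residue RMSF is computed after iterative
least-squares superposition of all frames onto the ensemble-average
structure (receptor Cα selection, convergence 1e-4 Å, ≤ 10 iterations),
refined on the *stable core*: after a first full-selection pass, the
least-mobile half of the alignment atoms re-anchors the fit
(`core_frac=0.5`; `None` disables). Without the core refinement a few
large-amplitude residues drag the least-squares frame and bleed apparent,
condition-dependent flexibility into every other residue. Receptor
residues are represented by their Cα, ligand entities by the mean of
their heavy-atom RMSFs. ΔRMSF = RMSF(bound) − RMSF(free) is differenced
per replica (replica k against replica k); a residue's change is
significant iff |mean over replicas| ≥ replicate SD *and* the mean is
nonzero. Replica-wise differencing is the only pairing that yields three
ΔRMSF values for the SD in that rule; a variant differencing the replica
means (SDs propagated in quadrature) is available behind
`pairing="mean"`. Note the rule's intrinsic behavior: for pure-noise
residues, mean/SD of three replicates is a scaled t statistic with 2
degrees of freedom, so its false-positive rate is P(|t₂| ≥ √3) ≈ 22.5%
*by construction*. The same operation with an explicit residue
correspondence compares a "non-cognate" receptor against the cognate one
(selectivity mode); residue alignment is never inferred.

**Clustering.** Frames of all production replicas of a condition are
pooled with a stride keeping at most 1,500 frames, pairwise receptor-Cα
RMSD is computed with optimal superposition (batched 3×3 SVDs of
cross-covariances), and average-linkage agglomerative clustering is cut
at ε = 2.5 Å (or a fixed cluster count). The representative of a cluster
is its medoid — the member frame minimizing mean RMSD to the cluster —
because a real frame is needed to compute a contact map; ties break to
the lowest frame index, and the most populated cluster (ties to the lower
id) supplies the saliency reference map.

**Reweighting.** A boosted run samples exp(−β[V+ΔV]); unbiased bin
probabilities are recovered as p_j ∝ n_j ⟨e^{βΔV}⟩_j with the bin-local
average approximated by the second-order cumulant expansion
ln⟨e^{βΔV}⟩_j ≈ βC1_j + β²C2_j/2 (exact for Gaussian bin-local boost;
the anharmonicity diagnostic γ = S_gauss − S_emp, the entropy deficit of
the boost histogram relative to a matched-variance Gaussian, checks that
regime). Alternatives: `exponential` (direct e^{βΔV}-weighted histogram —
unbiased but high-variance when βσ(ΔV) is large), `maclaurin(K)`
(truncated series; note a finite polynomial is *not* exactly invariant
under a constant boost shift — the violation vanishes as K grows), and
`unweighted` (no correction; kept for demonstrating that reweighting
matters). PMF = −kT ln p, min-shifted to zero over valid bins. Bins with
fewer than `cutoff` frames (default 100; bin size default 1.0 Å, both
within the standard 0.5–1.0 Å / 100–500-frame working ranges) are masked
and carry no value; C2 is computed from deviations about the bin mean
(two-pass) to avoid catastrophic cancellation. kB = 0.001987
kcal·mol⁻¹·K⁻¹; T comes from the boost series (310 K throughout).

**States and confinement.** Low-energy conformational states are local
minima of the valid-bin PMF (2 neighbors in 1D, 8 in 2D; invalid bins are
not neighbors; equal-value plateaus collapse to the lowest-index bin)
with PMF ≤ 1.0 kcal/mol above the global minimum. The threshold is a
package choice — published free-energy maps label states without a
numeric criterion — and is exposed as a parameter. The workflow's
headline readout is the confinement verdict: the state count of the
modulator-bound condition versus the free condition (e.g. "2 → 1
states").

## The synthetic study system

Real inputs at production scale are microseconds of membrane-protein MD;
the package therefore ships a generator whose outputs have *analytic*
ground truth, and the default `SyntheticSpec` is the fixed study
condition for all planted-signal tests.

A latent conformational coordinate s (Å) follows a Gaussian-mixture
potential V(s) = −kT ln Σ_k exp(−(s−s_k)²/2w_k² − βD_k): two wells for
the modulator-free condition (centers 3.0 and 7.0 Å, widths 0.8 Å, the
second well's floor 0.4 kcal/mol up), one well (the first) for the bound
condition — wells of the bound condition must be a subset of the free
ones. The boost is the harmonic lower-bound law on the grid, ΔV(s) =
[k0/(2(V_max−V_min))](V_max−V)² with E = V_max and k0 = 0.9, plus an
additive Gaussian term (baseline 4.0, SD 1.0 kcal/mol, clipped at zero)
standing in for the boost contributions of all other degrees of freedom.
Frames are drawn i.i.d. from the biased law p*(s) ∝ exp(−β[V+ΔV]) by
inverse-CDF sampling on a 4001-point grid — exactly the stationary
distribution a boosted simulation would sample, so the reweighting target
is the exact F(s) = V − min V carried in the `GroundTruth` sidecar.
A configured total boost SD above σ₀ = 6.0 kcal/mol is rejected,
mirroring the boost-SD ceiling used in production simulations.

Two boost presets exist deliberately. Production simulations report
total-boost means of ~13–16 kcal/mol with SDs of ~4–5; `paper_scale_spec()`
reproduces those magnitudes (baseline 12.0, jitter 4.3) and is what the
boost-statistics checks run on. The *default* spec uses jitter SD 1.0
because the per-bin PMF uncertainty of the cumulant estimator scales as
(β²/2)·√(2σ⁴/n_bin): at σ ≈ 4.3 and the desk-scale 3 × 5,000 frames that
is ~0.7 kcal/mol per bin, which no estimator can beat — quantitative PMF
recovery and production-scale boost magnitude are separate study
conditions at this frame count.

Geometry: 60 receptor beads (one Cα each) on a helix-like curve (radius
2.3 Å, 100° twist, 1.7 Å rise — neighbor spacing ~3.9 Å, closest eligible
pair (i,i+3) at ~5.6 Å) plus a 3-atom orthosteric ligand parked in a
pocket with identical statistics in both conditions. Signal is planted
three ways: (1) four sequence-local pairs — (10,13), (22,25), (34,37),
(46,49) — toggle into a 3.5 Å contact (a ~2 Å bead motion) with
probability 0.95 when bound vs 0.05 when free; (2) the eight member
residues jitter with SD 0.7 Å free vs 0.25 Å bound (everything else 0.4 Å,
condition-independent); (3) a reporter pair (2, 57) whose Cα distance is
d0 + s (d0 = 6 Å, jitter 0.15 Å so the reporter stays faithful to the
latent coordinate) carries the free-energy signal. No allosteric-modulator
entity is placed: a physically present/absent entity would add perfectly
separating contact pixels that compete with the planted pairs the
recovery tests are defined on (modulator roles are fully supported for
real data).

**What the generator does not emulate:** temporal autocorrelation (frames
are i.i.d., so convergence/equilibration behavior is untested), solvent
and membrane, anisotropic or correlated residue motions, multi-atom
side-chain packing, and any real receptor's landscape. Passing tests
therefore establish the *estimators* (reweighting identities, selection
logic, significance arithmetic, clustering/medoid definitions) and
end-to-end recoverability of planted signal under realistic noise — not
performance on correlated production trajectories.

## Numerical and design choices

- Units: Å and ns internally everywhere; XTC nm converted at the
  boundary (written at 1e-4 nm precision so round trips hold to 1e-3 Å).
  0-based residue/frame indices internally; 1-based only in PDB output.
- Boost-log dialect: whitespace-separated `frame ΔV_total [ΔV_dihedral]`
  with `#` headers, one record per saved frame; ΔV_total is what enters
  reweighting (the dihedral column is carried but not used in
  energetics). Negative boosts and non-monotone frame indices are
  rejected.
- Binning: edges snap to multiples of the bin size covering the data;
  the top edge is inclusive via right-open search with clipping.
- Determinism: every stochastic step (splitting, initialization,
  shuffling, generation) takes an explicit seed; independent replica
  streams come from spawned seed sequences; rerunning the CLI with the
  same config reproduces all output tables byte-for-byte (outputs carry
  no timestamps).
- Degenerate inputs: empty validation split, single-class datasets,
  residues without heavy atoms, all-zero saliency gradients, zero-variance
  anharmonicity, and all-masked PMFs are hard errors or explicit warnings,
  never silent.
- The pipeline computes a 1D PMF for the configured reaction coordinates
  and for every selected contact; the auxiliary 2D surface over the two
  leading coordinates is skipped with a warning when no 2D bin reaches
  the cutoff (small runs), while sparse 1D surfaces remain hard errors.

## Known limitations

- Saliency is vanilla gradients only; no SmoothGrad/Grad-CAM.
- The significance rule inherits its ~22.5% pure-noise false-positive
  rate from the three-replicate t-statistic; it is a screening filter,
  not a calibrated test.
- Clustering is O(n²) in pooled frames; the stride bounds cost but large
  systems should pre-stride.
- No periodic-boundary handling: inputs are assumed whole-molecule,
  unwrapped.
- PMF uncertainties (e.g. block analysis) are not computed.
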