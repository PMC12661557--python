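# Methods

This note documents the models and numerical choices behind cycloscape:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where genuinely open design
questions were settled.

## Observables

Every analysis reduces a conformational ensemble to per-frame scalars
computed on the backbone heavy atoms (N, Cα, C, O) only:

* **Backbone RMSD to a reference** — minimum root-mean-square deviation
  over rigid rotations and translations, via Kabsch superposition (SVD of
  the 3×3 covariance, with the determinant correction against improper
  rotations). Atom correspondence is by label order; there is no cyclic
  renumbering or symmetry search, since the mixed L/D chirality and
  sequence of the target peptides break ring symmetry. The batched path
  computes residuals from the rotated coordinates rather than the SVD
  trace identity: the trace form loses roughly seven digits to
  cancellation near zero deviation, while the coordinate form is accurate
  to ~1e−15 Å, which matters for rigid-invariance checks at 1e−9 Å.
* **Radius of gyration** — unweighted (geometric) RMS distance of the
  backbone atoms from their centroid. Geometric rather than mass-weighted
  because both observables are computed on the same backbone set and Rg is
  used purely as a shape coordinate; a `labels` argument on the low-level
  functions allows restricting any atom selection.

The first 10 % of every trajectory (`skip_fraction=0.10`, floor of the
frame count) is discarded before analysis to reduce starting-structure
bias. The skip is applied once per source run; merged or concatenated
ensembles are never re-trimmed. For simulated-tempering trajectories,
`select_temperature_frames` keeps frames within `tol_K` (default 0.5 K,
suitable for discrete ladders) of the 300 K target before analysis.

## Density profiles and free-energy maps

1D RMSD density profiles are normalized histograms over **explicit,
shared bin edges** — divergences are only meaningful on a common support,
so profile constructors require the edges and `default_bin_edges` builds
a fixed 0.1 Å grid over [0, global max + 0.1 Å] from the pooled data of
all series being compared. Values outside the range are clipped into the
end bins so no frame is silently dropped. The 0.1 Å width is a documented
choice (no canonical value exists); JSD results should be quoted together
with it.

2D free-energy maps histogram (Rg, RMSD) on a 100×100 grid over
data-driven [min, max] ranges (explicit edges can be passed so maps from
different protocols share axes) and apply

    F = −kT · ln(ρ),

with ρ the normalized bin probability, k_B = 0.0083144621 kJ/(mol·K) and
T = 300 K by default, shifted so the deepest occupied bin sits at F = 0.
The natural logarithm with kT in kJ/mol is the standard statistical-
mechanics convention; a 2:1 occupancy ratio therefore maps to
ΔF = kT·ln 2 ≈ 1.729 kJ/mol at 300 K. Empty bins are flagged unoccupied
(rendered white, excluded from minima searches) rather than assigned
infinite F.

## Convergence by Jensen–Shannon divergence

For repeated runs of one protocol, a mean RMSD profile is built by
evenly subsampling every run to the shortest run's length (deterministic
indices ⌊i·L/m⌋ — reproducibility over randomness), concatenating, and
histogramming. Each run's divergence from the mean profile is

    JSD(P‖Q) = ½ KL(P‖M) + ½ KL(Q‖M),   M = (P+Q)/2,

computed on bin probability masses with base-2 logarithms, so JSD ∈
[0, 1] with 0 for identical and 1 for disjoint profiles. Masses rather
than density heights make the value independent of the base measure;
0·log(0/x) := 0, and M > 0 wherever P or Q is, so no division by zero
arises. √JSD is a metric (triangle inequality), which the tests verify
numerically.

Convergence curves evaluate the run-vs-mean JSD on 100 growing prefixes
(0–t₁ … 0–t₁₀₀, equally spaced in frame count); the mean profile is
recomputed on the same prefix of every run (a fixed full-trajectory mean
is available via `recompute_mean=False`). A run is converged when its
end-point JSD is ≤ 0.05, a protocol when every run is. The 0.05 threshold
is the working definition of "profiles superpose"; relaxing it to 0.1
tolerates the borderline cases.

Inter-protocol agreement merges each protocol's runs, equalizes frame
counts between the two groups, builds their pooled average profile, and
records each group's JSD **to that average**; the matrix entry is the
mean (or max) of the two. Note that the entry is therefore roughly a
quarter of the direct pairwise JSD between the two group profiles: for
two-state populations (0.9, 0.1) vs (0.1, 0.9) the closed form gives
0.147 per group against the (0.5, 0.5) average, versus 0.531 group vs
group. Entries above the same 0.05 threshold flag protocol disagreement.

## Blind native-structure prediction

The prediction pipeline never sees the reference structure:

1. align all frames to the first frame (backbone Kabsch fit applied to
   all atoms); the one-frame arbitrariness was tested against a
   second-pass realignment protocol and retained for simplicity;
2. PCA on the flattened backbone coordinates, keeping the minimal number
   of components whose cumulative explained variance reaches 80 %
   (typically 2–6 for multi-basin ensembles);
3. cluster the retained-component scores. HDBSCAN (scikit-learn
   implementation) is the default, with `min_cluster_size = max(50, 2 %
   of frames)` — consistent with the convention of not reporting clusters
   under 2 % of the ensemble; k-means is available as the alternative,
   defaulting to the HDBSCAN cluster count when used for map annotation.
   Cluster ids are reassigned 1..k by decreasing population; −1 is noise.
   Each cluster is represented by its **medoid** (the actual frame nearest
   the cluster's mean score), so a concrete structure can be written out;
4. the star rule: the lowest-free-energy point is the densest bin of the
   100×100 histogram over the first two principal components (density is
   the Boltzmann-equivalent of free energy here, so no temperature enters;
   using all retained components instead is available via `density_pcs`).
   If that point falls in the most populated cluster, a **green** star
   marks that cluster's medoid. Otherwise a **cyan** star marks the
   lowest-FE cluster's medoid and a **yellow** star the most populated
   cluster's medoid; the yellow star is the retained prediction. Noise
   frames are excluded from the FE-minimum search so unclustered density
   cannot carry the star. Ties in population go to the cluster with the
   denser medoid, then the lower id.

`evaluate_prediction` (and only it) compares the starred frame with the
reference — backbone RMSD to the first deposited model and, when an NMR
ensemble is supplied, the minimum over all models. When a decoy basin
outweighs the native one the star lands in the decoy: the pipeline
reports this failure mode honestly rather than correcting it, because
quantifying exactly that failure across protocols is what the
combination analysis consumes.

## Combining simulations

Different force fields or sampling protocols rank the same basins
differently. `equalize_and_concatenate` subsamples every trajectory
evenly to the common minimum frame count and concatenates, so each
simulation contributes the same number of frames (frame-count-based
equal weighting by design; no energetic reweighting). The prediction
pipeline is re-run on the combined ensemble from scratch — alignment,
PCA, clustering, star — rather than averaging per-simulation answers.
All subsets of the available simulations (sizes 2..n, or a requested
list) are enumerated in deterministic order and each scored by the
median predicted-star RMSD over the peptide set; even peptide counts use
the midpoint median. Reports rank ascending by median, ties broken by
max RMSD then lexicographic subset.

## Synthetic ensemble generator

The generator plants ground truth that the pipeline must recover:

* **Ring reference** — residues equally spaced on a circle sized for a
  3.8 Å Cα–Cα spacing, N and C flanking each Cα along the circle and the
  carbonyl O offset outward/axially. The geometry is idealized (no real
  bond lengths/angles, no side chains); all downstream mathematics is
  coordinate-generic, so chemical realism buys nothing here.
* **Basins** — a random 3N-direction with net translation removed,
  rescaled by bisection so the superposed backbone RMSD of the centroid
  from the reference equals the requested displacement to 1e−6 Å.
* **Dynamics** — basin occupancy follows the lazy Markov chain
  T = s·I + (1−s)·1pᵀ: each step stays with probability `stay_prob`,
  otherwise redraws the basin from the stationary populations p (possibly
  re-selecting the current one). This chain's stationary distribution is
  exactly p, so planted populations are recoverable by construction; the
  integrated autocorrelation time is (1+s)/(1−s) frames. Frames are the
  occupied centroid plus isotropic N(0, σ²) noise per coordinate.
* **Protocol sets** — protocols share centroids and widths but get their
  own population vectors; runs within a protocol differ only by seed.

What the generator does **not** emulate: continuous diffusive motion
within basins, anisotropic or correlated fluctuations, basin-shape
asymmetry, temperature dependence, or any force-field physics. Passing
tests therefore demonstrate that the analysis machinery recovers planted
populations, displacements and protocol shifts under clean Markov/
Gaussian conditions — not that any force field or sampling protocol is
accurate.

## Test and experiment scales

The ground-truthed experiments use a 7-residue ring (28 backbone atoms),
per-coordinate noise σ = 0.25 Å, and basins separated by ≥ 2.5 Å RMSD —
comfortably resolved but not trivial. Recovery experiments run 2×10⁴
frames per trajectory over 5 seeds with `stay_prob = 0.7` (autocorrelation
time ≈ 5.7 frames, ~3,500 effective samples per run), sizes at which the
±0.03 population-recovery tolerance corresponds to ≈3.5 standard errors.
The combination-robustness design uses four protocols sharing a native
basin at 0.8 Å (population 0.40) plus one protocol-specific decoy each
(population 0.60): no single simulation ranks the native basin first,
while any ≥3-way equal-weight combination dilutes each decoy to 0.20 and
must. These scales are the package's reference experiment; larger frame
counts only tighten the statistics.

## Numerical conventions and edge cases

* Internal unit is Å throughout; PDB I/O (biotite) is Å natively.
* Zero-variance ensembles (all frames identical) short-circuit PCA to a
  single all-zero component instead of producing NaN variance ratios.
* Degenerate constant observables get a ±0.5 widened axis so 2D
  histogramming stays well-defined.
* Medoid and argmin ties resolve to the first (lowest-index) frame.
* All randomness flows from explicit integer seeds (numpy Generator);
  subsampling is deterministic; reruns are byte-identical.
* Per-frame alignment and RMSD are vectorized (batched SVD) — about
  10⁵ frames/s — so full pipelines on 10⁴–10⁵-frame ensembles run in
  seconds to a few tens of seconds.

## Known limitations

* JSD values depend on the 0.1 Å profile bin width; comparisons are only
  valid at a fixed width.
* HDBSCAN can merge adjacent low-FE basins into one cluster; the star
  rule then reports the merged cluster's medoid, which may sit between
  basins. This mirrors the behaviour of density-based clustering on real
  landscapes and is not corrected.
* The FE-minimum search uses the first two PCs by default; ensembles
  whose discriminating variance lies in higher components may need
  `density_pcs` raised.
* No reweighting across temperatures or Hamiltonians: combination is
  deliberately frame-count-based, and maps from different protocols are
  comparable only as sampling densities, not as rigorous free energies.
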