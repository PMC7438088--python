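# Methods

## Osmotic volume model

The cell is treated as a sphere whose volume changes only by water flux
across the membrane, driven by the osmotic pressure difference between
cytoplasm and bath (mixture-theory Kedem–Katchalsky form restricted to a
nonpermeating solute):

    dV/dt = A·L_p·Rθ·(c_i − c_e),   A = 3V/a,   c_i = n_i/(φ_i V),
    φ_i = 1 − (1 − φ_ir)·V_r/V,     dn_i/dt = 0.

Assumptions: the solute (NaCl) does not cross the membrane at room
temperature and the cell mounts no active volume recovery on the 5-minute
timescale; the osmotically inactive volume `(1 − φ_ir)·V_r` is carried
along unchanged; the cell stays spherical so its projected radius
determines its volume.  One osmolarity unit is taken as
1 mOsm/liter ≡ 1 mol/m³, `R = 8.314 J/(mol·K)`, and the default
temperature is 295.15 K (room temperature); both are configurable on
`ModelConstants`.

Internally the solver uses the dimensionless form `v = V/V_r`:

    dv/dt = (3 L_p Rθ / a_r) · v^{2/3} · (c_er φ_ir/(v − 1 + φ_ir) − c_e),

a single scalar ODE integrated with LSODA at relative tolerance 1e-8.
A soft floor at `v = 1 − φ_ir + 1e-6` keeps the water compartment
positive if the solver momentarily overshoots the physical barrier; the
trajectory itself never reaches it because the equilibrium volume lies
strictly above.  Multi-step protocols are integrated continuously: the
solute amount and solid volume are conserved across steps, and only the
bath osmolarity changes.

### Inverse problem

Each osmotic step is fitted independently.  The reference state is the
first sample of the step; the reference osmolarity is the previous bath
(the protocol holds each level for 5 minutes, ≈ 15 relaxation times, so
the cell is equilibrated at step boundaries).  `(L_p, φ_ir)` are
estimated by trust-region least squares on `V(t)/V_r` with L_p on a
log10 scale, bounds `L_p ∈ [1e-16, 1e-11] m³/(N·s)`, `φ_ir ∈ [0, 1]`.
φ_ir is initialized by inverting the equilibrium relation on the trace
plateau (mean of the final 30 s); a 13-point coarse sweep over log L_p at
that φ_ir selects the basin before joint refinement.  Residuals are
evaluated on volume (the cube of the measured radius), in linear space.

Quality control mirrors what an experimenter would exclude: traces whose
volume still changes by more than 5% over the final 30 s of a step
(no plateau), fits with R² < 0.8, single-frame volume jumps above 15%
(burst-like events), and estimates pinned to within 0.01 decades of an
L_p bound (no information about the rate).  All thresholds sit on
`QCConfig`.  Flagged fits still report their estimates; downstream
summaries exclude bound-pinned ones.

### Identifiability at high measurement noise

The default synthetic noise model applies 5% i.i.d. multiplicative noise
to the per-frame radius, i.e. ≈15% noise on volume.  Under the standard
protocol the hyperosmotic transient lasts ≈20 s (≈10 frames at 0.5 Hz)
with a total volume change of 17%, so the information about L_p is weak:
the Cramér–Rao bound on ln L_p at these settings is ≈0.53 per cell, and
the likelihood flattens toward large L_p (an instantaneous volume jump
fits a noisy trace nearly as well as the true transient).  Per-cell
estimates are therefore heavy-tailed at this noise level, and group means
of ~12 cells inherit that tail; the recovery tests characterize this
regime honestly rather than hide it.  At sub-percent radius noise — the
regime sub-pixel segmentation of a 45-pixel cell actually delivers — the
estimator is nearly unbiased and recovers generating values to a few
percent (see `test_small_noise_recovery_is_nearly_unbiased`).

## Hertz indentation fitting

Spherical indenter on an elastic half-space,
`F = (4/3)·E/(1−ν²)·√R_tip·δ^{3/2}`, with ν = 0.5 by default
(incompressible cell) and the tip radius taken from the curve metadata
(3 μm default in the generators).  The measured curve is modeled as a
constant pre-contact baseline plus the Hertz branch beyond an unknown
contact point.  Fitting proceeds in two stages: a 100-point grid over
candidate contact points, each solved in closed form for (baseline,
amplitude) by linear least squares, then a joint nonlinear refinement of
(contact point, baseline, log amplitude) in dimensionless coordinates
(z normalized by the scan span, force by the peak force) so the numerical
Jacobian stays well scaled.  A curve is declared non-converged when the
Hertz term explains less than 20% of the baseline-only residual variance
— the signature of a curve with no contact.  An optional `fit_fraction`
restricts the fit to shallow indentations where the half-space assumption
holds for thin samples; no bottom-effect correction is applied.

## Morphometry

Segmentation targets bright, round, well-separated cells on a flat
background: optional large-scale background subtraction (disabled by
default; the rendered fields are flat), Gaussian smoothing (σ = 2 px),
a global threshold, hole filling, small-object removal, optional
watershed splitting of touching objects, and border clearing.  The
default threshold is the midpoint between the background level (median)
and the object plateau (99.9th percentile): for a symmetric edge profile
this crosses the true boundary, keeping the radius bias below ~0.3 px
across radii 10–60 px, where Otsu inflates small objects by up to a
pixel.  A frame whose foreground–background contrast is below 10 robust
SDs is declared empty.

Perimeter is measured on the sub-pixel marching-squares contour smoothed
by a 5-point circular moving average before taking arc length; this
removes the staircase bias that makes chain-code perimeters overestimate
disks by ~4%.  With it, rasterized disks score circularity 0.99–1.0 and
an 80-px square lands within ~2.5% of the analytic π/4.  The smoothing
rounds corners, so very small polygons (side < ~40 px) bias high.

Tracking is nearest-centroid greedy linking with a 10 px/frame
displacement gate — adequate because cells in the osmotic assay are
attached and near-stationary.  Aspect ratio is the major/minor axis ratio
of the best-fit ellipse.  Gating removes objects outside a configurable
area window (defaults 50–700 μm², sized for ~9 μm cells), elongated
objects (aspect > 2), and — when the columns are present — out-of-focus
cells by a variance-of-Laplacian sharpness floor and intensity-clipped
cells.  The colocalization similarity score is `ln((1+ρ)/(1−ρ))` of the
in-mask Pearson correlation, with ρ clipped at ±(1 − 1e-7) so identical
channels return a large finite maximum; a constant channel yields an
invalid (flagged) score.

## Synthetic data

The generators emulate the study conditions rather than instrument
physics.  Treatment-group presets carry the reported means ± SD for
hyper-/hypo-osmotic L_p, isotonic radius, elastic modulus, and the
control-normalized circularity and pMLC levels; quantities with no
reported numeric value are explicit nulls that raise on use and surface
as `null (no reported value)` in reports.  φ_ir defaults to 0.6 for all
groups (no numeric group values are reported).  Populations are drawn
from truncated normals (L_p, radius, modulus > 0; φ_ir ∈ [0,1]) — the
underlying distribution family is not reported, and the truncation only
matters for high-variance groups.

Volume traces apply the radius noise per frame (CV 0.05 by default) and
cube the noisy radius.  Image fields place soft-edged disks (sigmoidal
edge, width 1.5 px) on a jittered grid that enforces non-overlap, with
background level 100 and Gaussian noise SD 5; a placement error is raised
when the requested cells cannot fit.  Shape phenotypes are polar stars
`r(θ) = a(1 + α·cos kθ)` (α = 0 gives disks; α ≥ 1 self-intersects and is
rejected) with analytic area/perimeter/circularity emitted as ground
truth.  Force curves prepend a flat baseline before the contact point and
add Gaussian force noise scaled to the peak.  Channel pairs are
correlated Gaussian fields hitting a target in-mask Pearson ρ.  What the
generators do **not** emulate: DIC/fluorescence optics, shading and
debris, cell motility, out-of-focus blur, overlapping cells, or active
volume regulation — so passing recovery tests demonstrate correctness of
the inference given the model, not robustness to every real-data
pathology.

## Statistics

Two-sample Kolmogorov–Smirnov (asymptotic p) for distribution-level
cytometry features; Student's two-tailed t test for two-group
biophysical comparisons (Welch via `equal_var=False`); one-way ANOVA
followed by Fisher's LSD (pooled within-group MSE, N − k df, uncorrected
two-tailed p) for the four-group design.  No family-wise correction
beyond LSD is applied, by design.  The KS test's discrete statistic is
conservative at small n (attained α ≈ 3.5% at n = 50); calibration holds
at the n ≈ 500 samples typical of cytometry data.  Cross-system
harmonization multiplies the second system's measurements by the ratio
of control means.  The scaling analysis regresses group means (never
per-cell values) of one metric on another by OLS and reports slope, R²
and p.

## Pipeline

A single `RunConfig` (YAML) drives `simulate → fit → report`.  Every run
writes a manifest with the config hash, seed, package version and
per-file content hashes; identical configs reproduce identical files.
Sub-seeds are derived per (group, assay) from the master seed by SHA-256,
so adding a group never perturbs another group's data.  Problem sizes
default to the study design (12 osmotic cells, 200 radius disks, 50 force
curves per group) and are configurable.  Unparseable CSV rows are skipped
with a log entry rather than aborting a run.

## Known limitations

- Per-cell L_p at 5% radius noise is weakly identified (see above);
  inference at that noise level needs either more informative protocols
  (larger steps, faster sampling) or lower measurement noise.
- The hypo-osmotic step's reference water fraction differs from the
  equilibration-state φ_ir because the reference volume is the shrunken
  cell; consumers comparing φ_ir across steps must account for this.
- The circularity perimeter is tuned for convex-ish cell-scale objects;
  shapes with sub-5-pixel features lose protrusion detail to the contour
  smoothing.
- Segmentation assumes bright objects on a darker, flat background;
  DIC-like shadow-casting appearance would need a different frontend.
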