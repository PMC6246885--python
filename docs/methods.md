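# Methods

## The quantification chain

`catransient` quantifies population calcium-imaging recordings of *Drosophila*
larval ventral-ganglion neurons responding to amino-acid withdrawal, together
with the expression-side computations used to interpret such experiments. The
chain is:

1. **Normalization.** Each cell's raw fluorescence trace F(t) is converted to
   ΔF/F = (F_t − F_0)/F_0, with F_0 the mean fluorescence over the first 10
   recorded frames (`compute_dff`, `n_baseline_frames` configurable). For
   peptide-release recordings (a GFP-tagged vesicular cargo whose fluorescence
   falls as it is released), the transform is (F_0 − F_t)/F_0 so that loss
   reads positive (`compute_release`).
2. **Responder classification.** A cell is a responder when its ΔF/F reaches
   the threshold (default 1.5) at any frame at or after the stimulus
   (withdrawal) time. The comparison is at-or-above (≥): published
   figure-legend usage of the rule is "ΔF/F ≥ 1.5", and a boundary value that
   counts is the less surprising convention; both threshold and the rule are
   configurable. Pre-stimulus frames never enter the peak, so baseline
   artifacts cannot create responders.
3. **Percent responders and topography.** Percent responders is
   100 × n_responders / n_cells, overall or per group. Topography maps calls
   onto the 12 hemisegments (segments T3–A5 × left/right), producing per-prep
   percentages and an across-prep mean ± SEM (SEM = sd(n−1)/√n_preps). The
   heatmap matrix is written as TSV with columns in fixed T3L…A5R order (the
   matrix2png convention), `NA` where a prep sampled no cells in a
   hemisegment.
4. **Phase-windowed AUC.** Response magnitude is the time integral of ΔF/F
   over a window, in ΔF/F·s. Default windows: full 60–600 s, initiation
   60–300 s, maintenance ("late") 300–600 s of a 600 s recording with the
   stimulus at 60 s; all are configurable. Integration is trapezoidal on the
   frame grid with linear interpolation at off-grid boundaries, so windows
   that share a grid-point boundary add exactly (AUC[a,c) = AUC[a,b) +
   AUC[b,c)). A rectangular (sum × Δt) mode exists as a cross-check, since
   spreadsheet-style summation is how such integrals are often done by hand.
   Negative excursions are never clipped. By default `phase_auc_table`
   integrates responder cells only — evoked-trace quantification pools the
   cells that crossed the threshold — with an all-cells mode for null
   conditions in which nothing responds.
5. **Group statistics.** Two-tailed Student t (pooled variance; Welch
   available), one-way fixed-effects ANOVA, and Tukey's multiple-comparison
   test, authored from the classical sums-of-squares formulas; the Tukey step
   refers q = |m_i − m_j| / √(MS_within/2 · (1/n_i + 1/n_j)) to the
   studentized-range distribution (Tukey–Kramer for unequal n). Group letter
   labels use Piepho-style insert-and-absorb: two groups share a letter if
   and only if their Tukey pair is non-significant at α (default 0.05).
   Minimal letter count is not guaranteed; assignments are deterministic
   given input order, letters lowercase a, b, c….
6. **Organism-level assays.** Pupariation is summarized per batch (nominal
   size 25, oversized batches flagged, never dropped) as percent pupariated
   within a 10-day horizon, with a cumulative rate curve at 12 h bins; the
   curve is non-decreasing by construction. The preference index is
   (n_test − n_control)/(n_test + n_control) over larvae still in the arena
   (escapers are excluded before counting); the assay convention leaves the
   formula implicit, so this symmetric index in [−1, 1] is adopted here as
   the package's convention.
7. **Expression side.** The consensus differential-expression gate filters
   three upstream engines' tables (CuffDiff2-, DESeq-, edgeR-style): a gene
   passes one method when expression is nonzero in both conditions,
   significance (q or FDR-adjusted p) is below 0.05, and the linear fold
   change shows at least a 25% change. The 25% rule is read symmetrically on
   the linear scale (up: FC ≥ 1.25, down: FC ≤ 0.75); the reciprocal reading
   (down: FC ≤ 1/1.25 = 0.8) is available via `symmetric_down=False` because
   the convention is genuinely ambiguous. Consensus sets are the
   direction-consistent triple intersections; genes significant everywhere
   but with conflicting directions are excluded and listed, and the 7-region
   Venn partition over the per-method sets is reported. qPCR fold changes use
   2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_housekeeping)_expt −
   (Ct_target − Ct_housekeeping)_control, technical duplicates averaged
   first, biological replicates paired by position with mean ± SEM.

## The synthetic-data generator

No imaging data accompany the experiments this pipeline quantifies, so every
stage is exercised against a generator with known ground truth
(`simulate_traces`, `simulate_release_traces`, `simulate_de_tables`,
`simulate_ct_table`). The calcium model is an event train convolved with a
causal difference-of-exponentials kernel K(t) = (e^(−t/τ_decay) −
e^(−t/τ_rise)) normalized to unit peak:

    F_i(t) = F0_i · (1 + Σ_k A_k K(t − t_k)) · e^(−bleach_rate·t) + ε_i(t)

- **Kernel:** τ_rise = 4 s, τ_decay = 30 s by default — multi-second
  GCaMP6m-scale transients; with 4 s frames each event spans several frames
  and overlapping events produce the multi-peaked responder traces seen in
  such recordings. Configurable.
- **Event trains:** responders (Bernoulli with the preset's
  `responder_prob`) receive a Poisson train at `init_event_rate` (default
  0.02 events/s) on the 240 s initiation window after the stimulus and at
  `maint_event_rate × maint_multiplier` (default 0.015 events/s × 1)
  thereafter. `maint_multiplier = 0` silences maintenance while leaving
  initiation untouched — because the kernel is causal, maintenance events
  cannot influence the initiation window, which is what makes the phase
  dissociation a clean in-silico experiment.
- **Amplitudes:** log-normal per event, median 3 ΔF/F with σ_log = 0.25, so
  >99% of single-event peaks clear the 1.5 threshold and the classified
  responder fraction tracks the generative probability. A responder can
  still be missed if its Poisson train is empty (probability e^(−λ) ≈ 2×10⁻⁴
  at the default rates); this is a property of the model, not a bug.
- **Baseline and noise:** per-cell baselines are log-normal (median 100 AU,
  σ_log = 0.25); noise is Gaussian with SD = `noise_sd` × baseline (default
  0.05). At that level a noise-only 200-cell run crosses the 1.5 threshold
  with probability far below 10⁻³ (a ≥ 30σ event per frame), which is why
  the mock-withdrawal condition classifies 0% responders by construction.
- **Geometry:** the frame grid includes the endpoint (600 s at 4 s → 151
  frames), so the 300 s phase boundary is a grid point and window additivity
  is exact. Segment/hemisegment labels are uniform at random by default
  (responding cells showed no anatomical bias), with an optional
  12-probability vector for testing topography code. Preparations are
  assigned round-robin.
- **Presets:** mock (responder_prob 0), eaa-withdrawal (0.5),
  arginine-withdrawal (0.42), eaa-minus-arginine (0.27), control (1.0) and
  maintenance-block (1.0 with maint_multiplier 0). The probabilities encode
  reported responder fractions; rates, amplitudes and noise are the package's
  calibration choices, fixed once, since the source experiments do not state
  transient kinetics or event counts.
- **Seeds are mandatory**; identical config + seed reproduces every dataset
  bit for bit. An unseeded config is an error, not a warning.

Release traces decline monotonically toward F0·(1 − drop_magnitude) with a
configurable time constant (default 120 s); DE tables plant down/up genes at
stated fold changes among near-unity nulls, with per-method misses available
both stochastically (`sig_jitter`) and deterministically (`miss`); Ct tables
shift the experimental target Ct by −log₂(fold) so the expected 2^−ΔΔCt is
the planted fold exactly.

**What the generator does not emulate:** shot noise and photon statistics,
bleaching interacting with motion, spatially correlated noise across ROIs,
cell-to-cell kinetic heterogeneity, and any anatomical structure in responder
placement. Passing tests therefore demonstrate that the quantification chain
is correct on data with the experiments' statistical shape — not that the
biological claims hold, which only real recordings can show.

## Numerical choices and degenerate inputs

- Uniform frame spacing is validated to 1e−6 s; ragged, missing or
  non-numeric values are schema errors naming the cell and frame. Missing
  data are never imputed.
- Baseline F0 ≤ 0 and recordings shorter than the baseline window are
  errors naming the offending cell.
- Zero-variance statistical inputs are handled explicitly: identical
  constant samples give t = 0 / F = 0 with p = 1; zero variance with unequal
  means gives p = 0, flagged `degenerate`.
- ΔF/F classification is invariant to affine rescaling of raw fluorescence
  (F → kF), verified to 1e−9 on random fixtures.
- Simulation sizes in the test suite (200–500 cells per run, 1000 replicate
  experiments of 30 cells/group for the phase-dissociation power check) were
  chosen to give the binomial and power calculations adequate resolution at
  a few seconds' runtime each.

## Known limitations

- Two-way designs (e.g., genotype × diet interactions) are out of scope;
  only one-way ANOVA and two-group t tests are provided.
- The AUC boxplot convention pools cells across preparations rather than
  averaging within preparation first; that matches the per-cell n-numbers
  such figures report, but a prep-first mode would need to be added for
  hierarchical designs.
- The DE engines themselves are not re-implemented; the consensus gate is a
  deterministic filter over their tabular outputs.
- Detrending, bleach correction, spike inference, image registration and ROI
  segmentation are upstream of this package.
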