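# Methods

`sfxkit` is a synthetic test bed for the statistics of serial
femtosecond crystallography (SFX): still-pattern simulation, Monte
Carlo merging, half-set quality metrics, scrambled-intensity validation
and difference-density readouts. This note records the models, the
parameters that matter, the numerical choices, and — importantly — what
the synthetic data do *not* emulate, hence what a green test suite does
and does not say about real beamtime data.

## Toy crystals and ground-truth structure factors

A `ToyStructure` is a list of point atoms (element, fractional
coordinates, isotropic B in Å², occupancy, optional anomalous term f''
in electrons) in a unit cell with one of six space-group settings: P1,
P2₁, C2, C222₁, P422, P42₁2. Symmetry operator lists and the
systematic-absence test are taken from gemmi; the reciprocal-space
machinery built on them is our own.

Structure factors are computed by direct summation over all symmetry
copies,

    F(hkl) = Σ_atoms occ · f(s) · exp(−B s²/4) · exp(2πi h·x),   s = 1/d,

with single-Gaussian form factors f(s) = Z·exp(−w s²). The widths w
(≈ 2–6 Å², heavier elements sharper) are a deliberate simplification:
they keep every amplitude analytically checkable by a brute-force
summation oracle while preserving the qualitative falloff of real
scattering factors. In anomalous mode an imaginary i·f'' term is added
and Friedel mates are kept separate, so |F(h)| ≠ |F(−h)| for acentric
reflections.

**ASU convention.** The unique representative of a reflection orbit is
its lexicographically greatest member under the point-group rotations,
Friedel-expanded when mates are merged. This single rule is uniform
across all six settings, trivially idempotent, and deterministic; it
replaces the per-Laue-group inequality conventions of the large
packages, which we do not need to interoperate with. Reflection
enumeration walks the index box |h_i| ≤ a_i/d_min (an exact bound),
filters on d_min ≤ d ≤ d_max inclusive at both ends, removes
systematic absences, folds to the ASU and sorts lexicographically.

## Still simulator

Each of N patterns is an independent still: a uniformly random
orientation, a per-shot scale G drawn log-normally (median
`scale_median`, log-sd `scale_sigma`, default 0.3), and a Bernoulli
subset of reflections "excited" at rate `excite_rate` (default 0.05).
Each excited reflection yields

    I = G · p · |F|² + ε_noise,   σ(I) = sqrt(a² + b·|I_true|),

with the noise floor a = `noise_floor_frac` · median|F|² (default
0.05) and b = `noise_poisson_b` (default 1), mimicking the
counting-plus-readout error budget of a pixel detector in arbitrary
intensity units.

**Partiality model.** p = exp(−z²/2) with z ~ N(0, σ_m), where σ_m
(default 1.0) is the rocking/orientation spread measured in units of
the intrinsic reflection width. σ_m = 0 gives full reflections (p = 1);
increasing σ_m pushes partialities toward 0 and widens their spread, so
half-set agreement (R_split) degrades monotonically with σ_m — the
behaviour a rocking-width knob must have. The expectation E[p] =
1/√(1+σ_m²) is analytic, which the law-of-large-numbers tests use:
merged intensities converge to E[G]·E[p]·|F|², i.e. Monte Carlo merging
is unbiased up to one global scale.

Excitation is statistical (Bernoulli thinning), not Ewald-exact: which
reflections appear on a still does not depend on the stored
orientation. The orientation is used only to place spots when patterns
are rendered to detector images (flat-panel projection of k_in + q,
Gaussian spots whose integrated ADU is gain·I, Poisson background;
defaults 110 µm pixels, 130 mm distance, 2.07 Å). This preserves
exactly the statistical structure that merging and the quality metrics
consume, at a small fraction of the cost of spot prediction; the price
is that per-image reflection counts are binomial rather than
geometry-correlated, and images are single-panel and idealized.

All randomness flows from one `seed` through `numpy.random.SeedSequence`
spawning (orientations / scales / excitation / partiality / noise are
independent child streams), so equal seeds give bit-identical data sets.

## Hit finding

The peak rule follows standard still-image practice: a candidate pixel
must exceed 400 ADU and be the maximum of its 9×9 box (background box
4); background and spread are estimated from the 32 border pixels of
the box as median and 1.4826·MAD (robust to the spot itself); the peak
is kept if local S/N ≥ 4 and at least 3 pixels, 8-connected to the
candidate, exceed background + S/N_min·spread. Peaks closer than one
box merge to the brighter. A frame is a hit when it carries strictly
more than ten peaks. The inner/outer split of the 9×9 box is not fully
pinned down by the published parameter set; the border-annulus
background is our documented choice. Autoindexing is out of scope: a
pattern is counted "indexable" by a stand-in rule (≥ 15 observations),
and indexing percentages are reported relative to hits.

## Monte Carlo merging

Observations fold to the ASU and average with *unweighted* means —
Monte Carlo philosophy, no inverse-variance weighting. σ(I) is the
sample standard deviation over √n; for n = 1 the observation's own
sigma is used (configurable, since conventions differ between
processing packages). Half sets split by *whole pattern* (a seeded
random partition; an even/odd-id parity option exists for deterministic
tests), so half-set statistics see independent shot scales and
partialities, as they must. Free flags are drawn once per unique
reflection (default 5%) and persist through scrambling and splicing.
Negative merged intensities are retained; conversion to amplitudes
happens only where amplitudes are needed, as sqrt(max(I, 0)) — a
French–Wilson treatment is deliberately out of scope.

## Quality metrics

Per shell (default: 10 shells with equal reflection counts; an
equal-reciprocal-volume scheme is available): R_split with its 1/√2
multiplicity correction, CC½ (Pearson on half-set pairs), CC* =
√(2·CC½/(1+CC½)) (undefined and reported missing for negative CC½),
⟨I/σ⟩ over *merged* reflections, the fraction with I/σ > 1,
completeness against the enumerated theoretical set, multiplicity, and
— for Friedel-separate merges — the anomalous CC as the Pearson
correlation of half-set Friedel differences. The overall row adds a
Wilson estimate of the overall B from the slope of ln⟨I⟩ against s²
(B = −2·slope); an absolute B additionally requires normalising by the
composition's Σf², for which the structure can be passed in.

CC½ significance uses t = CC½·√((n−2)/(1−CC½²)) against Student's t
with n−2 degrees of freedom, one-sided: half-set correlation is signed
by construction, so the alternative of interest is CC½ > 0. Calibration
is verified by a null simulation (type-I error within the exact
binomial band at α = 0.05). Note that CC* computed from *rounded* CC½
values can differ in the last digit from values computed on unrounded
inputs.

## Standardized R engine and validation

The full atomic refinement a structural study would run is replaced by
a deliberately minimal standardized engine: a two-parameter amplitude
scale model |F_o| ≈ k·exp(−B s²/4)·|F_c| fitted by least squares on
work reflections (closed-form k nested inside a bounded 1-D search over
B ∈ [−300, 300] Å²), reporting R = Σ||F_o|−k·w·|F_c|| / Σ|F_o| over
work and free sets, overall and per shell. It is exposed
statsmodels-style as `AmplitudeScaleModel.fit() → ScaleFitResults`
(with `summary()`), the one place in the package where a model is
genuinely fitted to data; the surrounding pipeline is not forced into
that shape. All validation logic is independent of which R engine sits
underneath and the interface allows swapping in a real refinement.

**Scrambling.** Reflections sort by descending d (ties broken
lexicographically by h,k,l), form consecutive bins of 10, and the
intensity records (I, σ and half-set columns) permute within each bin;
indices, d and free flags stay put. Per-bin and global (I, σ) multisets
are conserved exactly — the resolution dependence of the intensity
statistics survives, the per-reflection assignment does not. A
*chimeric* set takes real values at d ≥ cutoff and scrambled values
beyond; the default splice ladder is 5.8, 4.6, 4.0, 3.6, 3.4, 3.2,
3.0, 2.9 Å. Whether one sorts ascending or descending is statistically
irrelevant; descending is the documented choice.

**Deviation detection.** The chimeric per-shell R_free curve is
compared with the unscrambled reference on a common shell grid; the
deviation point is the first shell from which the excess exceeds a
threshold in that shell and all finer ones. The default threshold is
0.10 (10 R-factor points): with a two-parameter engine, a corrupted
resolution range leaks a few points (measured up to ~6) into *clean*
shells by dragging the global k and B, while the scrambled shells
themselves jump by tens of points; 10 points separates the two regimes
with margin on the package's default synthetic data. With a
higher-parameter engine the leakage shrinks and the threshold can be
lowered; it is a parameter, not a constant.

**Paired resolution scan.** For each adjacent ladder pair
(d_low, d_high) the engine is fitted at both cutoffs and both fits are
evaluated on the common d ≥ d_low set; ΔR_free > tolerance (default
0.0, i.e. "inclusion must not worsen R_free" — a definition made here,
since published practice reads the curves qualitatively) marks the finer
cutoff as not helping. The declared effective resolution is the finest
d_high whose inclusion passed. The same global-parameter leakage that
is a nuisance above is the *signal* here: junk high-resolution data
worsen the fit in the good region, which is exactly how junk is
detected. Rungs with fewer than 20 reflections are skipped with a
warning.

## Difference density

Maps are synthesized on a periodic grid (oversampling 3× relative to
d_min, even dimensions, aliasing guarded) by placing coefficients on
the FFT grid with Friedel completion:
ρ(x) = (1/V)·Σ F(h)·exp(−2πi h·x). Difference maps use unweighted
coefficients (|F_o| − k·e^{−Bs²/4}|F_c|)·exp(iφ_c) with (k, B) from the
scale engine — the maximum-likelihood m/D weighting of a real
refinement program is the single largest simplification in the package;
it mainly costs contrast, not peak position, on noiseless synthetic
data. Missing reflections are omitted, not filled. Maps are stored
mean-subtracted; peak heights are quoted in σ = rms units, which makes
them invariant to any global amplitude scale. Peak search takes local
extrema of both signs above a σ level and refines positions (and
heights) by per-axis 3-point quadratic interpolation; positions are
fractional. The anomalous difference Fourier uses coefficients
(|F⁺| − |F⁻|)·exp(i(φ_c − 90°)) over complete acentric Friedel pairs of
a Friedel-separate merge; as in real practice it is computed to a
conservative resolution cutoff, both because the anomalous signal is
weak and because the extreme value of a noise map grows with the number
of coefficients.

The density-vs-cutoff profile recomputes the difference map for each
rung of a cutoff ladder (refitting k, B each time) and reads the
σ-height at a fixed site; with data that are informative to some d* and
noise beyond, the profile rises to d* and plateaus — the ligand
"levelling-off" readout.

## Problem sizes and determinism

The test suite and acceptance checks run on deliberately small
problems: toy cells of 15–80 Å, ~800–5300 unique reflections,
400–4000 stills, chosen so each behavioural suite completes in seconds
while keeping ≥ ~20 free reflections per shell where per-shell R_free
is interrogated. Every stochastic stage is seeded; all suites are
reproducible bit for bit.

## What passing tests do not show

The generator emulates the statistical skeleton of SFX data, not its
physics. Not modelled: Ewald-sphere-exact excitation and spot overlap,
mosaic-block and bandwidth effects, multi-panel detector geometry and
calibration error, non-isomorphism between crystals, radiation damage,
background from the carrier medium, and real refinement with thousands
of parameters. Consequently, green suites here demonstrate that the
*algorithms* (merging estimators, half-set metrics, scramble/chimera
logic, paired scans, map readouts) behave correctly under the stated
statistical model — they do not predict the absolute data quality any
real experiment will achieve.
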