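# sfxkit

Serial femtosecond crystallography (SFX) collects one still diffraction
pattern per microcrystal: every reflection is recorded *partially*, at a
random orientation, with a different per-shot scale, and the data set is
assembled by Monte Carlo merging of thousands of such observations.
Judging whether weak, low-multiplicity SFX data carry real signal — and
down to which resolution — is a statistics problem, not a refinement
problem. `sfxkit` implements that statistics end to end on synthetic
data, so every stage can be exercised and tested without beamtime:

* a **toy-crystal layer**: unit cells, six common space-group settings
  (P1, P2₁, C2, C222₁, P422, P42₁2), reciprocal-ASU mapping, reflection
  enumeration, and ground-truth structure factors by direct summation;
* a **still simulator** producing per-pattern partial intensities
  I = G·p·|F|² + noise (log-normal shot scale G, partiality p ∈ (0,1],
  Gaussian-plus-Poisson-like noise) and optional 2-D detector images;
* a **hit finder** using the standard still-image peak rule (9×9 local
  box, robust background, local S/N ≥ 4, ≥ 3 connected pixels, 400 ADU
  pixel threshold; a frame is a hit at > 10 Bragg peaks);
* a **Monte Carlo merger** with whole-pattern half-set splits and
  cross-validation (free) flags;
* **quality metrics** per resolution shell:

  R_split = 2^(−1/2) · Σ|I_A − I_B| / (½ Σ(I_A + I_B)),
  CC½ (Pearson correlation of half-set intensities),
  CC* = √(2·CC½ / (1 + CC½)),
  a one-sided Student-t significance test for CC½
  (t = CC½·√((n−2)/(1−CC½²))), ⟨I/σ⟩, completeness, multiplicity,
  anomalous CC and a Wilson-slope overall-B estimate;
* **model-based validation**: bin-wise intensity scrambling, "chimeric"
  data sets (real to a cutoff, scrambled beyond), per-shell R_free
  deviation-point detection, and a paired stepwise-resolution scan that
  declares an *effective resolution*;
* **density tools**: unweighted Fo−Fc difference maps with model
  phases, σ-level peak search, density-vs-cutoff profiling at a site,
  and anomalous difference Fouriers from Friedel-separate merges.

The audience is methods developers and students who want a small,
fully inspectable sandbox for SFX data-quality reasoning.

## Worked example

```python
import sfxkit as sk

structure = sk.default_toy_structure()          # ~20 atoms, C2 cell
sfs = sk.calc_structure_factors(structure, d_max=30.0, d_min=2.5)
patterns = sk.simulate_stills(sfs, sk.SimulationParams(n_patterns=1000, seed=1))
merged = sk.monte_carlo_merge(patterns, structure.cell, structure.spacegroup,
                              d_max=30.0, d_min=2.5, split_seed=1)
print(sk.summarize_shells(merged, n_shells=5, structure=structure))
print(sk.AmplitudeScaleModel(sfs, merged).fit().summary())
```

prints

```
 d_low  d_high   n  i_over_sigma  frac_i_over_sigma_gt1  multiplicity  cc_half  cc_star  r_split  completeness
28.978   4.365 157        13.363                  0.994        48.968    0.978    0.994    9.181       100.000
 4.365   3.428 157        13.490                  1.000        49.796    0.987    0.997    7.349       100.000
 3.428   2.983 157        13.141                  0.987        50.261    0.983    0.996    7.971       100.000
 2.983   2.713 157        12.012                  0.994        49.987    0.983    0.996    8.157       100.000
 2.713   2.502 158        11.980                  0.994        50.076    0.989    0.997    7.369       100.000
overall: d_low=28.98  d_high=2.502  n=786  i_over_sigma=12.8  frac_i_over_sigma_gt1=0.9936  multiplicity=49.82  cc_half=0.9822  cc_star=0.9955  r_split=8.359  completeness=100  wilson_b=21.41

Amplitude scale model (|Fo| ~ k exp(-B s^2/4) |Fc|)
  cutoff d      : None
  n_work/n_free : 749/37
  k             : 0.859572
  B overall     : 0.0087 A^2
  R_work        : 3.1 %
  R_free        : 3.1 %
```

Reading it: 1000 stills at ~50-fold multiplicity merge to a complete
set whose half-sets agree to R_split ≈ 8% with CC½ ≈ 0.98 in every
shell; scaling the merged amplitudes against the ground-truth model
leaves a 3% residual — the Monte Carlo convergence error at this
pattern count, since no measurement noise beyond partiality and shot
scale was simulated. (k < 1 because the mean partiality and shot scale
are absorbed into one linear factor; B ≈ 0 because the simulation does
not add any resolution-dependent falloff beyond the model's own.)

A command-line interface mirrors the library
(`sfxkit simulate | hitfind | merge | stats | scramble | chimera |
resolve | diffmap | peaks | profile | anomap | run`); `sfxkit run`
drives the whole pipeline from a YAML config and writes text-format
intermediates plus a run manifest. File formats are documented in
`docs/formats.md`, the science and its simplifications in
`docs/methods.md`.

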