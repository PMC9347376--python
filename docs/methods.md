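# Methods

## The measurement model

A picornavirus capsid sample is a mixture of empty procapsids
(60 × {VP0, VP1, VP3}) and full mature virions (60 × {VP1, VP2, VP3, VP4}).
On-column thermal dissociation in reverse-phase UPLC separates the virion
proteins, which are detected on a fluorescence channel (Ex 280 nm / Em
352 nm) dominated by tryptophan emission. The package models the FLR
response of each VP peak as

    area(VP) = N_inj × 60 × occ(VP) × n_Trp(VP) × k

where `N_inj` is the number of capsids injected
(`conc × injection_volume / dilution_factor`), `occ` is the fraction of
capsids containing that VP (`f` for VP0, `1 − f` for VP2/VP4, 1 for
VP1/VP3, with `f` the empty fraction), `n_Trp` the tryptophan count and `k`
the instrument response (`response_per_trp`).

Two identities follow exactly from Trp conservation across the maturation
cleavage VP0 → VP2 + VP4 (`n_Trp(VP0) = n_Trp(VP2) + n_Trp(VP4)`):

* the **total** area is independent of `f` — so one calibration standard of
  known concentration quantifies any sample, pure or mixed;
* `area(VP0)/(area(VP2)+area(VP4)) = f/(1−f)` — the area ratio *is* the
  empty:full particle ratio, without response-factor corrections.

The empty fraction is reported as `f = r/(1+r)`. This conversion is a
modeling choice of the package (it treats the area ratio as an exact
particle ratio); it is consistent with the validation data the tests use
(a ratio of ≈0.52 corresponding to 34.3% empty) but it is not an
instrument-defined quantity. A `response_correction` hook on
`empty_full_ratio` allows per-VP response factors; it defaults to identity.

## Synthetic data generator

`vpquant.synthetic` emulates the FLR channel of the validated method:

* **Peaks** are pure Gaussians at the reference retention times
  (VP4 4.354, VP1 5.682, VP2 7.122, VP0 7.579, VP3 8.846 min; two-system
  averages of the validated method), σ = 0.04 min by default. Gaussians
  admit closed-form area oracles (`A·σ·√2π`), which the integration tests
  exploit. An exponentially modified Gaussian (`peak_shape="emg"`) is
  available for tailing-robustness studies.
* **Noise** is additive white Gaussian (default SD 5 × 10⁴ signal units,
  ≲0.1% of a major peak height) plus optional linear baseline drift — the
  simplest model that exercises baseline correction. The standard-series
  generator adds optional multiplicative area noise (`area_cv`) modeling
  injection-to-injection loading variability.
* **Sampling**: 600 points/min over 11.5 min, matching the two-stage
  gradient duration of the physical method (the gradient itself is stored
  as metadata only; retention is not modeled from %B).
* **Tryptophan counts** are synthetic fixtures (VP0 5, VP1 6, VP2 5, VP3 4,
  VP4 0): the real per-VP counts are not published. They honor the two
  structural constraints the assay rests on — VP4 has no Trp (hence its
  <1% FLR contribution and its absence from default FLR traces) and Trp is
  conserved across the VP0 cleavage. `response_per_trp = 2.25e-6` area
  units per capsid-copy-Trp makes a 3.66 × 10¹² capsids/mL sample at a
  10 µL injection produce a total area of ≈7.4 × 10⁷, the magnitude of the
  validated method's area tables. Tests that need five visible peaks use a
  variant fixture with `n_Trp(VP4) = 1, n_Trp(VP0) = 6`.
* **ESI spectra**: for each neutral mass M and charge z, a Gaussian peak of
  configurable half-height width (default 0.8 m/z, alternative 1.0) at
  `(M + z·1.00728)/z`, restricted to the m/z 400–3,000 acquisition window;
  charge-state intensities follow a symmetric Gaussian envelope over the
  charge range.

What the generator does **not** emulate: retention-time drift between runs,
tailing/fronting under the default shape, co-eluting impurities (host-cell
or serum proteins), detector saturation, spray instability, isotope
structure, and adduct heterogeneity within one peak. Passing tests
therefore demonstrate the correctness of the numerics and the internal
consistency of the stoichiometric model — not robustness to every artifact
of real instruments.

## Chromatographic processing

* **Detection**: `scipy.signal.find_peaks` with a prominence threshold
  expressed as a multiple (default 10×) of a robust noise estimate — the
  median absolute successive difference scaled to an SD. Apexes are refined
  by parabolic interpolation over the three samples around the discrete
  maximum; widths at half height come from `scipy.signal.peak_widths`.
  Peak bounds are the flanking signal minima (trace edges for the
  outermost peaks).
* **Integration**: trapezoidal, above a linear baseline. `drop_line`
  (default) anchors the baseline on the median of five samples at each
  bound, resisting single noisy samples; `valley_to_valley` uses the raw
  bound samples. Negative net areas clip to zero with a warning.
* **Resolution**: the half-height form Rs = 1.18 (t₂ − t₁)/(w½,₁ + w½,₂)
  (European Pharmacopoeia convention; robust for near-Gaussian peaks). The
  USP tangent form is available via `method="tangent"` assuming Gaussian
  shape (w_tangent = 1.699 · w½). The regulatory pass criterion Rs > 2 is
  exposed as `ResolutionResult.passes_regulatory`.
* **Assignment**: each VP takes the nearest unassigned peak within a
  retention-time window (default ±0.3 min); collisions resolve by smaller
  |Δrt|, then larger area, and are logged. Absent VPs (e.g. VP0 in
  purified full capsids) are reported as `None`, not errors.
* **%RSD** uses the n−1 sample standard deviation, which reproduces the
  printed precision statistics of the validated method exactly.

## Quantification

The standard curve is unweighted ordinary least squares with a free
intercept (the back-calculation formula explicitly carries an intercept).
Results outside the fitted range are returned with an `extrapolated` flag
rather than rejected; negative back-calculated counts raise. Dilutional
linearity regresses measured particles-per-injection against the corrected
injected volume (`injection_volume / dilution_factor`) and reports the %RSD
of the back-calculated concentration across levels. The theoretical
composition of spike mixtures weights the empty fraction by capsid count
(`Σ vᵢCᵢfᵢ / Σ vᵢCᵢ`), not volume — the form under which particle
bookkeeping balances, verified against a brute-force enumeration oracle.
`process_flag` thresholds the simplified VP0/VP2 ratio (defaults 0.04 for
purification intermediates, 0.01 for drug substance).

Report rounding: retention times 3 dp, areas to integers, ratios 3 dp,
concentrations 3 significant figures — matching bench reporting precision
so reports can be diffed against records.

The injection volume is a configurable default (0.010 mL), not a property
of the method.

## Intact-mass identification

Average (not monoisotopic) masses are used throughout — appropriate for
unresolved isotope envelopes of 7–37 kDa proteins. Sequence masses come
from `pyteomics`; the five CVA21 VP masses are consumed as published
constants (37,183 / 33,231 / 29,897 / 26,546 / 7,304 Da).

**Deconvolution** is a transparent charge-ladder scorer, a deliberately
simple, inspectable alternative to maximum-entropy deconvolution. For each
candidate mass M on a grid (default step 0.5 Da) the spectrum — smoothed
with a Gaussian kernel matching the instrument peak width (default 0.8 m/z
at half height) — is sampled at the predicted ladder `(M + z·1.00728)/z`.
The score is the sum over adjacent charge pairs of the geometric mean of
the two rung intensities, multiplied by the fraction of charge states with
intensity above 1% of the spectrum maximum. Requiring *consecutive*-charge
evidence suppresses harmonic ghosts: a 2M artifact matches only every
second rung, so each of its adjacent pairs contains an empty rung and
scores ≈0. Local maxima of the score above a relative threshold (default
20% of the global maximum), refined parabolically, are reported. On
synthetic spectra the recovered masses are accurate to well under 1 Da;
degenerate cases (empty spectrum, no mass above threshold) return an empty
list.

**Adduct assignment** searches species × adduct multisets exhaustively
(myristoyl ≤ 1 at +210.36 Da; sodium ≤ 3 at +21.98 Da per H→Na
replacement, both applied to the neutral mass) and returns the assignment
minimizing (|residual|, adduct count) lexicographically. The default ±5 Da
tolerance reflects the ≤3 Da residuals observed for these proteins after
adduct assignment. A mass with no assignment within tolerance yields an
explicit no-match value, never an exception.

## Numerical and design notes

* Proton mass 1.00728 Da; water 18.015 Da (average).
* The VP0 mass-closure check asserts
  |m(VP0) − (m(VP2) + m(VP4) − 18.02)| ≤ 1 Da: the published average masses
  close to 0.02 Da once the hydrolytic water is included.
* Seeding: every stochastic routine accepts a `numpy.random.Generator` or
  derives one from `InstrumentSpec.seed`; identical inputs and seed produce
  bit-identical traces.
* Simulation sizes used by the test-suite performance checks: six-level
  calibration series, single 11.5-min traces at 600 points/min, 50-spectrum
  deconvolution sweeps, 20-replicate sensitivity comparisons. These sizes
  make the stochastic checks stable at the asserted tolerances while
  keeping the suite fast.

## Known limitations

* The FLR response model ignores tyrosine entirely; with the default
  fixture VP4 is invisible on synthetic FLR traces (its real contribution
  is <1% of VP2).
* Co-eluting peaks are not deconvolved by curve fitting; the method's peaks
  are baseline-resolved (Rs ≥ ~5.8 for the closest pair) so drop-line
  integration suffices.
* The ratio→fraction conversion assumes equimolar FLR-equivalent response
  of VP0 vs VP2+VP4 — exact under Trp conservation, approximate if other
  fluorophores contribute.
* Published chromatographic resolution values of the physical column are
  not recomputable from first principles here; only the Rs computation on
  measured peaks is provided.
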