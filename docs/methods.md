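# Methods

## The question and the measurement model

A fluorescent reporter under a nucleoid-protein-regulated promoter is
inserted at several chromosomal positions; wells are grown in a plate
reader with OD600 and fluorescence read every 5 minutes.  Two effects
make expression position-dependent: (i) gene dosage — loci near the
replication origin are present in more copies per cell when replication
rounds overlap — and (ii) genuine position effects, e.g. silencing by
H-NS, which oligomerises on AT-rich DNA.  The pipeline's job is to
separate the two.

The measurement model underlying every derived quantity: fluorescence F
accumulates at rate a·OD (synthesis proportional to biomass, with a the
per-mass promoter activity), OD grows at rate α(t)·OD, and the
concentration c = F/OD therefore balances synthesis against dilution.
In steady exponential growth c → a·gcn/α, which the synthetic-data
generator reproduces and the tests verify to < 5%.

## Plate-reader kinetics

**Blanking.**  OD is corrected by the per-timepoint mean of the
medium-only blank wells; fluorescence by the mean of the
non-fluorescent background-strain wells grown in the same medium
(matched by the `medium` field; a missing match is an error naming the
medium).  Negative net fluorescence is kept, not clipped — clipping
would bias averages near zero — and flagged.  The OD detection floor is
`max(1e-4, 3 × per-timepoint blank SD)`; blanked OD is floored there
and every series is masked (`valid_mask`) below it.

**Derivatives.**  α(t) is the slope of a centred least-squares line
through `window` points of ln OD (default 5 points = 25 min; the single
tunable of the estimator).  This is a degree-1 Savitzky–Golay filter:
exact for exponential growth (the noise-free test demands relative
error < 1e-6), noise-robust, with a one-line standard error from the
local fit residuals.  Promoter activity uses the same estimator on the
linear fluorescence scale, divided by OD.  Doubling time is ln2/α,
masked for α ≤ 0.

**Growth-rate uncertainty.**  The SE of the local slope of ln OD is
σ_OD/(OD·√Σ(t−t̄)²): at 5-min sampling with window 5 this is
0.063·σ_OD/OD per minute.  With typical plate noise σ_OD ≈ 0.002 the SE
already equals a 60-min doubling rate (0.0116/min) at OD ≈ 0.011 — near
the detection floor the growth rate is simply not measurable pointwise.
Two SEs are combined (elementwise max): the residual-based SE of each
window fit, and a deterministic noise floor using a robust global σ_OD
estimated from second differences (MAD/√6).  The residual SE alone is
unreliable at 3 degrees of freedom; the floor prevents windows whose
residuals are small by chance from claiming spurious precision.

**Landmarks.**  The growth phases are anchored at t_exp (maximum growth
rate), t_entry (first downward crossing of α_max/2 after t_exp, located
by linear interpolation) and t_stat (first sample with
α ≤ ε_α·α_max, default ε_α = 0.02 — a literal zero is never reached in
noise).  Ties break to the earliest timepoint; absent landmarks are
reported as absent with a flag, never extrapolated.  For noisy data the
α series is first smoothed with a precision-weighted moving average
(weights 1/SE², SEs stabilised by a rolling median; default window 9),
and t_exp maximises the lower confidence bound `smoothed − 3·SE` over
points whose SE is below one third of a reference rate (the maximum α
among the best-measured decile of points).  The naive argmax of noisy α
is biased upward several-fold by the low-OD estimates; the penalised
argmax keeps α_max accurate to a few percent, which matters because the
measured α_max sets τ for the dosage model.  The pure geometric
definitions (used by the worked examples) are recovered with
`smooth_window=1`.

Two landmark caveats are inherent, not implementation artifacts.
First, in a lag-logistic culture started from a deep dilution the true
maximum of α occurs while OD is still below the detection floor, and α
stays within ~1% of its maximum for hundreds of minutes; t_exp is
therefore ill-determined to tens of minutes in principle, although
α_max (the quantity used downstream) is well determined.  Second, the
half-maximum crossing slope is |dα/dt| ≈ α_max·α·OD/K ~ 3e-5 min⁻²,
so even a smoothed-α noise of 2e-4 propagates to ~6 min of timing
scatter per well; t_entry and t_stat recover to tens of minutes at
realistic noise, not to one sampling interval.  Concentrations sampled
at these landmarks are much more stable than the landmark times
themselves, because c(t) is nearly flat where α is nearly flat.

## Gene dosage and the repression index

Copy number follows `gcn(m') = 2^[(C(1−m')+D)/τ]`.  C and D have no
hidden defaults: they are required inputs (examples/params.yml ships
clearly-labelled example values C = 42 min, D = 23 min).  τ is measured
from the data — ln2 / median α_max over the wells of each
(medium, temperature) condition — rather than taken from nominal medium
labels.  The expected-concentration curve has one free scale, fitted by
least squares over all sites; sites whose first-pass
|log2(obs/expected)| exceeds 0.5 are excluded and the scale refit once,
so a strongly repressed site cannot drag the baseline down.  The
repression index log2(obs/expected) is reported with a delta-method SEM
(sem/(mean·ln2)) and flagged when it exceeds twice its SEM.  Index
*differences* between sites are anchor-independent; no multiple-testing
correction is applied because the output is an effect size, not a
p-value.

Reference-site ratios (per medium/temperature/phase stratum) use the
delta method assuming independence of site and reference wells, which
matches an independent-replicate design; SEM over replicates uses the
n−1 sample SD (reported as 0 with a flag for n = 1).

## Genome context

Coordinates are 1-based inclusive at all interfaces; BED files are
read per the BED convention (0-based half-open) and converted.  m' is
the per-replichore linear scale: distance from oriC along the
replichore containing the position, divided by that replichore's
length, so m'(oriC) = 0, m'(ter) = 1 and the scale is continuous across
the origin wrap.  If ter is not supplied it defaults to the point
diametrically opposite oriC.  AT windows start at coordinate 1, advance
by the shift, wrap on circular genomes (verified against a
doubled-sequence linear oracle) and report the window centre; ambiguous
bases are excluded from numerator and denominator, and all-ambiguous
windows are masked.  Occupancy overlap reports union coverage of the
flanked site window per track plus the distance to the nearest interval
when there is no overlap; the binned histogram assigns each feature's
midpoint to one of n equal circular bins, conserving the total count.
The equal-bin midpoint histogram is an interpretation of
"multiple sliding windows histogram" tools whose exact algorithm is not
published; it conserves counts and is trivially auditable.

## Synthetic data: what it emulates and what it does not

Growth is lag-logistic — α(t) = α_max·s(t−lag)·(1−OD/K) with a logistic
switch s of width k — solved in closed form, so sampled OD and true
α(t) carry no integrator error.  Defaults emulate the stated
experimental design: 1:10,000 dilution (od0 = 3e-4), τ = 60 min,
90 min lag, K = 0.45, 5-min sampling for 20 h, triplicates, three
blanks and three background wells, additive Gaussian measurement noise
(σ_OD = 0.002, σ_F = 20), a constant blank offset (0.04 OD) and
autofluorescence proportional to biomass.  `lag_min = 0` means no lag
(the switch is fully on from t = 0), giving the pure-exponential limit.

The reporter obeys dF/dt = a·ρ(phase)·gcn(m', τ(t))·OD with the
quasi-static copy number gcn = 2^[(C(1−m')+D)·α/ln2] (→ 1 as growth
stops) and per-site, per-phase repression factors ρ ∈ (0, 1].  The
default scenario plants a constant two-fold repression at the
terminal-region site LT and a conditional entry-phase repression at RO.
An optional growth-rate coupling (`rho_tau_coupling = 1`) deepens a
site's repression as growth slows by exactly the dilution-plus-dosage
factor, producing the growth-rate-independent concentration that a
cooperatively autorepressed terminal gene shows; it is a
phenomenological planting, not a binding-kinetics model.

Not modelled (deliberately): intrinsic expression noise, reporter
maturation and degradation (a stable fluorophore dilutes rather than
decays), replication-fork asynchrony, plate spatial effects, H-NS
binding kinetics.  Passing the recovery tests therefore shows the
estimators are correct under additive measurement noise and the stated
generative model — not that real plates are free of maturation delays
or edge effects.

## Numerical choices

Time is minutes everywhere; OD and fluorescence stay in instrument
units (no absolute calibration).  τ = ∞ is a valid dosage-model input
(gcn → 1).  Interpolation of concentration at landmark times is linear
over valid points only; absent landmarks leave table cells empty.
Simulation is bit-reproducible from the seed (numpy `default_rng`; no
implicit entropy).  Problem sizes in the tests and the acceptance
script — a 33-well plate at 241 timepoints, genomes of 50–200 kb,
1,000 random overlap instances — were chosen so each suite completes in
seconds while keeping binomial/multinomial sampling errors well inside
the asserted bounds.

## Known limitations

The repression index inherits a small tilt across m' from any error in
the measured τ (Δindex ≈ C·Δm'·Δα/ln2); with the penalised-argmax
α_max estimate this stays under ~0.05 log2 units at default noise.
Landmark *times* are reliable to tens of minutes at realistic noise
(see above); analyses that need sharper timing should raise the
sampling rate or lower the noise, not reinterpret the landmarks.  The
polygon gate includes boundary points only to within floating-point
path tolerance.  BED round-trips preserve wrap-split intervals as two
records.
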