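# Methods

`emfdose` implements a combined exposure assessment for library workers who
are exposed to two kinds of magnetic fields: continuous intermediate-
frequency fields (IF-EMF, 220 Hz–14 kHz) from electromagnetic electronic
article surveillance gates (EM-EAS gates), and strong monophasic pulsed
fields from the magnetizers/demagnetizers used to process anti-theft strips
(book check units, BCUs). Exposures are expressed relative to the ICNIRP
2010 occupational limits and then weighted by weekly working conditions
from a questionnaire.

## Guideline layer

Two occupational limits are implemented over 25 Hz–10 MHz:

- reference level (RL), magnetic flux density:
  1000 μT below 300 Hz, 3×10⁵/f μT to 3 kHz, 100 μT above;
- basic restriction (BR), induced internal electric field:
  0.8 V/m rms below 3 kHz, 2.7×10⁻⁴·f V/m above.

Band boundaries belong to the lower-frequency band. The RL is continuous at
both edges, so only the BR at exactly 3 kHz needs the convention; 0.8 V/m
is used because every sub-3 kHz source here is assessed against 0.8 V/m.
For pulses the BR is converted from rms to a peak limit by ×√2, so the
computed peak induced field of a pulse can be compared directly. The
domain is deliberately restricted to the bands the devices occupy; no
extrapolation below 25 Hz is offered.

## Device registry

Eight gate types and nine BCU types are shipped as versioned TSV files.
Each gate carries its operating frequency, the 45-point spatial average of
its magnetic flux density (B_IEC, per the IEC 62369-1 grid), and an
internal-field constant. Only the reference gate (gate II: 14 kHz, 111 μT)
has a directly computed 99th-percentile induced field (0.88 V/m, from
voxel-model dosimetry, taken as a registry constant and never recomputed);
every other gate's constant is scaled linearly in frequency and B_IEC:

    E = E_ref · (f / f_ref) · (B_IEC / B_IEC_ref)

This assumes the gates' near-field spatial distributions are similar, which
is reasonable for coils of comparable geometry and is the same assumption
used to justify the substitutions: unmeasured gates III/VI take the field
of the representative model at their frequency (gates I/IV), and
unidentified gates ("other", "don't remember") take gate I's parameters,
gate I being the dominant installed model. Substitutions are always
recorded in `substituted_from` and surface as `substituted_device` flags in
profiles.

BCUs carry the measured pulse peak, FWHM, |dB/dt|peak and a peak induced
field that is *calculated* (BCUs I and V, 0.038 and 0.054 V/m),
*rough-estimated* (BCU VIII, 0.015 V/m, see below), or *substituted* (the
rest take BCU I's value). The registry also stores the printed pulse-field
column (`b_iec_pulse_ut`) verbatim for completeness; it plays no role in
any ratio.

## Pulse characterization

A monophasic pulse is summarized by its peak |B|, its FWHM (half-maximum
crossings located by linear interpolation between bracketing samples; a
valid pulse must have exactly two) and its peak |dB/dt| (central
differences, one-sided at the ends). Traces must be near-uniformly sampled
(max/min step ratio < 1.01) with at least three samples; internal units are
SI (s, T), with μT conversion at the I/O boundary.

By Faraday's law the induced field tracks dB/dt, so each fully
characterized device defines a proportionality constant
k = Ein_peak / |dB/dt|peak (0.12 and 0.07 V·s/(T·m) for BCUs I and V).
For a device whose field map is unknown but whose |dB/dt|peak was measured,
the peak induced field is estimated as mean(k) × |dB/dt|peak — the
unweighted mean of however many calculated constants exist (two here,
mean 0.095), giving 0.015 V/m for BCU VIII. Demagnetization pulse trains
are not modelled separately: their largest pulse matches the magnetizing
pulse, so the exposure ratio is the same.

## Short-term ratios E1–E3

- **E1** (seated, whole body, % RL): the field at seat distance r (cm) is
  extrapolated from B_IEC with the empirical decay law
  B(r) = B_IEC · 7.84×10⁴ · r^(−2.89), valid for r > 50 cm. Seats reported
  closer than 50 cm are clamped to 50 cm and flagged `distance_clamped`;
  the decay fit is not trusted nearer the coil.
- **E2** (gate pass, % BR): the scaled internal field over the rms BR at
  the gate's frequency.
- **E3** (BCU operation, % peak BR): the device's peak induced field over
  the √2-converted BR in the band of the pulse's spectral peak. That peak
  is ~200 Hz; the choice is configurable but inert, because the BR is flat
  below 3 kHz.

Ratios from simultaneous sources are additive. Reporting precision is two
significant figures (half-up), matching occupational-hygiene practice; all
downstream arithmetic uses unrounded values.

## Weekly dose indices D1–D3

D1 = E1 × hours in seat per week; D2 = E2 × gate-pass category weight;
D3 = E3 × BCU-operation category weight. The weekly frequencies are
ordinal questionnaire categories (gate passes: 0, 1–10, 11–20, 21–25,
26–30, >30 → categories 0–5; BCU operations: 0–20, 21–50, 51–100, 101–299,
≥300 → categories 1–5; the printed bin labels overlap at their shared
endpoints, resolved here as left-closed integer bins). The default weight
is the ordinal category index itself. This is a reconstruction — only the
categories are published — and a `midpoint` scheme using representative
weekly counts per bin is available behind a configuration switch. Time per
pass/operation is deliberately ignored: the indices count repetitions.
Summaries report median, mean, sample SD (n−1), max and min per exposure
pattern and for the pooled patterns 1–3; an index undefined for a group is
reported absent, never zero.

Group contrasts use the two-sided Mann-Whitney U test (exact null
distribution when the smaller group has ≤8 observations and no ties,
otherwise the tie-corrected normal approximation with continuity
correction), delegated to `scipy.stats.mannwhitneyu` and cross-checked in
the test suite against full enumeration.

## Cohort processing

Cleaning drops blank responses (neither screening question answered) and
records whose weekly seat time exceeds a plausibility ceiling, default
80 h/week: the ceiling must lie between the top retained answer bin
(50–60 h) and the one observed implausible value (87 h), and 80 h is a
round full-overtime bound inside that interval; it is configurable.

Missing gate-pass categories are filled by stratified hot-deck multiple
imputation: within strata of (sitting status × gate family), m = 5 donor
categories are drawn with replacement from the observed values; the
assigned category is the modal draw, with ties broken uniformly at random
from the tied categories. Random tie-breaking keeps the procedure
symmetric across categories, so a uniform donor pool yields uniformly
distributed imputations; any deterministic tie rule would bias the margin.
Note that modal pooling of m draws concentrates toward the majority
category for skewed donor pools — a deliberate property of producing one
pooled completion per record rather than m analysis datasets. Strata
without donors fall back to the marginal pool with a logged warning.
Observed values are never altered, and every imputation records its m
draws as provenance.

Exposure patterns: a respondent is IF-EMF exposed if they sit within 3 m
of an EM-EAS gate *or* a gate they could not identify (unidentified gates
are treated as EM, the dominant type), and pulsed-EMF exposed if they use
an EM-type BCU. Pattern 1 = both, 2 = IF only, 3 = pulsed only,
4 = neither. RFID, flapper/card-reader gates and RF or other non-EM check
units contribute no exposure.

## Synthetic cohorts

The survey's raw data are not deposited; the generator emulates its
published marginals so the full pipeline is testable. Defaults are the
published shares: 238/548 sitters; gate families 178/22/8/30 among
sitters; gate-model and BCU-model shares from the device table; seat
distances in six 50 cm bins (1.0/10.6/8.7/33.7/9.6/36.5 %); weekly seat
hours in six 10 h bins (61.1/20.2/5.8/9.1/3.4/0.5 %); gate-pass categories
(2.4/16.9/15.0/25.6/18.4/21.7 %); BCU-operation categories
(21.4/21.4/19.7/18.6/19.0 %). Printed percentages are normalized to sum to
one. Continuous values are uniform within their bin (midpoint sampling
available for deterministic tests).

Dimensions are sampled independently, with two documented exceptions:

1. **BCU type is conditional on the (sitting, gate family) cell**, using
   the published cross-tabulation. The survey shows strong association
   (86 % of EM-gate sitters use EM check units vs 39 % of non-sitters);
   full independence would put only ~20 % of respondents in the combined-
   exposure pattern instead of the observed 30.1 %.
2. **Gate II respondents sit at ≥ ~1 m** (distance bins truncated at the
   101–150 cm bin). Unconstrained independence would let the strongest
   gate appear at 50 cm seats, contradicting the published cohort maximum
   seated exposure of 15 % RL.

The gate-pass item carries a default 10 % missingness (the survey used
imputation for this item but did not report its non-response rate; 10 % is
a typical web-questionnaire item non-response, fixed once).

What the generator does *not* emulate: the true joint distribution of
distance × hours × device type (unpublished), library-level clustering,
and any respondent-level correlation beyond the two exceptions above.
Cohort-level checks on synthetic data are therefore model-tolerance
checks — e.g. the share of D1 and D2 values below 10 is asserted in the
band [0.75, 0.95] rather than at the survey's ">85 %" — and passing them
shows internal consistency of the pipeline under the published marginals,
not agreement with the unpublished microdata.

A deterministic fixture cohort reconstructs all 548 respondents from the
published cross-tabulation cell-for-cell (pattern counts 165/43/130/210,
295 EM-BCU users); gate and BCU models are apportioned by largest
remainder, and continuous fields are filled at stratified quantile
positions, so the fixture is byte-stable.

## Numerical choices and degenerate inputs

- Half-up decimal rounding everywhere a printed value is reproduced
  (Python's banker's rounding would flip several table cells).
- FWHM requires exactly two half-maximum crossings; biphasic or noisy
  multi-crossing traces are rejected rather than guessed at.
- Distance 0 or negative is an error; 0 < r < 50 cm clamps to 50 cm with a
  flag.
- Empty statistic groups yield NaN, not 0; absent sources yield `None`,
  not 0, end to end.
- All randomness (generator, imputation draws, tie-breaks) flows from one
  `numpy` `default_rng` seed; runs are bit-reproducible.

## Problem sizes

The bundled test suite runs the fixture cohort (548 records), 200
synthetic cohorts of 548 for the dose-share band, one 100 000-respondent
cohort for marginal recovery, and exhaustive U-test enumeration up to
group sizes of six — sizes chosen to make the statistical tolerances
(3σ multinomial bands, 1 % absolute marginal error) meaningful while the
whole suite stays fast on a single CPU.

## Known limitations

- The category-weight scheme for D2/D3 is a reconstruction (see above);
  absolute D values under the `midpoint` scheme differ by an order of
  magnitude and are not comparable to the default.
- E1 for seats clamped at 50 cm underestimates true close-range exposure;
  the decay law is simply not valid there.
- The internal-field scaling assumes geometrically similar gate coils; the
  registry records, but cannot correct, the substitution error for
  unidentified devices.
- Pattern classification treats unidentified gates as EM sources; if the
  true mix of "don't remember" answers leans non-EM, patterns 1/2 are
  overcounted.
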