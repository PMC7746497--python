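# Methods

## Data model and units

A chart event is one timestamped measurement of one parameter for one
hospital admission.  Values are converted to canonical units on read:
SABP mmHg, GCS integer score, RR breaths/min, HR beats/min, BT °F,
WBC ×10³/mm³.  Temperature is canonicalized to °F because both SIRS
temperature cutoffs are defined in °F; WBC is stored in thousands per mm³ so
a count of 12,000/mm³ reads 12.0 and compares directly against the SIRS
band.  Timestamps are truncated to minute resolution and are timezone-naive.

### Plausibility filtering

Values outside a per-parameter closed interval are excluded as presumed
data-entry mistakes, never imputed: SABP [20, 300] mmHg, GCS [3, 15],
RR [0, 80] /min, HR [0, 300] /min, BT [77, 110] °F, WBC [0, 200] ×10³/mm³.
These are deliberately generous physiologic envelopes — they should only
remove artifacts, not tail physiology.  All bounds are configurable; in
particular the GCS lower bound can be lowered for databases that record
scores below the clinical floor of 3.  Missing cells are simply absent
events; no carry-forward or imputation is performed anywhere.

## Criteria semantics

qSOFA comparisons are inclusive (RR ≥ 22, GCS ≤ 13, SABP ≤ 100); SIRS
comparisons are strict (BT > 100.4 or < 96.8, RR > 20, HR > 90, WBC > 12 or
< 4).  This asymmetry is encoded per criterion as an explicit predicate kind
(`at_least`, `at_most`, `greater`, `less`, `outside_band`) because
off-by-one-at-the-boundary is the classic error in re-implementations of
these screens: a value exactly at a qSOFA threshold meets the criterion, a
value exactly at a SIRS threshold does not.  The alternative SIRS
sub-criteria (PaCO₂ < 32 mmHg, >10% immature bands) are out of scope: they
have no corresponding chart parameter in this analysis.  GCS is treated as a
number; non-integer inputs are compared as-is.

Criteria sets serialize to/from plain dictionaries so thresholds can be
overridden from the pipeline config file without code changes.

## Alignment

A screening score is only defined at chart times where *every* parameter of
the set was observed, so `align` keeps exactly those (admission, time)
pairs.  The default tolerance is zero — exact minute-resolution equality —
with an optional window (e.g. 60 min) that bins timestamps into fixed
intervals anchored at 2000-01-01, because real charting is asynchronous.
Duplicate values of one parameter at one resolved time are averaged; first-
or last-wins rules were rejected as input-order-dependent.

The first-observation phase counters length-of-stay over-representation
(long stays contribute many more records).  Two restrictions are provided
and used for different analyses: `per_parameter` (earliest event of each
(admission, parameter) pair — used for per-criterion prevalence and summary
statistics, matching the convention of analysing each parameter's
first measurement) and `first_aligned` (earliest complete snapshot per
admission — used for scenario classification and correlation, the only
reading under which those are well-defined).  Ties at the identical earliest
minute are averaged (events) or broken by the lexicographically smallest
value tuple (aligned snapshots).

## Scenarios and prevalence

Scenario labels are exact-match sets ("met exactly these criteria"), not
supersets, because only exact-match labels partition the observations and
let scenario fractions sum to one.  Enumeration order is deterministic
(subset size, then lexicographic) and always includes every label, counts of
zero included, plus no-sepsis.  Percentages are rounded half-up to two
decimals via exact decimal arithmetic, matching the conventional printed
style (banker's rounding would differ at the .005 boundary).

Per-criterion prevalence is computed over all plausibility-filtered events
of that parameter; note the denominators legitimately differ per criterion
because each parameter has its own charting cadence.  No constraint ties the
per-criterion percentages together (criteria overlap freely).

## Dichotomy (correlation) analysis

Pairwise Pearson correlation is computed on simultaneous observations —
pairwise-complete by default (each pair aligned on the times where *both*
its parameters are present), with a `complete` switch restricting to times
where the whole parameter set is present.  At cohort scale (10⁴–10⁵ pairs)
statistical significance is meaningless for judging collinearity, so the
verdict is an effect-size band on |r|: negligible [0, 0.1), weak [0.1, 0.3),
moderate [0.3, 0.5), collinear [0.5, 1]; the edges are configurable and a
p-value is reported but never drives the band.  Degenerate pairs
(zero variance, <2 simultaneous observations) are marked in the report
rather than aborting it.

Summary statistics use the sample SD (n−1) and type-7 linearly interpolated
quartiles — stated explicitly because IQR endpoints differ across quantile
conventions.

Kernel density estimation uses a Gaussian kernel on an even grid spanning
the data range ± 4 bandwidths.  The default bandwidth is Silverman's
rule-of-thumb 0.9·min(sd, IQR/1.34)·n^(−1/5); Scott's rule
(1.06·sd·n^(−1/5)) and a fixed bandwidth are available (the fixed form also
handles zero-variance input, where rule-based bandwidths are undefined).
Curves integrate to 1 within 1% by construction when the grid spans the
data; criterion cutoffs are attached as annotations for plotting.

## Synthetic cohort generator

The generator emulates the *structure* of ICU charting, not its physiology.
Per admission: a lognormal stay length (median 48 h, log-SD 0.6, capped at
21 days — the stay distribution only matters for the observation-count
imbalance that the first-observation phase is designed to stress); a latent
6-dimensional standard normal series on an hourly grid with a configurable
correlation matrix (repaired by eigenvalue clipping if mildly non-PSD,
rejected if the repair moves any entry by more than 0.05); each parameter
observes the latent series on its own cadence (SABP/RR/HR hourly, GCS and BT
4-hourly, WBC 12-hourly) through its marginal's inverse CDF — a Gaussian
copula.  Simultaneous observations thus carry the latent correlation, while
marginals are matched by construction.

Defaults are chosen to emulate a screened ICU cohort: marginals
SABP ~ N(116.4, 24.78²), GCS ~ N(11.17, 3.66²) binned to integers 3–15,
RR ~ N(21.07, 6.52²), HR ~ N(89.1, 18.61²), BT ~ N(98.37, 1.57²) and
WBC lognormal moment-matched to mean 13.14, SD 7.30 (a right-skewed lab
value), each truncated to its plausibility interval; latent correlations
HR–RR 0.32, HR–BT 0.34, HR–WBC 0.13, RR–BT 0.11, RR–WBC 0.05, BT–WBC 0.03,
RR–GCS 0.09, GCS–SABP 0.07, RR–SABP 0.04, all other pairs 0; mortality
labels independent Bernoulli(0.2111) per admission (no outcome model).
Copula distortion of Pearson correlations is below 0.01 for these
near-Gaussian marginals (the worst case, the lognormal WBC, attenuates by
factor ≈ 0.93 at |r| ≤ 0.13), so configured latent correlations are
recovered within ±0.03 at n ≥ 50,000 simultaneous pairs.

Two marginal caveats.  GCS is hard-truncated and binned, so its realized
mean (≈10.3) sits below the configured 11.17; recovery tests compare against
the analytic binned-truncated mean (`MarginalSpec.expected_mean`).  And a
normal GCS is a deliberate simplification: real GCS distributions are
bimodal with heavy mass at 14–15, so synthetic altered-mental-status
prevalence runs higher than in real cohorts.  Passing tests therefore show
the *pipeline arithmetic* is correct under known marginals and correlations
— not that the generator reproduces any real cohort's prevalences.

Outliers are injected by replacement at a configured rate, strictly outside
the marginal bounds (one unit plus an exponential excess beyond the bound),
so the count injected must equal the count excluded by the default
plausibility filter — an end-to-end accounting invariant the tests assert.
Everything is driven by one `numpy` generator seeded from the config: equal
configs give byte-identical cohorts.

The scenario-mix generator plants labels directly: per observation it draws
a label from the mixture, then samples each parameter from its marginal
truncated to the met side of its criterion (label includes it) or the safe
side (it does not), with a small interior margin (10⁻⁶ relative) at strict
boundaries and exact integer-mass sampling for GCS.  Classification
therefore recovers the planted label with probability one — the oracle used
throughout the scenario-prevalence tests.  There are no temporal dynamics,
treatment effects or ventilation flags (a bimodal intubated/natural RR
would require a ventilation indicator and is noted as a possible extension).

## Pipeline and report

Stage order: read → canonicalize → plausibility filter → phase subsetting →
align → evaluate/classify → prevalence & dichotomy, for each of
{qSOFA, SIRS} × {entire trajectory, first observation} (either phase can be
disabled by flag; both run by default).  The report carries a filtering
ledger (read = kept + excluded, enforced), per-cell denominators (raw events
and aligned counts are both reported, since selection conventions differ
across studies), and validates against a published structural schema.  The
report contains no wall-clock timestamps, so identical inputs and
configuration give identical reports.

## Problem sizes used in the checks

Planted-mixture recovery uses 20,000 observations (binomial 3-SE bounds);
correlation recovery uses a 700-admission cohort with median 72 h stays,
giving ≈55,000 simultaneous hourly pairs and ≥4,900 pairs for the sparsest
(WBC) pairs; KDE reference checks use 10,000 standard-normal draws.  These
sizes make the sampling bounds sharp while keeping the default suite fast.

## Known limitations

* The generator matches first/second moments and pairwise correlation only;
  no autocorrelation within a stay, no drift toward deterioration, no
  admission-level heterogeneity beyond stay length.
* Real extraction pipelines face an item-ID vocabulary (many item codes per
  clinical concept); input here is assumed already mapped to the six
  parameters.
* The first-observation phase cannot disentangle intubated vs natural
  breathing in RR without a ventilation flag.
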