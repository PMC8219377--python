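# Methods

## The estimand

`famsir` quantifies familial aggregation of early-onset cancer from a linked
family/cancer registry by indirect standardization. For a set of probands
(first-diagnosed affected children in their families), relatives — siblings
and mothers — enter follow-up at the proband's diagnosis and leave at their
own qualifying diagnosis or at censoring. The standardized incidence ratio is

    SIR = O / E,    E = Σ_i Σ_j Σ_k λ_k(race, sex) · t_ijk

where `O = Σ D_ij` counts qualifying diagnoses among relatives, `t_ijk` is
person-years that relative *j* of family *i* spends in age interval *k*, and
`λ_k` is the reference incidence rate for the relative's race/ethnicity, sex
and age interval. The same machinery, started instead at a patient's own
first primary, yields the SIR of distinct second primary malignancies (SPMs).

Race/ethnicity of a family is the mother's self-identified group; children's
own codes are ignored for stratification.

## Time conventions

All events are collapsed to the middle of their calendar year, so age at any
event is exactly `event_year − birth_year` and window endpoints are whole
years. Age is stratified into seven half-open intervals
[0,1), [1,5), [5,10), [10,15), [15,20), [20,25), [25,30); an exact-integer
age belongs to the right-hand interval's left edge.

A relative's window runs from `start = age at proband diagnosis` (birth, for
siblings born later) to the earliest of: their qualifying diagnosis, a
non-qualifying cancer (see below), age at study end, or the follow-up age
ceiling (default 30, the upper edge of the last reference interval). An
in-window event must satisfy `proband_dx_year < diagnosis_year`, i.e.
`start < age_at_diagnosis ≤ end`: under the mid-year convention a relative
diagnosed in the proband's own diagnosis year was never cancer-free inside
the window, so such events (and mothers diagnosed earlier) contribute
neither person-time nor, by default, an event. The `paper_mode` flag instead
counts them through a degenerate zero-length window placed at the diagnosis
age, which reproduces conventions that count every affected mother.

Two small, known consequences of the year-resolution convention: (i) a
window capped by the age ceiling carries one final exposure year with no
matching event opportunity (relevant only to young mothers; ≈2% of maternal
expected counts here), and (ii) siblings born after the proband's diagnosis
have their age-0 event opportunity excluded by the strict inequality. Both
deflate pooled SIR estimates by well under 2% under the default conditions
and are invisible at the precision of any reported quantity.

## Qualifying events and outcome modes

Three outcome modes define which relative diagnoses count: `any_cancer`;
`same_category` (the hematologic/solid dichotomy — leukemias and lymphomas
versus the ten remaining ICCC-3 main groups — matching the proband's
category); and `same_group` (same ICCC-3 main group). In type-specific
modes a relative's non-qualifying cancer censors the window at that
diagnosis (the person is no longer at first-cancer risk); setting
`censor_at_other_cancer: false` instead follows the relative through other
cancers to their first qualifying one. Expected counts always use the rate
layer matching the mode (any / category / group).

## Second primaries and relapse adjudication

SPM follow-up covers every first-primary child patient (probands and
affected siblings; mothers are excluded), from the first primary to the
first adjudicated-distinct second primary or censoring. Because the registry
dialect records only primaries, relapses must be screened out by rule: a
second event sharing both the ICCC-3 main group and the subtype label of the
first primary is flagged as a relapse, excluded from events, and does not
end follow-up. An optional `relapse_min_gap_years` additionally flags
same-group second events closer than the gap regardless of subtype. This
rule is a deterministic stand-in for a clinician's review of diagnosis
codes; with real data its error rate is unknown, and the generator's planted
relapses (below) are constructed to be exactly recoverable by it.

The SPM enrichment analysis tabulates members with an SPM by family-risk
status (a family with two or more primary-cancer patients "exhibits familial
risk") and compares the two proportions with a pooled two-sided z-test
(Pearson chi-square without continuity correction — the uncorrected version
is what reproduces the published p-value).

## Inference

Observed counts are treated as Poisson. Below 100 observed events the 95%
interval inverts the exact Poisson tails via the chi-square identity
(`low = χ²_{α/2, 2O} / 2E`, `high = χ²_{1−α/2, 2(O+1)} / 2E`); at 100 or
more, Byar's cube-root normal approximation is used:

    low  = (O/E)·(1 − 1/(9O) − z/(3√O))³
    high = ((O+1)/E)·(1 − 1/(9(O+1)) + z/(3√(O+1)))³

The two methods agree to better than 1% everywhere above the switch point,
so the boundary choice (Byar at exactly 100) is immaterial. Cells with zero
observed events are reported with a `not_calculable` status and the exact
upper bound only.

Two SIRs sharing a reference schedule are compared conditionally: given
`n = O1 + O2`, equal SIRs make `O1 ~ Binomial(n, E1/(E1+E2))`. The exact
test sums outcome probabilities no larger than the observed one
(minimum-likelihood two-sided); the chi-square variant scores the same null
on one degree of freedom. The exact variant is conservative in the
mid-range of p (discreteness can push it ~0.05–0.09 above the chi-square
value there) but tracks it within 0.01 in the decision-relevant tail; the
chi-square variant is the default and its type-I error is calibrated to
0.05 ± 0.01 at moderate expected counts.

## The synthetic registry

The generator draws families of one mother plus 1–4 children
({1: 0.38, 2: 0.34, 3: 0.18, 4: 0.10}; mean 2.0), a five-group
race/ethnicity mixture (latino 0.45, nl_white 0.38, nl_black 0.06,
nl_api 0.09, other 0.02), child birth years uniform over the registry
period (1989–2015) and maternal age at first recorded birth uniform on
15–45. Each person-year at ages 0–29 inside the study period is a Bernoulli
trial at probability `1 − exp(−hazard)`; the baseline "any first primary"
hazard is flat at 20 per 100,000 person-years. Cancer types follow a fixed
ICCC-3 mixture (leukemias 27%, CNS tumors 17%, …) with two subtype labels
per group.

Familial dependence is a conditional multiplier: from the calendar year
after the first diagnosis in a family, surviving relatives' hazards are
multiplied by θ (default 3.32; optionally race-specific). Because relatives'
windows start exactly at that diagnosis, the true relative SIR equals θ by
construction — a clean recovery target. A mean-one gamma frailty shared
within the family (`frailty_shape`) is available as a robustness
alternative in which the marginal familial SIR is no longer θ exactly.

After a first primary, the distinct-SPM hazard is exactly φ·baseline
(default 7.27), so the true SPM SIR is φ. Planted relapses occur on top:
the total post-first-primary event hazard is `φ·baseline/(1 − relapse_rate)`
and a `relapse_rate` fraction (default 0.15) of its events copy the first
primary's group and subtype without ending the patient's distinct-SPM risk
— mirroring how the analysis treats an adjudicated relapse, and leaving φ
identifiable.

Two sampling frames exist. The population frame draws families
unconditionally and supports the closed-form event-count oracle
(`expected_event_count`, which sums person-year slots over the exact
discrete birth-year distributions, ignoring the θ feedback — valid in the
rare-disease regime). The ascertained frame retains only families that
acquire an affected child, emulating a proband-linked registry in which
every family contains a proband; ascertainment conditions only on the
proband's occurrence, so the post-diagnosis relative risk is still θ.

What the generator does not emulate: realistic type- and age-specific
incidence curves (the baseline is flat), secular trends, migration or loss
to follow-up, death as a competing risk, fathers, and multi-generation
pedigrees. Passing recovery tests therefore demonstrates correctness of the
estimator under the stated model, not robustness to those real-data
features.

## Test and verification sizes

Parameter recovery uses 150,000 ascertained families at the default
baseline: this yields roughly 300 expected relative events, so the ±10%
recovery band is a ≈3σ check rather than the ≈2σ it would be at 50,000
(the estimator's Monte-Carlo SD scales as 1/√E). Null-coverage uses 200
replicates of 2,000 ascertained families at a baseline of 200 per 100,000
so each replicate carries a moderate expected count (≈40) — small enough to
keep 200 replicates cheap, large enough that interval coverage of SIR = 1
is a meaningful ≈95% rather than trivially conservative. Calibration checks
(type-I error, exact-CI coverage) use 10,000 Monte-Carlo draws.

## Numerical and degenerate-input choices

- Proband ties on diagnosis year break on the smaller person id; under the
  mid-year convention the choice cannot change O or E.
- A relative whose window would start at or beyond its end (e.g. a mother
  older than the ceiling at proband diagnosis) is excluded and logged, as
  is anyone born after study end.
- Expected counts fail loudly (`CoverageError`) when the rate table lacks a
  touched stratum; absence is never read as zero.
- Rate tables accept a `per_100k_py` unit dialect and are converted on read.
- All exclusions are tallied into the run manifest together with the
  package version and a configuration hash; a fixed seed and configuration
  reproduce every output bit-for-bit.

## Known limitations

Calendar-year resolution makes all ages integral: analyses with genuinely
continuous dates lose sub-year information on input. Mothers contribute
follow-up only below the age ceiling, so maternal risk at older ages is out
of reach of the default reference table. The relapse rule is syntactic; the
enrichment test treats family size as fixed; and no multiple-testing
correction is applied across grid cells (each cell is reported with its own
interval).
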