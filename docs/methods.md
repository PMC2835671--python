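# Methods

## Model structure

The model is a two-arm decision tree over a 12-month horizon comparing
usual surgical practice with a computerised self-audit program for
colorectal cancer surgery, from a hospital (public and private)
perspective. Each arm first splits by surgery type — colon vs rectal,
weighted by the colon share of the casemix — and then passes through a
single chance node with seven mutually exclusive branches: the six
adverse-event categories and the no-event complement. Branch
probabilities are additive; concurrent complications are excluded from
the model by construction (none of the source case series reported
multiple concurrent complications, so there is no evidence with which to
parameterize joint events). Every adverse-event branch is costed at the
"with complications" AR-DRG average for its surgery type, the no-event
branch at the "no complications" AR-DRG. This embeds the cost of an
adverse event in the casemix class rather than micro-costing each
complication type — the standard trade-off when only aggregate national
cost collections are available — and it is the main reason the DRG cost
inputs carry wide sensitivity ranges.

The self-audit arm multiplies each event rate by (1 − r), where r is the
assumed relative reduction in adverse-event rates (base 0.50; small 0.25;
large 0.75 scenarios), and adds a per-case administration cost: the
annual software subscription amortized over the surgeon's annual caseload
plus a per-audit data-entry cost. Roll-back sums probability × cost over
the 14 leaves of each arm; the incremental saving is the usual-practice
expectation minus the audit-arm expectation and can be negative when r is
small enough that administration costs dominate. No discounting is
applied within the single-year horizon, and no health outcomes (QALYs)
are modelled — this is a cost analysis only.

## Parameters

All money is in 2009 Australian dollars; all rates are proportions.

| parameter | default | plausible range | notes |
|---|---|---|---|
| anastomotic leak | 0.044 | 0.005–0.082 | pooled from 11 Australian/NZ case series |
| wound infection | 0.056 | 0.021–0.091 | two outlier series excluded (see below) |
| DVT | 0.035 | 0.003–0.067 | |
| return to theatre | 0.075 | 0.027–0.122 | |
| respiratory | 0.055 | 0.002–0.107 | pneumonia, other infection, pulmonary embolism |
| 30-day death | 0.033 | 0.002–0.064 | see pooling note below |
| colon share | 0.687 | 0.687–0.759 | base at the lower bound, see below |
| rectal resection, complicated (G01A) | $33,277 | ±30% | national AR-DRG average |
| rectal resection, uncomplicated (G01B) | $18,094 | ±30% | |
| colon procedure, complicated (G02A) | $30,899 | ±30% | |
| colon procedure, uncomplicated (G02B) | $14,283 | ±30% | |
| audit software / year | $250 | fixed | amortized over the caseload |
| data entry / audit | $16.67 | fixed | 20 min at $50/h |
| annual caseload | 20 | scenarios 20/40/70 | typical surgeon volume |
| reduction fraction r | 0.50 | scenarios 0.25/0.75 | audit effect size |
| reduction SD (PSA) | 0.10 | config-exposed | see below |
| PSA draws | 2,000 | — | |
| national incidence | 13,076 | — | colorectal cancer, Australia 2005 |
| surgical uptake | 0.95 | — | share of incident cases operated |

### Evidence pooling

Base-case event rates are pooled from eleven published Australian and New
Zealand case series of colorectal cancer surgery. The pooling rule is
deliberately simple: the plausible range for an event is the minimum and
maximum over every reported value (a study reporting a low–high pair
contributes both endpoints), and the base-case rate is the midpoint of
that range. No meta-analytic weighting by study size is attempted — the
series differ too much in outcome definitions and casemix for a pooled
variance to be meaningful, and the one-way/probabilistic sensitivity
analyses carry the spread instead. Outliers are excluded by an explicit
per-study, per-event flag in the study table, never by an automatic rule.

Encoding the published series required four editorial choices, visible in
`src/audit_savings/data/study_series.csv`:

- Two wound-infection values are flagged as outliers: a 22.3% rate from a
  133-patient regional series (which counted both superficial and deep
  infections, more than double every other series) and an 11% rate from a
  191-patient series; both lie above the 9.1% pooled high that the
  remaining series support.
- One multi-report cohort's anastomotic-leak and pulmonary-embolism
  figures, published as 0.0–3.0% and 0–1.6% across its two reports, are
  encoded at their upper values; the zero endpoints reflect an outcome
  not observed in one sub-report rather than a plausible population rate,
  and the pooled lows (0.5% and 0.2%) come from other series.
- The pre-audit arm of a pre/post series contributes its 10.7% pneumonia
  rate to the respiratory pooling.
- 30-day deaths pool to 0.2–7.7% across the series, but the model's base
  case uses 3.3% (0.2–6.4%), the high being the largest *single-series*
  value (6.38%); the 7.7% endpoint comes from the upper end of one
  series' reported range and is dropped from the model inputs. The
  pooling module reports the full 0.2–7.7% so the discrepancy stays
  visible.

Display rounding is half-up to one decimal percent (4.35% → 4.4%);
internal computation is unrounded.

### Colon share and the death branch

The colon share's base value is 0.687, the lower bound of its 68.7–75.9%
range, not the midpoint. This choice is forced by an arithmetic
fingerprint: under the additive seven-branch structure, the one-way
sensitivity half-width for the uncomplicated colon cost equals
`w × (1 − 0.5 × Σp_i) × 0.30 × c`, and only w = 0.687 reproduces the
published SA endpoints for both uncomplicated costs simultaneously.

A 16% fraction of 30-day deaths attributed to complications is carried in
the parameter set as an optional modifier (`apply_death_attribution`):
when enabled, the audit-arm reduction on the death branch is scaled by
0.16. The base model leaves it off and reduces the full 3.3% death rate,
because the same SA fingerprint (no-event probability 0.851 =
1 − 0.5 × 0.298) requires full-rate reduction.

## Uncertainty analysis

**Elicitation.** Probability parameters get beta distributions matched by
the method of moments to the base-case mean and an SD of (high − low)/3.92
— i.e. the plausible range is read as a central 95% interval. Cost
parameters get gamma distributions (right-skewed, as episode costs are in
practice) with CV = 0.30/1.96, so the ±30% one-way band doubles as the
95% sampling interval; shape = 1/CV², scale = mean·CV². Both
constructions are exact: the analytic mean and SD of the parameterized
distribution equal their targets to 1e-9, enforced by tests. An
infeasible beta target (implied shape ≤ 0) raises an error suggesting the
range be shrunk. The audit effect size is sampled from a beta with mean r
and SD 0.10; no published estimate of its spread exists, so the SD is a
package default, config-exposed, chosen to keep the 50%-scenario interval
wide without crossing zero.

**One-way SA.** Each ranged parameter (six event rates, colon share, four
DRG costs — eleven in all) is set to its low and high with everything
else at base, and the audit-arm expected cost (or the saving) is
re-evaluated; entries are ranked by swing. The two uncomplicated surgery
costs dominate because they are weighted by the 85.1% of audited cases
with no adverse event.

**PSA.** 2,000 independent draws. All parameters are sampled
independently (no correlation structure is asserted by the evidence).
Colon share is sampled by default (beta over its range); the two audit
administration costs are held fixed by default; both behaviours are
config flags. Each parameter has its own RNG sub-stream, spawned from the
seed in a fixed documented order (six event rates, colon share, four DRG
costs, reduction, two admin costs), so adding a parameter cannot
silently reshuffle existing draws. A draw whose sampled set fails
validation — in practice, a gamma draw inverting a with/without
complications cost pair, roughly one per thousand draws — is re-sampled
with a cap of 100 retries and a logged tally. Percentile intervals use
the order-statistics linear-interpolation convention
(`numpy.percentile(..., method="linear")`), making CI endpoints
reproducible bit-for-bit given the seed.

## Extrapolation

Per-case PSA means and CI endpoints are computed once per effect-size
scenario, with administration amortized at the base caseload of 20, and
then multiplied by each caseload (1/20/40/70). They are deliberately
*not* re-amortized per caseload: the published annual figures are exact
multiples of their per-case rows, so scaling reproduces the intended
arithmetic, and it keeps mean and CI consistent across rows. The national
projection multiplies the 50%-scenario per-case mean by incidence
(13,076) × uptake (0.95).

## Synthetic data generator

`simulate_episodes` emulates the admission-level data-generating process
the aggregate inputs imply: surgery type ~ Bernoulli(colon share), at
most one adverse event per episode (categorical over the seven branches),
episode cost ~ gamma around the matching DRG cell mean with the same CV
as the PSA, so cost estimation tests exercise the right-skew assumption.
`simulate_pre_post` produces a pre/post audit comparison with a known
relative reduction. What it does **not** emulate: concurrent
complications, length-of-stay as a separate outcome, emergency/elective
strata, comorbidity or risk adjustment, and between-hospital cost
heterogeneity beyond the gamma spread. Passing recovery tests therefore
show the pipeline is internally consistent — estimators recover the
generator's truth — not that the model captures every feature of real
admission data.

## Numerical choices and problem sizes

- Money is rendered to whole dollars (half-up) in terminal output; files
  carry full precision.
- At zero reduction the saving equals the negated admin cost *exactly*:
  the saving is computed from the pre-admin leaf sums, which are
  identical float sequences in both arms when r = 0.
- Tornado ties (equal swings) keep the registry order (rates, share,
  costs); in practice swings are distinct.
- Test problem sizes: property tests run 40–150 randomized cases each;
  recovery tests use 100,000 synthetic episodes (50,000 per arm for the
  pre/post design), at which the binomial SE on the any-event rate is
  ~0.0014; the PSA consistency check uses 20 seeds × 2,000 draws. The
  full suite runs in well under a minute.
- Scenario seeds are derived from the user seed as
  `(seed × 1,000,003 + index) mod 2³¹`.

## Known limitations

- The published deterministic arm costs ($20,627 usual / $18,156 audit)
  are not exactly recoverable from the printed inputs under any single
  documented tree wiring; the structure implemented here reproduces the
  published one-way SA half-widths exactly and lands within ~2% on the
  usual arm ($20,294) and ~4% on the saving ($2,380 vs $2,471). The
  residual is reported, not absorbed by tuning.
- Hospital perspective only: costs flowing to primary and community care
  (e.g. post-discharge surgical-site infections) are excluded, so the
  savings are conservative.
- The audit effect size is an assumption, not an estimate; all results
  should be read as scenario analyses conditional on r.
- Generic complicated-DRG costing ignores severity differences between
  complication types; micro-costing would likely raise, not lower, the
  estimated savings.
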