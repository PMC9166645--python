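# Methods

This note documents the models behind `telecosim`, the assumptions they
make, the choices taken where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## The evaluation problem

A hospital offering specialist consultations can serve a patient three
ways: a physical consultation (CS) at the hospital, a teleconsultation by
videoconferencing (video TC), or a teleconsultation through a telehealth
station operated with an accompanying nurse (station TC). The two TC
routes avoid patient travel but require fixed investments — stations,
software licences, peripherals — whose profitability depends on how
intensively they are used and on who the patients are. The package
evaluates this trade-off twice: retrospectively, as a matched per-patient
cost comparison over a fixed follow-up window, and prospectively, as a
discrete-event simulation of deployment scenarios.

## Per-patient cost model (`telecosim.costs`)

The total cost of a patient's care pathway over the 298-day follow-up
window (165 days before + 133 days after the index hospital stay) is:

```
total_i = NbConsult_i · consult_fee
        + p_station · NbTC_i · nurse_fee
        + share_med · MedTransport(dist_i) + (1 − share_med) · rate_km · dist_i
        + 1{TC patient} · Equipment / N_TC
```

where `dist_i = 2 · one-way km · (NbConsult_i − NbTC_i)` — every physical
visit is a round trip; remote consultations contribute no travel. Because
the retrospective data cannot tell video TCs from station TCs at the
individual level, each TC carries the nurse accompaniment fee weighted by
the observed probability (0.2656) that a TC used a station.

`MedTransport` is a probability-weighted mix of three reimbursed transport
modes (light health vehicle, taxi, ambulance), each an
affine-with-minimum tariff `max(minimum, base + per_km · d)`. The exact
French conventional schedules and the national mode shares are not public
at the precision needed, so the defaults (VSL 13.70 + 0.93/km, taxi
2.30 + 1.35/km min 7.30, ambulance 51.30 + 2.17/km; shares
0.45/0.40/0.15) are documented placeholders approximating those
conventions; both are fully configurable.

### Equipment composition

Fixed TC infrastructure is allocated per TC patient over the observation
window (7 months, 532 TC patients):

* **amortized over 60 months** (straight line): full-station purchase
  (21,686.4) + installation (1,680) + training (1,020 per team); wallet
  (device-free) station purchase (10,200) + training;
* **monthly**: maintenance (90/station), software licence (70 per doctor);
* **annual**: consumable medical equipment (360/station, charged at
  360/12 per month);
* **one-off**: medical device kits (360 per equipped station) and
  headset/camera (110 per doctor).

Two compositional details are not pinned down by the source data and are
package decisions: the device kit is charged only to the 6 full stations
(`med_equipment_full_stations_only=True`; device-free wallets have no
devices to equip), and consumables accrue per year rather than per 200
TCs. Under this composition the default inputs price equipment at
€103.69 per TC patient, and the two standard sensitivity scenarios follow
arithmetically: free software lowers the incremental cost by
70·30·7/532 = €27.63, and doubling the depreciation period to 10 years
lowers it by (6·24,386.4 + 6·11,220)/60/2 · 7/532 = €23.43 — one-off and
monthly items are untouched by the depreciation period.

Costs are not discounted (the window is under 12 months) and all amounts
are 2020 euros; dollar figures are display-time multiplication by 1.1.

## Matched economic evaluation (`telecosim.evaluation`)

Selection into the TC group is driven by diagnosis, care unit and pathway
shape, so the group comparison uses propensity-score matching:

1. **Propensity logit**, fit by maximum likelihood: age, gender, travel
   time, median standard of living, population density, pathway type,
   ICD-10 chapter and care unit. Continuous covariates enter linearly
   (z-scored internally — the scores are invariant to affine rescaling,
   and raw euro-scale columns break the optimizer's line search);
   categoricals enter as full indicator sets with one reference level.
   Perfect separation raises an error advising covariate review rather
   than silently dropping variables.
2. **1:1 greedy nearest-neighbour matching** on the score, without
   replacement and without caliper (a caliper option exists but defaults
   off). Order and tie-breaks are deterministic: TC patients in
   descending score order, ties by smallest patient id; equidistant
   controls by smallest patient id.
3. **Balance diagnostics**: group means, two-sample t-tests (continuous) /
   two-proportion z-tests (category levels), and standardized mean
   differences (SMD). SMD is the assertable criterion in tests because
   p-values scale with n.
4. **Incremental cost** = difference of matched group mean totals, with a
   percentile bootstrap CI (1000 replications by default) resampling
   patients with replacement *within each group, unpaired* — consistent
   with resampling from the initial data set per group, and with the wide
   intervals such resampling produces.
5. **Tornado analysis**: one-at-a-time overrides of any cost input,
   re-pricing the matched sample; scenarios sorted by absolute deviation
   from the base incremental cost, which reproduces the pipeline point
   estimate bit-for-bit.

## Pathway simulation (`telecosim.des`)

A day-stepped stochastic simulation written directly in Python (the model
needs no queueing: there is no waiting-time indicator, so days are the
scheduling unit, station quotas reset daily, and within-day order is
arrival order). One day counts as 1440 minutes; the default horizon of
5 × 253 working days is 1,821,600 minutes.

* **Arrivals**: Poisson per day (default rate 89.953782), agent attributes
  resampled with replacement from a patient table.
* **Eligibility**: agents whose ICD-10 chapter or care unit never occurs
  in the TC calibration cohort always take the CS route; the scenario's
  (P_CS, P_video, P_station) triple applies to eligible agents only.
  Agents older than 80 have P_video capped at 0.3, the excess reallocated
  equally to the other two routes.
* **Service times**: triangular distributions per activity (parameters
  canonicalized by sorting, since source tables mix (min, max, mode) and
  (min, mode, max) orderings) and a shifted lognormal for station consults
  (log-mean 2.1888426, log-sd 0.57548749, shift 3.0333333 minutes; mean
  ≈ 13.57). "New" agents (probability 0.2368 × 0.8512, the patient-level
  first-TC share converted to the consultation level) draw longer
  administrative times; video consults additionally draw a doctor
  registration time with probability 0.8512. This composition of the two
  first-TC probabilities is a package decision — the source calibration is
  ambiguous about how they combine.
* **Transfers**: a station agent whose nurse is sick (probability
  0.05/teams) or whose fleet has no remaining daily slot (7 per station
  per day, load-balanced to the least-loaded station) completes a same-day
  CS instead; a video agent needs a physical follow-up within a week with
  probability 0.0672 (the video TC still completes, and a full CS is
  added). Both count as transfers.
* **Travel accounting**: per agent, travel + travel-avoided equals the
  round-trip a pure-CS pathway would have charged; avoided travel is
  credited only to completed TCs.
* **Costs**: variable costs per completed consultation via the cost model
  (CS: fee + travel; video: fee; station: fee + nurse fee, no travel).
  Fixed equipment costs are charged once per replication at
  monthly-amortized rates × horizon months (horizon_days/253 × 12) plus
  one-off items; over a 60-month horizon this equals the full five-year
  investment. Charging is usage-based — a technology with zero completed
  consultations carries no investment — because the elderly video cap can
  route agents to stations even when the configured station probability
  is zero.
* **Randomness**: independent named substreams (arrivals, pathway,
  durations, transfer, nurse sick leave, new-patient) spawned from one
  root seed per replication, so adding an indicator never perturbs
  existing draws; fixed seeds give bit-identical runs.

Resources other than stations are uncapacitated accumulators tracked in
minutes (doctor, administrative staff, nurse).

## Experiments and break-even (`telecosim.experiments`)

Experiment sweeps instantiate one scenario per probability triple on a
simplex lattice (step 0.1 → 66 scenarios by default). Sweeps use common
random numbers — the same per-replication seed in every scenario — so
scenario rankings are paired on identical agent streams.

Break-even volumes solve `fixed / (reference_cs_cost − variable_cost)`,
rounded up; per-day rates divide by working days (and stations) at
one-decimal rounding. The reference CS cost is the mean per-CS variable
cost simulated *within the same experiment* — it is population-specific
(travel dominates it), not a model constant. A non-positive margin yields
a flagged "never amortized" result rather than an exception. Stratified
break-even runs the pipeline per population stratum (urban < 20 km,
peri-urban 20–50 km, remote ≥ 50 km one-way, plus arbitrary predicates
such as nursing-home populations at a fixed 13.06 km with universal
medical transport).

## Synthetic populations (`telecosim.population`)

The real cohort is private; the generator reproduces the structure the
analyses need:

* categorical covariates drawn independently from the published marginal
  frequencies (gender, 3 pathway types, 18 ICD-10 chapters, 18 care
  units). No joint distribution is published, so none is emulated;
* TC-group selection through a logit whose default category coefficients
  are the log odds ratios implied by the published group-wise counts
  (categories never observed for TC patients get a clipped −12,
  effectively ineligible), with the intercept solved numerically to hit
  the target prevalence (424/13,626 ≈ 3.1% by default);
* age ~ Normal(61.5, 16) clipped to [18, 100]; one-way distance ~
  lognormal(median 15 km, log-sd 0.854), which gives a mean travel time of
  ≈ 24 min at the fixed 0.9 km/min conversion speed and non-empty mass in
  all three distance strata; municipal covariates Normal/Gamma around the
  published means;
* consultation counts: zero-truncated Poisson per group with means 3.53
  (TC) / 2.94 (CS), dates uniform over the 298-day window; each TC-group
  visit is remote with probability 1/(0.8512 · 3.53) ≈ 0.33 (at least one
  forced), which targets ≈ 1.17 TCs per TC patient and leaves most TC
  patients with mixed pathways.

What the generator does **not** emulate: covariate dependence (e.g.
age × care unit), geography beyond a scalar distance, seasonal consult
timing, and any within-patient correlation between covariates and
consultation counts beyond group membership. Passing tests therefore
demonstrate that the machinery recovers known structure under the stated
model, not that the real cohort's joint distribution is reproduced.

## Test and acceptance sizing

Property checks run at sizes chosen so sampling noise is small against the
asserted bands, by desk calculation before running:

* balance restoration: n = 20,000 with a 15% treated fraction (~3,000
  matched pairs). At the 3.1% cohort prevalence only ~620 pairs exist and
  each SMD carries sampling noise of ~0.06, so a max-over-32-levels
  < 0.1 check would measure noise rather than the matching machinery;
  at 3,000 pairs per-SMD noise is ~0.026;
* bootstrap coverage: 200 repetitions of a 600-patient null population
  (no selection, equal consult means, all TC-specific cost channels
  zeroed) — coverage SE ≈ 1.5%;
* the scenario sweep keeps the full 1,265-day horizon but scales the
  arrival rate to 25/day, so all 66 scenarios × 5 replications complete
  in about two minutes while every scenario still completes > 25,000
  consultations, keeping per-CS average-cost noise well inside the 2%
  volume-independence band.

## Known limitations

* Transport tariffs and mode shares are placeholder approximations.
* The simulated break-even volumes depend on the synthetic population's
  distance distribution; only their per-day conversion arithmetic is
  population-free.
* Greedy matching will not reproduce any particular matched-sample size
  from the retrospective study; its loss mechanism (424 → 404) is not
  documented and nothing here depends on it.
* The day-stepped engine cannot produce waiting-time or congestion
  indicators; station capacity is the only binding resource.
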