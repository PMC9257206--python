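# Methods

This note documents the models, conventions and design choices behind
`ricascade`, in the order data flow through the pipeline.

## Isolation indices

All barrier strengths are two-arm RI indices, `RI = 1 - 2H/(H+C)`,
mapping the heterospecific fraction of reproductive success onto
[-1, 1]. The index is invariant to rescaling both arms, so counts,
rates and proportions are interchangeable *within* one barrier; mixing
units across arms of a single call is a data-preparation error and is
guarded by the ingestion layer, not the formula. An undefined index
(C + H = 0) raises a typed error naming the barrier and direction
rather than returning a sentinel, so reports can mark barriers as "not
estimable" instead of silently propagating NaN.

Phenological isolation is the one-sided variant `1 - S/(S+U)` on the
shared/unshared proportions of the *focal* species' flowering window;
because S and U are proportions of the same window, S + U = 1 and the
index is simply the unshared fraction. The two directions of a pair
generally differ when window lengths differ.

Negative RI values (heterospecific advantage) are legal and propagate
unchanged through the cascade.

## Flowering windows

Per-individual records carry first and last flowering day;
species-level windows are the union of the closed day intervals over
individuals, at integer day-of-year resolution. Field phenology surveys
are typically scored at 4–6-day intervals, so sub-day precision would
be spurious. Sites are pooled by default; a per-site mode computes
windows within site. ISO-8601 dates are accepted and converted to
day-of-year on ingestion.

## Foraging bouts and ethological isolation

A bout is one pollinator's ordered visit sequence; consecutive visits
define transitions. For a focal species the ethological RI takes
C = focal→focal transitions and H = other→focal transitions — the
pollen arriving on focal stigmas. This orientation is the package's
convention for directed ethological isolation; only the pooled
transition table matters, so the result is invariant to how visits are
segmented into bouts.

The G-test compares pooled intra- vs interspecific transition counts
against equal expected counts with one degree of freedom, using the
uncorrected likelihood-ratio statistic `2 Σ O ln(O/E)` (zero cells
contribute zero). The equal-count null is a modelling convention for a
balanced two-species array, not a claim about relative floral
availability; no Williams/continuity correction is applied.

Per-bout constancy uses `CI = (c - e)/(c + e - 2ce)` with
`e = p² + (1-p)²`. The denominator, `c(1-e) + e(1-c)`, vanishes only at
c = e = 1 (e ≥ ½ always); that limit is defined as CI = 1, which also
covers single-species visit sequences (p ∈ {0,1}). Bouts with fewer
than two visits carry no transition information and are excluded from
aggregation; a pollinator summarised from a single bout reports SD 0.0
with an explicit n = 1 flag, following the conventional table format.

## Hand-pollination stages

Four post-pollination stages are summarised per direction (maternal ×
paternal), always intraspecific-cross arm (C) against
interspecific-cross arm (H). Self-pollinations measure compatibility,
not isolation, and are summarised separately but excluded from RI.

* style / ovary — by default the mean of per-pistil conditional
  proportions (tubes in style / tubes on stigma; tubes in ovary / tubes
  in style), which is robust to unequal pollen loads across pistils;
  pistils with a zero denominator carry no information about that
  conditional stage and are skipped. A pooled-raw-count mode is
  provided for sensitivity analysis, since assay protocols are
  sometimes reported as summed tube numbers. Neither mode is declared
  canonical.
* fruit — fruit counts per arm (a fruit is a dense, turgid capsule;
  soft hollow capsules score zero but are retained for seed-assay
  linkage).
* seed — the pooled large-embryo rate over fruits, i.e. per-fruit rates
  weighted by seeds scored (~300 seeds per fruit is the conventional
  assay size).

## The cascade

Barriers act in the fixed life-cycle order phenology, ethological,
style, ovary, fruit, seed (a custom order is available for sensitivity
analysis). The cumulative recurrence

    RI[1,i] = RI[1,i-1] + RI_i (1 - RI[1,i-1])

discounts each barrier by what earlier barriers already removed;
equivalently `1 - RI[1,i] = Π (1 - RI_j)`, so for all-non-negative
ladders the total equals `1 - Π(1 - RI_i)` exactly and is
order-invariant. A barrier with RI = 1 makes the cumulative value
exactly 1.0 (not merely ≈ 1) and absorbs the rest of the cascade. The
raw recurrence can fall below -1 when several strong
heterospecific-advantage barriers compound — more than complete
advantage is outside the index's range — so the cumulative value is
floored at -1; with realistic ladders (negative entries near zero) the
floor never engages. Absolute contributions `AC_i = RI[1,i] -
RI[1,i-1]` telescope exactly to the total.

Non-estimable barriers are skipped, not zero-filled: a zero entry would
silently understate the contribution of every later barrier.

Two totals are reported side by side, because published studies are
often ambiguous about which they used: the recurrence total (the value
the AC decomposition telescopes to) and a flowering-weighted total

    RI_total = 1 - 2 (S·Hs + U·Hu) / [(S·Hs + U·Hu) + (S·Cs + U·Cu)]

where Hs, Cs compound the per-stage heterospecific/conspecific success
proportions over the post-phenology barriers during the shared
flowering period, Hu = 0 (the partner cannot sire seed while not
flowering) and Cu = Cs (conspecific reproduction proceeds all season).
When explicit stage success proportions are unavailable, each stage's
(C, H) is recovered from its RI as ((1+RI)/2, (1-RI)/2), which
preserves the ratio H/C — the only quantity the weighted total depends
on under these conventions. For the packaged reference ladders the two
totals differ in the third decimal.

Per-barrier uncertainty comes from a nonparametric bootstrap that
resamples raw observations with replacement within arm (bouts as
wholes; pistils, flowers and scored fruits within the intraspecific and
interspecific arms separately), recomputes the full ladder per
replicate, and reports 2.5/97.5 percentile intervals. The phenological
RI is held fixed — it is a population-level window statistic, not an
exchangeable observation. B defaults to 2,000; a seed is mandatory and
results are bit-reproducible under it. Arms below five observations are
flagged unstable.

## Synthetic data

The generators emulate a single-season field campaign on a two- or
three-species system, with defaults chosen to mirror the canonical
design: ~30 flowering individuals per species, ~10 foraging bouts of
mean length 3 visits per array, ~30 pistils and ~50 flowers per
pollination arm, 300 seeds scored per fruit.

* Phenology: start day ~ rounded Normal(μ_s, σ_s), duration ~
  max(1, rounded Normal(μ_d, σ_d)) per individual.
* Foraging: a one-parameter Markov model — the next visit stays
  conspecific with probability κ + (1-κ)·abundance(current species),
  else switches. κ interpolates between abundance-random foraging
  (κ = 0, expected RI 0) and perfect constancy (κ = 1, RI = CI = 1); it
  is the simplest model reproducing both limits. Bout length is
  1 + Geometric, matching the ~3 visits/bout typical of nocturnal moth
  arrays; single-visit bouts occur and contribute no transitions.
* Crosses: stigma tube count ~ Poisson(λ) truncated ≥ 1, style ~
  Binomial(stigma, p_style), ovary ~ Binomial(style, p_ovary) — the
  anatomical nesting holds by construction; fruit ~ Bernoulli per
  flower; embryo categories (large / small / aborted / empty) ~
  Multinomial(300, ·) per fruit that set. When several directions share
  a maternal species, the intraspecific control arm is generated once
  and shared, as in a real crossing design.

All generators draw from a single `numpy` Generator seeded from the
config, so datasets are bit-identical across runs with the same seed.
The generators produce exchangeable, independent observations; real
field data have structure they do not emulate — among-year and
among-site phenology variation, pollinator individual identity across
bouts, inflorescence effects in crosses, observation gaps. Passing
parameter-recovery tests therefore validates the estimators'
arithmetic and sampling behaviour, not robustness to those field
complications.

The packaged reference dataset stores the pooled and per-pollinator
transition cells of the two choice arrays verbatim, together with the
published per-barrier RI ladder per direction. The individual visit
sequences behind the partially constant pollinator rows were never
published, so their printed CI means cannot be re-derived and are
stored for reference only; fully constant rows (all transitions
conspecific) are reconstructible up to the irrelevant split of
transitions over bouts. The published ladders contain a single
pollinia–pistil entry (pollen tubes reaching the ovary), stored under
`ovary` with no separate style value. The recurrence applied to those
printed ladders reproduces the published totals to within 0.006
(rounding of the printed per-barrier values and the study's
flowering-weighting, whose exact inputs were not published, account for
the residual); exact replication is not claimed.

## Numerical conventions

* Day arithmetic is exact integer set arithmetic; S + U = 1 holds
  exactly.
* RI, CI and G are computed in double precision; `x·ln(x)` at x = 0 is
  evaluated as 0 via `scipy.special.xlogy`.
* The AC telescoping identity and the `1 - Π(1-RI)` identity hold to
  machine precision (checked at 1e-12 over thousands of random
  ladders).
* Validation errors carry row numbers (CSV) or bout/pistil identifiers
  so field data can be corrected at the source.

## Known limitations

* Two-species arrays only; the RI index has no multi-species
  generalisation here.
* No flowering-curve modelling (per-day flower counts, skew fits) and
  no among-year phenology comparison.
* Mechanical isolation (pollinaria placement on different body parts)
  is treated qualitatively by the field protocol this package serves
  and is not quantified.
* Late postzygotic stages (germination, seedling fitness) are out of
  scope, as is geographic/ecogeographic isolation.
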