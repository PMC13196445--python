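# Methods

This note documents the statistical procedures implemented in `multimorb`,
the design of the synthetic cohort generator, and the numerical choices
made where the underlying survey methodology left the design open.

## Condition operationalization

Thirteen chronic conditions are classified from raw measurements and
self-reported provider diagnoses into ternary states (present / absent /
missing):

| condition | rule | missing when |
|---|---|---|
| hypertension | mean SBP ≥ 140 or mean DBP ≥ 90 mmHg, or self-reported treatment | both BP readings absent and no self-report |
| diabetes | fasting glucose ≥ 126 mg/dL (inclusive) or self-reported treatment | glucose absent and no self-report |
| anaemia | Hb < 13.0 g/dL (men) / < 12.0 g/dL (women), strict | Hb absent |
| CKD | eGFR < 60 mL/min/1.73 m² or uACR ≥ 30 mg/g | both axes absent |
| depression / anxiety | PHQ-9 ≥ 10 / GAD-7 ≥ 10 | score absent |
| chronic respiratory disease | self-reported asthma/COPD or COPD-PS ≥ 5 | both absent |
| heart disease, arthritis, epilepsy, cancer, sickle-cell, other mental disorder | self-reported provider diagnosis | self-report item absent |

eGFR uses the 2021 race-free CKD-EPI creatinine equation (configurable
thresholds throughout). The KDIGO chronicity requirement (≥ 3 months)
cannot be established at a single survey visit, so the classification is a
single-time-point call — exactly what a cross-sectional survey can
ascertain. The COPD-PS screening cut defaults to the instrument's
published value of 5.

Multimorbidity is the presence of ≥ 2 conditions. Missing states
contribute nothing to the count (pairwise-available convention), so a
participant with 3 present and 2 missing states counts 3; a strict
complete-case variant (`count_missing_as_absent=False`) is available. The
anaemia threshold for women follows the WHO criterion (*below*
12.0 g/dL); survey write-ups occasionally misprint this direction.

## Prevalence under cluster sampling

Crude prevalence uses complete-case denominators per condition. The 95%
CI is Wald with the half-width inflated by the square root of the design
effect: p ± z·√(p(1−p)/n)·√DEFF, DEFF = 1.5 by default (hamlet-level
clustering). Inflating the half-width — rather than literally multiplying
the CI limits by √DEFF — is the only reading that keeps the interval
centred on p and dimensionally meaningful, and it reproduces published
intervals of this form (0.552 on n = 2333 → 52.7–57.7%). At p ∈ {0, 1}
the Wald interval is undefined and the estimate degenerates to a point.

The survey sample-size formula is n_min = ⌈DEFF·z²·p₀(1−p₀)/d²⌉ with
d = p₀ × relative precision, then n_final = ⌈n_min/(1−r)⌉ for
non-response rate r. Division by (1−r) — not multiplication by (1+r) —
is the standard epidemiological inflation; 1924 participants at r = 0.15
gives 2264. Note the formula inputs p₀ = 0.23, 10% relative precision,
95% confidence and DEFF 1.5 evaluate to n_min = 1930 (1929.1 before the
ceiling); a published figure of 1924 for the same inputs presumably used a
different rounding path, so both values are surfaced in the tests rather
than reconciled.

Direct age standardization computes p_std = Σ w_s·(cases_s/denom_s) with
variance Σ w_s²·p_s(1−p_s)/denom_s, DEFF-inflated like the crude CI. The
default standard population is the analysis cohort's own age distribution
in 10-year bands (the choice of standard is configurable); with the
cohort's own weights and no differential missingness the standardized and
crude estimates coincide, which the tests exploit as an invariant.

## Logistic association models

Multimorbidity odds are modelled by binary logistic regression fitted by
Newton–Raphson / IRLS: β ← β + (XᵀWX + εI)⁻¹Xᵀ(y − p) with W = p(1−p),
ridge jitter ε = 1e−8 for near-singular information matrices, convergence
when the maximum absolute score component drops below 1e−8 (max 100
iterations). Wald intervals are exp(β ± z·SE) with SEs from the inverse
information at the optimum. Rank-deficient designs raise an error naming
the collinear columns (pivoted QR); separation is detected by divergence
(|β| > 20 or non-convergence) and flagged with a warning rather than
silently reported.

Covariates are coded against fixed reference levels: age 30–49, male sex,
highest education, normal BMI (18.5–22.9 kg/m², Asian cut-offs), normal
waist circumference (≤ 90 cm men / ≤ 80 cm women), no tobacco, no
alcohol. Model fitting is complete-case (listwise deletion) with the
fitted n reported; crude ORs come from single-covariate-group fits.
Plain ML standard errors are used — the survey design's clustering enters
the prevalence CIs via DEFF but not the regression.

## Co-occurrence networks and Louvain clustering

Nodes are conditions with marginal prevalence ≥ 5% (on their own
available denominators). Edge weights are joint prevalences — the
fraction of participants with both conditions among those with both
states observed — or Jaccard indices |A∩B|/|A∪B| on the same
pairwise-complete denominators. Edges at or below the configured
threshold are dropped; the primary analysis keeps all non-zero edges.

Density (2E/N(N−1)), global transitivity (3 × triangles / connected
triples) and diameter (longest shortest hop-path, per largest component
when disconnected) are computed on the unweighted skeleton, matching the
hop-count semantics under which a fully connected 9-node network has
36 edges, density 1.0, clustering coefficient 1.0 and diameter 1.

Modularity is the weighted Newman–Girvan form with resolution γ (default
1); self-loop weights (which appear in aggregated graphs) count once in
A_ii and twice in the degree, the convention shared by networkx and
igraph, against both of which the implementation is verified to 1e−10.
The Louvain detector is implemented in-repo: greedy local moving (each
node relocated to the neighbouring community with the largest positive
gain ΔQ ∝ w_{i,C} − γ·Σ_tot(C)·k_i/2m, ties broken toward the
lower-numbered community), then aggregation of communities into
super-nodes, repeated until the Q gain falls below 1e−9. The node visit
order, shuffled by the seed (default 20240701), is the only stochastic
element. On fixtures small enough for exhaustive search over all set
partitions (≤ 8 nodes, Bell(8) = 4140) Louvain attains the global
modularity maximum. Because Louvain is a greedy heuristic, different
implementations can legitimately settle in different local optima on
unstructured random graphs; validation therefore checks (a) that
independent libraries recompute exactly the Q we report for our
partition, and (b) exact recovery of planted structure, not equality of
heuristic optima.

Sensitivity sweeps rebuild the network over edge thresholds (0, 1%, 2%),
both weight schemes, and with rare (< 5%) conditions included, reporting
metrics, partitions, and the adjusted Rand index of each partition
against the primary analysis.

## Synthetic cohort generator

The generator emulates a community survey of ~2,333 adults ≥ 30 years.
Per participant: age from a normal (mean 50.0, SD 13.2 years) truncated
at 30; 58.1% women; education, tobacco, alcohol and anthropometric
category margins by age group matching the emulated survey's descriptive
table. Each participant carries two independent standard-normal latent
factors. Condition c is present with probability
σ(β₀c + s_c·(age−50)/10 + λ_c·F_block(c)), where s_c is the per-decade
age slope (back-derived from the survey's ≤ 50 / > 50 prevalence
contrast, e.g. 0.74 for hypertension, 0 for the rare conditions) and
λ_c = 1.2 log-odds/SD for the nine block-assigned conditions — five
cardio-metabolic (hypertension, diabetes, anaemia, heart disease, CKD) on
one factor, four others (respiratory disease, arthritis, depression,
anxiety) on the second, the four rare conditions unloaded. The loading of
1.2 yields within-block pairwise odds ratios around 2–3 — strong but
epidemiologically plausible comorbidity clustering — and was fixed once as
part of the generator design, whose purpose is to plant a cleanly
recoverable two-block truth.

Intercepts β₀c are calibrated by deterministic bisection (tolerance 1e−6,
bracket [−30, 30]) so that the expected prevalence over a fixed
10,000-draw sample of the (age, factor) mixture equals the target
(the survey's printed marginals by default); an unreachable target raises
an error naming the condition. The calibration stream is independent of
the cohort seed, so intercepts depend only on the spec.

Measurements are then drawn from truncated normals conditional on the
planted status so the threshold rules recover it exactly: e.g. cases draw
SBP in [140.5, 220], non-cases in [92, 139.4] with DBP below both its cut
and SBP − 8; CKD cases are planted via a low-eGFR or high-uACR route
(50/50) with creatinine back-computed by inverting the CKD-EPI equation.
This is deliberately not a physiological model — measurement error,
borderline values straddling cut-offs, treatment-controlled cases and
within-person variability are absent — so passing recovery tests
demonstrates pipeline correctness, not robustness to real measurement
noise.

Missingness is completely at random per measurement block: fasting
glucose 7.5%, haemoglobin 9.8%, renal panel 13.0% (creatinine and uACR
share one collection event, keeping complete-case CKD prevalence
unbiased), small per-item self-report missingness (heart disease 0.8%,
cancer 2.0%, sickle-cell 7.5%; arthritis 2%, epilepsy and other mental
disorder 1% — the last three chosen at the same order as the printed
neighbours because the source table's footnote is truncated). Thirty
percent of true hypertension/diabetes cases also carry a self-reported
treatment history, which rescues their classification when the
measurement goes missing; this induces a small (< 0.5 pp) upward shift in
the complete-case diabetes prevalence relative to the target, an analysed
and accepted consequence of emulating self-report supplementation. Real
surveys' missingness is rarely MCAR; conclusions about missing-data
behaviour beyond MCAR are out of scope.

The generated cohort is deterministic given (spec, seed), byte-identical
across runs.

## Pipeline and problem sizes

`run_pipeline` orders the stages simulate → classify → prevalence →
regression → network → sensitivity sweep, writes UTF-8 delimited text
("NA" for missing), GraphML for networks, and a JSON run log (seed,
config hash, per-stage record counts). Default analyses use the survey
scale (N = 2,333); validation tests use cohorts of 2,000–20,000
participants, 2,000 replicate cohorts for CI-coverage checks (beta-
binomial clusters of 30 at DEFF 1.5), 100 random weighted graphs for
oracle-equivalence checks, and 1,000 replicates for regression CI
coverage — sizes chosen so Monte-Carlo error is comfortably below the
tolerances being asserted.

## Known limitations

- Condition rules are single-visit operationalizations; no chronicity,
  severity staging, or medication reconciliation.
- The scalar DEFF treats clustering as exchangeable across hamlets; no
  survey weights or finite-population correction.
- Joint-prevalence networks are nearly complete by construction at survey
  prevalences, so community structure rests entirely on weight
  heterogeneity; no permutation-based edge significance testing.
- The default 5% node filter excludes anxiety at the emulated survey's
  4.5% marginal; analyses that reproduce the nine-condition network use a
  4% filter, mirroring the nine conditions the emulated survey retained.
- The generator's cross-block association is whatever the shared age
  gradient induces; no further cross-block correlation is planted, since
  no data exist to calibrate one.
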