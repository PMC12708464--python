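# Methods

## Model and assumptions

The package implements the quantitative core of the STAR (Socio-Technical
Allocation of Resources) approach for a single disease-care pathway over a
**one-year horizon** (the budget-planning period; multi-year extension and
discounting are out of scope by design).

For a baseline intervention with annual activity `n_treated`, number needed
to treat `nnt` and relative benefit score `v ∈ [0, 100]`:

- number benefiting `b = n_treated / nnt`, kept as a real number —
  flooring to whole people would introduce quantisation that the published
  tables do not exhibit;
- population health benefit `PHB = b · v`, a relative, unitless quantity.
  It is anchored to the dataset's own benchmark (the option rated 100) and
  to 0 (no benefit over current care), so PHB values are **not QALYs and
  not comparable across datasets**.

Key simplifying assumption, carried through everywhere: each intervention's
benefit is independent of the others, so pathway totals are plain sums and
improvements are valued in isolation. Interdependencies between
interventions (e.g. case finding feeding rehabilitation) are not modelled.

### Valuation protocol

`valuation` enforces the anchored-VAS structure: every final score set must
contain the benchmark at exactly 100 and all scores in [0, 100]. Real STAR
valuations emerge from facilitated discussion, which has no algorithmic
form; `consensus_scores` is a declared deterministic stand-in (per-rater
panel → median, or trimmed mean, → rescale so the maximum is exactly 100)
used by the synthetic pipeline and the sensitivity analysis. It is invariant
to rater order and monotone under rescaling; benchmark ties resolve to the
lexicographically smallest id for determinism.

### Efficiency frontier

Each intervention is a right triangle — horizontal leg at the entry height
`y0`, vertical leg at the exit cost `x1`, hypotenuse from `(x0, y0)` to
`(x1, y1)` — with cost on the x-axis and PHB on the y-axis. The frontier
orders triangles by slope `PHB/cost` descending and chains them from the
origin, which is the unique ordering (up to the tie rule) making the
cumulative curve concave, equivalently the ordering maximising the area
under the curve (the tests check this against a brute-force permutation
oracle). Conventions:

- zero-cost, positive-benefit items have INFINITE slope and sort first;
- zero-benefit, zero-cost items have slope 0 by convention;
- slope ties break by larger PHB, then id ascending;
- the baseline frontier admits only non-negative costs. Improvements with
  negative *net* cost are displayed on a separate net-cost × PHB-gain
  scatter, not inserted into the baseline frontier.

### Improvement economics

For a scenario with gross implementation cost `g ≥ 0` and offset savings
`sav ≥ 0`:

- `net_cost = g − sav` (the only place a negative cost can appear; input
  cost fields are non-negative so the sign convention is single-sourced);
- `cost_ratio = sav / g` ("saves £r for every £1 spent elsewhere in the
  pathway"); INFINITE when `g = 0 < sav`, UNDEFINED for 0/0;
- `cost_phb_ratio = net_cost / ΔPHB`, UNDEFINED when `ΔPHB = 0`.

Ranking sorts ascending by cost/PHB ratio; UNDEFINED ratios rank last
rather than erroring (published tables rank rows with unavailable cost
ratios normally, because the cost/PHB ratio is always computable there);
ties break by larger PHB gain, then ids. Ranks are exactly 1..n.

`recommend` is explicitly a stand-in for a deliberative step the source
process does not algorithmise: a greedy prefix walk of the ranking that
stops at the first scenario whose ratio is not defined and below the
threshold (default 1.0 currency/PHB) or whose inclusion would push the
running net cost over the budget cap. Because net-saving items reduce the
running total, a zero cap still admits a rank-1 saver. The greedy walk makes
no optimality claim over subsets — the tests assert cap- and order-respect,
not optimality.

UNDEFINED and INFINITE are represented as `nan` and `inf` floats; displayed
ratios are rounded **half away from zero to two decimals** (the tables'
apparent convention — a display concern only, internal values are never
rounded).

## Fixtures

`synthetic.load_fixture` returns transcriptions of the five published
ranked-improvement tables from the STAR COPD pilot (17, 13, 16, 9 and 11
ranked entries respectively; multi-scenario rows become one record per
uptake level). The tables print *net* cost and rounded ratios, not the
gross/savings decomposition, so fixture records store `net_cost` directly
and carry the printed rank, cost ratio and cost/PHB ratio as annotations;
the decomposition cannot be recovered for rows printing "N/A", "∞", exactly
1.00 or negative cost ratios, and inventing one would plant false precision.

Each row carries a `consistency_flag`: true iff the printed cost/PHB ratio
equals `round(net_cost / phb_gain, 2)`. Nine of 87 rows fail this check and
are retained verbatim but excluded from reproduction tests — two
Northamptonshire rows are inconsistent with every candidate formula, and
the rest are sub-scenarios of stacked cells where a single printed ratio
covers scenarios whose computed ratios differ in the second decimal (one of
them via an implausible printed cost of 24,405,820 that computes to 426.75
against a printed 42.07). `recommended_flag` is a best-effort reading of
the tables' highlighting, reconstructed from the accompanying narrative
(e.g. the five flagged Gloucestershire rows sum to the stated −£1.04 M per
year); no test or acceptance quantity depends on it beyond reporting that
sum. Baseline intervention lists are empty because only the improvement
tables were published in machine-readable form; `population_copd` is an
indicative round number used purely as context.

## Synthetic generator

`generate_ics` emulates the *shape* of an ICS dataset, not COPD
epidemiology: benefit scores from a Beta(2, 2) scaled to [0, 100] with
exactly one intervention forced to the 100 anchor; NNTs log-uniform on
[2, 40]; activity counts log-normal (median 1,500 treated/year); costs as
log-normal unit costs (median 200 currency units, σ = 1.2) times activity,
reproducing the hundreds-to-millions cost spread of real pathways; each
improvement has a savings component with probability 0.5 (log-normal ratio
around break-even, so net signs mix); 30% of improvements replicate across
10%/25%/50% uptake scenarios with activity and costs scaled linearly.
Every scenario's latent cost/PHB ratio is stored in
`extras["latent_cost_phb_ratio"]`, so the pipeline's ranking can be
compared with planted truth *exactly* — the pipeline is deterministic
arithmetic on the same floats. A passing planted-truth test therefore
demonstrates internal consistency of the pipeline, not validity of any
epidemiological claim; what generated data do **not** emulate includes
intervention interdependencies, uncertainty in NNTs, correlated costs, and
deliberative valuation dynamics.

All generation is driven by one integer seed through a single RNG; equal
seeds give byte-identical datasets on disk.

## Sensitivity analysis

`rank_stability` perturbs each scenario's valuation with
u ~ Uniform(−δ, +δ) on the 0–100 scale per Monte-Carlo draw: scenarios
carrying an explicit benefit score have the score shifted and clipped to
[0, 100] before PHB is recomputed; fixture scenarios that only carry a PHB
gain are scaled by `max(0, 1 + u/100)` — the same noise expressed relative
to the 100-point benchmark. Net costs are held fixed. Re-anchoring the
benchmark after perturbation is a uniform positive rescale of every PHB
gain and cannot change any rank, so it is not simulated. Reported outputs
are per-scenario mean rank and top-k retention frequency; δ = 0 reproduces
the point ranking with probability 1, and the analysis is deterministic
given its seed.

## Numerical choices

- Cumulative frontier coordinates accumulate left-to-right, so segment
  chaining and the conservation of totals are exact float identities, not
  approximate ones.
- Supplied vs computed PHB gains must agree within 0.5% (relative); net
  cost vs decomposition within 0.5 currency units.
- CSV serialization writes floats via shortest round-trip representation;
  NaN and ±inf annotations serialize as `NA` / `inf` / `-inf` (also inside
  JSON, which cannot represent them natively). Round-trips are lossless.
- Validation is pydantic-based; a generated JSON Schema for the
  single-document format ships under `star_allocate/schemas/`.

## Problem sizes

The test suite and acceptance script use small, fixed problem sizes chosen
to make brute-force oracles exact: frontier orderings are checked against
full permutation enumeration on pathways of ≤ 6 interventions (200 random
sets), planted-truth recovery uses 20 generator seeds at the default 12
interventions / 8 improvements, and stability checks use 50–1,000
Monte-Carlo draws. These sizes already cover every code path; the model
itself is linear-time in the number of scenarios and needs no scaling
machinery.

## Known limitations

- The recommended-set selector and the consensus rule are declared
  stand-ins for deliberative steps; results depending on them are
  annotations, not reproductions.
- PHB is relative: no cross-dataset league tables, no absolute health gain,
  no QALY conversion.
- One-year horizon only; prevention benefits accruing over a lifetime are
  understated by construction.
- The two internally inconsistent Northamptonshire rows are preserved
  verbatim and flagged, not reconciled; no candidate formula reproduces
  them.
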