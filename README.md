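# star-allocate

Decision-analytic modelling for the **STAR** (Socio-Technical Allocation of
Resources) approach to healthcare resource allocation: a deliberative form of
cost-effectiveness analysis in which local stakeholders value every
intervention in a disease-care pathway, the valuations are combined with
routine activity data into a *population health benefit* measure, and
candidate pathway improvements are costed and ranked by their net cost per
unit of health gained.

The package is aimed at health-economics and public-health analysts working
with Integrated Care Systems (ICSs) or similar regional commissioning bodies.
It ships the five published ranked improvement tables from the STAR COPD
pilot in English ICSs (Birmingham and Solihull, Coventry Place,
Gloucestershire, Northamptonshire, Nottingham and Nottinghamshire) as
transcribed fixtures, plus a synthetic-data generator with planted ground
truth so every pipeline stage is testable without access to real ICS data.

## The model

Each baseline intervention *i* carries annual activity *nᵢ* (people treated),
a number needed to treat *NNTᵢ*, an annual cost *cᵢ*, and a relative benefit
score *vᵢ* rated on a 0–100 visual analogue scale during a decision
conference — the option delivering the greatest individual benefit anchors
the scale at *v* = 100, and 0 means no benefit over current care. Then

```
bᵢ   = nᵢ / NNTᵢ              (number who benefit per year)
PHBᵢ = bᵢ · vᵢ                (population health benefit, relative units)
```

PHB is *not* a QALY and is not comparable across datasets. Benefits are
assumed independent across interventions, so pathway totals are sums.

**Efficiency frontier.** Each intervention is a right triangle (cost on x,
PHB on y) with slope *PHBᵢ/cᵢ*. Sorting by slope descending and chaining the
triangles from the origin gives a concave cumulative curve — the baseline
frontier. Tall, narrow triangles are more cost-effective than short, wide
ones; the goal of pathway redesign is to move the curve up and left.

**Improvement ranking.** A candidate improvement scenario *s* with gross
implementation cost *gₛ* and expected offset savings *savₛ* (from reduced
resource use elsewhere in the pathway, e.g. avoided admissions) is scored by

```
net_costₛ        = gₛ − savₛ                    (negative ⇒ net saving)
cost_ratioₛ      = savₛ / gₛ                    ("saves £r per £1 spent")
cost_phb_ratioₛ  = net_costₛ / ΔPHBₛ            (the ranking key)
```

Scenarios are ranked ascending by cost/PHB ratio (most negative first).
A greedy selector (`recommend`) walks the ranking under a budget cap and a
ratio threshold, and a Monte-Carlo analysis (`rank_stability`) reports how
stable each rank is under uniform ±δ noise on the 0–100 valuations.

## Worked example

```bash
$ star-allocate rank --fixture nottingham_nottinghamshire --output out
rank 1: targeted_screening / most optimistic scenario (cost/PHB -5.28)
selected 11 scenario(s); net cost -1392866.00; PHB gain 2308211.00
wrote out/ranking.csv
```

The rank-1 row of `out/ranking.csv` is the targeted COPD screening
programme in its most optimistic scenario: a PHB gain of 254,505 with a net
cost of −£1,344,055, i.e. a predicted saving of £5.28 for every unit of
population health benefit generated (cost/PHB ratio −5.28), with a cost
ratio of 3.80 — £3.80 saved elsewhere in the pathway per £1.00 spent. The
greedy selection (default threshold: ratio < 1) takes the eleven scenarios
whose cost per PHB unit is below £1, for a combined net saving of
£1,392,866 and a combined PHB gain of 2,308,211.

The same pipeline is available as a library:

```python
import star_allocate as sa

ds = sa.load_fixture("gloucestershire")
ranked = sa.rank_improvements(ds.improvements)
print(ranked[0].improvement_id, round(ranked[0].cost_phb_ratio, 2))
# vw_effective_use -19.09

synth = sa.generate_ics(sa.GeneratorConfig(seed=7))
frontier = sa.baseline_frontier(synth)       # concave triangle chain
```

Other subcommands: `star-allocate validate`, `generate`, `frontier`,
`sensitivity` — see `--help`. `generate --output -` and `rank --input -`
pipe a JSON dataset through stdout/stdin.

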