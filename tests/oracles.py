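"""Independent brute-force oracles used by the frontier tests.

Ordering interventions by non-increasing PHB-per-cost slope maximises the
area under the cumulative frontier path (exchange argument); the oracle
enumerates all permutations of a small item set and returns the maximal
area, against which the package's ordering is checked.
"""

import itertools
import math


def path_area(items):
    """Area under the chained-hypotenuse path for items [(phb, cost), ...]."""
    area = 0.0
    x = y = 0.0
    for phb, cost in items:
        x1, y1 = x + cost, y + phb
        area += (y + y1) / 2.0 * cost
        x, y = x1, y1
    return area


def max_area_over_permutations(items):
    return max(path_area(p) for p in itertools.permutations(items))


def is_concave_sequence(slopes):
    return all(b <= a for a, b in zip(slopes, slopes[1:]))


def random_frontier_items(rng, n):
    """Random (id, phb, cost) triples including occasional degenerate points."""
    out = []
    for i in range(n):
        kind = rng.uniform()
        phb = 0.0 if kind < 0.1 else float(rng.uniform(0, 500))
        cost = 0.0 if 0.1 <= kind < 0.2 else float(rng.uniform(0, 2000))
        out.append((f"i{i}", phb, cost))
    return out


def planted_order(dataset):
    """Latent cost/PHB ordering planted by the generator, using the same
    declared tie rule as the ranking (ratio ascending, larger PHB first,
    then ids)."""
    latent = dataset.extras["latent_cost_phb_ratio"]
    phb = {
        f"{s.improvement_id}::{s.scenario_label}": s.effective_phb_gain
        for s in dataset.improvements
    }
    return sorted(
        latent,
        key=lambda k: (latent[k], -phb[k], k.split("::")[0], k.split("::")[1]),
    )
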