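"""Detect and date LTR retrotransposons planted at known ages.

Builds a 1 Mb chromosome with 30 elements inserted 0.5, 2 and 5 Myr ago,
recovers them structurally, and dates each from the divergence of its two
LTRs via K = -3/4 ln(1 - 4 lambda/3) and T = K / (2 r) with
r = 7e-9 substitutions/site/year.
"""

import collections

import numpy as np

from paleoevo import ltrclock, ltrscan, simulate as sim

cfg = sim.SimConfig(seed=11)
rng = sim.stage_rng(cfg.seed, "example-dating")
ages = [0.5e6, 2e6, 5e6]
elements = [
    sim.simulate_ltr_element(ages[i % 3], cfg, rng=rng, element_id=f"e{i}")
    for i in range(90)
]
genome = sim.random_genome({"chr1": 2_000_000}, cfg.background_gc, rng)
sim.place_elements(genome, elements, rng, min_spacing=4000)
genome, truth = sim.insert_elements(genome, elements, cfg)

candidates = ltrscan.scan_ltr_pairs(genome)
records = ltrclock.date_elements(genome, candidates, r=cfg.r)

print(f"planted {len(elements)} elements, detected {len(candidates)}")

by_age = collections.defaultdict(list)
for cand, rec in zip(candidates, records):
    if rec.status != "ok":
        continue
    for el in elements:
        if abs(el.start - cand.element_interval[0]) < 50:
            by_age[el.age_years].append(rec.T_years)
print(f"{'planted age':>12} {'n':>4} {'mean estimate':>14}")
for age in sorted(by_age):
    est = np.array(by_age[age])
    print(f"{age / 1e6:>10.1f}My {len(est):>4} {est.mean() / 1e6:>12.2f}My")
print("the two LTRs were identical at insertion, so their divergence is a")
print("clock; with 30 elements per age the means scatter by a few percent")
print("(single young elements carry only ~2 expected mismatches per LTR)")
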