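"""Contribution-to-variance decomposition of the pooled total risk.

Which stochastic inputs drive the uncertainty? Each factor a-h shares one
rank stream across working types; the hazard index shares one normal
stream across cells. Contributions are signed, normalized squared
Spearman correlations.
"""

import minerisk as mr

records, config = mr.reference_study()
table = mr.tabulate_occurrences(records)

p, prof, specs = {}, {}, {}
for wt in mr.KEY_WORKING_TYPE_IDS:
    block = config.working_types[wt]
    p[wt] = {c: mr.occurrence_probability(table, wt, c) for c in block.behaviors}
    prof[wt] = block.profile
    specs[wt] = {c: b.hazard for c, b in block.behaviors.items()}

# 1e6 iterations: the factor signals are tiny (|rho| ~ 0.001-0.01) because
# the correction slope 0.0167 keeps F's variance minuscule next to I's.
res = mr.pooled_sensitivity(p, prof, specs, iterations=1_000_000, seed=1)
for name, c in mr.rank_sensitivities(res):
    rho = res.rank_correlations[name]
    print(f"  {name}: {c:+9.4f}%   (rho = {rho:+.5f})")

# The hazard index I dominates with a positive sign; the factors act
# negatively (higher scores shrink F, hence P, hence R).
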