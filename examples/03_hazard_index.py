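"""Build and sample the accident-hazard index I = B * C.

B grades how likely an unsafe behavior is to trigger an explosion
(0.01 - 1); C grades the severity of the loss (1 - 5). Per cell, I is
modelled as a normal distribution elicited from experts.
"""

import minerisk as mr

print("possibility grades B:", dict(mr.POSSIBILITY_GRADES))
print("severity grades C:  ", dict(mr.SEVERITY_GRADES))

# a behavior that "probably" (B=0.5) causes a fatal accident (C=4):
print("I =", mr.hazard_index(0.5, 4))

spec = mr.HazardIndexSpec("ventilation", "OIW", mean=2.0, sd=1.2)
x = mr.sample_hazard_index(spec, n=100_000, seed=0, truncation="none")
print(f"sampled I ~ N(2, 1.2): mean {x.mean():.3f}, sd {x.std(ddof=1):.3f}")

x_pos = mr.sample_hazard_index(spec, n=100_000, seed=0, truncation="resample")
print(f"resample policy: min {x_pos.min():.4f} (> 0), mean {x_pos.mean():.3f}")
# resampling the negative tail shifts the mean up by the truncation bias.
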