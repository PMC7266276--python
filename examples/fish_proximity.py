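"""3D-FISH proximity: does ATRA move the gene locus toward the telomere?

Simulates 200 nuclei per condition, pairs red/green spots, classifies cis
pairs as adjacent / intermediate / separated and tests the distance shift.
"""

from epilocus import fish3d
from epilocus.fish3d import THRESHOLDS
from epilocus.profiles import FISH_PROFILES
from epilocus.simulate import simulate_fish

pairs = {}
for name in ("LR1_untreated_fish", "LR1_ATRA_fish"):
    spots = simulate_fish(FISH_PROFILES[name], seed=50, n_nuclei=200)
    pairs[name] = fish3d.pair_spots(spots)

summary, tests = fish3d.summarize_condition(pairs, THRESHOLDS["NB4-LR1"])
print(summary.round(1).to_string(index=False))
print(tests[["condition_a", "condition_b", "p_value", "significant"]].to_string(index=False))

# Percent adjacent rises from ~37 % to ~55 % after ATRA; the Mann-Whitney
# test on raw cis distances flags the shift, consistent with a long-range
# telomere-looping (TPE-OLD) contribution to gene repression.
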