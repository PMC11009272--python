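"""Theoretical AOA:NOB abundance band from physiological traits.

Marine AOA have a higher biomass yield than NOB but a smaller per-cell carbon
quota; with ammonia and nitrite oxidation rates balanced, the expected cell
ratio is yield_ratio / quota_ratio.
"""

import nitribalance as nb

published = nb.theoretical_band(mode="published")
computed = nb.theoretical_band(mode="computed")

print(f"published band : {published.low} / {published.central} / {published.high}")
print(f"computed band  : {computed.low:.3f} / {computed.central:.3f} / {computed.high:.3f}")
print()
print("An observed AOA:NOB ratio above the band's high edge means the surveyed")
print("NOB families cannot balance the nitrite flux produced by the AOA —")
print("evidence that a nitrite oxidizer is missing from the count. The small")
print("published/computed difference comes from rounding of the trait values.")
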