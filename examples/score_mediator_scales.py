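"""Score psychosocial mediator scales from Likert item responses.

Shows plain summation, reverse keying and the handling of missing items.
"""

from actimediate import DEFAULT_SCALES, ScaleDefinition, score_scale

barriers = DEFAULT_SCALES["barriers"]  # 9 items, levels 1-4, range 9-36
print("perceived barriers, all items 'very true' (4):",
      score_scale([4] * 9, barriers).score)          # -> 36, the scale maximum

# a 5-item scale with item 1 reverse keyed: 2 becomes 1+6-2 = 5
demo = ScaleDefinition("demo", 5, 1, 6, reverse_items=frozenset({1}))
print("reverse-keyed sum of {2,3,4,5,6}:", score_scale([2, 3, 4, 5, 6], demo).score)  # -> 23

# one missing item voids the score; nothing is prorated
result = score_scale([3, None, 3, 3, 3], DEFAULT_SCALES["self_efficacy"])
print("score with a missing item:", result.score, "complete:", result.complete)
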