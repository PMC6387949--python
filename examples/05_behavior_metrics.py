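"""Behavioral measures: intensity means, accuracy, d-prime, anxiety score.

Uses the study's trial design: 1-9 emotional-intensity ratings per
laboratory condition and 128 shoot/don't-shoot trials per simulation
condition scored as hits (H), misses (M), false alarms (FA), and correct
rejections (CR).
"""

import pandas as pd

from emolink.behavior import (
    accuracy,
    anxiety_raw,
    anxiety_tscore,
    mean_intensity,
    sdt_rates,
)

ratings = pd.DataFrame({
    "condition": ["attend"] * 4 + ["reinterpret"] * 4,
    "rating": [4, 5, 3, 4, 2, 3, 3, 2],
})
means = mean_intensity(ratings)
print(f"mean intensity  attend: {means['attend']:.2f}   "
      f"reinterpret: {means['reinterpret']:.2f}")

outcomes = ["H"] * 55 + ["M"] * 9 + ["FA"] * 11 + ["CR"] * 53
print(f"accuracy (H + CR)/128: {accuracy(outcomes, n=128):.4f}")
rates = sdt_rates(outcomes)
print(f"hit rate {rates['hit_rate']:.3f}, FA rate {rates['fa_rate']:.3f}, "
      f"d' = {rates['dprime']:.2f}")

endorsed = ["tense", "shaky", "afraid", "energetic", "alert"]
raw = anxiety_raw(endorsed)
print(f"anxiety raw score: {raw} of 10 subscale adjectives endorsed")

# T-score conversion needs the publisher's norm table (proprietary);
# a user-supplied table is a simple (raw, total-checked) lookup:
toy_norms = {(3, 5): 62.0}
print(f"T-score from a user-supplied table: {anxiety_tscore(raw, 5, toy_norms)}")
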