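"""Counting metrics from per-video count pairs.

ACP (average counting precision), MAE and RMSE summarize how close the
tracker's unique-ID counts come to the true per-video fruit counts.
The pairs below compare a baseline tracker with a fully improved one
over three survey videos of 57, 95 and 96 fruits.
"""

from peppertrack import counting_metrics

baseline = counting_metrics([(57, 63), (95, 104), (96, 111)])
improved = counting_metrics([(57, 62), (95, 96), (96, 100)])

print("baseline tracker")
print(baseline.format())
print()
print("improved tracker (re-matching + merging)")
print(improved.format())
# Fewer duplicated identities bring the counts closer to the truth:
# ACP rises by ~7 percentage points and RMSE drops by ~7 fruits.
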