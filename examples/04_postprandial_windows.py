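"""Postprandial and peak-anchored (zeitgeber-time) window analysis.

Meal-anchored stacks average glucose over the two hours after each declared
breakfast; peak-anchored stacks align windows at the glucose peak (ZT = 0)
to show what movement intensity and distal skin temperature do around the
excursion.
"""

import numpy as np

import chronomeal as cm
from chronomeal.windows import extract_stack, merge_stacks, prepost_contrast, stack_aucs

bundle = cm.simulate_cohort(cm.CohortParams(n_participants=8, seed=5))

glu_stacks, dst_stacks = [], []
for trace in bundle.glucose:
    pid = trace.participant_id
    epoched = cm.to_epochs(trace, 300)
    acm = next(a for a in bundle.acm if a.participant_id == pid)
    meals = [e for e in bundle.events
             if e.participant_id == pid and e.meal_type == "breakfast"]
    if not meals:
        continue
    glu_stacks.append(
        extract_stack(meals, glucose=epoched, anchor_kind="meal_time",
                      pre_minutes=0, post_minutes=120)["glucose"]
    )
    peaks = [lm.peak for lm in cm.link_meals_to_peaks(
        meals, cm.detect_peaks(epoched)) if lm.linked]
    if peaks:
        st = extract_stack(peaks, acm=acm, anchor_kind="glucose_peak",
                           pre_minutes=60, post_minutes=120)
        st["dst"].anchor_ids = [pid] * len(st["dst"].anchor_ids)
        dst_stacks.append(st["dst"])

merged = merge_stacks(glu_stacks)
apex = merged.offsets[np.nanargmax(merged.mean_curve)]
print(f"mean post-breakfast curve: {merged.rows.shape[0]} windows, "
      f"apex {np.nanmax(merged.mean_curve):.1f} mg/dL at +{apex:.0f} min")
aucs = stack_aucs(merged)
print(f"2-h postprandial AUC: {np.nanmean(aucs):,.0f} mg/dL*min "
      "(a flat 100 mg/dL trace would give 12,000)")

contrasts = prepost_contrast(merge_stacks(dst_stacks))
pre = np.nanmean([c.pre_mean for c in contrasts])
post = np.nanmean([c.post_mean for c in contrasts])
print(f"\nDST around the breakfast glucose peak (ZT = 0): "
      f"pre-peak 1 h {pre:.2f} C vs post-peak 2 h {post:.2f} C")
print("Around breakfast, wrist temperature is still descending from its "
      "nocturnal high, so the post-peak mean sits at or below the pre-peak "
      "mean; after dinner the contrast reverses as DST anticipates sleep.")
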