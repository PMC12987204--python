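"""Clean the meal annotations and compute peak-related accuracy.

App (KE) and wrist-marker (KW) annotations are deduplicated (<= 15 min),
coupled (<= 30 min), filtered for glucose coverage, and each surviving app
annotation is linked to its nearest subsequent glucose peak; a meal counts
as accurate when that peak falls within the first two postprandial hours.
"""

import chronomeal as cm
from chronomeal.io_formats import extract_kw_events

bundle = cm.simulate_cohort(cm.CohortParams(n_participants=5, seed=3))

all_linked = []
coupled_n = ke_n = 0
for trace in bundle.glucose:
    pid = trace.participant_id
    epoched = cm.to_epochs(trace, 300)
    ke = cm.dedup_events(
        [e for e in bundle.events if e.participant_id == pid]
    )
    kw = cm.dedup_events(
        extract_kw_events(next(a for a in bundle.acm if a.participant_id == pid))
    )
    coupled, _ = cm.couple_ke_kw(ke, kw)
    coupled_n += sum(c.coupled for c in coupled)
    ke_n += len(ke)
    ke = cm.exclude_missing_glucose(ke, epoched)
    peaks = cm.detect_peaks(epoched)
    all_linked.extend(cm.link_meals_to_peaks(ke, peaks))

print(f"KE-KW coincidence: {100 * coupled_n / ke_n:.1f}% "
      f"({coupled_n}/{ke_n} app annotations confirmed by a wrist press)")
print("\npeak-related accuracy:")
print(cm.peak_related_accuracy(all_linked).table.to_string(index=False))
print("\nlag between annotation and its glucose peak (linked events):")
print(cm.lag_summary(all_linked).round(2).to_string(index=False))
print("\nMain meals should score higher than snacks: snack excursions are "
      "smaller and often stay below the 1-SD detection threshold.")
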