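"""Simulate a monitored subject and segment the trace into postprandial periods.

Generates two weeks of 5-min CGM data with three daily meals, reports the
standard glycemic summary, and shows how the segmentation and discard rules
play out.
"""

from csarima import SimConfig, generate_subject, glycemic_summary, segment_postprandial

config = SimConfig(days=14, seed=1)
series, events, labels = generate_subject(config)

summary = glycemic_summary(series)
print(f"{config.days}-day subject, {len(series)} samples, {len(events.meals)} meals")
print(
    f"missing {summary.missing_pct:.1f}%  CV {summary.cv:.1f}%  "
    f"TIR {summary.tir:.1f}%  TAR {summary.tar:.1f}%  TBR {summary.tbr:.1f}%"
)
# CV is glycemic variability (100*sd/mean); TIR/TAR/TBR are the percent of
# time in 70-180 mg/dL, above 180, and below 70.

pps = segment_postprandial(series, events)
print(f"\n{len(pps)} postprandial periods retained out of {len(events.meals)} meals")
full = sum(pp.observed_length == 48 for pp in pps)
print(f"{full} run the full 4 h; the rest were cut short by the next meal")
print(f"example PP: {pps[0].observed_length} observed slots, "
      f"{pps[0].n_missing_observed} missing inside the window")
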