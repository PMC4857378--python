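"""Criterion validity: summary statistics of the known-rectangle series.

The embedded reference data are 30 repeated width/height measurements
of a flat 25 cm x 15 cm rectangle filmed on the rotating platform.
Aggregating them reproduces the published summary row and shows the
instrument's percent error against the known dimensions.
"""

from posturekit import aggregate_metrics, percent_error, table1_fixture

fixture = table1_fixture()
aggs = aggregate_metrics(fixture.as_frames(), rounding="printed-table")

for name, truth in (("width", fixture.true_width), ("height", fixture.true_height)):
    s = aggs[name].summary
    err = percent_error(s.mean, truth)
    print(f"{name:>6}: n={s.n} mean={s.mean:.2f} cm  sd={s.sd:.2f}  cv={s.cv:.2f}%  "
          f"range=[{s.min:.2f}, {s.max:.2f}]  error vs {truth:g} cm = {err:.3f}%")

print()
print("The means sit within 0.1% of the true dimensions: averaging the")
print("30 frames suppresses the parallax and annotation scatter that is")
print("visible in the per-frame range.")
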