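"""Image-uniformity arithmetic and tube-heating-aware scan scheduling.

Feeds one series of five positional VOI means (center, left, top,
right, bottom — the layout of the Catphan uniformity module read per
installation-product-acceptance rules) into the uniformity arithmetic,
then prints the scan schedules the two accelerator types allow.
"""

from gelshot import schedule_scans, uniformity_ipa

# five positional means (HU) of one acceptance-style report row
means = {"center": 11.58, "left": 1.89, "top": 3.86, "right": 6.36, "bottom": 2.70}
report = uniformity_ipa([means])
row = report.rows[0]
print("peripheral - center differences (HU):")
for pos in ("left", "top", "right", "bottom"):
    print(f"  {pos:6s}: {row.diffs[pos]:7.2f}  "
          f"({'ok' if row.verdicts[pos] else 'OUT'} of +/-30 HU)")
print(f"mean of the four differences: {row.mean_of_four:.2f} HU "
      f"-> {'PASS' if report.passed else 'FAIL'}")
print()

for acc, mode in (("TrueBeam", "Pelvis"), ("Halcyon", "Pelvis"),
                  ("Halcyon", "Pelvis Large")):
    sched = schedule_scans(acc, mode, n_scans=5)
    print(f"{acc:9s} {mode:13s}: gaps between 5 scans = {sched.gaps_min} min")
print()
print("A TrueBeam runs five consecutive scans back to back; a Halcyon "
      "overheats its X-ray tube after two, so later scans need a 5 min "
      "(Pelvis) or 6 min (Pelvis Large) cool-down.")
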