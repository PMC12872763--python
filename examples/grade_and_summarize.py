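"""Grade stipe lengths, split a dataset 7:2:1 and summarize a trait column.

Grading uses the five-class scheme (extremely short .. extremely long) with
inclusive upper bounds at 11.56 / 27.69 / 43.83 / 59.96 mm; the splitter
reproduces the 689/197/99 partition of 985 samples; summary statistics are
the mean/max/min/sample-std/median columns of a trait table.
"""

from stipemorph import grade_length, split_dataset, summary_stats

for length in (8.0, 11.56, 11.57, 30.0, 55.0, 61.2):
    print(f"  {length:6.2f} mm -> {grade_length(length)}")

train, test, val = split_dataset(985)
print(f"\n985 samples split 7:2:1 -> train {train}, test {test}, val {val}")

lengths_mm = [48.2, 55.1, 56.3, 57.0, 58.4, 60.9, 63.5, 51.7, 54.8, 59.2]
mean, vmax, vmin, std, median = summary_stats(lengths_mm)
print(f"\nlength summary over {len(lengths_mm)} samples (mm): "
      f"mean {mean:.2f}, max {vmax:.2f}, min {vmin:.2f}, "
      f"std {std:.2f}, median {median:.2f}")
print()
print("Every non-negative length falls in exactly one grade; the split")
print("counts always sum to n (floor / round-half-up / remainder rule).")
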