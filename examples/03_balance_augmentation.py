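"""Balance an imbalanced cohort by stochastic augmentation.

Starts from 17 benign and 82 malignant synthetic cases (the imbalance of
the open DDTI thyroid cohort) and grows both classes to 1594 rows by
seeded flipping, rotation and blurring -- 3188 rows in total.  Identical
seeds give byte-identical cohorts.
"""

from gmnodule import AugmentationConfig, balance_and_augment, generate_cohort

cohort = generate_cohort((17, 82), seed=11)
print(f"original cohort: {sum(c.label == 0 for c in cohort)} benign, "
      f"{sum(c.label == 1 for c in cohort)} malignant")

cfg = AugmentationConfig(target_per_class=1594, seed=5)
rows = balance_and_augment(cohort, cfg)
n0 = sum(r.label == 0 for r in rows)
n1 = sum(r.label == 1 for r in rows)
print(f"augmented cohort: {len(rows)} rows ({n0} benign + {n1} malignant)")
print(f"originals retained: {sum(r.source_tag == 'original' for r in rows)}")

sample = next(r for r in rows if r.source_tag == "augmented")
print(f"example op log for {sample.case_id}: {sample.op_log}")

again = balance_and_augment(cohort, cfg)
identical = all(
    (a.contour.points == b.contour.points).all() for a, b in zip(rows, again)
)
print(f"same seed reproduces the cohort exactly: {identical}")
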