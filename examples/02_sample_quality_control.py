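"""Screen a noisy training set with repeated SOM clustering.

Injects label noise into a synthetic sample set (10% of samples keep
their true-class series but carry a wrong label), estimates each
sample's cluster-label frequency over repeated self-organizing-map runs,
and removes samples whose own label matches less than 80% of the time.
"""

from lucmap import default_patterns, evaluate_samples, filter_samples, generate_samples

patterns = default_patterns()
samples, truth = generate_samples(
    patterns, n_per_class=30, mislabel_rate=0.1, seed=3, return_truth=True
)
n_wrong = sum(s.label != t for s, t in zip(samples, truth))
print(f"{len(samples)} samples, {n_wrong} with injected wrong labels")

# A handful of short runs is enough at this scale; production settings
# are 20 runs of 100 epochs.
reliabilities = evaluate_samples(samples, n_runs=5, epochs=30, seed=4)
retained, removed, report = filter_samples(reliabilities, 0.8, samples)

print(f"retained {report.n_retained}, removed {report.n_removed} "
      f"({report.reduction_pct}% reduction)")

removed_ids = {r["sample_id"] for r in report.rows if not r["retained"]}
wrong_ids = {i for i, (s, t) in enumerate(zip(samples, truth)) if s.label != t}
caught = len(removed_ids & wrong_ids)
print(f"mislabels caught: {caught}/{n_wrong}; "
      f"clean samples lost: {len(removed_ids - wrong_ids)}")
# A mislabelled sample sits among its true-class neighbours on the map,
# so its best-matching neuron is voted to the true class and the sample's
# own-label frequency collapses -- which is what the filter detects.
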