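"""Estimate the CPU-hours of a search workload from k-mer profiles.

Builds a synthetic DNA query set and reference, computes 11-mer profiles
(both strands), and predicts total search cost with the linear overlap model
T = alpha + beta * x, where x is the dot product of query k-mer counts with
the reference profile's relative frequencies.
"""

from elastiseq import (RuntimeModel, SyntheticSpec, compute_profile,
                       generate_synthetic, overlap_statistic,
                       predict_cpu_hours, reference_weights)

query = generate_synthetic(SyntheticSpec(500, 200, 400, seed=1))
reference = generate_synthetic(SyntheticSpec(40, 500, 900, seed=2))

k = 5  # a dense word size for this small example; DNA default is 11
ref_profile = compute_profile(reference, k)
weights = reference_weights(ref_profile)
query_profile = compute_profile(query, k)

x = overlap_statistic(query_profile, weights)
model = RuntimeModel(k=k, alphabet="dna", reference_weights=weights,
                     alpha=0.05, beta=2e-4)
t = predict_cpu_hours(model, query_profile)

print(f"query k-mers counted : {query_profile.total}")
print(f"overlap statistic x  : {x:.1f}")
print(f"estimated CPU-hours T: {t:.3f}")
print()
print("T is the total processor time the search is expected to need; the")
print("partition planner and provisioner both size their decisions from it.")
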