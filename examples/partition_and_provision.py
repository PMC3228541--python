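"""From a runtime estimate to a partition plan and an instance plan.

Given T estimated CPU-hours for N_q query sequences, the planner chooses the
partition size P so each parallel work unit runs about R hours (default 2),
and the provisioner picks an instance count through the policy hierarchy:
hard-coded floors, then the provider cap, then the user's own limit.
"""

from elastiseq import (ProvisionPolicy, plan_partitions, plan_provisioning)

n_query, t_est = 10_000, 10.0
plan = plan_partitions(n_query, t_est, r_target=2.0)
print(f"N_q={n_query}, T={t_est} h, R={plan.r_target} h")
print(f"  -> partition size P={plan.p_size}, {plan.n_parts} partitions "
      f"(~{t_est / plan.n_parts:.1f} h each)")

for t in (0.5, 400.0):
    p = plan_provisioning("search", t, ProvisionPolicy())
    print(f"T={t:>6} h -> {p.count} x {p.instance_type.name} "
          f"({p.total_cpus} CPUs), rationale: {p.rationale}")

print()
print("A tiny search still gets the 5-instance / 40-CPU floor; a 400 CPU-hour")
print("search wants ceil(400/(2*8))=25 instances but is capped at the")
print("provider's default account limit of 20.")
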