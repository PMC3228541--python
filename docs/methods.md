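# Methods

`elastiseq` is a desk-scale, fully deterministic simulator of an elastic
cloud pipeline for parallel sequence search. It reproduces the *control*
architecture of such systems — runtime estimation, partition planning,
provisioning policy, master/worker queueing, peer-to-peer data staging and
the client-side wrapper state machine — without any real infrastructure or
real search tool. This note records the models, the parameters that matter,
the numerical choices, and what the simulation does and does not show.

## Runtime estimation from k-mer profiles

The cost of a sequence-database search depends on how much of the query's
word content is represented in the reference. The estimator works on k-mer
profiles: the multiset of length-k subwords of a sequence set, counted with a
sliding window. DNA profiles include the reverse-complemented strand, making
them strand-symmetric; the defaults are k = 11 for DNA and k = 3 for protein.
Windows containing an ambiguity code (N for DNA, X for protein) are skipped
rather than expanded — deterministic, cheap, and unbiased for the random
synthetic inputs used here.

The profile comparison is a linear overlap model:

    x = Σ_w  c_q(w) · ω_ref(w)          (overlap statistic)
    T = α + β · x                        (estimated CPU-hours)

where `c_q` are query k-mer counts and `ω_ref` are per-k-mer reference
weights, by default the relative frequencies of the reference database's own
profile. α (fixed overhead, CPU-hours, ≥ 0) and β (CPU-hours per overlap
unit) are calibrated by ordinary least squares on timed runs; a negative
fitted intercept is clamped to zero and β refit through the origin, since a
negative fixed cost is meaningless. This is the simplest model consistent
with per-database pre-calculation; it is deliberately swappable — any object
with `reference_weights`, `alpha` and `beta` drives the same prediction
path. The model is linear and monotone in every query count by construction:
doubling all query counts exactly doubles x.

## Partition planning

Queries are split into partitions searched concurrently. With T the total
estimated CPU-hours, N_q the query count, and R the preferred per-partition
execution time (default 2 h), the default ("corrected") rule is

    n_parts = max(1, ceil(T / R)),   P = ceil(N_q / n_parts),

so each partition is expected to run about R hours. The historical form
P = N_q·T/R is kept behind `mode="literal"`; note it is dimensionally
inconsistent with R's role (it *grows* the partition size with T, producing
fewer, longer partitions for bigger jobs), which is why it is not the
default. Both modes clamp P to [1, N_q]: at least one partition, and never
more partitions than sequences (over-partitioning only buys scheduler
overhead). Assignment is contiguous in input order; the concatenation of the
partitions reproduces the input exactly.

One integer subtlety: when ceil(N_q / ceil(N_q / n_parts)) < n_parts (e.g.
N_q = 10, n_parts = 6 gives P = 2 and only 5 partitions), the realized
partition count drops below the target by granularity. The planner reports
the realized count.

## Provisioning policy

Instance selection follows a strict hierarchy: (1) hard-coded protocol
assumptions, (2) the provider's account cap, (3) the user's per-pipeline cap,
with the estimate filling in the free dimension:

    count = max(min_instances, ceil(T / (R · cpus_per_instance))).

Defaults: a floor of five 8-CPU instances (40 CPUs) for search-style
protocols; a provider cap of 20 instances per account; a single high-memory
instance (m2.xlarge, 17.1 GB RAM) for short-read assembly inputs, where RAM,
not parallelism, is the constraint. An explicit user cap below the floor
wins — a user limit is a promise never to start more than that many
instances. `count` denotes compute (worker) instances; the wrapper runs one
master besides them, and the provider cap bounds the account total, so a
capped plan tops out at 20 instances including the master.

Billing is in whole hours from launch (minimum one). The idle-termination
rule releases a jobless worker when it is within a configurable window
(default 0.1 h) of its next whole-hour uptime boundary — terminating just
before a new billed hour would start. The default hourly rate of the 8-CPU
type, 0.675 units/h, is the per-instance rate implied by a 160-instance
fleet costing 108 units per hour.

## The simulated cloud

Time is a shared virtual clock in hours; nothing sleeps. The backend exposes
exactly three provider calls — run, terminate, describe instances — plus an
append-only call log so tests can assert that the orchestration layer never
uses anything else. Instances boot after a latency (default 0.02 h) with
per-instance uniform jitter (default up to 0.01 h) drawn from a seeded
generator, reproducing staggered boots deterministically. Each instance has
a private ephemeral disk that becomes inaccessible at termination. The
network model is minimal: one point-to-point bandwidth inside the cloud
(default 40 MB/s) and a lower desktop↔cloud rate (default 10 MB/s).

## Cluster, queues and peer-to-peer staging

The first instance of a cluster is the master; the rest register as workers
on boot. Work flows through slot-limited queues: `exec.q` offers one slot
per worker CPU (the master only joins when it is the sole instance — the
'local' cluster is both master and worker); `staging.q` and `harvesting.q`
bound how many simultaneous prolog (input) and epilog (output) transfers the
master serves (default 2 each). A job's inputs are copied to its worker
before execution and its outputs harvested back after; the job holds an exec
slot only between prolog completion and epilog start. Scheduling is a small
heapq event loop; jobs are placed on the least-committed running host,
ties broken by lowest instance id, which is deterministic and balances load.

Shared reference data is mirrored to all workers peer-to-peer: initially the
master is the only source; a worker that completes its copy joins
`stagingsub.q` and immediately serves peers. Pending recipients attach to
the least-loaded eligible source (tie → lowest id), bounded by a per-host
outbound limit (default 1). Transfers are non-preemptive whole-payload
copies — directory-synchronization semantics, not chunked swarming. Under
unit concurrency and uniform links the source count doubles each round, so n
workers complete in ceil(log2(n+1)) rounds versus n master-only rounds. Note
the bound "P2P is at least twice as fast" holds only from n = 6 workers
(ceil(log2(5)) = 3 > 4/2 at n = 4); strict improvement holds from n ≥ 2.

Dataset transfers between clusters are idempotent: per-file content
checksums are recomputed at transfer time and only changed files move, so an
immediate repeat moves zero bytes. Reference URLs are fetched into a local
store at most once, guarded by a recorded checksum that also detects
corruption.

## The wrapper pipeline

Seven phases in fixed order: validate → start cluster → upload → run worker →
monitor → download → post-process. Phases 2, 3 and 6 are skipped in local
mode. Validation failures fail the run before any backend call; any later
failure still tears the cluster down — a terminal run leaves zero running
instances. The monitor polls every 0.05 virtual hours, scales the cluster up
toward the provisioning plan before the parallel stage (a provider refusal
is logged and the run continues with what it has), and after job completion
terminates idle workers at their hourly boundaries while the master survives
until the download finishes. Output datasets record provenance: pipeline id,
protocol id and version, and the full parameter snapshot.

The worker workload is a toy exact k-mer seed matcher (per-query count of
k-windows present in the reference), merged across partitions in partition
order, so the merged output is invariant to the partitioning. Its simulated
CPU cost follows the same α + β·x law the estimator uses — intentionally:
this closes the loop so runtime predictions can be validated against
simulated execution exactly. Real-search fidelity (alignment scoring,
E-values, database formatting) is explicitly out of scope.

## Configuration dialect

Pipelines are configured by one sectioned key=value file with four sections
— `[input]`, `[params]`, `[cluster]`, `[output]` — and `#` comments. Keys
are schema-checked per protocol; unknown keys or sections are rejected.
Templates from `describe_protocol` round-trip bit-exactly through
`serialize_config`/`parse_config`. Profiles and runtime models serialize to
a line-oriented text format: `key=value` header lines (`k`, `alphabet`,
`type`, and `alpha`/`beta` for models) followed by one `<kmer>\t<value>`
line per word.

## Synthetic data and what the tests show

All inputs are generated by `SyntheticSpec`: i.i.d. uniform residues (no
ambiguity codes) with lengths uniform in a configurable range, byte-identical
under a fixed seed. Test and example workloads use a few hundred queries of
200–400 nt against references of tens of 400–900 nt sequences; the
integration check runs 1,000 × 400 nt queries end to end in seconds. Random
sequences have no repeat structure, composition bias, or real k-mer sharing,
so profile overlaps at k = 11 are sparse and spiky; tests that need uniform
per-partition costs use a denser word size (k = 5). Consequently, passing
tests demonstrate the correctness of the *mechanisms* (counting, planning,
scheduling, policy arithmetic, determinism), not the predictive accuracy of
the timing model on real genomic data, which would require calibration
against a real search tool.

## Numerical choices and limitations

- Ties everywhere break by lowest identifier; all iteration orders are
  sorted — full determinism under a seed.
- The idle-boundary test uses a 1e-9 epsilon against float drift.
- Virtual time is float hours; transfers and jobs are scheduled to exact
  endpoints, so equal-length rounds compare exactly in tests via
  `pytest.approx`.
- Harvest (epilog) transfers are master-directed only; outputs are never
  peer-relayed. Workers added by mid-run scaling do not retroactively
  receive the staging mirror (the mirror completes before job submission).
- The monitor only scales down by terminating idle workers; it never
  preempts running work.
- CLI state across invocations is a replayable action log; pipeline runs are
  one-shot within a single invocation.
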