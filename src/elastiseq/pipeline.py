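"""The seven-phase wrapper pipeline and the session that hosts it.

A run of an analysis protocol is driven by a client-side state machine with a
fixed phase order:

1. pre-processing — input validation and integrity checks;
2. start cluster — provision instances on the cloud;
3. upload — move input datasets to the cluster master;
4. run worker — partition the queries and submit the worker workload;
5. monitor — poll the cluster, scale it up before the parallel stage, and
   terminate idle workers on the hourly billing boundary;
6. download — retrieve the merged output dataset;
7. post-processing — record provenance and tear the cluster down.

Phases 2, 3 and 6 only execute in cloud mode; in local mode the workload runs
on the 'local' cluster (the client itself) and those phases are skipped. A
failing phase halts the run, and in cloud mode the cluster is torn down no
matter what: a terminal run never leaves instances running.

The worker workload shipped here is a toy exact k-mer seed matcher standing in
for a real search tool: it counts, for every query sequence, how many of its
k-length windows occur in the reference. Its simulated CPU cost follows the
same linear law the runtime estimator is calibrated with, so estimates can be
validated end to end against simulated execution.
"""

from __future__ import annotations

import itertools
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import estimator, partition, provision, registry as reg
from .cloudsim import SimCloud
from .cluster import ClusterService, LOCAL_HOST
from .errors import CapacityError, ElastiseqError, SimulationError, ValidationError
from .seqio import SequenceRecord, format_fasta, read_fasta

PHASE_NAMES = (
    "pre-processing",
    "start-cluster",
    "upload",
    "run-worker",
    "monitor",
    "download",
    "post-processing",
)
#: phases that only execute when a remote cloud platform is used
CLOUD_ONLY_PHASES = frozenset({"start-cluster", "upload", "download"})

_FORBIDDEN_SUFFIXES = (".sff", ".fastq", ".fq", ".qual", ".gb", ".gbk")


@dataclass
class PhaseRecord:
    name: str
    status: str = "pending"  # pending|running|complete|skipped|failed
    start: Optional[float] = None
    end: Optional[float] = None
    detail: str = ""


@dataclass
class WorkerTask:
    """A pluggable worker workload: a per-partition cost law plus a function
    producing the partition's result text. Deterministic given its inputs."""

    name: str
    cost_alpha: float
    cost_beta: float

    def cost(self, overlap: float) -> float:
        return self.cost_alpha + self.cost_beta * overlap


def toy_search_worker(
    records: Sequence[SequenceRecord], reference_kmers: Set[str], k: int
) -> str:
    """Exact k-mer seed-match counting of each query against the reference.

    Returns one tab-separated line per query: id, number of query windows
    found in the reference k-mer set. Windows with ambiguity codes count as
    non-matching.
    """
    if not reference_kmers:
        raise ValidationError("empty reference: no k-mers to match against")
    lines = []
    for rec in records:
        seq = rec.seq.upper()
        n = sum(
            1 for i in range(len(seq) - k + 1)
            if seq[i : i + k] in reference_kmers
        )
        lines.append(f"{rec.id}\t{n}")
    return "\n".join(lines) + "\n"


@dataclass
class PipelineRun:
    id: str
    config: reg.PipelineConfig
    mode: str
    phases: List[PhaseRecord]
    state: str = "pending"  # pending|running|complete|failed
    cluster_name: Optional[str] = None
    outputs: Optional[str] = None
    t_est: float = 0.0
    provision_plan: Optional[provision.ProvisionPlan] = None
    partition_plan: Optional[partition.PartitionPlan] = None
    merged_output: bytes = b""
    timeline: List[Tuple[float, int, int]] = field(default_factory=list)
    scaling_actions: List[str] = field(default_factory=list)
    makespan_hours: float = 0.0
    # internal carry-over between phases
    _query: List[SequenceRecord] = field(default_factory=list, repr=False)
    _reference: List[SequenceRecord] = field(default_factory=list, repr=False)
    _traits: Tuple[str, ...] = ()
    _jobs: list = field(default_factory=list, repr=False)

    def phase(self, name: str) -> PhaseRecord:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    def executed_phases(self) -> Set[str]:
        return {p.name for p in self.phases if p.status == "complete"}

    def skipped_phases(self) -> Set[str]:
        return {p.name for p in self.phases if p.status == "skipped"}

    def timeline_csv(self) -> str:
        rows = ["time_h,instances,running_jobs"]
        rows += [f"{t:.4f},{n},{j}" for t, n, j in self.timeline]
        return "\n".join(rows) + "\n"


class Session:
    """Wires the simulated cloud, cluster service and registry together.

    One session owns one virtual clock; every source of randomness (boot
    jitter, keypairs) descends from its seed, so two sessions with the same
    seed replay identically.
    """

    def __init__(
        self,
        seed: int = 0,
        provider_cap: int = 20,
        local_cpus: int = 4,
        boot_latency: float = 0.02,
        boot_jitter: float = 0.01,
        poll_interval: float = 0.05,
        idle_window: float = 0.1,
        min_instances: int = 5,
        scratch: Optional[Path] = None,
    ) -> None:
        self.seed = seed
        self.cloud = SimCloud(
            seed=seed, provider_cap=provider_cap,
            boot_latency=boot_latency, boot_jitter=boot_jitter,
        )
        self.clusters = ClusterService(self.cloud, seed=seed,
                                       local_cpus=local_cpus)
        self.registry = reg.Registry(self.cloud, self.clusters)
        self.cloud.add_credential("default", "account-default")
        self.poll_interval = poll_interval
        self.idle_window = idle_window
        self.min_instances = min_instances
        self.scratch = Path(scratch) if scratch else Path(tempfile.mkdtemp(
            prefix="elastiseq-"))
        self.runs: Dict[str, PipelineRun] = {}
        self._run_counter = itertools.count(1)

    # -- helpers --------------------------------------------------------------

    def _policy(self, config: reg.PipelineConfig) -> provision.ProvisionPolicy:
        itype = provision.DEFAULT_CATALOG[config.cluster["instance_type"]]
        return provision.ProvisionPolicy(
            min_instances=self.min_instances,
            provider_cap=self.cloud.provider_cap,
            user_cap=config.cluster["user_cap"],
            target_hours=config.params["target_hours"],
            default_type=itype,
            idle_window_hours=self.idle_window,
        )

    @staticmethod
    def _slots(config: reg.PipelineConfig) -> Tuple[str, str]:
        """(query slot, reference slot) for the protocol's toy workload."""
        if config.protocol in ("search", "metagenomics"):
            return "query", "reference"
        return "reads", "reads"  # single-input protocols self-search

    # -- the seven phases ------------------------------------------------------

    def run_pipeline(self, config: reg.PipelineConfig) -> PipelineRun:
        mode = config.cluster["mode"]
        run = PipelineRun(
            id=f"pipeline-{next(self._run_counter):04d}",
            config=config, mode=mode,
            phases=[PhaseRecord(n) for n in PHASE_NAMES],
        )
        self.runs[run.id] = run
        run.state = "running"
        steps = {
            "pre-processing": self._phase_validate,
            "start-cluster": self._phase_start_cluster,
            "upload": self._phase_upload,
            "run-worker": self._phase_run_worker,
            "monitor": self._phase_monitor,
            "download": self._phase_download,
            "post-processing": self._phase_post,
        }
        for rec in run.phases:
            if mode == "local" and rec.name in CLOUD_ONLY_PHASES:
                rec.status = "skipped"
                continue
            rec.status = "running"
            rec.start = self.cloud.clock.now
            try:
                steps[rec.name](run)
            except ElastiseqError as exc:
                rec.status = "failed"
                rec.end = self.cloud.clock.now
                rec.detail = str(exc)
                run.state = "failed"
                self._teardown(run)
                return run
            rec.status = "complete"
            rec.end = self.cloud.clock.now
        run.state = "complete"
        return run

    def _phase_validate(self, run: PipelineRun) -> None:
        config = run.config
        spec = reg.PROTOCOLS.get(config.protocol)
        if spec is None:
            raise ValidationError(f"unknown protocol {config.protocol!r}")
        if run.mode not in ("local", "cloud"):
            raise ValidationError(f"invalid mode {run.mode!r}")
        for slot in spec.input_slots:
            if not config.inputs.get(slot):
                raise ValidationError(f"missing required input {slot!r}")
            if not self.registry.has(config.inputs[slot], LOCAL_HOST):
                raise ValidationError(
                    f"input dataset {config.inputs[slot]!r} is not registered "
                    f"on the local cluster"
                )
        qslot, rslot = self._slots(config)
        alphabet = config.params["alphabet"]
        loaded = {}
        for slot in {qslot, rslot}:
            ds = self.registry.get(config.inputs[slot], LOCAL_HOST)
            records: List[SequenceRecord] = []
            for entry in ds.files:
                fname = entry.name.lower()
                if fname.endswith(_FORBIDDEN_SUFFIXES):
                    raise ValidationError(
                        f"{entry.name}: only FASTA input is supported "
                        f"(SFF/FASTQ/QUAL are not)"
                    )
                if entry.path is None:
                    raise ValidationError(
                        f"{entry.name}: input dataset must point at real files"
                    )
                records.extend(read_fasta(entry.path, alphabet=alphabet))
            loaded[slot] = records
        run._query = loaded[qslot]
        run._reference = loaded[rslot]
        qds = self.registry.get(config.inputs[qslot], LOCAL_HOST)
        if config.protocol == "microbe" and qds.tags.get("platform") == "illumina":
            run._traits = ("illumina-assembly",)
        run.t_est = self._estimate(run)

    def _estimate(self, run: PipelineRun) -> float:
        params = run.config.params
        if params["cpu_hours"] is not None:
            return float(params["cpu_hours"])
        k = params["kmer_size"]
        alphabet = params["alphabet"]
        revcomp = alphabet == "dna"
        ref_profile = estimator.compute_profile(
            run._reference, k, alphabet, include_revcomp=revcomp)
        weights = estimator.reference_weights(ref_profile)
        model = estimator.RuntimeModel(
            k=k, alphabet=alphabet, reference_weights=weights,
            alpha=params["cost_alpha"], beta=params["cost_beta"],
        )
        query_profile = estimator.compute_profile(
            run._query, k, alphabet, include_revcomp=revcomp)
        return estimator.predict_cpu_hours(model, query_profile)

    def _phase_start_cluster(self, run: PipelineRun) -> None:
        config = run.config
        policy = self._policy(config)
        plan = provision.plan_provisioning(
            config.protocol, run.t_est, policy, input_traits=run._traits)
        run.provision_plan = plan
        # reseed boot jitter from the run's parameter seed for reproducibility
        self.cloud._rng.seed(
            (int(config.params["seed"]) * 1_000_003 + 17) % (2**31))
        if plan.rationale == "hardcoded" and plan.instance_type.name == "m2.xlarge":
            total = 1  # a single high-memory instance; the master does the work
        else:
            total = 1 + min(plan.count, policy.min_instances)
        total = min(total, policy.effective_cap)
        cluster = self.clusters.add_cluster(
            run.id, config.cluster["credential"], plan.instance_type, total)
        run.cluster_name = cluster.name

    def _phase_upload(self, run: PipelineRun) -> None:
        qslot, rslot = self._slots(run.config)
        for slot in {qslot, rslot}:
            self.registry.transfer_dataset(
                run.config.inputs[slot], LOCAL_HOST, run.cluster_name)

    def _phase_run_worker(self, run: PipelineRun) -> None:
        config = run.config
        params = config.params
        k = params["kmer_size"]
        alphabet = params["alphabet"]
        revcomp = alphabet == "dna"
        task = WorkerTask("toy-search", params["cost_alpha"], params["cost_beta"])

        plan = partition.plan_partitions(
            len(run._query), run.t_est, params["target_hours"],
            mode=params["partition_mode"])
        run.partition_plan = plan
        parts = partition.partition_records(run._query, plan)

        ref_profile = estimator.compute_profile(
            run._reference, k, alphabet, include_revcomp=revcomp)
        weights = estimator.reference_weights(ref_profile)
        ref_kmers = set(ref_profile.counts)

        cluster_name = run.cluster_name if run.mode == "cloud" else LOCAL_HOST
        cluster = self.clusters[cluster_name]
        if run.mode == "cloud" and cluster.workers:
            qslot, rslot = self._slots(config)
            payload = self.registry.get(config.inputs[rslot], cluster_name).nbytes
            cluster.mirror_staging(payload)

        for chunk in parts:
            profile = estimator.compute_profile(
                chunk, k, alphabet, include_revcomp=revcomp)
            overlap = estimator.overlap_statistic(profile, weights)
            duration = task.cost(overlap)
            prolog = len(format_fasta(chunk)) if run.mode == "cloud" else 0
            epilog = 24 * len(chunk) if run.mode == "cloud" else 0
            job = cluster.submit_job(
                work=lambda c=chunk: toy_search_worker(c, ref_kmers, k),
                duration=duration, prolog_bytes=prolog, epilog_bytes=epilog,
            )
            run._jobs.append(job)

    def monitor_and_scale(self, run: PipelineRun) -> List[str]:
        """Scaling decisions for a run in its monitoring phase.

        Before the parallel stage: grow the cluster toward the provisioning
        plan (a provider refusal is logged, not fatal). After job completion:
        terminate idle workers near their hourly uptime boundary.
        """
        actions: List[str] = []
        cluster = self.clusters[run.cluster_name]
        policy = self._policy(run.config)
        target_total = min(1 + run.provision_plan.count, policy.effective_cap)
        current = 1 + len(cluster.workers)
        if not cluster.idle():
            if current < target_total:
                want = target_total - current
                try:
                    self.clusters.add_instances(run.cluster_name, want)
                    actions.append(f"add_instances:{want}")
                except CapacityError as exc:
                    actions.append(f"add_instances_refused:{want}")
        else:
            now = self.cloud.clock.now
            due = []
            for host in list(cluster.workers):
                if cluster.host_busy(host):
                    continue
                uptime = self.cloud.instances[host].uptime(now)
                if provision.idle_termination_due(
                        uptime, False, window=policy.idle_window_hours):
                    due.append(host)
            if due:
                self.clusters.terminate_workers(run.cluster_name, due)
                actions.append(f"terminate_idle:{len(due)}")
        run.scaling_actions.extend(actions)
        return actions

    def _phase_monitor(self, run: PipelineRun) -> None:
        cluster_name = run.cluster_name if run.mode == "cloud" else LOCAL_HOST
        cluster = self.clusters[cluster_name]
        clock = self.cloud.clock
        stage_start = clock.now
        if run.mode == "cloud":
            self.monitor_and_scale(run)  # grow before the parallel stage
        while not cluster.idle():
            cluster.run_until(clock.now + self.poll_interval)
            self._observe(run, cluster)
        run.makespan_hours = clock.now - stage_start
        failed = [j for j in run._jobs if j.state == "failed"]
        if failed:
            raise SimulationError(
                f"worker failure in {failed[0].job_id}: {failed[0].error}")
        run.merged_output = b"".join(
            j.result.encode() for j in run._jobs)
        if run.mode == "cloud":
            # release idle workers at their hourly boundaries; keep the master
            deadline = clock.now + 1.0 + 2 * self.poll_interval
            while cluster.workers and clock.now < deadline:
                self.monitor_and_scale(run)
                cluster.run_until(clock.now + self.poll_interval)
                self._observe(run, cluster)
            out_name = f"{run.id}-{run.config.output['dataset']}"
            self.registry.add_dataset(
                cluster_name, out_name,
                [reg.FileEntry.from_content(out_name + ".tsv",
                                            run.merged_output)],
                producer=self._provenance(run),
            )
            run.outputs = out_name

    def _observe(self, run: PipelineRun, cluster) -> None:
        now = self.cloud.clock.now
        if run.mode == "cloud":
            descs = self.cloud.describe_instances(run.config.cluster["credential"])
            n_inst = sum(1 for d in descs if d["state"] != "terminated")
        else:
            n_inst = 1
        n_jobs = sum(1 for j in run._jobs if j.state == "running")
        run.timeline.append((now, n_inst, n_jobs))

    def _phase_download(self, run: PipelineRun) -> None:
        self.registry.transfer_dataset(run.outputs, run.cluster_name, LOCAL_HOST)

    def _phase_post(self, run: PipelineRun) -> None:
        if run.mode == "cloud":
            self.clusters.terminate_cluster(run.cluster_name)
        else:
            out_name = f"{run.id}-{run.config.output['dataset']}"
            self.registry.add_dataset(
                LOCAL_HOST, out_name,
                [reg.FileEntry.from_content(out_name + ".tsv",
                                            run.merged_output)],
                producer=self._provenance(run),
            )
            run.outputs = out_name
        outdir = run.config.output.get("dir")
        if outdir:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / f"{run.outputs}.tsv").write_bytes(run.merged_output)

    def _provenance(self, run: PipelineRun) -> reg.Provenance:
        spec = reg.PROTOCOLS[run.config.protocol]
        return reg.Provenance(
            pipeline_id=run.id, protocol=spec.id, version=spec.version,
            params=dict(run.config.params),
        )

    def _teardown(self, run: PipelineRun) -> None:
        """Cloud teardown guarantee: a terminal run leaves nothing running."""
        if run.cluster_name and run.cluster_name in self.clusters.clusters:
            self.clusters.terminate_cluster(run.cluster_name)

    # -- status ---------------------------------------------------------------

    def describe_pipeline(self, run_id: str) -> Dict[str, object]:
        run = self.runs.get(run_id)
        if run is None:
            raise ValidationError(f"unknown pipeline {run_id!r}")
        return {
            "id": run.id,
            "state": run.state,
            "mode": run.mode,
            "phases": [
                {"name": p.name, "status": p.status,
                 "start": p.start, "end": p.end, "detail": p.detail}
                for p in run.phases
            ],
            "running_jobs": sum(1 for j in run._jobs if j.state == "running"),
            "timeline": list(run.timeline),
            "outputs": run.outputs,
        }
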