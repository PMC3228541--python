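"""Master/worker cluster semantics on top of the simulated cloud.

A cluster is a set of instances with a single master (the first instance
started) and zero or more workers that register on boot. Work is scheduled
through Grid-Engine-like queues with per-host slot limits:

``exec.q``
    compute slots; each worker offers as many slots as it has CPUs (the
    master only joins when it is the sole instance, as in the 'local'
    cluster, which is both master and worker);
``staging.q`` / ``harvesting.q``
    bound how many simultaneous input (prolog) / output (epilog) transfers
    the master will serve — every job's inputs are copied from the master to
    the worker's local disk before it runs, and its outputs copied back after;
``stagingsub.q``
    membership records which workers hold a complete copy of the shared
    staging directory and may therefore mirror it to peers.

Shared reference data is disseminated with a peer-to-peer scheme
(:meth:`Cluster.mirror_staging`): initially only the master is a source; as
soon as a worker completes its copy it becomes an additional source, so under
unit per-host concurrency the number of sources doubles every round and n
workers are served in ceil(log2(n+1)) rounds instead of n.

Everything runs on a shared virtual clock via a small heapq-based
discrete-event loop; transfers are non-preemptive whole-payload copies
(rsync-of-a-directory semantics, no chunk swarming).
"""

from __future__ import annotations

import heapq
import itertools
import random
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from .cloudsim import MB, SimCloud
from .errors import SimulationError, ValidationError
from .provision import InstanceType

LOCAL_HOST = "local"


@dataclass
class QueueConfig:
    name: str
    slots_per_host: int
    member_hosts: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.slots_per_host < 1:
            raise ValidationError("slots_per_host must be >= 1")


@dataclass(frozen=True)
class TransferEvent:
    source: str
    dest: str
    nbytes: int
    start: float
    end: float
    queue: str = "staging.q"

    @property
    def rate_mb_s(self) -> float:
        return (self.nbytes / MB) / ((self.end - self.start) * 3600.0)


@dataclass
class StagingSchedule:
    """Full event schedule of one staging-directory mirroring operation."""

    events: List[TransferEvent]
    start: float
    completion_time: float  # elapsed hours from start to last completion

    @property
    def total_bytes(self) -> int:
        return sum(e.nbytes for e in self.events)

    def aggregate_throughput_curve(self) -> List[Tuple[float, float]]:
        """Stepwise aggregate throughput: (time, MB/s) breakpoints."""
        deltas: Dict[float, float] = {}
        for e in self.events:
            deltas[e.start] = deltas.get(e.start, 0.0) + e.rate_mb_s
            deltas[e.end] = deltas.get(e.end, 0.0) - e.rate_mb_s
        curve, level = [], 0.0
        for t in sorted(deltas):
            level += deltas[t]
            curve.append((t, max(0.0, level)))
        return curve

    @property
    def peak_throughput_mb_s(self) -> float:
        return max((rate for _, rate in self.aggregate_throughput_curve()),
                   default=0.0)


@dataclass
class Job:
    job_id: str
    queue: str
    work: Optional[Callable[[], object]]
    duration: float
    prolog_bytes: int = 0
    epilog_bytes: int = 0
    host_affinity: Optional[str] = None
    state: str = "queued"
    host: Optional[str] = None
    result: object = None
    error: Optional[str] = None
    submit_time: float = 0.0
    start_time: Optional[float] = None
    end_time: Optional[float] = None
    finish_time: Optional[float] = None  # after epilog

    @property
    def terminal(self) -> bool:
        return self.state in ("done", "failed")


@dataclass(frozen=True)
class SlotInterval:
    """One slot occupancy on a host, for conservation checks."""

    host: str
    queue: str
    job_id: str
    start: float
    end: float


class Cluster:
    def __init__(
        self,
        service: "ClusterService",
        name: str,
        credential: Optional[str],
        master: str,
        workers: Sequence[str],
        itype: Optional[InstanceType],
        keypair: str,
        local: bool = False,
        local_cpus: int = 4,
        staging_slots: int = 2,
        harvesting_slots: int = 2,
    ) -> None:
        self.service = service
        self.cloud = service.cloud
        self.clock = service.cloud.clock
        self.name = name
        self.credential = credential
        self.master = master
        self.workers: List[str] = list(workers)
        self.itype = itype
        self.keypair = keypair
        self.local = local
        self.local_cpus = local_cpus
        self.closed = False
        exec_slots = local_cpus if local else itype.cpus
        self.queues: Dict[str, QueueConfig] = {
            "exec.q": QueueConfig("exec.q", exec_slots, set(self._exec_hosts())),
            "staging.q": QueueConfig("staging.q", staging_slots, {master}),
            "harvesting.q": QueueConfig("harvesting.q", harvesting_slots, {master}),
            "stagingsub.q": QueueConfig("stagingsub.q", 1, set()),
        }
        self.jobs: List[Job] = []
        self.transfer_log: List[TransferEvent] = []
        self.slot_log: List[SlotInterval] = []
        self._usage: Dict[Tuple[str, str], int] = {}
        self._committed: Dict[str, int] = {}
        self._heap: List[Tuple[float, int, Callable[[], None]]] = []
        self._seq = itertools.count(0)
        self._job_counter = itertools.count(0)
        for host in self.workers or [self.master]:
            self._wake_at_boot(host)

    # -- membership -----------------------------------------------------------

    def _exec_hosts(self) -> List[str]:
        return list(self.workers) if self.workers else [self.master]

    def _host_running(self, host: str) -> bool:
        if self.local:
            return True
        inst = self.cloud.instances.get(host)
        return inst is not None and inst.state(self.clock.now) == "running"

    def _wake_at_boot(self, host: str) -> None:
        if self.local:
            return
        inst = self.cloud.instances.get(host)
        if inst is not None and inst.boot_at > self.clock.now:
            self._schedule(inst.boot_at, lambda: None)

    def running_instances(self) -> List[str]:
        if self.local:
            return []
        return [
            h for h in [self.master] + self.workers
            if self._host_running(h)
        ]

    def total_cpus(self) -> int:
        """CPUs across all (non-terminated) instances of the cluster."""
        if self.local:
            return self.local_cpus
        n = sum(
            1 for h in [self.master] + self.workers
            if self.cloud.instances[h].termination_time is None
        )
        return n * self.itype.cpus

    def exec_slot_total(self) -> int:
        q = self.queues["exec.q"]
        return q.slots_per_host * len(q.member_hosts)

    # -- event engine ---------------------------------------------------------

    def _schedule(self, when: float, fn: Callable[[], None]) -> None:
        heapq.heappush(self._heap, (when, next(self._seq), fn))

    def _usage_of(self, host: str, queue: str) -> int:
        return self._usage.get((host, queue), 0)

    def _acquire(self, host: str, queue: str) -> None:
        q = self.queues[queue]
        if self._usage_of(host, queue) >= q.slots_per_host:
            raise SimulationError(f"slot overflow on {host}/{queue}")
        self._usage[(host, queue)] = self._usage_of(host, queue) + 1

    def _release(self, host: str, queue: str) -> None:
        self._usage[(host, queue)] = self._usage_of(host, queue) - 1

    def run_until(self, t: float) -> None:
        """Process all events up to virtual time t, then land the clock on t."""
        self._dispatch()
        while self._heap and self._heap[0][0] <= t:
            when, _, fn = heapq.heappop(self._heap)
            self.clock.advance(max(self.clock.now, when))
            fn()
            self._dispatch()
        self.clock.advance(max(self.clock.now, t))
        self._dispatch()

    def run_until_idle(self) -> None:
        """Advance virtual time until every submitted job is terminal."""
        self._dispatch()
        while not all(j.terminal for j in self.jobs):
            if not self._heap:
                raise SimulationError(
                    "jobs pending but no future events: nothing can progress"
                )
            when, _, fn = heapq.heappop(self._heap)
            self.clock.advance(max(self.clock.now, when))
            fn()
            self._dispatch()

    def idle(self) -> bool:
        return all(j.terminal for j in self.jobs)

    # -- job scheduling -------------------------------------------------------

    def submit_job(
        self,
        work: Optional[Callable[[], object]] = None,
        duration: float = 0.0,
        prolog_bytes: int = 0,
        epilog_bytes: int = 0,
        queue: str = "exec.q",
        host_affinity: Optional[str] = None,
    ) -> Job:
        """Submit a work unit.

        Inputs are staged to the chosen worker before execution (staging.q),
        outputs harvested back to the master after (harvesting.q); the job
        occupies one exec slot between prolog completion and epilog start.
        """
        if queue not in self.queues:
            raise ValidationError(f"unknown queue {queue!r}")
        if self.closed:
            raise ValidationError(f"cluster {self.name!r} is terminated")
        job = Job(
            job_id=f"{self.name}-job-{next(self._job_counter):05d}",
            queue=queue, work=work, duration=duration,
            prolog_bytes=prolog_bytes, epilog_bytes=epilog_bytes,
            host_affinity=host_affinity, submit_time=self.clock.now,
        )
        self.jobs.append(job)
        self._dispatch()
        return job

    def _pick_host(self, job: Job) -> Optional[str]:
        hosts = self._exec_hosts()
        if job.host_affinity is not None:
            hosts = [h for h in hosts if h == job.host_affinity]
        hosts = [h for h in hosts if self._host_running(h)]
        if not hosts:
            return None
        return min(hosts, key=lambda h: (self._committed.get(h, 0), h))

    def _dispatch(self) -> None:
        now = self.clock.now
        for job in self.jobs:
            if job.state == "queued":
                host = self._pick_host(job)
                if host is None:
                    continue
                job.host = host
                self._committed[host] = self._committed.get(host, 0) + 1
                job.state = "prolog_wait" if job.prolog_bytes > 0 else "ready"
            if job.state == "prolog_wait":
                if self._usage_of(self.master, "staging.q") < \
                        self.queues["staging.q"].slots_per_host:
                    self._start_transfer(job, "staging.q",
                                         self.master, job.host,
                                         job.prolog_bytes, "prolog")
            if job.state == "ready":
                if self._usage_of(job.host, "exec.q") < \
                        self.queues["exec.q"].slots_per_host:
                    self._start_exec(job)
            if job.state == "harvest_wait":
                if self._usage_of(self.master, "harvesting.q") < \
                        self.queues["harvesting.q"].slots_per_host:
                    self._start_transfer(job, "harvesting.q",
                                         job.host, self.master,
                                         job.epilog_bytes, "epilog")

    def _start_transfer(self, job: Job, queue: str, src: str, dst: str,
                        nbytes: int, phase: str) -> None:
        now = self.clock.now
        end = now + self.cloud.transfer_hours(src, dst, nbytes)
        self._acquire(self.master, queue)
        self.transfer_log.append(
            TransferEvent(source=src, dest=dst, nbytes=nbytes,
                          start=now, end=end, queue=queue)
        )
        job.state = "prolog" if phase == "prolog" else "harvesting"

        def done() -> None:
            self._release(self.master, queue)
            if phase == "prolog":
                job.state = "ready"
            else:
                job.state = "done"
                job.finish_time = self.clock.now
                self._committed[job.host] -= 1

        self._schedule(end, done)

    def _start_exec(self, job: Job) -> None:
        now = self.clock.now
        self._acquire(job.host, "exec.q")
        job.state = "running"
        job.start_time = now
        end = now + job.duration

        def done() -> None:
            self._release(job.host, "exec.q")
            job.end_time = self.clock.now
            self.slot_log.append(SlotInterval(job.host, "exec.q", job.job_id,
                                              job.start_time, job.end_time))
            try:
                job.result = job.work() if job.work is not None else None
            except Exception as exc:  # worker failure halts the job, not the sim
                job.state = "failed"
                job.error = str(exc)
                job.finish_time = self.clock.now
                self._committed[job.host] -= 1
                return
            if job.epilog_bytes > 0:
                job.state = "harvest_wait"
            else:
                job.state = "done"
                job.finish_time = self.clock.now
                self._committed[job.host] -= 1

        self._schedule(end, done)

    def host_busy(self, host: str) -> bool:
        if self._usage_of(host, "exec.q") > 0:
            return True
        return any(
            not j.terminal and j.host == host for j in self.jobs
        )

    # -- peer-to-peer staging mirroring ---------------------------------------

    def mirror_staging(
        self,
        payload_bytes: int,
        per_host_limit: int = 1,
        p2p: bool = True,
        advance_clock: bool = True,
    ) -> StagingSchedule:
        """Mirror the staging directory from the master to every worker.

        Initially only the master is a source; with ``p2p`` each worker
        becomes an additional source the moment it holds a complete copy
        (and joins stagingsub.q). Pending recipients are matched to the
        least-loaded eligible source, ties broken by lowest instance id.
        No worker ever receives the payload twice.
        """
        if payload_bytes <= 0:
            raise ValidationError("payload must be > 0 bytes")
        if not self.workers:
            raise ValidationError("cluster has no workers to mirror to")
        start = self.clock.now
        outbound: Dict[str, int] = {}
        have: Set[str] = {self.master}
        pending: List[str] = sorted(self.workers)
        events: List[TransferEvent] = []
        # (time, seq, kind, payload): completions and boot-eligibility ticks
        heap: List[Tuple[float, int, str, Optional[tuple]]] = []
        seq = itertools.count(0)

        def eligible_at(worker: str) -> float:
            if self.local:
                return start
            return max(start, self.cloud.instances[worker].boot_at)

        for w in pending:
            t = eligible_at(w)
            if t > start:
                heapq.heappush(heap, (t, next(seq), "eligible", None))

        def sources() -> List[str]:
            pool = have if p2p else {self.master}
            return [s for s in pool
                    if outbound.get(s, 0) < per_host_limit]

        def try_start(now: float) -> None:
            started = True
            while started:
                started = False
                for w in list(pending):
                    if eligible_at(w) > now:
                        continue
                    free = sources()
                    if not free:
                        return
                    src = min(free, key=lambda s: (outbound.get(s, 0), s))
                    pending.remove(w)
                    outbound[src] = outbound.get(src, 0) + 1
                    end = now + self.cloud.transfer_hours(src, w, payload_bytes)
                    events.append(TransferEvent(src, w, payload_bytes,
                                                now, end, "stagingsub.q"))
                    heapq.heappush(heap, (end, next(seq), "done", (src, w)))
                    started = True

        try_start(start)
        while heap:
            now, _, kind, payload = heapq.heappop(heap)
            if kind == "done":
                src, w = payload
                outbound[src] -= 1
                have.add(w)
                self.queues["stagingsub.q"].member_hosts.add(w)
            try_start(now)

        end_time = max((e.end for e in events), default=start)
        if advance_clock:
            self.run_until(end_time)
        self.transfer_log.extend(events)
        return StagingSchedule(events=events, start=start,
                               completion_time=end_time - start)

    # -- reporting ------------------------------------------------------------

    def describe(self) -> str:
        lines = [
            f"cluster: {self.name}",
            f"master: {self.master}",
            f"workers: {len(self.workers)}",
            f"total_cpus: {self.total_cpus()}",
        ]
        for q in self.queues.values():
            lines.append(
                f"queue {q.name}: slots_per_host={q.slots_per_host} "
                f"hosts={len(q.member_hosts)}"
            )
        if not self.local:
            billed = sum(self.cloud.billed_hours(h)
                         for h in [self.master] + self.workers)
            lines.append(f"billed_instance_hours: {billed}")
        lines.append(f"virtual_time: {self.clock.now:.3f} h")
        return "\n".join(lines)


class ClusterService:
    """The cluster-management layer (add / resize / terminate / describe).

    Only ever touches the backend through its three provider calls.
    """

    def __init__(self, cloud: SimCloud, seed: int = 0, local_cpus: int = 4,
                 staging_slots: int = 2, harvesting_slots: int = 2) -> None:
        self.cloud = cloud
        self.local_cpus = local_cpus
        self.staging_slots = staging_slots
        self.harvesting_slots = harvesting_slots
        self._rng = random.Random((seed * 2654435761 + 97) % (2**31))
        self.clusters: Dict[str, Cluster] = {}
        self.clusters[LOCAL_HOST] = Cluster(
            self, LOCAL_HOST, credential=None, master=LOCAL_HOST, workers=[],
            itype=None, keypair=self._new_keypair(), local=True,
            local_cpus=local_cpus,
        )

    def _new_keypair(self) -> str:
        return f"{self._rng.getrandbits(128):032x}"

    def __getitem__(self, name: str) -> Cluster:
        try:
            return self.clusters[name]
        except KeyError:
            raise ValidationError(f"unknown cluster {name!r}") from None

    @property
    def local(self) -> Cluster:
        return self.clusters[LOCAL_HOST]

    def add_cluster(
        self, name: str, credential: str, itype: InstanceType, count: int
    ) -> Cluster:
        """Start a cluster of ``count`` instances; the first is the master."""
        if name in self.clusters:
            raise ValidationError(f"cluster name {name!r} already in use")
        if count < 1:
            raise ValidationError("count must be >= 1")
        ids = self.cloud.run_instances(credential, itype, count)
        cluster = Cluster(
            self, name, credential=credential, master=ids[0], workers=ids[1:],
            itype=itype, keypair=self._new_keypair(),
            staging_slots=self.staging_slots,
            harvesting_slots=self.harvesting_slots,
        )
        self.clusters[name] = cluster
        return cluster

    def add_instances(self, name: str, count: int) -> Cluster:
        """Grow a cluster; new instances register as workers on boot."""
        cluster = self[name]
        if count < 0:
            raise ValidationError("count must be >= 0")
        if count == 0:
            return cluster
        ids = self.cloud.run_instances(cluster.credential, cluster.itype, count)
        had_workers = bool(cluster.workers)
        cluster.workers.extend(ids)
        execq = cluster.queues["exec.q"]
        if not had_workers:
            execq.member_hosts.discard(cluster.master)
        execq.member_hosts.update(ids)
        for h in ids:
            cluster._wake_at_boot(h)
        return cluster

    def terminate_workers(self, name: str, hosts: Sequence[str]) -> None:
        """Release idle workers (idle-termination policy)."""
        cluster = self[name]
        hosts = [h for h in hosts if h in cluster.workers]
        busy = [h for h in hosts if cluster.host_busy(h)]
        if busy:
            raise ValidationError(f"cannot terminate busy workers: {busy}")
        if not hosts:
            return
        self.cloud.terminate_instances(cluster.credential, hosts)
        for h in hosts:
            cluster.workers.remove(h)
            for q in cluster.queues.values():
                q.member_hosts.discard(h)

    def terminate_cluster(self, name: str) -> None:
        """Terminate every instance of the cluster; idempotent."""
        cluster = self[name]
        if cluster.local:
            raise ValidationError("the 'local' cluster cannot be terminated")
        if not cluster.closed:
            self.cloud.terminate_instances(
                cluster.credential, [cluster.master] + cluster.workers
            )
            cluster.closed = True
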