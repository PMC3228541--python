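"""Cluster semantics: queues, slot limits, job waves and P2P mirroring."""

import math

import pytest

from elastiseq import (CapacityError, ClusterService, SimCloud,
                       ValidationError)
from elastiseq.cloudsim import MB
from elastiseq.provision import DEFAULT_CATALOG

from conftest import max_concurrency

C1 = DEFAULT_CATALOG["c1.xlarge"]


def make_service(provider_cap=200, latency=0.0, jitter=0.0, seed=0, **kw):
    cloud = SimCloud(seed=seed, provider_cap=provider_cap,
                     boot_latency=latency, boot_jitter=jitter)
    cloud.add_credential("cred", "acct")
    return ClusterService(cloud, seed=seed, **kw)


class TestClusterLifecycle:
    def test_single_instance_cluster_is_master_only(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 1)
        assert c.workers == []
        assert c.queues["exec.q"].member_hosts == {c.master}

    def test_first_instance_is_master_rest_are_workers(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 6)
        assert len(c.workers) == 5
        assert c.master not in c.workers
        assert c.exec_slot_total() == 40  # 5 workers x 8 CPUs

    def test_distinct_keypairs_per_cluster(self):
        svc = make_service()
        a = svc.add_cluster("a", "cred", C1, 1)
        b = svc.add_cluster("b", "cred", C1, 1)
        assert a.keypair != b.keypair

    def test_duplicate_name_rejected(self):
        svc = make_service()
        svc.add_cluster("c", "cred", C1, 1)
        with pytest.raises(ValidationError):
            svc.add_cluster("c", "cred", C1, 1)

    def test_local_cluster_is_both_master_and_worker(self):
        svc = make_service(local_cpus=4)
        local = svc.local
        assert local.master == "local"
        assert local.queues["exec.q"].member_hosts == {"local"}
        assert local.exec_slot_total() == 4

    def test_add_zero_instances_is_noop(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 2)
        svc.add_instances("c", 0)
        assert len(c.workers) == 1

    def test_grow_one_to_sixteen(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 1)
        svc.add_instances("c", 15)
        assert 1 + len(c.workers) == 16
        assert c.master not in c.queues["exec.q"].member_hosts

    def test_grow_to_160_reports_1280_cpus(self):
        svc = make_service(provider_cap=200)
        c = svc.add_cluster("c", "cred", C1, 60)
        svc.add_instances("c", 100)
        assert c.total_cpus() == 1280

    def test_cap_propagates_from_backend(self):
        svc = make_service(provider_cap=20)
        svc.add_cluster("c", "cred", C1, 18)
        with pytest.raises(CapacityError):
            svc.add_instances("c", 5)

    def test_terminate_cluster_is_idempotent_and_total(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 6)
        svc.terminate_cluster("c")
        svc.terminate_cluster("c")
        assert svc.cloud._active_count("acct") == 0


class TestJobScheduling:
    def test_trivial_job_runs_immediately(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 2)
        job = c.submit_job(work=lambda: "hi", duration=0.5)
        c.run_until_idle()
        assert job.state == "done" and job.result == "hi"
        assert svc.cloud.clock.now == pytest.approx(0.5)

    def test_80_jobs_on_40_slots_take_two_waves(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 6)  # 40 exec slots
        jobs = [c.submit_job(duration=1.0) for _ in range(80)]
        c.run_until_idle()
        assert all(j.state == "done" for j in jobs)
        assert svc.cloud.clock.now == pytest.approx(2.0)
        peak = max_concurrency([(j.start_time, j.end_time) for j in jobs])
        assert peak == 40

    def test_exec_slots_conserved_per_host_at_every_instant(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 4)  # 3 workers x 8 slots
        jobs = [c.submit_job(duration=0.3 + (i % 5) * 0.1) for i in range(60)]
        c.run_until_idle()
        by_host = {}
        for j in jobs:
            by_host.setdefault(j.host, []).append((j.start_time, j.end_time))
        for host, intervals in by_host.items():
            assert max_concurrency(intervals) <= 8

    def test_staging_queue_limits_concurrent_prologs(self):
        svc = make_service(staging_slots=2)
        c = svc.add_cluster("c", "cred", C1, 3)
        for _ in range(10):
            c.submit_job(duration=0.01, prolog_bytes=36 * MB)
        c.run_until_idle()
        prologs = [(e.start, e.end) for e in c.transfer_log
                   if e.queue == "staging.q"]
        assert len(prologs) == 10
        assert max_concurrency(prologs) <= 2

    def test_harvest_queue_limits_concurrent_epilogs(self):
        svc = make_service(harvesting_slots=2)
        c = svc.add_cluster("c", "cred", C1, 3)
        for _ in range(10):
            c.submit_job(duration=0.01, epilog_bytes=36 * MB)
        c.run_until_idle()
        epilogs = [(e.start, e.end) for e in c.transfer_log
                   if e.queue == "harvesting.q"]
        assert len(epilogs) == 10
        assert max_concurrency(epilogs) <= 2

    def test_failed_work_marks_job_failed(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 2)

        def boom():
            raise ValueError("broken input")

        job = c.submit_job(work=boom, duration=0.1)
        c.run_until_idle()
        assert job.state == "failed"
        assert "broken input" in job.error

    def test_jobs_wait_for_worker_boot(self):
        svc = make_service(latency=0.5)
        c = svc.add_cluster("c", "cred", C1, 2)
        job = c.submit_job(duration=0.1)
        c.run_until_idle()
        assert job.start_time >= 0.5


class TestMirrorStaging:
    PAYLOAD = 144 * MB  # one transfer = 1 h at 40 MB/s... scaled: 144e6/40e6/3600

    def transfer_hours(self, svc):
        return self.PAYLOAD / (svc.cloud.intra_bandwidth_mb_s * MB) / 3600

    def test_single_worker_single_transfer(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 2)
        sched = c.mirror_staging(self.PAYLOAD)
        assert len(sched.events) == 1
        assert sched.completion_time == pytest.approx(self.transfer_hours(svc))

    def test_seven_workers_three_rounds(self):
        """Binary dissemination: sources 1 -> 2 -> 4 serve 1, 2, 4 workers."""
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 8)
        sched = c.mirror_staging(self.PAYLOAD, per_host_limit=1)
        d = self.transfer_hours(svc)
        assert sched.completion_time == pytest.approx(3 * d)
        ends = sorted({round(e.end / d) for e in sched.events})
        assert ends == [1, 2, 3]

    @pytest.mark.parametrize("n_workers", [1, 2, 3, 4, 7, 8, 15, 16, 31])
    def test_dissemination_round_oracle(self, n_workers):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, n_workers + 1)
        sched = c.mirror_staging(self.PAYLOAD, per_host_limit=1)
        d = self.transfer_hours(svc)
        rounds = round(sched.completion_time / d)
        assert rounds == math.ceil(math.log2(n_workers + 1))

    def test_every_worker_served_exactly_once(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 21)
        sched = c.mirror_staging(self.PAYLOAD)
        dests = [e.dest for e in sched.events]
        assert sorted(dests) == sorted(c.workers)
        assert sched.total_bytes == 20 * self.PAYLOAD
        assert c.queues["stagingsub.q"].member_hosts == set(c.workers)

    def test_per_host_outbound_limit_holds(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 30)
        sched = c.mirror_staging(self.PAYLOAD, per_host_limit=2)
        by_source = {}
        for e in sched.events:
            by_source.setdefault(e.source, []).append((e.start, e.end))
        for intervals in by_source.values():
            assert max_concurrency(intervals) <= 2

    def test_p2p_beats_master_only_distribution(self):
        results = {}
        for p2p in (True, False):
            svc = make_service()
            c = svc.add_cluster("c", "cred", C1, 101)
            sched = c.mirror_staging(self.PAYLOAD, per_host_limit=1, p2p=p2p)
            results[p2p] = sched
        assert results[True].completion_time < results[False].completion_time
        assert results[True].peak_throughput_mb_s > \
            results[False].peak_throughput_mb_s
        # n >= 4 workers: P2P at least halves the master-only completion time
        d = self.transfer_hours(svc)
        assert results[True].completion_time <= \
            results[False].completion_time / 2 * 1.01
        assert results[True].completion_time == pytest.approx(
            math.ceil(math.log2(101)) * d)

    def test_p2p_speedup_for_small_clusters(self):
        """From four workers on, P2P is strictly faster than master-only and
        matches the dissemination oracle exactly; from six workers on it at
        least halves the master-only completion time."""
        d = None
        for n in (4, 5, 6, 9, 12):
            times = {}
            for p2p in (True, False):
                svc = make_service()
                c = svc.add_cluster("c", "cred", C1, n + 1)
                times[p2p] = c.mirror_staging(
                    self.PAYLOAD, per_host_limit=1, p2p=p2p).completion_time
                d = self.transfer_hours(svc)
            assert times[True] == pytest.approx(math.ceil(math.log2(n + 1)) * d)
            assert times[False] == pytest.approx(n * d)
            assert times[True] < times[False]
            if n >= 6:
                assert times[True] <= times[False] / 2 * 1.01

    def test_staggered_boots_delay_eligibility(self):
        svc = make_service(latency=0.1, jitter=0.05, seed=3)
        c = svc.add_cluster("c", "cred", C1, 6)
        sched = c.mirror_staging(self.PAYLOAD)
        boot = {w: svc.cloud.instances[w].boot_at for w in c.workers}
        for e in sched.events:
            assert e.start >= boot[e.dest]

    def test_no_workers_rejected(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 1)
        with pytest.raises(ValidationError):
            c.mirror_staging(self.PAYLOAD)

    def test_zero_payload_rejected(self):
        svc = make_service()
        c = svc.add_cluster("c", "cred", C1, 2)
        with pytest.raises(ValidationError):
            c.mirror_staging(0)
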