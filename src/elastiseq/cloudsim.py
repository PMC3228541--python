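"""A simulated elastic-cloud backend.

The simulator exposes exactly the three provider calls the orchestration layer
is allowed to use — ``run_instances``, ``terminate_instances`` and
``describe_instances`` — plus an append-only API call log so tests can assert
that nothing else is ever invoked. Time is a shared virtual clock in hours (no
wall-clock sleeps); instances boot after a configurable latency with uniform
per-instance jitter (reproducing staggered boots under a fixed seed), carry a
private ephemeral key->bytes disk that becomes inaccessible at termination,
and are billed in whole hours from launch.

Each account is bounded by a provider cap (default 20 concurrent instances);
a request that would exceed it is refused outright.

The network model is minimal: one point-to-point bandwidth for links inside
the cloud (default 40 MB/s) and a lower one for the desktop<->cloud link.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import CapacityError, ValidationError
from .provision import InstanceType, billed_instance_hours

MB = 1_000_000  # bytes


class VirtualClock:
    """Monotone virtual time in hours, shared by cloud and clusters."""

    def __init__(self) -> None:
        self.now: float = 0.0

    def advance(self, to: float) -> None:
        if to < self.now:
            raise ValidationError("virtual time cannot move backwards")
        self.now = to


@dataclass
class Credential:
    """An opaque alias for a cloud account; no real keys are stored."""

    name: str
    account: str


@dataclass
class CloudInstance:
    instance_id: str
    itype: InstanceType
    account: str
    launch_time: float            # virtual hours at run_instances
    boot_at: float                # pending -> running transition time
    termination_time: Optional[float] = None
    disk: Dict[str, bytes] = field(default_factory=dict)

    def state(self, now: float) -> str:
        if self.termination_time is not None and now >= self.termination_time:
            return "terminated"
        return "pending" if now < self.boot_at else "running"

    def uptime(self, now: float) -> float:
        end = now if self.termination_time is None else min(now, self.termination_time)
        return max(0.0, end - self.launch_time)

    def disk_put(self, now: float, key: str, value: bytes) -> None:
        self._check_alive(now)
        self.disk[key] = value

    def disk_get(self, now: float, key: str) -> bytes:
        self._check_alive(now)
        return self.disk[key]

    def _check_alive(self, now: float) -> None:
        if self.state(now) == "terminated":
            raise ValidationError(
                f"ephemeral disk of {self.instance_id} is gone (terminated)"
            )


class SimCloud:
    """The simulated provider. All state is deterministic under a seed."""

    def __init__(
        self,
        seed: int = 0,
        provider_cap: int = 20,
        boot_latency: float = 0.02,
        boot_jitter: float = 0.01,
        intra_bandwidth_mb_s: float = 40.0,
        wan_bandwidth_mb_s: float = 10.0,
        clock: Optional[VirtualClock] = None,
    ) -> None:
        self.clock = clock or VirtualClock()
        self.provider_cap = provider_cap
        self.boot_latency = boot_latency
        self.boot_jitter = boot_jitter
        self.intra_bandwidth_mb_s = intra_bandwidth_mb_s
        self.wan_bandwidth_mb_s = wan_bandwidth_mb_s
        self._rng = random.Random(seed)
        self._credentials: Dict[str, Credential] = {}
        self.instances: Dict[str, CloudInstance] = {}
        self._log: List[Tuple[str, dict]] = []
        self._id_counter = itertools.count(0)

    # -- credentials (a configuration action, not a provider API call) -------

    def add_credential(self, name: str, account: str) -> Credential:
        if name in self._credentials:
            raise ValidationError(f"credential {name!r} already registered")
        cred = Credential(name=name, account=account)
        self._credentials[name] = cred
        return cred

    def _resolve(self, credential: str) -> Credential:
        try:
            return self._credentials[credential]
        except KeyError:
            raise ValidationError(f"unknown credential {credential!r}") from None

    # -- the three provider calls --------------------------------------------

    def run_instances(
        self, credential: str, itype: InstanceType, count: int
    ) -> List[str]:
        self._log.append(("run_instances", {"credential": credential,
                                            "type": itype.name, "count": count}))
        cred = self._resolve(credential)
        if count < 1:
            raise ValidationError("count must be >= 1")
        active = self._active_count(cred.account)
        if active + count > self.provider_cap:
            raise CapacityError(
                f"account {cred.account!r} has {active} active instances; "
                f"starting {count} more would exceed the cap of {self.provider_cap}"
            )
        now = self.clock.now
        ids = []
        for _ in range(count):
            iid = f"i-{next(self._id_counter):06d}"
            boot_at = now + self.boot_latency + self._rng.uniform(0, self.boot_jitter)
            self.instances[iid] = CloudInstance(
                instance_id=iid, itype=itype, account=cred.account,
                launch_time=now, boot_at=boot_at,
            )
            ids.append(iid)
        return ids

    def terminate_instances(self, credential: str, ids: Sequence[str]) -> List[str]:
        self._log.append(("terminate_instances", {"credential": credential,
                                                  "ids": list(ids)}))
        self._resolve(credential)
        confirmed = []
        for iid in ids:
            inst = self.instances.get(iid)
            if inst is None:
                raise ValidationError(f"unknown instance id {iid!r}")
            if inst.termination_time is None:  # double-terminate is a no-op
                inst.termination_time = max(self.clock.now, inst.launch_time)
            confirmed.append(iid)
        return confirmed

    def describe_instances(
        self, credential: str, instance_ids: Optional[Sequence[str]] = None
    ) -> List[dict]:
        self._log.append(("describe_instances", {"credential": credential}))
        cred = self._resolve(credential)
        now = self.clock.now
        out = []
        for iid in sorted(self.instances):
            inst = self.instances[iid]
            if inst.account != cred.account:
                continue
            if instance_ids is not None and iid not in instance_ids:
                continue
            out.append({
                "instance_id": iid,
                "type": inst.itype.name,
                "state": inst.state(now),
                "launch_time": inst.launch_time,
                "uptime": inst.uptime(now),
            })
        return out

    # -- instrumentation and accounting --------------------------------------

    def api_call_log(self) -> List[Tuple[str, dict]]:
        return list(self._log)

    def _active_count(self, account: str) -> int:
        return sum(
            1 for inst in self.instances.values()
            if inst.account == account and inst.termination_time is None
        )

    def billed_hours(self, instance_id: str) -> int:
        inst = self.instances[instance_id]
        end = inst.termination_time
        if end is None:
            end = self.clock.now
        return billed_instance_hours(inst.launch_time, max(end, inst.launch_time))

    def total_cost(self) -> float:
        """Sum over all instances of billed hours times the type's hourly rate."""
        return sum(
            self.billed_hours(iid) * inst.itype.hourly_cost
            for iid, inst in self.instances.items()
        )

    def bandwidth_mb_s(self, src: str, dst: str) -> float:
        """Point-to-point bandwidth; 'local' denotes the desktop client."""
        if src == "local" or dst == "local":
            return self.wan_bandwidth_mb_s
        return self.intra_bandwidth_mb_s

    def transfer_hours(self, src: str, dst: str, nbytes: int) -> float:
        return (nbytes / MB) / self.bandwidth_mb_s(src, dst) / 3600.0
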