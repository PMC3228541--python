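"""Instance-type and cluster-size selection for a pipeline run.

The provisioning decision follows a fixed hierarchy:

1. hard-coded protocol assumptions (e.g. a short-read assembly step needs one
   high-memory instance; search-style protocols get a floor of five 8-CPU
   instances, i.e. 40 CPUs, before any estimate is consulted);
2. the cloud provider's account-wide instance cap (default 20);
3. the user's optional per-pipeline instance limit;

with the runtime estimate filling in the count between floor and caps:
count = max(min_instances, ceil(T / (R * cpus_per_instance))), which targets a
wall-clock of about R hours for a T CPU-hour workload.

Also here: the hourly billing model (instances are billed in whole hours from
boot, minimum one) and the idle-termination rule (an idle worker is released
shortly before its next whole-hour uptime boundary, so a billed hour is never
started just to idle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

from .errors import ValidationError

KNOWN_PROTOCOLS = ("search", "microbe", "sixteen_s", "metagenomics")


@dataclass(frozen=True)
class InstanceType:
    name: str
    cpus: int
    ram_gb: float
    hourly_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.cpus < 1 or self.ram_gb <= 0:
            raise ValidationError(f"invalid instance type {self.name!r}")


#: default catalog: an 8-CPU compute type, a high-memory type, and the
#: academic-cloud 4-CPU type. The 0.675/h figure is the per-instance rate
#: implied by a 160-instance cluster costing 108 currency-units per hour.
DEFAULT_CATALOG: Dict[str, InstanceType] = {
    "c1.xlarge": InstanceType("c1.xlarge", cpus=8, ram_gb=7.5, hourly_cost=0.675),
    "m2.xlarge": InstanceType("m2.xlarge", cpus=2, ram_gb=17.1, hourly_cost=0.5),
    "medium": InstanceType("medium", cpus=4, ram_gb=8.0, hourly_cost=0.0),
}


@dataclass(frozen=True)
class ProvisionPolicy:
    min_instances: int = 5           # floor for search-style (BLAST-backed) work
    provider_cap: int = 20           # provider's per-account instance limit
    user_cap: Optional[int] = None   # optional per-pipeline limit from config
    target_hours: float = 2.0        # R
    default_type: InstanceType = DEFAULT_CATALOG["c1.xlarge"]
    idle_window_hours: float = 0.1   # how close to the hour boundary "idle" fires

    def __post_init__(self) -> None:
        if self.min_instances < 1:
            raise ValidationError("min_instances must be >= 1")
        if self.provider_cap < 1 or (self.user_cap is not None and self.user_cap < 1):
            raise ValidationError("caps must be >= 1")
        if self.target_hours <= 0:
            raise ValidationError("target_hours must be > 0")

    @property
    def effective_cap(self) -> int:
        if self.user_cap is None:
            return self.provider_cap
        return min(self.provider_cap, self.user_cap)


@dataclass(frozen=True)
class ProvisionPlan:
    instance_type: InstanceType
    count: int                       # compute (worker) instances requested
    rationale: str                   # 'hardcoded' | 'estimated' | 'capped'

    @property
    def total_cpus(self) -> int:
        return self.count * self.instance_type.cpus


def plan_provisioning(
    protocol: str,
    t_est: float,
    policy: ProvisionPolicy,
    input_traits: Sequence[str] = (),
    catalog: Optional[Dict[str, InstanceType]] = None,
) -> ProvisionPlan:
    """Choose instance type and count for a protocol given the estimate T."""
    if protocol not in KNOWN_PROTOCOLS:
        raise ValidationError(f"unknown protocol {protocol!r}")
    if t_est < 0:
        raise ValidationError("t_est must be >= 0")
    catalog = DEFAULT_CATALOG if catalog is None else catalog
    if not catalog:
        raise ValidationError("empty instance catalog")

    # 1) hard-coded assumptions fire first: a short-read assembly needs RAM,
    #    not parallelism — one high-memory instance.
    if protocol == "microbe" and "illumina-assembly" in input_traits:
        if "m2.xlarge" not in catalog:
            raise ValidationError("catalog lacks the high-memory type m2.xlarge")
        return ProvisionPlan(catalog["m2.xlarge"], 1, rationale="hardcoded")

    itype = policy.default_type
    estimated = math.ceil(t_est / (policy.target_hours * itype.cpus))
    count = max(policy.min_instances, estimated)
    rationale = "estimated" if estimated > policy.min_instances else "hardcoded"

    # 2)+3) provider and user caps bound everything, including the floor: an
    #    explicit user limit below the floor still wins.
    if count > policy.effective_cap:
        count = policy.effective_cap
        rationale = "capped"
    return ProvisionPlan(itype, count, rationale=rationale)


def idle_termination_due(
    node_uptime: float, node_busy: bool, window: float = 0.1
) -> bool:
    """True iff an idle node sits within ``window`` hours of its next
    whole-hour uptime boundary (the moment just before a new billed hour)."""
    if node_uptime < 0:
        raise ValidationError("uptime must be >= 0")
    if node_busy:
        return False
    frac = node_uptime - math.floor(node_uptime)
    return (1.0 - frac) <= window + 1e-9


def billed_instance_hours(boot: float, terminate: float) -> int:
    """Whole billed hours between boot and termination; minimum 1."""
    if terminate < boot:
        raise ValidationError("terminate time precedes boot time")
    return max(1, math.ceil(terminate - boot))
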