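"""Datasets, analysis protocols and the pipeline configuration dialect.

Datasets are named lists of files registered with a cluster, each file carried
with its byte size and content checksum. Transfers between clusters are
idempotent in the rsync sense: only files whose checksum differs at the
destination are moved, so repeating a transfer moves zero bytes.

Protocols are versioned descriptions of an analysis (its parameter schema and
expected input slots). A pipeline is configured by a single sectioned
key=value file with four sections — [input], [params], [cluster], [output] —
'#' comments, and strict key checking (unknown keys are rejected). Templates
produced by :func:`describe_protocol` round-trip exactly through the dialect.

Every pipeline-output dataset records provenance: the producing pipeline id,
the protocol id and version, and the full parameter snapshot.
"""

from __future__ import annotations

import configparser
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

from .cloudsim import SimCloud
from .cluster import LOCAL_HOST, ClusterService
from .errors import ValidationError

PROTOCOL_SECTION_ORDER = ("input", "params", "cluster", "output")


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


@dataclass
class FileEntry:
    """One dataset member: either a real file on disk or in-memory content."""

    name: str
    nbytes: int
    sha256: str
    path: Optional[Path] = None
    content: Optional[bytes] = None

    @classmethod
    def from_path(cls, path: Union[str, Path]) -> "FileEntry":
        path = Path(path)
        if not path.is_file():
            raise ValidationError(f"no such file: {path}")
        data = path.read_bytes()
        return cls(name=path.name, nbytes=len(data), sha256=_sha256(data),
                   path=path)

    @classmethod
    def from_content(cls, name: str, content: bytes) -> "FileEntry":
        return cls(name=name, nbytes=len(content), sha256=_sha256(content),
                   content=content)

    def refreshed(self) -> "FileEntry":
        """Re-read size and checksum from disk (detects modified files)."""
        if self.path is not None:
            return FileEntry.from_path(self.path)
        return self

    def read(self) -> bytes:
        if self.content is not None:
            return self.content
        return self.path.read_bytes()


@dataclass
class Provenance:
    pipeline_id: str
    protocol: str
    version: str
    params: Dict[str, object] = field(default_factory=dict)


@dataclass
class Dataset:
    name: str
    files: List[FileEntry]
    tags: Dict[str, str] = field(default_factory=dict)
    home_cluster: str = LOCAL_HOST
    producer: Optional[Provenance] = None

    def __post_init__(self) -> None:
        if not self.files:
            raise ValidationError(f"dataset {self.name!r} has no files")

    @property
    def nbytes(self) -> int:
        return sum(f.nbytes for f in self.files)


@dataclass(frozen=True)
class TransferReport:
    dataset: str
    src: str
    dst: str
    bytes_moved: int
    files_moved: List[str]
    elapsed_hours: float


# -- protocol schemas ---------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    name: str
    type: type
    default: object = None
    required: bool = False


@dataclass(frozen=True)
class ProtocolSpec:
    id: str
    version: str
    input_slots: Sequence[str]
    parameters: Sequence[ParamSpec]

    def param(self, name: str) -> ParamSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise ValidationError(f"protocol {self.id!r} has no parameter {name!r}")


_COMMON_PARAMS = (
    ParamSpec("seed", int, 0),
    ParamSpec("target_hours", float, 2.0),
    ParamSpec("kmer_size", int, 11),
    ParamSpec("alphabet", str, "dna"),
    ParamSpec("cost_alpha", float, 0.05),
    ParamSpec("cost_beta", float, 2e-4),
    ParamSpec("cpu_hours", float, None),  # optional user-supplied estimate
    ParamSpec("partition_mode", str, "corrected"),
)

PROTOCOLS: Dict[str, ProtocolSpec] = {
    "search": ProtocolSpec("search", "1.0", ("query", "reference"),
                           _COMMON_PARAMS),
    "metagenomics": ProtocolSpec("metagenomics", "1.0", ("query", "reference"),
                                 _COMMON_PARAMS),
    "microbe": ProtocolSpec("microbe", "1.0", ("reads",), _COMMON_PARAMS),
    "sixteen_s": ProtocolSpec("sixteen_s", "1.0", ("reads",), _COMMON_PARAMS),
}

_CLUSTER_KEYS = {
    "credential": ParamSpec("credential", str, "default"),
    "mode": ParamSpec("mode", str, "local"),
    "user_cap": ParamSpec("user_cap", int, None),
    "instance_type": ParamSpec("instance_type", str, "c1.xlarge"),
}
_OUTPUT_KEYS = {
    "dataset": ParamSpec("dataset", str, "output"),
    "dir": ParamSpec("dir", str, None),
}


@dataclass
class PipelineConfig:
    protocol: str
    inputs: Dict[str, str] = field(default_factory=dict)
    params: Dict[str, object] = field(default_factory=dict)
    cluster: Dict[str, object] = field(default_factory=dict)
    output: Dict[str, object] = field(default_factory=dict)


def describe_protocol(protocol_id: str) -> PipelineConfig:
    """A fully-defaulted configuration template for a protocol."""
    try:
        spec = PROTOCOLS[protocol_id]
    except KeyError:
        raise ValidationError(f"unknown protocol {protocol_id!r}") from None
    return PipelineConfig(
        protocol=spec.id,
        inputs={slot: "" for slot in spec.input_slots},
        params={p.name: p.default for p in spec.parameters},
        cluster={k: s.default for k, s in _CLUSTER_KEYS.items()},
        output={k: s.default for k, s in _OUTPUT_KEYS.items()},
    )


def _fmt(value: object) -> str:
    return repr(value) if isinstance(value, float) else str(value)


def serialize_config(config: PipelineConfig) -> str:
    """Serialize to the sectioned key=value dialect (None values omitted)."""
    out = io.StringIO()
    out.write("# pipeline configuration\n")
    sections = {
        "input": dict(config.inputs),
        "params": {"protocol": config.protocol, **config.params},
        "cluster": config.cluster,
        "output": config.output,
    }
    for section in PROTOCOL_SECTION_ORDER:
        out.write(f"[{section}]\n")
        for key, value in sections[section].items():
            if value is None:
                continue
            out.write(f"{key}={_fmt(value)}\n")
        out.write("\n")
    return out.getvalue()


def _convert(spec: ParamSpec, raw: str):
    try:
        if spec.type is int:
            return int(raw)
        if spec.type is float:
            return float(raw)
        return raw
    except ValueError:
        raise ValidationError(
            f"parameter {spec.name!r}: cannot parse {raw!r} as {spec.type.__name__}"
        ) from None


def parse_config(text: str) -> PipelineConfig:
    """Parse and validate a pipeline configuration from the dialect."""
    cp = configparser.ConfigParser(interpolation=None, comment_prefixes=("#",))
    cp.optionxform = str  # keys are case-sensitive
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ValidationError(f"malformed configuration: {exc}") from exc
    for section in cp.sections():
        if section not in PROTOCOL_SECTION_ORDER:
            raise ValidationError(f"unknown section [{section}]")
    raw_params = dict(cp["params"]) if cp.has_section("params") else {}
    protocol_id = raw_params.pop("protocol", None)
    if protocol_id is None:
        raise ValidationError("missing 'protocol' key in [params]")
    spec = PROTOCOLS.get(protocol_id)
    if spec is None:
        raise ValidationError(f"unknown protocol {protocol_id!r}")

    inputs = dict(cp["input"]) if cp.has_section("input") else {}
    for slot in inputs:
        if slot not in spec.input_slots:
            raise ValidationError(
                f"protocol {protocol_id!r} has no input slot {slot!r}"
            )
    params: Dict[str, object] = {p.name: p.default for p in spec.parameters}
    for key, raw in raw_params.items():
        params[key] = _convert(spec.param(key), raw)

    cluster = {k: s.default for k, s in _CLUSTER_KEYS.items()}
    for key, raw in (dict(cp["cluster"]) if cp.has_section("cluster") else {}).items():
        if key not in _CLUSTER_KEYS:
            raise ValidationError(f"unknown [cluster] key {key!r}")
        cluster[key] = _convert(_CLUSTER_KEYS[key], raw)
    if cluster["mode"] not in ("local", "cloud"):
        raise ValidationError(f"mode must be 'local' or 'cloud', got {cluster['mode']!r}")

    output = {k: s.default for k, s in _OUTPUT_KEYS.items()}
    for key, raw in (dict(cp["output"]) if cp.has_section("output") else {}).items():
        if key not in _OUTPUT_KEYS:
            raise ValidationError(f"unknown [output] key {key!r}")
        output[key] = _convert(_OUTPUT_KEYS[key], raw)

    return PipelineConfig(protocol=protocol_id, inputs=inputs, params=params,
                          cluster=cluster, output=output)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    return parse_config(Path(path).read_text())


# -- the dataset registry -----------------------------------------------------

class Registry:
    """Named datasets per cluster, with idempotent inter-cluster transfer."""

    def __init__(self, cloud: SimCloud, clusters: ClusterService) -> None:
        self.cloud = cloud
        self.clusters = clusters
        self._datasets: Dict[tuple, Dataset] = {}

    def add_dataset(
        self,
        cluster: str,
        name: str,
        files: Sequence[Union[str, Path, FileEntry]],
        tags: Optional[Mapping[str, str]] = None,
        producer: Optional[Provenance] = None,
    ) -> Dataset:
        self.clusters[cluster]  # must exist
        if (cluster, name) in self._datasets:
            raise ValidationError(
                f"dataset {name!r} already registered on cluster {cluster!r}"
            )
        entries = [
            f if isinstance(f, FileEntry) else FileEntry.from_path(f)
            for f in files
        ]
        ds = Dataset(name=name, files=entries, tags=dict(tags or {}),
                     home_cluster=cluster, producer=producer)
        self._datasets[(cluster, name)] = ds
        return ds

    def get(self, name: str, cluster: str) -> Dataset:
        try:
            return self._datasets[(cluster, name)]
        except KeyError:
            raise ValidationError(
                f"no dataset {name!r} on cluster {cluster!r}"
            ) from None

    def has(self, name: str, cluster: str) -> bool:
        return (cluster, name) in self._datasets

    def transfer_dataset(self, name: str, src: str, dst: str) -> TransferReport:
        """Move a dataset between clusters; unchanged files cost zero bytes."""
        ds = self.get(name, src)
        self.clusters[dst]
        fresh = [f.refreshed() for f in ds.files]
        existing = self._datasets.get((dst, name))
        have = {f.name: f.sha256 for f in existing.files} if existing else {}
        moved = [f for f in fresh if have.get(f.name) != f.sha256]
        nbytes = sum(f.nbytes for f in moved)
        src_end = LOCAL_HOST if src == LOCAL_HOST else "cloud"
        dst_end = LOCAL_HOST if dst == LOCAL_HOST else "cloud"
        hours = self.cloud.transfer_hours(src_end, dst_end, nbytes) if nbytes else 0.0
        self.cloud.clock.advance(self.cloud.clock.now + hours)
        self._datasets[(dst, name)] = Dataset(
            name=name, files=fresh, tags=dict(ds.tags), home_cluster=dst,
            producer=ds.producer,
        )
        return TransferReport(dataset=name, src=src, dst=dst,
                              bytes_moved=nbytes,
                              files_moved=[f.name for f in moved],
                              elapsed_hours=hours)

    def describe_dataset(self, name: str, cluster: str) -> Dict[str, object]:
        ds = self.get(name, cluster)
        meta: Dict[str, object] = {
            "name": ds.name,
            "cluster": cluster,
            "files": [{"name": f.name, "bytes": f.nbytes, "sha256": f.sha256}
                      for f in ds.files],
            "bytes": ds.nbytes,
            "tags": dict(ds.tags),
        }
        if ds.producer is not None:
            meta["producer"] = {
                "pipeline_id": ds.producer.pipeline_id,
                "protocol": ds.producer.protocol,
                "version": ds.producer.version,
                "params": dict(ds.producer.params),
            }
        return meta


@dataclass(frozen=True)
class MirrorResult:
    path: Path
    bytes_moved: int


def mirror_reference_once(
    name: str, source: Union[str, Path], local_store: Union[str, Path]
) -> MirrorResult:
    """Fetch a reference file into a local store at most once.

    The first call copies the file and records its checksum; later calls
    return the cached path moving zero bytes. A cache whose checksum no
    longer matches the recorded one (corruption) triggers a re-fetch.
    """
    src = str(source)
    if src.startswith("file://"):
        src = src[len("file://"):]
    src_path = Path(src)
    if not src_path.is_file():
        raise ValidationError(f"unresolvable reference source: {source}")
    store = Path(local_store)
    store.mkdir(parents=True, exist_ok=True)
    target = store / name
    sidecar = store / f"{name}.sha256"
    if target.is_file() and sidecar.is_file():
        if _sha256(target.read_bytes()) == sidecar.read_text().strip():
            return MirrorResult(path=target, bytes_moved=0)
    data = src_path.read_bytes()
    target.write_bytes(data)
    sidecar.write_text(_sha256(data) + "\n")
    return MirrorResult(path=target, bytes_moved=len(data))
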