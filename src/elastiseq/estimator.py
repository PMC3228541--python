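"""k-mer profile runtime estimation for parallel sequence-search workloads.

A search workload's CPU cost depends on how much of the query's k-mer content
is represented in the reference database. The estimator therefore works on
k-mer profiles: the multiset of length-k words of a sequence set, counted over
both strands for DNA (k = 11 for DNA, k = 3 for protein by default).

The timing model is deliberately simple and swappable: an overlap statistic

    x = sum_w  query_count(w) * reference_weight(w)

(the dot product of query k-mer counts with per-k-mer reference weights,
where the default weights are the reference profile's relative frequencies)
feeds a linear model

    T = alpha + beta * x     [CPU-hours]

whose coefficients are calibrated by ordinary least squares on timed runs,
with the fixed overhead alpha clamped at zero (a negative fixed cost is
meaningless). Doubling every query count exactly doubles the overlap term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np

from .errors import ValidationError
from .seqio import SequenceRecord, reverse_complement

DEFAULT_K = {"dna": 11, "protein": 3}
#: residues whose presence invalidates a window (ambiguity codes)
_SKIP = {"dna": "N", "protein": "X"}


@dataclass
class KmerProfile:
    """Counts of length-k words of a sequence set.

    For DNA profiles built with ``include_revcomp`` the counts cover each
    sequence and its reverse complement, making the profile strand-symmetric.
    """

    k: int
    alphabet: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def scaled(self, factor: int) -> "KmerProfile":
        return KmerProfile(
            self.k, self.alphabet, {w: c * factor for w, c in self.counts.items()}
        )


@dataclass
class RuntimeModel:
    """Calibrated coefficients mapping a query profile to CPU-hours."""

    k: int
    alphabet: str
    reference_weights: Dict[str, float]
    alpha: float = 0.0  # fixed overhead, CPU-hours
    beta: float = 0.0   # CPU-hours per unit of profile overlap

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha (fixed overhead) must be >= 0")


@dataclass(frozen=True)
class CalibrationRun:
    """One timed run: the overlap statistic x and the measured CPU-hours."""

    query_profile_overlap: float
    observed_cpu_hours: float

    def __post_init__(self) -> None:
        if self.query_profile_overlap < 0 or self.observed_cpu_hours < 0:
            raise ValidationError("calibration values must be non-negative")


def _count_windows(counts: Dict[str, int], seq: str, k: int, skip: str) -> None:
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if skip in word:
            continue
        counts[word] = counts.get(word, 0) + 1


def compute_profile(
    records: Iterable[SequenceRecord],
    k: int,
    alphabet: str = "dna",
    include_revcomp: bool = True,
) -> KmerProfile:
    """Sliding-window k-mer counts over a record set.

    Windows containing an ambiguity code (N for DNA, X for protein) are
    skipped; sequences shorter than k contribute nothing. Reverse-complement
    counting is only meaningful (and only allowed) for DNA.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if alphabet not in _SKIP:
        raise ValidationError(f"unknown alphabet {alphabet!r}")
    if include_revcomp and alphabet != "dna":
        raise ValidationError("reverse-complement counting requires DNA")
    skip = _SKIP[alphabet]
    counts: Dict[str, int] = {}
    for rec in records:
        seq = rec.seq.upper()
        _count_windows(counts, seq, k, skip)
        if include_revcomp:
            _count_windows(counts, reverse_complement(seq), k, skip)
    return KmerProfile(k=k, alphabet=alphabet, counts=counts)


def reference_weights(profile: KmerProfile) -> Dict[str, float]:
    """Per-k-mer weights from a reference profile: its relative frequencies."""
    total = profile.total
    if total == 0:
        return {}
    return {w: c / total for w, c in profile.counts.items()}


def overlap_statistic(query: KmerProfile, weights: Mapping[str, float]) -> float:
    """x = sum_w query.counts[w] * weights[w]; linear and monotone in counts."""
    return float(sum(c * weights.get(w, 0.0) for w, c in query.counts.items()))


def fit_model(
    runs: Sequence[CalibrationRun],
    k: int,
    reference_weights: Mapping[str, float],
    alphabet: str = "dna",
) -> RuntimeModel:
    """Least-squares fit of T ~ alpha + beta * x over calibration runs.

    Requires at least two runs with distinct x. If the unconstrained intercept
    comes out negative it is clamped to zero and beta refit through the origin.
    """
    if len(runs) < 2:
        raise ValidationError("need at least 2 calibration runs")
    x = np.array([r.query_profile_overlap for r in runs], dtype=float)
    t = np.array([r.observed_cpu_hours for r in runs], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("calibration runs must span distinct overlap values")
    beta, alpha = np.polyfit(x, t, 1)
    if alpha < 0:
        alpha = 0.0
        beta = float(np.dot(x, t) / np.dot(x, x))
    return RuntimeModel(
        k=k,
        alphabet=alphabet,
        reference_weights=dict(reference_weights),
        alpha=float(alpha),
        beta=float(beta),
    )


def predict_cpu_hours(model: RuntimeModel, query: KmerProfile) -> float:
    """Estimated CPU-hours T = alpha + beta * overlap(query); never negative."""
    if query.k != model.k:
        raise ValidationError(f"profile k={query.k} does not match model k={model.k}")
    if query.alphabet != model.alphabet:
        raise ValidationError(
            f"profile alphabet {query.alphabet!r} does not match model "
            f"{model.alphabet!r}"
        )
    x = overlap_statistic(query, model.reference_weights)
    return max(0.0, model.alpha + model.beta * x)


# -- serialization ------------------------------------------------------------
#
# Profiles and models are stored as a small line-oriented text format:
# '#'-prefixed comments, 'key=value' header lines, then one '<kmer>\t<value>'
# line per word. Documented in docs/methods.md.

def save_profile(profile: KmerProfile, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = [f"k={profile.k}", f"alphabet={profile.alphabet}", "type=profile"]
    for w in sorted(profile.counts):
        lines.append(f"{w}\t{profile.counts[w]}")
    path.write_text("\n".join(lines) + "\n")
    return path


def save_model(model: RuntimeModel, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = [
        f"k={model.k}",
        f"alphabet={model.alphabet}",
        "type=model",
        f"alpha={model.alpha!r}",
        f"beta={model.beta!r}",
    ]
    for w in sorted(model.reference_weights):
        lines.append(f"{w}\t{model.reference_weights[w]!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_kv_file(path: Union[str, Path]):
    header: Dict[str, str] = {}
    body: List[tuple] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line and "\t" not in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
        else:
            word, _, val = line.partition("\t")
            body.append((word, val))
    return header, body


def load_profile(path: Union[str, Path]) -> KmerProfile:
    header, body = _parse_kv_file(path)
    if header.get("type") != "profile":
        raise ValidationError(f"{path}: not a k-mer profile file")
    return KmerProfile(
        k=int(header["k"]),
        alphabet=header["alphabet"],
        counts={w: int(v) for w, v in body},
    )


def load_model(path: Union[str, Path]) -> RuntimeModel:
    header, body = _parse_kv_file(path)
    if header.get("type") != "model":
        raise ValidationError(f"{path}: not a runtime-model file")
    return RuntimeModel(
        k=int(header["k"]),
        alphabet=header["alphabet"],
        reference_weights={w: float(v) for w, v in body},
        alpha=float(header["alpha"]),
        beta=float(header["beta"]),
    )
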