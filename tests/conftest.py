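"""Shared fixtures and oracles for the test suite.

All sequence inputs are synthetic and generated at test time; nothing is read
from outside the repository.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

import pytest

from elastiseq import (Session, SyntheticSpec, generate_synthetic, write_fasta)
from elastiseq.registry import describe_protocol


def brute_force_profile(seqs: Iterable[str], k: int, alphabet: str = "dna",
                        include_revcomp: bool = True) -> dict:
    """Independent sliding-window k-mer oracle (naive enumeration).

    Deliberately written without reusing any package internals: the reverse
    complement is built from an explicit base map, and windows are collected
    by direct slicing.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    skip = "N" if alphabet == "dna" else "X"
    counts: dict = {}
    for seq in seqs:
        seq = seq.upper()
        strands = [seq]
        if include_revcomp:
            strands.append("".join(comp[b] for b in reversed(seq)))
        for strand in strands:
            for i in range(len(strand) - k + 1):
                w = strand[i:i + k]
                if skip not in w:
                    counts[w] = counts.get(w, 0) + 1
    return counts


def max_concurrency(intervals: List[Tuple[float, float]]) -> int:
    """Peak number of overlapping (start, end) intervals; ends are exclusive."""
    events = []
    for start, end in intervals:
        events.append((start, 1))
        events.append((end, -1))
    events.sort(key=lambda e: (e[0], e[1]))  # end (-1) before start (+1) at ties
    peak = level = 0
    for _, delta in events:
        level += delta
        peak = max(peak, level)
    return peak


@pytest.fixture
def fasta_pair(tmp_path):
    """A small synthetic (query, reference) FASTA pair on disk."""
    query = generate_synthetic(SyntheticSpec(40, 150, 300, seed=11))
    reference = generate_synthetic(SyntheticSpec(15, 400, 700, seed=12))
    qpath = write_fasta(query, tmp_path / "query.fasta")
    rpath = write_fasta(reference, tmp_path / "reference.fasta")
    return qpath, rpath


@pytest.fixture
def search_session(fasta_pair):
    """A session with the query/reference pair registered on 'local'."""
    qpath, rpath = fasta_pair
    session = Session(seed=7)
    session.registry.add_dataset("local", "query-set", [qpath])
    session.registry.add_dataset("local", "ref-db", [rpath])
    return session


def search_config(mode: str = "local", **params):
    cfg = describe_protocol("search")
    cfg.inputs = {"query": "query-set", "reference": "ref-db"}
    cfg.cluster["mode"] = mode
    cfg.params.update(params)
    return cfg
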