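"""Multi-FASTA reading, writing and synthetic sequence generation.

All test inputs in this package are synthetic: :func:`generate_synthetic`
produces reproducible random sequence sets from a :class:`SyntheticSpec`, so no
external data is ever required. Reading goes through Biopython's FASTA parser
(tolerant of multi-line bodies and CRLF); writing is canonical — 60-column
wrapped, LF-only — so that identical record lists always serialize to identical
bytes.

Only FASTA is supported. Other raw-read formats (SFF, FASTQ, QUAL) are out of
scope and are rejected with a clear validation error.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio import SeqIO

from .errors import ValidationError

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: residues drawn by the synthetic generator (no ambiguity codes)
DNA_DRAW = "ACGT"
PROTEIN_DRAW = "ACDEFGHIKLMNPQRSTVWY"

_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class SequenceRecord:
    """A single FASTA record.

    ``id`` is the header token up to the first whitespace; the remainder of the
    header line, if any, is kept in ``description``.
    """

    id: str
    seq: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        if self.alphabet not in _ALPHABETS:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = _ALPHABETS[self.alphabet]
        bad = set(self.seq.upper()) - allowed
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains illegal {self.alphabet} "
                f"residue(s): {''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic multi-FASTA fixture.

    Identical specs (including the seed) always yield byte-identical FASTA.
    """

    n_records: int
    length_min: int
    length_max: int
    alphabet: str = "dna"
    seed: int = 0
    id_prefix: str = "seq"

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValidationError("n_records must be >= 0")
        if self.length_min < 1 or self.length_min > self.length_max:
            raise ValidationError(
                f"invalid length bounds ({self.length_min}, {self.length_max})"
            )
        if self.alphabet not in _ALPHABETS:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")


def read_fasta(path: Union[str, Path], alphabet: str = "dna") -> List[SequenceRecord]:
    """Read an ordered list of records from a multi-FASTA file.

    Multi-line bodies are concatenated and CRLF line endings accepted. Raises
    :class:`ValidationError` for an empty file, a malformed header, or an
    illegal residue (naming the offending record).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    records: List[SequenceRecord] = []
    try:
        with open(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                records.append(
                    SequenceRecord(
                        id=rec.id, seq=str(rec.seq), alphabet=alphabet,
                        description=desc,
                    )
                )
    except ValueError as exc:  # Biopython's malformed-FASTA signal
        raise ValidationError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        raise ValidationError(f"{path}: empty or contains no FASTA records")
    return records


def format_fasta(records: Iterable[SequenceRecord], wrap: int = 60) -> str:
    """Serialize records to canonical FASTA text (LF-only, wrapped bodies)."""
    if wrap < 1:
        raise ValidationError("wrap must be >= 1")
    out: List[str] = []
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        out.append(f">{header}\n")
        for i in range(0, len(rec.seq), wrap):
            out.append(rec.seq[i : i + wrap] + "\n")
    return "".join(out)


def write_fasta(
    records: Sequence[SequenceRecord], path: Union[str, Path], wrap: int = 60
) -> Path:
    """Write records to ``path`` in canonical form; returns the path."""
    path = Path(path)
    path.write_text(format_fasta(records, wrap=wrap))
    return path


def generate_synthetic(spec: SyntheticSpec) -> List[SequenceRecord]:
    """Generate random sequence records; a pure function of the spec."""
    rng = random.Random(spec.seed)
    draw = DNA_DRAW if spec.alphabet == "dna" else PROTEIN_DRAW
    width = max(4, len(str(max(spec.n_records - 1, 0))))
    records = []
    for i in range(spec.n_records):
        length = rng.randint(spec.length_min, spec.length_max)
        seq = "".join(rng.choice(draw) for _ in range(length))
        records.append(
            SequenceRecord(
                id=f"{spec.id_prefix}_{i:0{width}d}", seq=seq, alphabet=spec.alphabet
            )
        )
    return records


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N<->N); an involution."""
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"reverse_complement requires DNA input; illegal residue(s): "
            f"{''.join(sorted(bad))}"
        )
    return seq.translate(_COMPLEMENT)[::-1]
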