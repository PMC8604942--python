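"""Sequence primitives shared by every pipeline stage.

Nucleotide sequences are plain upper-case strings over ``{A,C,G,T,N,-}``
carried in a light :class:`NucSequence` wrapper; codon alignments are
validated collections of equal-length rows anchored at column 0. All
coordinates are 0-based half-open intervals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
ALPHABET = set("ACGTN-")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
#: the 61 sense codons of the standard nuclear code, lexicographic order
SENSE_CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SequenceError(ValueError):
    """Raised on malformed sequence input."""


@dataclass(frozen=True)
class NucSequence:
    """A labelled nucleotide sequence over ``{A,C,G,T,N,-}``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def ungap_with_map(self) -> tuple[str, np.ndarray]:
        """Strip gaps, returning the gap-free string and, for each of its
        positions, the original (alignment-column) coordinate."""
        arr = np.frombuffer(self.residues.encode(), dtype="S1")
        keep = arr != b"-"
        return self.residues.translate({ord("-"): None}), np.flatnonzero(keep)


def reverse_complement(seq: str | NucSequence) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Gap or unknown characters are rejected: the operation is only defined
    on (sub)sequences that have been ungapped first.
    """
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    try:
        return "".join(_COMPLEMENT[ch] for ch in reversed(s))
    except KeyError as exc:
        raise SequenceError(f"cannot reverse-complement character {exc.args[0]!r}")


def translate(seq: str | NucSequence, frame_offset: int = 0) -> str:
    """Translate with the standard nuclear code.

    The trailing partial codon is dropped, stops render as ``*`` and any
    codon containing ``N`` renders as ``X``.
    """
    if frame_offset not in (0, 1, 2):
        raise SequenceError("frame_offset must be 0, 1 or 2")
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    out = []
    for i in range(frame_offset, len(s) - 2, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif "-" in codon:
            raise SequenceError(f"gap inside codon {codon!r} at offset {i}")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TO_AA[codon])
    return "".join(out)


class GranthamMatrix:
    """Grantham's (1974) amino-acid physicochemical distance table.

    Integer distances over the 20 standard amino acids, range 5-215 with
    mean ~100; symmetric with a zero diagonal. Shipped as a data file and
    validated at load time.
    """

    def __init__(self, distances: dict[tuple[str, str], int]):
        self._d = distances
        self._validate()

    @classmethod
    def load(cls) -> "GranthamMatrix":
        text = (
            importlib.resources.files("tswitch.data")
            .joinpath("grantham.tsv")
            .read_text()
        )
        lines = [ln.split("\t") for ln in text.rstrip().splitlines()]
        header = lines[0][1:]
        d: dict[tuple[str, str], int] = {}
        for row in lines[1:]:
            a = row[0]
            for b, val in zip(header, row[1:]):
                d[(a, b)] = int(val)
        return cls(d)

    def _validate(self) -> None:
        aas = sorted({a for a, _ in self._d})
        assert len(aas) == 20, "expected 20 amino acids"
        offdiag = []
        for a in aas:
            assert self._d[(a, a)] == 0, "diagonal must be zero"
            for b in aas:
                assert self._d[(a, b)] == self._d[(b, a)], "matrix must be symmetric"
                if a != b:
                    offdiag.append(self._d[(a, b)])
        assert min(offdiag) == 5 and max(offdiag) == 215, (
            "Grantham distances must span 5-215"
        )

    def distance(self, aa1: str, aa2: str) -> int:
        key = (aa1.upper(), aa2.upper())
        if key not in self._d:
            raise SequenceError(f"Grantham distance undefined for pair {key}")
        return self._d[key]

    def __call__(self, aa1: str, aa2: str) -> int:
        return self.distance(aa1, aa2)


_GRANTHAM: GranthamMatrix | None = None


def grantham_distance(aa1: str, aa2: str) -> int:
    """Distance between two standard amino acids (stop/X rejected)."""
    global _GRANTHAM
    if _GRANTHAM is None:
        _GRANTHAM = GranthamMatrix.load()
    return _GRANTHAM.distance(aa1, aa2)


@dataclass
class CodonAlignment:
    """A gapped, in-frame codon alignment (frame anchored at column 0)."""

    taxa: list[NucSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.taxa:
            n = len(self.taxa[0])
            if any(len(t) != n for t in self.taxa):
                raise SequenceError("alignment rows differ in length")
            if n % 3 != 0:
                raise SequenceError(f"alignment length {n} not divisible by 3")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.taxa[0]) if self.taxa else 0

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.taxa]

    def __iter__(self) -> Iterator[NucSequence]:
        return iter(self.taxa)

    def row(self, taxon: str) -> NucSequence:
        for t in self.taxa:
            if t.id == taxon:
                return t
        raise KeyError(taxon)

    def has_internal_stop(self) -> bool:
        """True if any row carries an in-frame stop codon before its last codon."""
        for t in self.taxa:
            aa = translate(t.ungapped)
            if aa and "*" in aa[:-1]:
                return True
        return False

    def check_no_internal_stops(self) -> None:
        if self.has_internal_stop():
            raise SequenceError("alignment contains an internal (immature) stop codon")

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        return cls(taxa=read_fasta(path))

    def to_fasta(self, path) -> None:
        write_fasta(self.taxa, path)


def read_fasta(path) -> list[NucSequence]:
    return [
        NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[NucSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")
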