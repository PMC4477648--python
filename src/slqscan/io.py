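"""FASTA input/output and the bundled oligonucleotide fixtures.

Sequences are normalized on input: uppercased (soft-masked lowercase bases are
scanned like any other) and restricted to the alphabet {A, C, G, T, N}.  Any
other character is a parse error naming the offending line.

The bundled oligos are the fourteen printed SLQS oligonucleotides used in the
NMR and mutational studies, keyed by their SLQS IDs: ten representative hits
from MYT1L, ARHGAP31, RICTOR, PIM1, ELFN1, MYBL1, CCNY, RET, MDK and HIC1
loci, the MYO9B mutation pair (wild type and its six-nucleotide deletion
mutant, the deletion applied), and the two BMP8A single-nucleotide
polymorphs (the bracketed SNP allele resolved into each plain sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "bundled_oligos",
    "NMR_STUDY_IDS",
    "MUTATION_STUDY_IDS",
]

_ALPHABET = set("ACGTN")


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N}, uppercased."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(f"record {self.name!r} contains illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


def _find_bad_line(path, bad_chars: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return lineno
    return 0


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a (wrapped or unwrapped, multi-record) FASTA file.

    Sequences are uppercased; record order is preserved.  Illegal characters
    raise :class:`FastaParseError` naming the line number.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALPHABET
        if bad:
            lineno = _find_bad_line(path, bad)
            raise FastaParseError(
                f"{path}: illegal characters {sorted(bad)} in record {rec.id!r} "
                f"(line {lineno})"
            )
        records.append(SequenceRecord(name=rec.id, seq=seq))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    seqio_records = [
        SeqRecord(Seq(r.seq), id=r.name, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqio_records)


# SLQS ID -> plain sequence (5'->3').
_NMR_OLIGOS = {
    "G4ST02001786748": "AGGGAGAGGAGAGCTCTGGGTTGGGTGGG",
    "G4ST03120547683": "GTGGGTGCAGTCAGAGCTGCTGGGAGTGGGTAGCCTCAGGCTAGGG",
    "G4ST05039110287": "GCGGGCGCGGCGCGCGGGGAGGGGAAGGGGT",
    "G4ST06037246104": "GCGGGAGGGCGCGCCAGCGGGGTCGGGC",
    "G4ST07001717478": "CAGGGTGGGTCTGCTGTGCAGGGGTGGGT",
    "G4ST08067688172": "GAGGGCGGGGCTGGGGAGCTGGAAGCTGGGA",
    "G4ST10035665408": "GAGGGCGGGCGCCGCTGGCGAGGGAGGGC",
    "G4ST10042891022": "CAGGGAAGGGACCTGATAGGTAGGGAGGGGC",
    "G4ST11046359281": "CTGGGGCGGTTTCCGCGGGTGGGCAGGGA",
    "G4ST17001906030": "GTGGGGGGGAGGGGGGAGCCACGCAGCTCCCAGGGGA",
}

_MUTATION_OLIGOS = {
    "G4ST19017166594": "CTGGGGTGGGAGAGTCTTCTCTGGGCTTGGGGC",
    # GAGAGT deletion applied
    "G4ST19017166594del": "CTGGGGTGGCTTCTCTGGGCTTGGGGC",
    # SNP alleles resolved
    "G4ST01039729840A": "CCGGGGGTGGGCGGGCAGCACAGACGGCTGAGCCGGGGC",
    "G4ST01039729840G": "CCGGGGGTGGGCGGGCGGCACAGACGGCTGAGCCGGGGC",
}

NMR_STUDY_IDS = tuple(_NMR_OLIGOS)
MUTATION_STUDY_IDS = tuple(_MUTATION_OLIGOS)


def bundled_oligos() -> dict[str, SequenceRecord]:
    """The fourteen bundled SLQS oligonucleotides keyed by SLQS ID."""
    out = {}
    for oid, seq in {**_NMR_OLIGOS, **_MUTATION_OLIGOS}.items():
        out[oid] = SequenceRecord(name=oid, seq=seq)
    return out
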