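"""Aligned amino-acid orthogroups: the per-locus container and its FASTA I/O.

An orthogroup is one aligned locus, possibly with several sequences per
taxon before paralog pruning.  Sequence identifiers encode the taxon of
origin as the substring before the first delimiter (``"Lumbricus|c1"`` ->
taxon ``"Lumbricus"``), mirroring transcriptome contig naming.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue order (PAML order) used for all count vectors and
#: substitution matrices.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
#: Integer code assigned to gaps, ``X`` and anything non-standard.
MISSING_CODE = 20
#: Characters treated as missing data in occupancy and census statistics.
MISSING_CHARS = frozenset("-X")

DEFAULT_DELIMITER = "|"


def taxon_of(sequence_id: str, delimiter: str = DEFAULT_DELIMITER) -> str:
    """Extract the taxon label from a sequence identifier."""
    return sequence_id.split(delimiter, 1)[0]


@dataclasses.dataclass(frozen=True)
class Record:
    """One aligned sequence: ``(taxon_id, sequence_id, residues)``."""

    taxon_id: str
    sequence_id: str
    residues: str

    def nongap_length(self) -> int:
        """Number of non-gap residues (the 'unaligned length' of a contig)."""
        return sum(1 for c in self.residues if c != "-")


@dataclasses.dataclass
class AlignedOrthogroup:
    """One aligned amino-acid locus, possibly multi-copy per taxon."""

    locus_id: str
    records: list[Record]

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(
                f"orthogroup {self.locus_id!r}: unequal aligned lengths {sorted(lengths)}"
            )
        keys = [(r.taxon_id, r.sequence_id) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError(f"orthogroup {self.locus_id!r}: duplicate (taxon, sequence) pair")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].residues) if self.records else 0

    @property
    def n_records(self) -> int:
        return len(self.records)

    def taxa(self) -> list[str]:
        """Distinct taxa, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.taxon_id, None)
        return list(seen)

    def record_by_id(self, sequence_id: str) -> Record:
        for r in self.records:
            if r.sequence_id == sequence_id:
                return r
        raise KeyError(sequence_id)

    def codes(self) -> np.ndarray:
        """Encode as an ``(n_records, length)`` int8 matrix.

        Residues map to 0..19 in :data:`AA_ORDER`; gaps, ``X`` and any other
        character map to :data:`MISSING_CODE`.
        """
        out = np.full((len(self.records), self.length), MISSING_CODE, dtype=np.int8)
        for i, r in enumerate(self.records):
            out[i] = encode_residues(r.residues)
        return out

    def subset(self, sequence_ids: Iterable[str]) -> "AlignedOrthogroup":
        wanted = set(sequence_ids)
        return AlignedOrthogroup(
            self.locus_id, [r for r in self.records if r.sequence_id in wanted]
        )

    def drop_all_gap_columns(self) -> "AlignedOrthogroup":
        if not self.records:
            return AlignedOrthogroup(self.locus_id, [])
        rows = np.array([list(r.residues) for r in self.records])
        keep = ~(rows == "-").all(axis=0)
        if keep.all():
            return self
        recs = [
            dataclasses.replace(r, residues="".join(rows[i, keep]))
            for i, r in enumerate(self.records)
        ]
        return AlignedOrthogroup(self.locus_id, recs)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)


_ENCODE_TABLE = np.full(128, MISSING_CODE, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _ENCODE_TABLE[ord(_a)] = _i
    _ENCODE_TABLE[ord(_a.lower())] = _i


def encode_residues(residues: str) -> np.ndarray:
    """Encode one residue string to int8 codes (missing -> 20)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[np.minimum(raw, 127)]


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_residues`; missing decodes to ``-``."""
    alphabet = np.array(list(AA_ORDER + "-"))
    return "".join(alphabet[np.asarray(codes, dtype=int)])


def read_orthogroup(path, locus_id: str | None = None,
                    delimiter: str = DEFAULT_DELIMITER) -> AlignedOrthogroup:
    """Read one aligned FASTA file as an orthogroup.

    The taxon of each record is the header token before the first
    ``delimiter``.
    """
    import os

    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(str(path)))[0]
    records = [
        Record(taxon_of(rec.id, delimiter), rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return AlignedOrthogroup(locus_id, records)


def write_orthogroup(orthogroup: AlignedOrthogroup, path) -> None:
    """Write an orthogroup as aligned FASTA (full sequence IDs as headers)."""
    recs = [
        SeqRecord(Seq(r.residues), id=r.sequence_id, description="")
        for r in orthogroup.records
    ]
    SeqIO.write(recs, str(path), "fasta")
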