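"""Supermatrix construction and bookkeeping.

Concatenates pruned one-sequence-per-taxon loci into a single matrix with a
RAxML-style partition table, removes gappy sites, and computes the summary
statistics usually reported for phylogenomic matrices: locus/character
counts, parsimony-informative characters, and per-taxon / overall percent
missing data.  Gaps (``-``) and ambiguity (``X``) both count as missing, so
absent loci dominate a taxon's missingness as they do in practice.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .align import AlignedOrthogroup, MISSING_CODE, Record, encode_residues


@dataclasses.dataclass(frozen=True)
class Partition:
    """One locus range in the supermatrix; 1-based inclusive coordinates."""

    locus_id: str
    start: int
    end: int
    model_name: str = "AUTO"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class Supermatrix:
    """One row per taxon; ordered, contiguous partitions covering all columns."""

    taxa: list[str]
    rows: list[str]
    partitions: list[Partition]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        n = self.length
        if any(len(r) != n for r in self.rows):
            raise ValueError("rows have unequal lengths")
        pos = 1
        for p in self.partitions:
            if p.start != pos or p.end < p.start:
                raise ValueError(f"partitions not contiguous at {p.locus_id}")
            pos = p.end + 1
        if self.partitions and pos != n + 1:
            raise ValueError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_loci(self) -> int:
        return len(self.partitions)

    def codes(self) -> np.ndarray:
        return np.vstack([encode_residues(r) for r in self.rows]) if self.rows \
            else np.zeros((0, 0), dtype=np.int8)


@dataclasses.dataclass
class MatrixSummary:
    """One row of a Table-2-style matrix characteristics report."""

    n_loci: int
    n_characters: int
    n_parsimony_informative: int
    pct_missing_overall: float
    pct_missing_per_taxon: dict[str, float]

    def to_row(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "n_characters": self.n_characters,
            "n_parsimony_informative": self.n_parsimony_informative,
            "pct_missing": round(self.pct_missing_overall, 2),
        }


def concatenate(orthogroups: list[AlignedOrthogroup],
                model_names: dict[str, str] | None = None) -> Supermatrix:
    """Concatenate one-per-taxon loci; absent cells are gap-filled.

    Taxon set is the union over loci (first-appearance order); locus order
    is input order.
    """
    model_names = model_names or {}
    taxa: dict[str, None] = {}
    for og in orthogroups:
        seen = set()
        for r in og.records:
            if r.taxon_id in seen:
                raise ValueError(
                    f"locus {og.locus_id!r} has multiple records for taxon {r.taxon_id!r}")
            seen.add(r.taxon_id)
            taxa.setdefault(r.taxon_id, None)
    taxon_list = list(taxa)
    pieces: dict[str, list[str]] = {t: [] for t in taxon_list}
    partitions: list[Partition] = []
    pos = 1
    for og in orthogroups:
        by_taxon = {r.taxon_id: r.residues for r in og.records}
        gap_fill = "-" * og.length
        for t in taxon_list:
            pieces[t].append(by_taxon.get(t, gap_fill))
        partitions.append(Partition(og.locus_id, pos, pos + og.length - 1,
                                    model_names.get(og.locus_id, "AUTO")))
        pos += og.length
    return Supermatrix(taxon_list, ["".join(pieces[t]) for t in taxon_list], partitions)


def remove_gappy_sites(obj, max_gap_fraction: float = 0.5):
    """Drop columns whose gap proportion is strictly above the threshold.

    Works on an orthogroup (TrimAl role, applied per locus before
    concatenation) or on a whole supermatrix (partition coordinates are
    recomputed).  Only ``-`` counts as a gap here; ``X`` is an observed,
    ambiguous residue.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    if isinstance(obj, AlignedOrthogroup):
        if not obj.records:
            return obj
        rows = np.array([list(r.residues) for r in obj.records])
        keep = (rows == "-").mean(axis=0) <= max_gap_fraction
        recs = [dataclasses.replace(r, residues="".join(rows[i, keep]))
                for i, r in enumerate(obj.records)]
        return AlignedOrthogroup(obj.locus_id, recs)
    if isinstance(obj, Supermatrix):
        if not obj.rows:
            return obj
        rows = np.array([list(r) for r in obj.rows])
        keep = (rows == "-").mean(axis=0) <= max_gap_fraction
        new_rows = ["".join(rows[i, keep]) for i in range(len(obj.taxa))]
        partitions = []
        pos = 1
        for p in obj.partitions:
            kept = int(keep[p.start - 1:p.end].sum())
            if kept:
                partitions.append(Partition(p.locus_id, pos, pos + kept - 1, p.model_name))
                pos += kept
        return Supermatrix(list(obj.taxa), new_rows, partitions)
    raise TypeError("expected AlignedOrthogroup or Supermatrix")


def percent_missing(matrix: Supermatrix) -> tuple[dict[str, float], float]:
    """Per-taxon and overall percent missing (``-`` and ``X`` cells)."""
    if not matrix.rows or matrix.length == 0:
        return {t: 0.0 for t in matrix.taxa}, 0.0
    codes = matrix.codes()
    miss = codes == MISSING_CODE
    per_taxon = {
        t: 100.0 * float(miss[i].mean()) for i, t in enumerate(matrix.taxa)
    }
    return per_taxon, 100.0 * float(miss.mean())


def count_parsimony_informative(matrix) -> int:
    """Columns with >= 2 distinct unambiguous residues each in >= 2 rows."""
    codes = matrix.codes()
    if codes.size == 0:
        return 0
    n = 0
    for col in codes.T:
        vals, counts = np.unique(col[col < MISSING_CODE], return_counts=True)
        if (counts >= 2).sum() >= 2:
            n += 1
    return n


def summarize(matrix: Supermatrix) -> MatrixSummary:
    """Bundle locus/character/informative/missing statistics."""
    per_taxon, overall = percent_missing(matrix)
    return MatrixSummary(
        n_loci=matrix.n_loci,
        n_characters=matrix.length,
        n_parsimony_informative=count_parsimony_informative(matrix),
        pct_missing_overall=overall,
        pct_missing_per_taxon=per_taxon,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(matrix: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for t, row in zip(matrix.taxa, matrix.rows):
            fh.write(f">{t}\n{row}\n")


def write_phylip(matrix: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.length}\n")
        width = max((len(t) for t in matrix.taxa), default=0) + 2
        for t, row in zip(matrix.taxa, matrix.rows):
            fh.write(f"{t:<{width}}{row}\n")


def write_partitions(matrix: Supermatrix, path) -> None:
    """RAxML partition file: ``<MODEL>, <locus_id> = <start>-<end>``."""
    with open(path, "w") as fh:
        for p in matrix.partitions:
            fh.write(f"{p.model_name}, {p.locus_id} = {p.start}-{p.end}\n")


def read_fasta(path, partitions: list[Partition] | None = None) -> Supermatrix:
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if partitions is None:
        partitions = [Partition("all", 1, len(rows[0]) if rows else 0)] if rows else []
    return Supermatrix(taxa, rows, partitions)


def read_phylip(path, partitions: list[Partition] | None = None) -> Supermatrix:
    taxa, rows = [], []
    with open(path) as fh:
        header = fh.readline().split()
        n, ncols = int(header[0]), int(header[1])
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(seq.strip().upper())
    if len(taxa) != n or any(len(r) != ncols for r in rows):
        raise ValueError("malformed relaxed PHYLIP file")
    if partitions is None:
        partitions = [Partition("all", 1, ncols)] if rows else []
    return Supermatrix(taxa, rows, partitions)


def read_partitions(path) -> list[Partition]:
    parts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            model, rest = line.split(",", 1)
            name, coords = rest.split("=")
            start, end = coords.strip().split("-")
            parts.append(Partition(name.strip(), int(start), int(end), model.strip()))
    return parts


def summary_tsv(summaries: dict[str, MatrixSummary], path) -> None:
    import pandas as pd

    rows = []
    for label, s in summaries.items():
        row = {"matrix": label}
        row.update(s.to_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
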