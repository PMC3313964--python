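"""Aligned-FASTA and sample-metadata I/O, alignment cleaning, concatenation.

Coordinate convention: 0-based half-open column ranges internally; logs and
reports render 1-based inclusive ranges.  Missing loci in a concatenated
matrix are padded with ``?`` so that downstream distance code can treat
alignment gaps (``-``) and absent loci identically as non-comparable while
reporting them separately.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
GAP = "-"
MISSING = "?"
VALID_CHARS = IUPAC_DNA | {GAP, MISSING}

#: source codes accepted in metadata; single letters mirror herbarium-sheet
#: conventions (A arboretum, W wild collected, H herbarium)
SOURCE_CODES = {
    "A": "arboretum",
    "W": "wild",
    "H": "herbarium",
    "arboretum": "arboretum",
    "wild": "wild",
    "herbarium": "herbarium",
    "synthetic": "synthetic",
}


@dataclass(frozen=True)
class SampleRecord:
    """One specimen: identifier, species label, section label, provenance."""

    sample_id: str
    species: str
    section: str
    source: str = "synthetic"


@dataclass
class LocusAlignment:
    """Equal-length aligned sequences for a single locus.

    ``rows`` preserves input order (an ordered mapping sample_id -> aligned
    sequence over the IUPAC DNA alphabet plus ``-`` and ``?``).
    """

    locus: str
    rows: dict[str, str]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.locus!r} has no sequences")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"unequal alignment lengths in locus {self.locus!r}: {sorted(lengths)}"
            )
        object.__setattr__(self, "n_columns", lengths.pop())
        if self.n_columns == 0:
            raise ValueError(f"alignment {self.locus!r} has zero columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows)

    def subset(self, sample_ids) -> "LocusAlignment":
        keep = [s for s in self.rows if s in set(sample_ids)]
        return LocusAlignment(self.locus, {s: self.rows[s] for s in keep})


@dataclass
class ConcatenatedAlignment:
    """Multi-locus supermatrix tolerant of missing loci.

    ``blocks`` maps locus -> (start, end) half-open column range; a sample is
    present iff it has at least one locus, absent blocks padded with ``?``.
    """

    loci: list[str]
    blocks: dict[str, tuple[int, int]]
    rows: dict[str, str]
    presence_mask: dict[str, set[str]]

    @property
    def n_columns(self) -> int:
        return max(e for _, e in self.blocks.values())

    def as_locus_alignment(self, name: str = "concatenated") -> LocusAlignment:
        return LocusAlignment(name, dict(self.rows))


@dataclass(frozen=True)
class IndelRemoval:
    """Log entry for one private indel handled during alignment cleaning."""

    sample_id: str
    locus: str
    start: int  # 0-based half-open, internal convention
    end: int
    kind: str  # "private_insertion" (columns removed) | "private_deletion" (logged only)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


def _validate_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in VALID_CHARS:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {pos + 1} in record {name!r}"
            )
    return seq


def read_fasta_alignment(path, locus_name: str) -> LocusAlignment:
    """Read an aligned FASTA file into a :class:`LocusAlignment`.

    Rows keep file order.  Raises on empty files, ragged alignments (the
    error names the offending record) and non-IUPAC characters.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    expected_len: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(rec.seq), rec.id)
        if rec.id in rows:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        if expected_len is not None and len(seq) != expected_len:
            raise ValueError(
                f"unequal alignment lengths in {path}: record {rec.id!r} has "
                f"{len(seq)} columns, expected {expected_len}"
            )
        expected_len = expected_len if expected_len is not None else len(seq)
        rows[rec.id] = seq
    if not rows:
        raise ValueError(f"empty FASTA file: {path}")
    return LocusAlignment(locus_name, rows)


def write_fasta_alignment(aln: LocusAlignment, path, wrap: int = 70) -> None:
    """Write aligned FASTA with a fixed line-wrap width (0 = single line)."""
    with open(path, "w") as fh:
        for sid, seq in aln.rows.items():
            fh.write(f">{sid}\n")
            if wrap <= 0:
                fh.write(seq + "\n")
            else:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")


def read_metadata(path) -> list[SampleRecord]:
    """Read the sample table (TSV with header sample_id species section source).

    Enforces unique sample ids, a single section per species, and known
    source codes (single-letter codes A/W/H are expanded).
    """
    records: list[SampleRecord] = []
    seen_ids: set[str] = set()
    species_section: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "species", "section", "source"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"metadata header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            sid = row["sample_id"].strip()
            species = row["species"].strip()
            section = row["section"].strip()
            source_raw = row["source"].strip()
            if not species:
                raise ValueError(f"empty species for sample {sid!r}")
            if sid in seen_ids:
                raise ValueError(f"duplicate sample_id {sid!r}")
            seen_ids.add(sid)
            if species in species_section and species_section[species] != section:
                raise ValueError(
                    f"species {species!r} mapped to two sections: "
                    f"{species_section[species]!r} and {section!r}"
                )
            species_section[species] = section
            if source_raw not in SOURCE_CODES:
                raise ValueError(f"unknown source code {source_raw!r} for sample {sid!r}")
            records.append(SampleRecord(sid, species, section, SOURCE_CODES[source_raw]))
    return records


def write_metadata(records: list[SampleRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "species", "section", "source"])
        for r in records:
            writer.writerow([r.sample_id, r.species, r.section, r.source])


def strip_autapomorphic_indels(
    aln: LocusAlignment, coding: bool
) -> tuple[LocusAlignment, list[IndelRemoval]]:
    """Treat private indels in coding loci as processing errors.

    In a coding locus, a maximal run of columns where exactly one sample
    carries residues and every other sample is gapped is a *private
    insertion*: those columns are deleted from the alignment.  A maximal gap
    run private to one sample (*private deletion*) is logged but the columns
    are kept, since nothing can be restored.  Non-coding alignments are
    returned unchanged with an empty log.
    """
    if not coding:
        return aln, []
    ids = aln.sample_ids
    n = len(ids)
    if n < 2:
        return aln, []
    cols = list(zip(*aln.rows.values()))
    log: list[IndelRemoval] = []
    # private insertions: exactly one residue carrier per column, same carrier
    # across the maximal run
    insertion_cols: set[int] = set()
    c = 0
    while c < aln.n_columns:
        col = cols[c]
        carriers = [i for i, ch in enumerate(col) if ch != GAP and ch != MISSING]
        if len(carriers) == 1:
            carrier = carriers[0]
            start = c
            while c < aln.n_columns:
                col = cols[c]
                cs = [i for i, ch in enumerate(col) if ch != GAP and ch != MISSING]
                if len(cs) == 1 and cs[0] == carrier:
                    c += 1
                else:
                    break
            log.append(
                IndelRemoval(ids[carrier], aln.locus, start, c, "private_insertion")
            )
            insertion_cols.update(range(start, c))
        else:
            c += 1
    # private deletions: maximal gap run in one sample, all others residues
    for i, sid in enumerate(ids):
        seq = aln.rows[sid]
        c = 0
        while c < aln.n_columns:
            if seq[c] == GAP and c not in insertion_cols:
                start = c
                while c < aln.n_columns and seq[c] == GAP and c not in insertion_cols:
                    c += 1
                # private iff no other sample is gapped anywhere in the run
                private = all(
                    all(cols[k][j] != GAP for j in range(n) if j != i)
                    for k in range(start, c)
                )
                if private:
                    log.append(IndelRemoval(sid, aln.locus, start, c, "private_deletion"))
            else:
                c += 1
    if insertion_cols:
        keep = [c for c in range(aln.n_columns) if c not in insertion_cols]
        new_rows = {sid: "".join(seq[c] for c in keep) for sid, seq in aln.rows.items()}
        aln = LocusAlignment(aln.locus, new_rows)
    log.sort(key=lambda r: (r.start, r.sample_id))
    return aln, log


def write_removal_log(log: list[IndelRemoval], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "locus", "start_1based", "end_1based", "length", "kind"])
        for r in log:
            writer.writerow([r.sample_id, r.locus, r.start_1based, r.end_1based, r.length, r.kind])


def concatenate(
    alns: list[LocusAlignment], samples: list[SampleRecord]
) -> ConcatenatedAlignment:
    """Concatenate loci into a supermatrix, padding missing loci with ``?``.

    A sample appears iff it has at least one locus; samples present in the
    metadata but absent from every locus are dropped with a warning.
    """
    if not alns:
        raise ValueError("concatenate requires at least one alignment")
    known_ids = {r.sample_id for r in samples}
    for aln in alns:
        unknown = set(aln.sample_ids) - known_ids
        if unknown:
            raise ValueError(
                f"locus {aln.locus!r} contains sample ids absent from metadata: {sorted(unknown)}"
            )
    blocks: dict[str, tuple[int, int]] = {}
    offset = 0
    for aln in alns:
        blocks[aln.locus] = (offset, offset + aln.n_columns)
        offset += aln.n_columns
    presence: dict[str, set[str]] = {}
    for r in samples:
        present = {aln.locus for aln in alns if r.sample_id in aln.rows}
        if not present:
            warnings.warn(
                f"sample {r.sample_id!r} absent from all loci; dropped from concatenation",
                stacklevel=2,
            )
            continue
        presence[r.sample_id] = present
    rows: dict[str, str] = {}
    for sid in presence:
        parts = []
        for aln in alns:
            parts.append(aln.rows.get(sid, MISSING * aln.n_columns))
        rows[sid] = "".join(parts)
    return ConcatenatedAlignment([a.locus for a in alns], blocks, rows, presence)
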