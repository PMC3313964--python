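"""Column-level alignment statistics and the indel catalogue.

Variable site: a column with at least two distinct unambiguous nucleotide
states.  Diagnostic (parsimony-informative) site: at least two states each
carried by at least two sequences.  Gaps, ``?`` and IUPAC ambiguity codes
never contribute states.

Indel events are grouped by exact span: every maximal gap run with identical
start/end across its carriers is one event.  Runs touching the first or last
column are treated as terminal missing tails (incomplete reads) and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .io_metadata import GAP, LocusAlignment, SampleRecord

NUCLEOTIDES = ("A", "C", "G", "T")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in tabular reports."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SiteClassification:
    n_columns: int
    variable_sites: list[int]  # 0-based column indices, sorted
    informative_sites: list[int]
    state_counts: list[dict[str, int]]

    @property
    def n_variable(self) -> int:
        return len(self.variable_sites)

    @property
    def n_informative(self) -> int:
        return len(self.informative_sites)

    @property
    def pct_variable(self) -> float:
        return round_half_up(100.0 * self.n_variable / self.n_columns)

    @property
    def pct_informative(self) -> float:
        return round_half_up(100.0 * self.n_informative / self.n_columns)


@dataclass
class IndelEvent:
    locus: str
    start: int  # 0-based half-open
    end: int
    members: list[str]
    classification: str  # autapomorphic | shared | clade_diagnostic
    note: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_sites(aln: LocusAlignment) -> SiteClassification:
    """Classify every column as variable and/or parsimony-informative."""
    if len(aln.rows) < 2:
        raise ValueError("site classification requires at least two sequences")
    variable: list[int] = []
    informative: list[int] = []
    state_counts: list[dict[str, int]] = []
    seqs = list(aln.rows.values())
    for c in range(aln.n_columns):
        counts: dict[str, int] = {}
        for seq in seqs:
            ch = seq[c]
            if ch in NUCLEOTIDES:
                counts[ch] = counts.get(ch, 0) + 1
        state_counts.append(counts)
        if len(counts) >= 2:
            variable.append(c)
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative.append(c)
    return SiteClassification(aln.n_columns, variable, informative, state_counts)


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def indel_catalogue(
    aln: LocusAlignment,
    samples: list[SampleRecord] | None = None,
    outgroup_id: str | None = None,
) -> list[IndelEvent]:
    """Group maximal identical gap runs into classified indel events.

    Classification: ``autapomorphic`` (one carrier), ``clade_diagnostic``
    (carriers coincide exactly with all sampled members of one or more whole
    species, or of one section), otherwise ``shared``.  When an outgroup id
    is given it is excluded from clade-membership bookkeeping; an event
    carried by every ingroup sample but not the outgroup gets the polarity
    note "outgroup lacks state".
    """
    by_span: dict[tuple[int, int], list[str]] = {}
    for sid, seq in aln.rows.items():
        for start, end in _gap_runs(seq):
            if start == 0 or end == aln.n_columns:
                continue  # terminal missing tail, not an indel
            by_span.setdefault((start, end), []).append(sid)

    species_of: dict[str, str] = {}
    section_of: dict[str, str] = {}
    if samples:
        species_of = {r.sample_id: r.species for r in samples}
        section_of = {r.sample_id: r.section for r in samples}
    present = [s for s in aln.sample_ids if s != outgroup_id]
    species_members: dict[str, set[str]] = {}
    section_members: dict[str, set[str]] = {}
    for sid in present:
        if sid in species_of:
            species_members.setdefault(species_of[sid], set()).add(sid)
            section_members.setdefault(section_of[sid], set()).add(sid)

    events: list[IndelEvent] = []
    for (start, end), members in sorted(by_span.items()):
        members = sorted(members)
        note = ""
        ingroup_members = [m for m in members if m != outgroup_id]
        if len(members) == 1:
            cls = "autapomorphic"
        else:
            carrier_set = set(ingroup_members)
            whole_species = [
                sp for sp, mem in species_members.items() if mem and mem <= carrier_set
            ]
            covered = set().union(*(species_members[sp] for sp in whole_species)) if whole_species else set()
            is_species_union = bool(whole_species) and carrier_set == covered
            is_section = any(
                mem == carrier_set for mem in section_members.values() if mem
            )
            if is_species_union or is_section:
                cls = "clade_diagnostic"
            else:
                cls = "shared"
        if (
            outgroup_id is not None
            and outgroup_id in aln.rows
            and outgroup_id not in members
            and set(ingroup_members) == set(present)
        ):
            note = "outgroup lacks state"
            if len(members) > 1:
                cls = "clade_diagnostic"
        events.append(IndelEvent(aln.locus, start, end, members, cls, note))
    return events


def write_indel_catalogue(events: list[IndelEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tstart\tend\tlength\tn_members\tclassification\tmembers\n")
        for e in events:
            fh.write(
                f"{e.locus}\t{e.start + 1}\t{e.end}\t{e.length}\t{len(e.members)}\t"
                f"{e.classification}\t{','.join(e.members)}\n"
            )
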