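"""Leave-one-out sequence identification with a seed-and-extend local aligner.

The aligner is a deliberately small BLAST-like heuristic: exact-word
seeding, grouping of seed hits into diagonal clusters, then a banded
affine-gap Smith-Waterman extension around each cluster.  Within the band
the score is the exact local-alignment optimum for the configured scoring
scheme; alignments whose optimal path would leave the band can score lower
(the band width is configurable and recorded in reports).  Query/subject
pairs sharing no seed word score 0 and are logged as seedless.

Scoring defaults (+1 match, -2 mismatch, -5 first gap position, -2 each
additional) follow conventional nucleotide-BLAST-like practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .distances import DistanceMatrix
from .io_metadata import GAP, MISSING, LocusAlignment, SampleRecord

_ACGT = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class AlignerConfig:
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5  # score of the first gapped position
    gap_extend: int = -2
    band: int = 24  # half-width of the extension band around a seed cluster
    max_hits: int = 10
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")


@dataclass
class Hit:
    subject: str
    species: str
    section: str
    score: float
    k2p_distance: float  # K2P over the shared aligned columns (NaN if undefined)


@dataclass
class HitList:
    query: str
    hits: list[Hit]
    rank_first_conspecific: int | None  # 1-based; None if no conspecific hit
    top1_correct: bool
    top3_correct: bool
    section_correct_at_top1: bool
    unidentifiable: bool = False


@njit(cache=False)
def _banded_sw(q, s, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Exact affine-gap local alignment restricted to diagonals i-j in
    [dlo, dhi] (1-based DP indices); out-of-band cells are unreachable."""
    m = q.shape[0]
    n = s.shape[0]
    W = dhi - dlo + 1
    NEG = -1.0e9
    # band column k of DP row i corresponds to subject index j = i - dhi + k;
    # padded arrays (index k+1) keep out-of-band neighbours at NEG
    Hp = np.full(W + 2, NEG)
    Fp = np.full(W + 2, NEG)
    for k in range(W):
        j = 0 - dhi + k
        if 0 <= j <= n:
            Hp[k + 1] = 0.0
    best = 0.0
    for i in range(1, m + 1):
        Hc = np.full(W + 2, NEG)
        Fc = np.full(W + 2, NEG)
        E = NEG
        qc = q[i - 1]
        for k in range(W):
            j = i - dhi + k
            if j < 1 or j > n:
                continue
            h_left = 0.0 if j == 1 else Hc[k]
            E = max(h_left + gap_open, E + gap_extend)
            F = max(Hp[k + 2] + gap_open, Fp[k + 2] + gap_extend)
            diag = 0.0 if j == 1 else Hp[k + 1]
            sub = match if (qc == s[j - 1] and qc != 4) else mismatch
            h = diag + sub
            if h < E:
                h = E
            if h < F:
                h = F
            if h < 0.0:
                h = 0.0
            Hc[k + 1] = h
            Fc[k + 1] = F
            if h > best:
                best = h
        Hp = Hc
        Fp = Fc
    return best


def _encode_ungapped(seq: str) -> np.ndarray:
    return np.array([_ACGT.get(ch, 4) for ch in seq], dtype=np.int8)


def _kmer_positions(seq: str, w: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        if set(word) <= set("ACGT"):
            out.setdefault(word, []).append(i)
    return out


def _seed_diagonals(query: str, subject_index: dict[str, list[int]], w: int) -> list[int]:
    diags: set[int] = set()
    for i in range(len(query) - w + 1):
        word = query[i : i + w]
        for j in subject_index.get(word, ()):
            diags.add(i - j)
    return sorted(diags)


def _cluster_diagonals(diags: list[int], band: int) -> list[tuple[int, int]]:
    clusters: list[tuple[int, int]] = []
    for d in diags:
        if clusters and d - clusters[-1][1] <= 2 * band:
            clusters[-1] = (clusters[-1][0], d)
        else:
            clusters.append((d, d))
    return [(lo - band, hi + band) for lo, hi in clusters]


def local_align(query: str, subject: str, cfg: AlignerConfig | None = None) -> float:
    """Best local-alignment score between two ungapped DNA strings.

    Symmetric in its arguments.  Returns 0 when the pair shares no seed
    word (including queries shorter than the word size).
    """
    cfg = cfg or AlignerConfig()
    query = query.upper()
    subject = subject.upper()
    best = _local_align_one_strand(query, subject, cfg)
    if cfg.both_strands:
        rc = subject.translate(_COMPLEMENT)[::-1]
        best = max(best, _local_align_one_strand(query, rc, cfg))
    return best


def _local_align_one_strand(query: str, subject: str, cfg: AlignerConfig) -> float:
    if len(query) < cfg.word_size or len(subject) < cfg.word_size:
        return 0.0
    index = _kmer_positions(subject, cfg.word_size)
    diags = _seed_diagonals(query, index, cfg.word_size)
    if not diags:
        return 0.0
    q = _encode_ungapped(query)
    s = _encode_ungapped(subject)
    best = 0.0
    for dlo, dhi in _cluster_diagonals(diags, cfg.band):
        best = max(
            best,
            _banded_sw(
                q, s, dlo, dhi,
                float(cfg.match), float(cfg.mismatch),
                float(cfg.gap_open), float(cfg.gap_extend),
            ),
        )
    return best


def loo_identify(
    aln: LocusAlignment,
    samples: list[SampleRecord],
    cfg: AlignerConfig | None = None,
    matrix: DistanceMatrix | None = None,
) -> list[HitList]:
    """Leave-one-out identification: each sequence queried against all others.

    The self-hit is excluded.  Hits are ranked by descending score with ties
    broken by (1) smaller K2P distance over the dataset's aligned columns,
    (2) lexicographic subject id.  Queries with no scoring hit at all are
    marked unidentifiable and excluded from summary denominators.
    """
    cfg = cfg or AlignerConfig()
    species_of = {r.sample_id: r.species for r in samples}
    section_of = {r.sample_id: r.section for r in samples}
    ids = list(aln.rows)
    missing_labels = [s for s in ids if s not in species_of]
    if missing_labels:
        raise ValueError(f"sequences without species labels: {missing_labels}")
    ungapped = {
        sid: seq.replace(GAP, "").replace(MISSING, "") for sid, seq in aln.rows.items()
    }
    n = len(ids)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sc = local_align(ungapped[ids[i]], ungapped[ids[j]], cfg)
            scores[i, j] = scores[j, i] = sc

    def pair_k2p(i: int, j: int) -> float:
        if matrix is None:
            return math.nan
        return float(matrix.values[matrix.ids.index(ids[i]), matrix.ids.index(ids[j])])

    out: list[HitList] = []
    for i, qid in enumerate(ids):
        cand = []
        for j, sid in enumerate(ids):
            if j == i or scores[i, j] <= 0:
                continue
            d = pair_k2p(i, j)
            cand.append(
                Hit(sid, species_of[sid], section_of[sid], float(scores[i, j]), d)
            )
        if not cand:
            out.append(HitList(qid, [], None, False, False, False, unidentifiable=True))
            continue
        cand.sort(
            key=lambda h: (
                -h.score,
                h.k2p_distance if not math.isnan(h.k2p_distance) else math.inf,
                h.subject,
            )
        )
        cand = cand[: cfg.max_hits]
        rank = None
        for r, h in enumerate(cand, start=1):
            if h.species == species_of[qid]:
                rank = r
                break
        top1 = bool(cand) and cand[0].species == species_of[qid]
        top3 = rank is not None and rank <= 3
        sec1 = bool(cand) and cand[0].section == section_of[qid]
        out.append(HitList(qid, cand, rank, top1, top3, sec1))
    return out


@dataclass
class IdentificationSummary:
    n_queries: int
    n_unidentifiable: int
    per_species: dict[str, dict]  # species -> {n, top1_frac, top3_frac}
    n_species_all_top1: int
    n_species_all_top3: int
    n_species_majority_top1: int  # strictly more than 50% of specimens
    n_species_majority_top3: int
    n_singleton_species: int  # no conspecific in the database; reported apart
    per_section_pct: dict[str, float]  # % individuals assigned to own section
    mean_section_pct_unweighted: float
    mean_section_pct_weighted: float
    top1_accuracy_pct: float  # over identifiable queries of multi-sample species
    config: dict = field(default_factory=dict)


def identification_summary(
    hitlists: list[HitList], samples: list[SampleRecord]
) -> IdentificationSummary:
    """Tally per-species and per-section identification success.

    Species-level counts consider species with at least two sampled
    sequences (a leave-one-out query can never match a conspecific it does
    not have); singleton species are counted separately.  Section-level
    rates use the top-1 hit of every identifiable query.
    """
    species_of = {r.sample_id: r.species for r in samples}
    section_of = {r.sample_id: r.section for r in samples}
    present = [h.query for h in hitlists]
    sp_counts: dict[str, int] = {}
    for q in present:
        sp_counts[species_of[q]] = sp_counts.get(species_of[q], 0) + 1

    per_species: dict[str, dict] = {}
    for h in hitlists:
        sp = species_of[h.query]
        rec = per_species.setdefault(sp, {"n": 0, "top1": 0, "top3": 0, "excluded": 0})
        if h.unidentifiable:
            rec["excluded"] += 1
            continue
        rec["n"] += 1
        rec["top1"] += int(h.top1_correct)
        rec["top3"] += int(h.top3_correct)

    multi = {sp for sp, c in sp_counts.items() if c >= 2}
    singletons = {sp for sp, c in sp_counts.items() if c == 1}
    all1 = all3 = maj1 = maj3 = 0
    for sp in multi:
        rec = per_species.get(sp)
        if rec is None or rec["n"] == 0:
            continue
        f1 = rec["top1"] / rec["n"]
        f3 = rec["top3"] / rec["n"]
        rec["top1_frac"] = f1
        rec["top3_frac"] = f3
        all1 += f1 == 1.0
        all3 += f3 == 1.0
        maj1 += f1 > 0.5
        maj3 += f3 > 0.5

    sec_tot: dict[str, int] = {}
    sec_ok: dict[str, int] = {}
    for h in hitlists:
        if h.unidentifiable:
            continue
        sec = section_of[h.query]
        sec_tot[sec] = sec_tot.get(sec, 0) + 1
        sec_ok[sec] = sec_ok.get(sec, 0) + int(h.section_correct_at_top1)
    per_section = {
        sec: 100.0 * sec_ok[sec] / sec_tot[sec] for sec in sorted(sec_tot)
    }
    unweighted = (
        sum(per_section.values()) / len(per_section) if per_section else 0.0
    )
    tot = sum(sec_tot.values())
    weighted = 100.0 * sum(sec_ok.values()) / tot if tot else 0.0

    n_id = sum(
        1
        for h in hitlists
        if not h.unidentifiable and species_of[h.query] in multi
    )
    n_ok = sum(
        1
        for h in hitlists
        if not h.unidentifiable and species_of[h.query] in multi and h.top1_correct
    )
    return IdentificationSummary(
        n_queries=len(hitlists),
        n_unidentifiable=sum(h.unidentifiable for h in hitlists),
        per_species=per_species,
        n_species_all_top1=all1,
        n_species_all_top3=all3,
        n_species_majority_top1=maj1,
        n_species_majority_top3=maj3,
        n_singleton_species=len(singletons),
        per_section_pct=per_section,
        mean_section_pct_unweighted=unweighted,
        mean_section_pct_weighted=weighted,
        top1_accuracy_pct=100.0 * n_ok / n_id if n_id else 0.0,
    )


def write_hit_table(hitlists: list[HitList], path) -> None:
    """Tab-separated hit table in an outfmt-6-like layout."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tk2p_distance\trank\n")
        for hl in hitlists:
            for r, h in enumerate(hl.hits, start=1):
                d = "NA" if math.isnan(h.k2p_distance) else f"{h.k2p_distance:.6f}"
                fh.write(f"{hl.query}\t{h.subject}\t{h.score:g}\t{d}\t{r}\n")
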