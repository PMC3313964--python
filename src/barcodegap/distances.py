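"""Pairwise Kimura two-parameter (K2P) substitution rates and barcode-gap
statistics.

The K2P model distinguishes transitions (purine<->purine, pyrimidine<->
pyrimidine) from transversions.  With transition proportion P and
transversion proportion Q observed over the mutually unambiguous columns of
a pair, the per-site rate is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Gaps, ``?`` and IUPAC ambiguity codes are excluded pairwise (pairwise
deletion); pairs with fewer than ``min_overlap`` comparable columns, or for
which the logarithm arguments are non-positive (saturation), are undefined.

Distances are stored per site and rendered per 100 sites in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io_metadata import LocusAlignment, SampleRecord
from .site_stats import SiteClassification, round_half_up

# encoding: A=0 G=1 C=2 T=3 (purines < 2 <= pyrimidines); >=4 means
# non-comparable (gap, missing, ambiguity)
_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("AGCT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

DEFAULT_MIN_OVERLAP = 50


def encode_alignment(aln: LocusAlignment) -> np.ndarray:
    """Encode rows as a (n_samples, n_columns) uint8 matrix."""
    buf = "".join(aln.rows.values()).encode("ascii")
    arr = _CODE[np.frombuffer(buf, dtype=np.uint8)]
    return arr.reshape(len(aln.rows), aln.n_columns)


@dataclass(frozen=True)
class PairwiseComparison:
    n_compared: int
    P: float
    Q: float
    d: float | None
    reason: str | None = None  # set when d is undefined


def k2p_from_counts(n: int, transitions: int, transversions: int) -> PairwiseComparison:
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return PairwiseComparison(n, P, Q, None, "saturated")
    d = -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # normalize -0.0
    return PairwiseComparison(n, P, Q, d)


def k2p(seq_a, seq_b, min_overlap: int = DEFAULT_MIN_OVERLAP) -> PairwiseComparison:
    """K2P comparison of two aligned sequences (strings or encoded arrays)."""
    if isinstance(seq_a, str):
        seq_a = _CODE[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    if isinstance(seq_b, str):
        seq_b = _CODE[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    mask = (seq_a < 4) & (seq_b < 4)
    n = int(mask.sum())
    if n == 0:
        return PairwiseComparison(0, 0.0, 0.0, None, "no comparable columns")
    if n < min_overlap:
        return PairwiseComparison(n, 0.0, 0.0, None, f"overlap {n} < {min_overlap}")
    a = seq_a[mask]
    b = seq_b[mask]
    diff = a != b
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    tv = int(diff.sum()) - ts
    return k2p_from_counts(n, ts, tv)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of per-site K2P rates; NaN marks undefined entries."""

    ids: list[str]
    values: np.ndarray
    reasons: dict[tuple[int, int], str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_undefined(self) -> int:
        return len(self.reasons)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def imputed(self) -> tuple[np.ndarray, int]:
        """Replace undefined entries with the maximum finite distance.

        Keeps partially sequenced samples in the tree; the substitution is
        advisory and the count is returned for logging.
        """
        vals = self.values.copy()
        nan = np.isnan(vals)
        np.fill_diagonal(nan, False)
        n_imputed = int(nan.sum()) // 2
        if n_imputed:
            finite = vals[~np.isnan(vals)]
            if finite.size == 0:
                raise ValueError("distance matrix has no defined entries")
            vals[nan] = finite.max()
        return vals, n_imputed

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(
                    "NA" if np.isnan(v) else f"{v:.8f}" for v in self.values[i]
                )
                fh.write(f"{sid:<12s}{row}\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(
                    "NA" if np.isnan(v) else f"{v:.8f}" for v in self.values[i]
                )
                fh.write(f"{sid}\t{row}\n")


def distance_matrix(
    aln: LocusAlignment, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs K2P matrix with pairwise deletion."""
    if len(aln.rows) < 2:
        raise ValueError("distance matrix requires at least two sequences")
    enc = encode_alignment(aln)
    n = enc.shape[0]
    vals = np.zeros((n, n), dtype=float)
    reasons: dict[tuple[int, int], str] = {}
    comparable = enc < 4
    for i in range(n):
        ai = enc[i]
        mi = comparable[i]
        for j in range(i + 1, n):
            mask = mi & comparable[j]
            m = int(mask.sum())
            if m == 0:
                vals[i, j] = vals[j, i] = np.nan
                reasons[(i, j)] = "no comparable columns"
                continue
            if m < min_overlap:
                vals[i, j] = vals[j, i] = np.nan
                reasons[(i, j)] = f"overlap {m} < {min_overlap}"
                continue
            a = ai[mask]
            b = enc[j][mask]
            diff = a != b
            ts = int((diff & ((a >> 1) == (b >> 1))).sum())
            tv = int(diff.sum()) - ts
            pc = k2p_from_counts(m, ts, tv)
            if pc.d is None:
                vals[i, j] = vals[j, i] = np.nan
                reasons[(i, j)] = pc.reason or "undefined"
            else:
                vals[i, j] = vals[j, i] = pc.d
    return DistanceMatrix(
        list(aln.rows),
        vals,
        reasons,
        {"locus": aln.locus, "min_overlap": min_overlap},
    )


@dataclass
class DistancePartition:
    intra: list[tuple[str, float]]  # (species, d)
    inter: list[tuple[str, str, float]]  # (species_a, species_b, d)
    excluded_singletons: list[str]
    n_undefined: int

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([d for _, d in self.intra], dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([d for _, _, d in self.inter], dtype=float)


def partition(matrix: DistanceMatrix, samples: list[SampleRecord]) -> DistancePartition:
    """Split pairwise distances into intra- and interspecific lists.

    Species represented by a single sample are excluded from the
    intraspecific side and reported in ``excluded_singletons`` (they still
    contribute interspecific pairs).
    """
    species_of = {r.sample_id: r.species for r in samples}
    unlabeled = [s for s in matrix.ids if s not in species_of]
    if unlabeled:
        raise ValueError(f"samples without species labels: {unlabeled}")
    counts: dict[str, int] = {}
    for sid in matrix.ids:
        counts[species_of[sid]] = counts.get(species_of[sid], 0) + 1
    singletons = sorted(sp for sp, c in counts.items() if c == 1)
    intra: list[tuple[str, float]] = []
    inter: list[tuple[str, str, float]] = []
    n_undef = 0
    for i, j in combinations(range(matrix.n), 2):
        d = matrix.values[i, j]
        sp_i = species_of[matrix.ids[i]]
        sp_j = species_of[matrix.ids[j]]
        if np.isnan(d):
            n_undef += 1
            continue
        if sp_i == sp_j:
            if counts[sp_i] > 1:
                intra.append((sp_i, float(d)))
        else:
            inter.append((sp_i, sp_j, float(d)))
    return DistancePartition(intra, inter, singletons, n_undef)


@dataclass
class BarcodeGapReport:
    """Distribution summary of intra- vs interspecific rates (per 100 sites)."""

    bin_width: float
    bin_edges: np.ndarray
    intra_freq: np.ndarray  # relative frequencies, sum to 1
    inter_freq: np.ndarray
    overlap_fraction: float | None  # share of inter pairs <= max intra
    local_gaps: dict[str, float]  # species -> min inter - max intra (per 100)
    note: str = ""

    @property
    def min_local_gap(self) -> float | None:
        return min(self.local_gaps.values()) if self.local_gaps else None


def barcode_gap(part: DistancePartition, bin_width: float = 0.5) -> BarcodeGapReport:
    """Histogram the two distance classes and quantify their overlap.

    The global overlap fraction is the share of interspecific pairs at or
    below the maximum intraspecific distance; the per-species local gap is
    (min interspecific distance involving the species) - (max intraspecific
    distance within it), both per 100 sites.
    """
    intra = part.intra_values * 100.0
    inter = part.inter_values * 100.0
    if inter.size == 0:
        raise ValueError("barcode gap requires interspecific distances")
    if intra.size == 0:
        edges = np.arange(0.0, inter.max() + 2 * bin_width, bin_width)
        inter_freq = np.histogram(inter, bins=edges)[0] / inter.size
        return BarcodeGapReport(
            bin_width, edges, np.zeros(len(edges) - 1), inter_freq, None, {},
            note="gap undefined: all species are singletons",
        )
    top = max(intra.max(), inter.max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    intra_freq = np.histogram(intra, bins=edges)[0] / intra.size
    inter_freq = np.histogram(inter, bins=edges)[0] / inter.size
    overlap = float((inter <= intra.max()).sum() / inter.size)
    max_intra: dict[str, float] = {}
    for sp, d in part.intra:
        max_intra[sp] = max(max_intra.get(sp, 0.0), d * 100.0)
    min_inter: dict[str, float] = {}
    for sp_a, sp_b, d in part.inter:
        for sp in (sp_a, sp_b):
            cur = min_inter.get(sp)
            if cur is None or d * 100.0 < cur:
                min_inter[sp] = d * 100.0
    local = {
        sp: min_inter[sp] - mx
        for sp, mx in max_intra.items()
        if sp in min_inter
    }
    return BarcodeGapReport(bin_width, edges, intra_freq, inter_freq, overlap, local)


@dataclass
class DistanceSummary:
    """Machine-readable row of the per-locus evaluation table."""

    dataset: str
    n_species: int
    n_samples: int
    n_columns: int
    n_variable: int
    pct_variable: float
    n_informative: int
    pct_informative: float
    min_rate: float  # per 100 sites
    max_rate: float
    mean_intra: float | None
    min_intra: float | None
    max_intra: float | None
    mean_inter: float
    min_inter: float
    max_inter: float

    def table_row(self) -> dict:
        fmt = lambda v: None if v is None else round_half_up(v, 1)
        return {
            "dataset": self.dataset,
            "n_species": self.n_species,
            "n_samples": self.n_samples,
            "n_sites": self.n_columns,
            "variable_sites": self.n_variable,
            "variable_pct": self.pct_variable,
            "diagnostic_sites": self.n_informative,
            "diagnostic_pct": self.pct_informative,
            "min_pairwise_rate_per100": fmt(self.min_rate),
            "max_pairwise_rate_per100": fmt(self.max_rate),
            "mean_intra_per100": fmt(self.mean_intra),
            "intra_range_per100": None
            if self.mean_intra is None
            else f"{fmt(self.min_intra)}-{fmt(self.max_intra)}",
            "mean_inter_per100": fmt(self.mean_inter),
            "inter_range_per100": f"{fmt(self.min_inter)}-{fmt(self.max_inter)}",
        }


def summarize(
    aln: LocusAlignment,
    matrix: DistanceMatrix,
    part: DistancePartition,
    sites: SiteClassification,
    samples: list[SampleRecord],
    dataset_name: str | None = None,
) -> DistanceSummary:
    """Populate the per-dataset summary row (rates per 100 sites)."""
    species = {r.species for r in samples if r.sample_id in aln.rows}
    finite = matrix.values[np.triu_indices(matrix.n, k=1)]
    finite = finite[~np.isnan(finite)]
    intra = part.intra_values
    inter = part.inter_values
    has_intra = intra.size > 0
    return DistanceSummary(
        dataset=dataset_name or aln.locus,
        n_species=len(species),
        n_samples=len(aln.rows),
        n_columns=aln.n_columns,
        n_variable=sites.n_variable,
        pct_variable=sites.pct_variable,
        n_informative=sites.n_informative,
        pct_informative=sites.pct_informative,
        min_rate=float(finite.min()) * 100.0 if finite.size else 0.0,
        max_rate=float(finite.max()) * 100.0 if finite.size else 0.0,
        mean_intra=float(intra.mean()) * 100.0 if has_intra else None,
        min_intra=float(intra.min()) * 100.0 if has_intra else None,
        max_intra=float(intra.max()) * 100.0 if has_intra else None,
        mean_inter=float(inter.mean()) * 100.0 if inter.size else 0.0,
        min_inter=float(inter.min()) * 100.0 if inter.size else 0.0,
        max_inter=float(inter.max()) * 100.0 if inter.size else 0.0,
    )
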