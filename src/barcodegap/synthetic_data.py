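"""Synthetic multi-locus barcode datasets with a known truth ledger.

The generator emulates the statistical regime of chloroplast barcoding in a
recently diverged tree genus: a sectioned, ultrametric species tree of
shallow depth; within-species coalescent variation whose lineages can
persist past their species stem (incomplete lineage sorting, ILS), which
produces haplotype sharing across species; K2P sequence evolution with a
transition/transversion ratio kappa; and indel events in non-coding
(spacer) loci, emitted directly as gap blocks in a true alignment.

ILS is modelled phenomenologically: each sampled lineage escapes its
within-species coalescent with probability ``ils`` and only coalesces in
ancestral populations.  This is sufficient to reproduce species
non-monophyly and shared haplotypes without full multispecies-coalescent
machinery.

Every stochastic step derives from the single mandatory seed; identical
parameters and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io_metadata import (
    LocusAlignment,
    SampleRecord,
    write_fasta_alignment,
    write_metadata,
)

OUTGROUP_ID = "outgroup_01"
OUTGROUP_SPECIES = "outgroup_sp"
OUTGROUP_SECTION = "outgroup"


@dataclass
class LocusSpec:
    name: str
    length: int
    relative_rate: float = 1.0
    coding: bool = False
    indel_rate: float = 0.0  # expected indel events per gene tree (non-coding)
    indel_length_p: float = 0.25  # geometric length parameter (mean 1/p)
    missing_rate: float = 0.0  # per-sample probability the locus is absent
    planted_autapomorphies: int = 0  # private insertions planted for cleaning tests

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError("locus length must be >= 100")


@dataclass
class SimulationParams:
    seed: int
    n_sections: int = 4
    species_per_section: tuple[int, ...] | int = 3
    samples_per_species: tuple[int, int] = (2, 5)
    n_singleton_species: int = 0
    total_samples: int | None = None  # optional exact target, counts adjusted
    tree_depth: float = 0.01  # T: species-tree depth, expected subs/site
    theta: float = 0.004  # within-species diversity (mean intra pairwise)
    ils: float = 0.0  # per-lineage probability of escaping its species stem
    kappa: float = 2.0  # transition/transversion rate ratio
    loci: list[LocusSpec] = field(
        default_factory=lambda: [LocusSpec("locusA", 800)]
    )
    mislabel_rate: float = 0.0
    include_outgroup: bool = True
    # species-tree shape: node-height windows as fractions of tree_depth
    within_section_heights: tuple[float, float] = (0.25, 0.6)
    section_join_heights: tuple[float, float] = (0.75, 0.97)
    outgroup_depth_factor: float = 2.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, v in (("tree_depth", self.tree_depth), ("theta", self.theta),
                        ("ils", self.ils), ("mislabel_rate", self.mislabel_rate)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


class TreeNode:
    """Minimal tree node used for both species and gene trees (time = age)."""

    __slots__ = ("children", "time", "name", "parent_time")

    def __init__(self, name=None, time=0.0, children=None):
        self.name = name
        self.time = time
        self.children = children or []
        self.parent_time = None

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def rec(node, parent_time):
            length = (parent_time - node.time) if parent_time is not None else 0.0
            if not node.children:
                return f"{node.name}:{length:.8f}"
            inner = ",".join(rec(c, node.time) for c in node.children)
            return f"({inner}):{length:.8f}"

        inner = ",".join(rec(c, self.time) for c in self.children)
        return f"({inner});"


@dataclass
class IndelPlant:
    locus: str
    start: int  # 0-based half-open columns
    end: int
    members: list[str]  # samples carrying the gap
    kind: str  # insertion | deletion | planted_autapomorphy


@dataclass
class TruthLedger:
    params: dict
    species_tree_newick: str = ""
    section_map: dict[str, str] = field(default_factory=dict)
    gene_tree_newicks: dict[str, str] = field(default_factory=dict)
    indel_events: list[IndelPlant] = field(default_factory=list)
    label_swaps: list[dict] = field(default_factory=list)
    true_species: dict[str, str] = field(default_factory=dict)
    _gene_trees: dict[str, TreeNode] = field(default_factory=dict, repr=False)

    def pairwise_path_lengths(self, locus: str) -> dict[tuple[str, str], float]:
        """Realized patristic distances on the true gene tree (subs/site)."""
        root = self._gene_trees[locus]
        dists: dict[tuple[str, str], float] = {}

        def rec(node):
            if not node.children:
                return {node.name: node.time}
            groups = [rec(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, ta in groups[gi].items():
                        for b, tb in groups[gj].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = 2.0 * node.time - ta - tb
            merged = {}
            for g in groups:
                merged.update(g)
            return merged

        rec(root)
        return dists

    def to_json(self, path) -> None:
        payload = {
            "params": self.params,
            "species_tree": self.species_tree_newick,
            "section_map": self.section_map,
            "gene_trees": self.gene_tree_newicks,
            "indel_events": [asdict(e) for e in self.indel_events],
            "label_swaps": self.label_swaps,
            "true_species": self.true_species,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _join_at_heights(clusters: list[TreeNode], heights: np.ndarray, rng) -> TreeNode:
    """Agglomerate clusters by random pairing at the given ascending ages."""
    clusters = list(clusters)
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        node = TreeNode(time=float(h), children=[clusters[i], clusters[j]])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [node]
    assert len(clusters) == 1
    return clusters[0]


def simulate_species_tree(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[TreeNode, dict[str, str]]:
    """Random ultrametric species tree with monophyletic sections.

    Within-section splits fall in ``within_section_heights`` x T, section
    joins in ``section_join_heights`` x T with the root pinned at exactly T,
    so the expected divergence between two random species is ~2T.
    """
    rng = rng or np.random.default_rng(params.seed)
    T = params.tree_depth
    per_section = params.species_per_section
    if isinstance(per_section, int):
        per_section = tuple([per_section] * params.n_sections)
    if len(per_section) != params.n_sections:
        raise ValueError("species_per_section length must equal n_sections")
    section_map: dict[str, str] = {}
    section_roots: list[TreeNode] = []
    idx = 0
    for si, n_sp in enumerate(per_section):
        section = f"section{si + 1}"
        tips = []
        for _ in range(n_sp):
            idx += 1
            name = f"sp{idx:03d}"
            section_map[name] = section
            tips.append(TreeNode(name=name, time=0.0))
        if len(tips) == 1:
            section_roots.append(tips[0])
            continue
        lo, hi = params.within_section_heights
        heights = np.sort(rng.uniform(lo * T, hi * T, size=len(tips) - 1))
        section_roots.append(_join_at_heights(tips, heights, rng))
    if len(section_roots) == 1:
        root = section_roots[0]
        root.time = T
    else:
        lo, hi = params.section_join_heights
        heights = np.sort(rng.uniform(lo * T, hi * T, size=len(section_roots) - 1))
        heights[-1] = T  # pin total depth
        root = _join_at_heights(section_roots, heights, rng)
    if params.include_outgroup:
        og = TreeNode(name=OUTGROUP_SPECIES, time=0.0)
        section_map[OUTGROUP_SPECIES] = OUTGROUP_SECTION
        root = TreeNode(time=params.outgroup_depth_factor * T, children=[root, og])
    _set_parent_times(root)
    return root, section_map


def _set_parent_times(root: TreeNode) -> None:
    root.parent_time = None
    stack = [root]
    while stack:
        node = stack.pop()
        for c in node.children:
            c.parent_time = node.time
            stack.append(c)


def _coalesce(lineages, t, bound, theta, rng):
    """Kingman-style pairwise coalescence at mean pair time theta/2."""
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        pairs = k * (k - 1) / 2.0
        dt = rng.exponential((theta / 2.0) / pairs) if theta > 0 else 0.0
        t = t + dt
        if bound is not None and t > bound:
            return lineages
        i, j = sorted(rng.choice(k, size=2, replace=False))
        node = TreeNode(time=t, children=[lineages[i], lineages[j]])
        lineages = [l for q, l in enumerate(lineages) if q not in (i, j)] + [node]
    return lineages


def simulate_gene_tree(
    species_tree: TreeNode,
    theta: float,
    ils: float,
    samples: dict[str, list[str]],
    rng: np.random.Generator,
) -> TreeNode:
    """Coalescent gene tree inside the species tree with ILS escapes.

    With theta=0 and ils=0 the gene tree collapses onto the species-tree
    topology with zero within-species depth.
    """

    def process(node: TreeNode) -> list[TreeNode]:
        if not node.children:
            tips = [TreeNode(name=sid, time=0.0) for sid in samples.get(node.name, [])]
            if not tips:
                return []
            escaped = []
            pool = []
            for lin in tips:
                if ils > 0 and rng.random() < ils:
                    escaped.append(lin)
                else:
                    pool.append(lin)
            pool = _coalesce(pool, node.time, node.parent_time, theta, rng)
            return pool + escaped
        pool = []
        for c in node.children:
            pool.extend(process(c))
        return _coalesce(pool, node.time, node.parent_time, theta, rng)

    lineages = process(species_tree)
    if len(lineages) == 1:
        root = lineages[0]
    else:  # root population: force final coalescence
        t = species_tree.time
        while len(lineages) > 1:
            k = len(lineages)
            dt = rng.exponential((max(theta, 1e-6) / 2.0) / (k * (k - 1) / 2.0))
            t += dt
            i, j = sorted(rng.choice(k, size=2, replace=False))
            node = TreeNode(time=t, children=[lineages[i], lineages[j]])
            lineages = [l for q, l in enumerate(lineages) if q not in (i, j)] + [node]
        root = lineages[0]
    _set_parent_times(root)
    return root


# nucleotide codes match distances.encode_alignment: A=0 G=1 C=2 T=3
_BASES = np.array(list("AGCT"))


def _k2p_probs(t: float, kappa: float) -> tuple[float, float, float]:
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_same, p_ts, p_tv_each


def evolve_sequences(
    gene_tree: TreeNode,
    locus: LocusSpec,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[IndelPlant]]:
    """K2P substitution process along the gene tree plus planted indels.

    Branch lengths are scaled by the locus relative rate.  Indels are gap
    blocks: a deletion gaps the subtree below a branch, an insertion gaps
    its complement (the alignment is the truth, no realignment happens).
    """
    L = locus.length
    seqs: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, parent_seq: np.ndarray | None) -> None:
        if parent_seq is None:
            seq = rng.integers(0, 4, size=L, dtype=np.int8)
        else:
            t = (node.parent_time - node.time) * locus.relative_rate
            p_same, p_ts, p_tv = _k2p_probs(t, kappa)
            u = rng.random(L)
            seq = parent_seq.copy()
            ts_mask = (u >= p_same) & (u < p_same + p_ts)
            tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
            tv2_mask = u >= p_same + p_ts + p_tv
            seq[ts_mask] ^= 1  # transition partner (A<->G, C<->T)
            seq[tv1_mask] ^= 2
            seq[tv2_mask] ^= 3
        if not node.children:
            seqs[node.name] = seq
        for c in node.children:
            evolve(c, seq)

    evolve(gene_tree, None)
    all_ids = sorted(seqs)

    events: list[IndelPlant] = []
    gap_masks: dict[str, np.ndarray] = {sid: np.zeros(L, dtype=bool) for sid in all_ids}
    if not locus.coding and locus.indel_rate > 0:
        branches = []  # (child node, length)
        stack = [gene_tree]
        while stack:
            node = stack.pop()
            for c in node.children:
                branches.append((c, node.time - c.time))
                stack.append(c)
        lengths = np.array([b[1] for b in branches])
        if lengths.sum() > 0:
            weights = lengths / lengths.sum()
            n_ev = rng.poisson(locus.indel_rate)
            used_spans: set[tuple[int, int]] = set()
            for _ in range(n_ev):
                bi = int(rng.choice(len(branches), p=weights))
                below = {lf.name for lf in branches[bi][0].leaves()}
                kind = "deletion" if rng.random() < 0.5 else "insertion"
                carriers = sorted(below) if kind == "deletion" else sorted(
                    set(all_ids) - below
                )
                if not carriers or len(carriers) == len(all_ids):
                    continue
                g = min(int(rng.geometric(locus.indel_length_p)), max(L // 4, 1))
                if L - g - 2 <= 1:
                    continue
                for _attempt in range(20):
                    start = int(rng.integers(1, L - g - 1))
                    if (start, start + g) not in used_spans:
                        break
                else:
                    continue
                used_spans.add((start, start + g))
                for sid in carriers:
                    gap_masks[sid][start : start + g] = True
                events.append(IndelPlant(locus.name, start, start + g, carriers, kind))
    if locus.planted_autapomorphies > 0:
        occupied = np.zeros(L, dtype=bool)
        for _ in range(locus.planted_autapomorphies):
            carrier = all_ids[int(rng.integers(0, len(all_ids)))]
            g = max(int(rng.geometric(0.3)), 1)
            for _attempt in range(50):  # keep planted runs clearly apart
                start = int(rng.integers(1, L - g - 1))
                if not occupied[max(start - 2, 0) : start + g + 2].any():
                    break
            else:
                continue
            occupied[start : start + g] = True
            for sid in all_ids:
                if sid != carrier:
                    gap_masks[sid][start : start + g] = True
            events.append(
                IndelPlant(
                    locus.name, start, start + g,
                    sorted(set(all_ids) - {carrier}), "planted_autapomorphy",
                )
            )

    rows: dict[str, str] = {}
    for sid in all_ids:
        chars = _BASES[seqs[sid]]
        chars[gap_masks[sid]] = "-"
        rows[sid] = "".join(chars)
    return rows, events


@dataclass
class SyntheticDataset:
    alignments: dict[str, LocusAlignment]
    records: list[SampleRecord]
    ledger: TruthLedger

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            write_fasta_alignment(aln, outdir / f"{name}.fasta")
        write_metadata(self.records, outdir / "metadata.tsv")
        self.ledger.to_json(outdir / "truth_ledger.json")


def _draw_sample_counts(params: SimulationParams, n_species: int, rng) -> list[int]:
    lo, hi = params.samples_per_species
    counts = [1] * params.n_singleton_species + [
        int(np.clip(rng.geometric(0.22) + max(lo, 2) - 1, max(lo, 2), hi))
        for _ in range(n_species - params.n_singleton_species)
    ]
    if params.total_samples is not None:
        target = params.total_samples
        adjustable = list(range(params.n_singleton_species, n_species))
        guard = 0
        while sum(counts) != target and guard < 100000:
            guard += 1
            i = int(rng.choice(adjustable))
            if sum(counts) < target and counts[i] < hi:
                counts[i] += 1
            elif sum(counts) > target and counts[i] > max(lo, 2):
                counts[i] -= 1
        if sum(counts) != target:
            raise ValueError("cannot reach total_samples within per-species bounds")
    rng.shuffle(counts)
    return counts


def generate_dataset(params: SimulationParams) -> SyntheticDataset:
    """One aligned FASTA per locus, a metadata table and the truth ledger."""
    rng = np.random.default_rng(params.seed)
    species_tree, section_map = simulate_species_tree(params, rng)
    species = sorted(
        sp for sp in section_map if sp != OUTGROUP_SPECIES
    )
    counts = _draw_sample_counts(params, len(species), rng)
    samples: dict[str, list[str]] = {}
    for sp, k in zip(species, counts):
        samples[sp] = [f"{sp}_{i + 1:02d}" for i in range(k)]
    if params.include_outgroup:
        samples[OUTGROUP_SPECIES] = [OUTGROUP_ID]

    ledger = TruthLedger(
        params={
            "seed": params.seed,
            "tree_depth": params.tree_depth,
            "theta": params.theta,
            "ils": params.ils,
            "kappa": params.kappa,
            "mislabel_rate": params.mislabel_rate,
            "loci": [asdict(l) for l in params.loci],
        },
        species_tree_newick=species_tree.newick(),
        section_map=dict(section_map),
    )
    for sp, sids in samples.items():
        for sid in sids:
            ledger.true_species[sid] = sp

    alignments: dict[str, LocusAlignment] = {}
    full_rows: dict[str, dict[str, str]] = {}
    all_ids = [sid for sp in samples for sid in samples[sp]]
    for locus in params.loci:
        gtree = simulate_gene_tree(species_tree, params.theta, params.ils, samples, rng)
        ledger.gene_tree_newicks[locus.name] = gtree.newick()
        ledger._gene_trees[locus.name] = gtree
        rows, events = evolve_sequences(gtree, locus, params.kappa, rng)
        full_rows[locus.name] = rows
        ledger.indel_events.extend(events)
        keep = []
        for sid in all_ids:
            if sid == OUTGROUP_ID or locus.missing_rate <= 0:
                keep.append(sid)
            elif rng.random() >= locus.missing_rate:
                keep.append(sid)
        alignments[locus.name] = LocusAlignment(
            locus.name, {sid: rows[sid] for sid in keep if sid in rows}
        )
    # every sample keeps at least one locus: restore dropped-everywhere samples
    for sid in all_ids:
        if not any(sid in aln.rows for aln in alignments.values()):
            lname = params.loci[0].name
            restored = dict(alignments[lname].rows)
            restored[sid] = full_rows[lname][sid]
            alignments[lname] = LocusAlignment(lname, restored)

    records: list[SampleRecord] = []
    assigned: dict[str, str] = dict(ledger.true_species)
    multi_species = [sp for sp in species if len(samples[sp]) >= 2]
    n_swaps = int(round(params.mislabel_rate * (len(all_ids) - int(params.include_outgroup))))
    if params.mislabel_rate > 0 and n_swaps == 0:
        n_swaps = 1
    swap_pool = [sid for sp in multi_species for sid in samples[sp]]
    if n_swaps and swap_pool:
        chosen = rng.choice(len(swap_pool), size=min(n_swaps, len(swap_pool)), replace=False)
        for ci in np.atleast_1d(chosen):
            sid = swap_pool[int(ci)]
            true_sp = ledger.true_species[sid]
            true_sec = section_map[true_sp]
            foreign = [
                sp for sp in species
                if section_map[sp] not in (true_sec, OUTGROUP_SECTION)
            ]
            new_sp = foreign[int(rng.integers(0, len(foreign)))]
            assigned[sid] = new_sp
            ledger.label_swaps.append(
                {"sample_id": sid, "true_species": true_sp, "assigned_species": new_sp}
            )
    for sid in all_ids:
        sp = assigned[sid]
        records.append(SampleRecord(sid, sp, section_map[sp], "synthetic"))
    return SyntheticDataset(alignments, records, ledger)


def preset(name: str, seed: int) -> SimulationParams:
    """Named study conditions.

    ``fraxinus-like``: 56 species in 6 sections, 253 samples (7 singleton
    species), two spacer loci of 698 and 1023 columns, shallow divergence
    with strong ILS -- the overlap-heavy, low-discrimination regime.

    ``gapped``: 12 species in 4 sections, deep species tree relative to
    within-species diversity (T/theta = 40) and no ILS -- a strict barcode
    gap where every method should succeed.
    """
    if name == "fraxinus-like":
        return SimulationParams(
            seed=seed,
            n_sections=6,
            species_per_section=(15, 3, 9, 11, 9, 9),
            samples_per_species=(2, 28),
            n_singleton_species=7,
            total_samples=253,
            tree_depth=0.011,
            theta=0.005,
            ils=0.5,
            kappa=2.0,
            within_section_heights=(0.02, 0.42),
            loci=[
                LocusSpec("spacerA", 698, 1.0, False, indel_rate=25,
                          indel_length_p=0.12, missing_rate=0.11),
                LocusSpec("spacerB", 1023, 1.3, False, indel_rate=20,
                          indel_length_p=0.12, missing_rate=0.20),
            ],
            mislabel_rate=0.008,
        )
    if name == "gapped":
        return SimulationParams(
            seed=seed,
            n_sections=4,
            species_per_section=3,
            samples_per_species=(2, 5),
            tree_depth=0.08,
            theta=0.002,
            ils=0.0,
            kappa=2.0,
            loci=[LocusSpec("locusA", 800, 1.0, False, indel_rate=4,
                            indel_length_p=0.2)],
            mislabel_rate=0.0,
        )
    raise ValueError(f"unknown preset {name!r}")


def nonmonophyletic_species(gene_tree: TreeNode, true_species: dict[str, str]) -> set[str]:
    """Species whose samples do not form a clade in the (rooted) gene tree."""
    leaves_total: dict[str, int] = {}
    for sid, sp in true_species.items():
        leaves_total[sp] = leaves_total.get(sp, 0) + 1
    mono: set[str] = set()

    def rec(node) -> set[str]:
        if not node.children:
            return {node.name}
        below = set()
        for c in node.children:
            below |= rec(c)
        sps = {true_species[s] for s in below}
        if len(sps) == 1:
            (sp,) = sps
            if len(below) == leaves_total[sp]:
                mono.add(sp)
        return below

    rec(gene_tree)
    return {
        sp for sp, n in leaves_total.items() if n >= 2 and sp not in mono
    }
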