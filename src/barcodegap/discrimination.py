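"""Monophyly-based species discrimination on a rooted tree.

A species is considered discriminated when more than a fraction tau
(default 0.5, strict inequality: "more than 50%") of its sampled
individuals fall in a single monophyletic group containing no other
species.  Samples flagged as probable misidentifications are ignored
entirely.  Singleton species are reported separately and excluded from the
headline count, since a lone leaf is trivially "monophyletic".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .io_metadata import SampleRecord
from .nj_tree import SupportTree


@dataclass
class SpeciesDelineation:
    species: str
    n_individuals: int
    largest_pure_clade: int
    fraction: float
    discriminated: bool
    bootstrap: float | None  # support of that clade, when available
    monospecific_group: bool  # species has a maximal pure clade of >= 2
    singleton: bool


@dataclass
class MisidentificationFlag:
    sample_id: str
    reason: str  # out_of_section_placement | distant_from_conspecifics
    nearest_neighbor_species: str
    excluded_from_delineation: bool = True


def _species_counts_below(tree, species_of, excluded):
    """Per-node Counter of species among unflagged descendant leaves."""
    counts: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            c = Counter()
            if label not in excluded and label in species_of:
                c[species_of[label]] += 1
            counts[node] = c
        else:
            c = Counter()
            for ch in node.child_nodes():
                c.update(counts[ch])
            counts[node] = c
    return counts


def delineate(
    st: SupportTree,
    samples: list[SampleRecord],
    tau: float = 0.5,
    excluded: set[str] | None = None,
) -> list[SpeciesDelineation]:
    """Apply the clade-fraction criterion to every species on a rooted tree."""
    if st.rooted == "unrooted":
        raise ValueError("delineation requires a rooted tree (monophyly is root-relative)")
    excluded = excluded or set()
    species_of = {r.sample_id: r.species for r in samples}
    leaves = [lf.taxon.label for lf in st.tree.leaf_node_iter()]
    unlabeled = [l for l in leaves if l not in species_of]
    if unlabeled:
        raise ValueError(f"leaves without species labels: {unlabeled}")

    totals = Counter(
        species_of[l] for l in leaves if l not in excluded
    )
    counts = _species_counts_below(st.tree, species_of, excluded)
    st.annotate_supports()

    best_clade: dict[str, int] = {sp: 0 for sp in totals}
    best_support: dict[str, float | None] = {sp: None for sp in totals}
    has_group: dict[str, bool] = {sp: False for sp in totals}
    for node in st.tree.preorder_node_iter():
        c = counts[node]
        if len(c) != 1:
            continue
        (sp, k), = c.items()
        if k == 0:
            continue
        parent = node.parent_node
        is_maximal = parent is None or len(counts[parent]) != 1
        if is_maximal and k >= 2:
            has_group[sp] = True
        if k > best_clade[sp]:
            best_clade[sp] = k
            best_support[sp] = getattr(node, "support", None)

    out = []
    for sp in sorted(totals):
        n = totals[sp]
        k = best_clade[sp]
        frac = k / n if n else 0.0
        singleton = n == 1
        out.append(
            SpeciesDelineation(
                species=sp,
                n_individuals=n,
                largest_pure_clade=k,
                fraction=frac,
                discriminated=(not singleton) and frac > tau,
                bootstrap=best_support[sp],
                monospecific_group=has_group[sp],
                singleton=singleton,
            )
        )
    return out


def count_discriminated(delineations: list[SpeciesDelineation]) -> int:
    """Number of multi-sample species passing the clade-fraction criterion."""
    return sum(1 for d in delineations if d.discriminated)


def count_monospecific_groups(delineations: list[SpeciesDelineation]) -> int:
    return sum(1 for d in delineations if d.monospecific_group)


def flag_misidentified(
    st: SupportTree,
    matrix: DistanceMatrix,
    samples: list[SampleRecord],
) -> list[MisidentificationFlag]:
    """Heuristic flag for probable misidentifications.

    A sample is flagged when BOTH hold: (i) the smallest clade containing it
    together with any conspecific also contains individuals of at least two
    other species, and (ii) its nearest neighbor by K2P belongs to a
    different section.  Samples without conspecifics are never flagged.
    Flags are advisory; re-running :func:`delineate` with the flagged set
    excluded yields the cleaned delineation.
    """
    species_of = {r.sample_id: r.species for r in samples}
    section_of = {r.sample_id: r.section for r in samples}
    leaves = {lf.taxon.label: lf for lf in st.tree.leaf_node_iter()}
    totals = Counter(species_of[l] for l in leaves)
    counts = _species_counts_below(st.tree, species_of, set())

    flags: list[MisidentificationFlag] = []
    for sid, leaf in leaves.items():
        sp = species_of[sid]
        if totals[sp] < 2:
            continue
        node = leaf.parent_node
        while node is not None and counts[node][sp] < 2:
            node = node.parent_node
        if node is None:
            continue
        other_species = [s for s in counts[node] if s != sp and counts[node][s] > 0]
        if len(other_species) < 2:
            continue
        i = matrix.ids.index(sid)
        row = matrix.values[i].copy()
        row[i] = np.nan
        if np.all(np.isnan(row)):
            continue
        nn = matrix.ids[int(np.nanargmin(row))]
        if section_of.get(nn) != section_of.get(sid):
            flags.append(
                MisidentificationFlag(
                    sample_id=sid,
                    reason="out_of_section_placement",
                    nearest_neighbor_species=species_of.get(nn, "?"),
                )
            )
    return flags


def write_delineation_table(delineations: list[SpeciesDelineation], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_individuals\tlargest_pure_clade\tfraction\tdiscriminated\tbootstrap\n")
        for d in delineations:
            sup = "" if d.bootstrap is None else f"{d.bootstrap:.0f}"
            fh.write(
                f"{d.species}\t{d.n_individuals}\t{d.largest_pure_clade}\t"
                f"{d.fraction:.3f}\t{int(d.discriminated)}\t{sup}\n"
            )
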