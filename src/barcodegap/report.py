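"""Whole-pipeline orchestration and reporting.

``run_evaluation`` executes, per configured dataset (single locus or
concatenation): site statistics -> K2P distances -> barcode-gap statistics
-> NJ tree (optionally bootstrapped) -> outgroup rooting -> misidentification
flags -> monophyly-based discrimination -> optional leave-one-out
identification, and emits a machine-readable report whose every number is
recomputable from the inputs plus the echoed configuration.

The outgroup sample is used for rooting only; distance partitions, site
statistics and identification run on the ingroup.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import discrimination as disc
from . import distances as dist
from . import identification as ident
from . import io_metadata as iom
from . import nj_tree as njt
from . import site_stats as sst

matplotlib_imported = False


def _ensure_matplotlib():
    global matplotlib_imported, plt
    if not matplotlib_imported:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt  # noqa: F401

        matplotlib_imported = True
    return plt


def evaluate_dataset(
    name: str,
    aln: iom.LocusAlignment,
    records: list[iom.SampleRecord],
    outgroup_id: str | None = None,
    tau: float = 0.5,
    bootstrap_B: int = 0,
    seed: int = 0,
    min_overlap: int = dist.DEFAULT_MIN_OVERLAP,
    run_identification: bool = False,
    aligner: ident.AlignerConfig | None = None,
    bin_width: float = 0.5,
) -> dict:
    """Full evaluation of one dataset; returns a nested result dict."""
    records_by_id = {r.sample_id: r for r in records}
    missing = [s for s in aln.sample_ids if s not in records_by_id]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    ingroup_ids = [s for s in aln.sample_ids if s != outgroup_id]
    ingroup_aln = aln.subset(ingroup_ids)
    ingroup_records = [records_by_id[s] for s in ingroup_ids]

    sites = sst.classify_sites(ingroup_aln)
    matrix_full = dist.distance_matrix(aln, min_overlap)
    matrix_in = dist.distance_matrix(ingroup_aln, min_overlap) if outgroup_id else matrix_full
    part = dist.partition(matrix_in, ingroup_records)
    gap = dist.barcode_gap(part, bin_width) if part.inter else None
    summary = dist.summarize(ingroup_aln, matrix_in, part, sites, ingroup_records, name)

    if bootstrap_B > 0:
        tree = njt.bootstrap_support(aln, njt.BootstrapConfig(bootstrap_B, seed), min_overlap)
    else:
        tree = njt.neighbor_joining(matrix_full)
    rooted = njt.root_at_outgroup(tree, outgroup_id if outgroup_id in aln.rows else None)

    flags = disc.flag_misidentified(rooted, matrix_full, records)
    excluded = {f.sample_id for f in flags}
    if outgroup_id:
        excluded.add(outgroup_id)
    delineations = disc.delineate(rooted, records, tau, excluded)

    result = {
        "dataset": name,
        "summary": summary.table_row(),
        "n_undefined_pairs": matrix_in.n_undefined,
        "overlap_fraction": None if gap is None else gap.overlap_fraction,
        "min_local_gap_per100": None if gap is None else gap.min_local_gap,
        "excluded_singleton_species": part.excluded_singletons,
        "n_species_discriminated_nj": disc.count_discriminated(delineations),
        "n_monospecific_groups": disc.count_monospecific_groups(delineations),
        "n_multisample_species": sum(1 for d in delineations if not d.singleton),
        "misidentification_flags": [asdict(f) for f in flags],
        "bootstrap_effective_B": tree.effective_B,
        "newick": rooted.write_newick(),
    }
    result["_objects"] = {
        "tree": rooted,
        "gap": gap,
        "delineations": delineations,
        "matrix": matrix_in,
        "sites": sites,
    }
    if run_identification:
        hitlists = ident.loo_identify(ingroup_aln, ingroup_records, aligner, matrix_in)
        summ = ident.identification_summary(hitlists, ingroup_records)
        result["identification"] = {
            "n_queries": summ.n_queries,
            "n_unidentifiable": summ.n_unidentifiable,
            "n_species_all_top1": summ.n_species_all_top1,
            "n_species_all_top3": summ.n_species_all_top3,
            "n_species_majority_top1": summ.n_species_majority_top1,
            "n_species_majority_top3": summ.n_species_majority_top3,
            "top1_accuracy_pct": summ.top1_accuracy_pct,
            "per_section_pct": summ.per_section_pct,
            "mean_section_pct_unweighted": summ.mean_section_pct_unweighted,
            "mean_section_pct_weighted": summ.mean_section_pct_weighted,
        }
        result["_objects"]["hitlists"] = hitlists
    return result


def plot_distance_histograms(gap: dist.BarcodeGapReport, path, title: str = "") -> None:
    """Overlaid relative-frequency histograms of intra vs inter rates."""
    plt = _ensure_matplotlib()
    centers = (gap.bin_edges[:-1] + gap.bin_edges[1:]) / 2.0
    w = gap.bin_width * 0.45
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(centers - w / 2, gap.intra_freq, width=w, color="tab:blue",
           label="intraspecific")
    ax.bar(centers + w / 2, gap.inter_freq, width=w, color="tab:red",
           label="interspecific")
    ax.set_xlabel("K2P substitution rate per 100 sites")
    ax.set_ylabel("relative frequency")
    cap = title
    if gap.overlap_fraction is not None:
        cap = f"{title} (overlap {gap.overlap_fraction:.2f})".strip()
    ax.set_title(cap)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def run_evaluation(config: dict, outdir) -> dict:
    """Execute the configured evaluation end to end and write artifacts.

    Config keys: ``metadata`` (TSV path), ``loci`` (list of {name, path,
    coding}), ``datasets`` (list of {name, loci}), ``outgroup_id``, ``tau``,
    ``bootstrap``, ``seed``, ``min_overlap``, ``identify`` (dataset names to
    run leave-one-out identification on), ``aligner`` (AlignerConfig
    overrides), ``bin_width``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("metadata", "loci", "datasets"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    meta_path = Path(config["metadata"])
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    for lspec in config["loci"]:
        if not Path(lspec["path"]).exists():
            raise FileNotFoundError(lspec["path"])

    records = iom.read_metadata(meta_path)
    loci: dict[str, iom.LocusAlignment] = {}
    removal_logs: list[iom.IndelRemoval] = []
    for lspec in config["loci"]:
        aln = iom.read_fasta_alignment(lspec["path"], lspec["name"])
        aln, log = iom.strip_autapomorphic_indels(aln, bool(lspec.get("coding", False)))
        removal_logs.extend(log)
        loci[lspec["name"]] = aln
    if removal_logs:
        iom.write_removal_log(removal_logs, outdir / "indel_removals.tsv")

    aligner = ident.AlignerConfig(**config.get("aligner", {}))
    identify = set(config.get("identify", []))
    rows = []
    report: dict = {"datasets": {}, "config": _echo_config(config, aligner)}
    for ds in config["datasets"]:
        name = ds["name"]
        ds_loci = [loci[l] for l in ds["loci"]]
        if len(ds_loci) == 1:
            aln = ds_loci[0]
        else:
            concat = iom.concatenate(ds_loci, records)
            aln = concat.as_locus_alignment(name)
        result = evaluate_dataset(
            name,
            aln,
            records,
            outgroup_id=config.get("outgroup_id"),
            tau=float(config.get("tau", 0.5)),
            bootstrap_B=int(config.get("bootstrap", 0)),
            seed=int(config.get("seed", 0)),
            min_overlap=int(config.get("min_overlap", dist.DEFAULT_MIN_OVERLAP)),
            run_identification=name in identify,
            aligner=aligner,
            bin_width=float(config.get("bin_width", 0.5)),
        )
        objs = result.pop("_objects")
        objs["tree"].write_newick(outdir / f"{name}.nwk")
        if objs["gap"] is not None:
            plot_distance_histograms(objs["gap"], outdir / f"{name}_hist.png", name)
        disc.write_delineation_table(objs["delineations"], outdir / f"{name}_delineation.tsv")
        objs["matrix"].to_phylip(outdir / f"{name}.phylip.dist")
        if "hitlists" in objs:
            ident.write_hit_table(objs["hitlists"], outdir / f"{name}_hits.tsv")
        row = dict(result["summary"])
        row["n_species_identified_nj"] = result["n_species_discriminated_nj"]
        if "identification" in result:
            row["n_species_identified_top1_majority"] = result["identification"][
                "n_species_majority_top1"
            ]
        rows.append(row)
        report["datasets"][name] = result
    pd.DataFrame(rows).to_csv(outdir / "report.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _echo_config(config: dict, aligner: ident.AlignerConfig) -> dict:
    echo = {k: v for k, v in config.items() if k != "aligner"}
    echo["aligner"] = asdict(aligner)
    echo.setdefault("tau", 0.5)
    echo.setdefault("bootstrap", 0)
    echo.setdefault("seed", 0)
    echo.setdefault("min_overlap", dist.DEFAULT_MIN_OVERLAP)
    return echo


def compare_to_reference(report_rows: list[dict], reference_rows: list[dict]) -> pd.DataFrame:
    """Per-column deviation report between computed and reference table rows.

    Rows are matched on ``dataset``; numeric columns common to both are
    compared and the absolute and relative deviations reported.  Intended
    for re-analyses of published datasets where exact agreement is not
    expected (alignment differences propagate into every downstream count).
    """
    ref_by_name = {r["dataset"]: r for r in reference_rows}
    out = []
    for row in report_rows:
        name = row.get("dataset")
        ref = ref_by_name.get(name)
        if ref is None:
            continue
        for col, val in row.items():
            if col == "dataset" or not isinstance(val, (int, float)) or val is None:
                continue
            rv = ref.get(col)
            if not isinstance(rv, (int, float)):
                continue
            dev = float(val) - float(rv)
            out.append(
                {
                    "dataset": name,
                    "column": col,
                    "computed": float(val),
                    "reference": float(rv),
                    "deviation": dev,
                    "relative_deviation": dev / rv if rv else np.nan,
                }
            )
    return pd.DataFrame(out)
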