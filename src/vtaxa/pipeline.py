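"""End-to-end orchestration: simulate -> delimit -> matrices -> stats -> sem.

One master seed drives every stochastic stage (simulation, bootstrap,
rarefaction, NMDS starts, Mantel permutations), so a fixed seed reproduces
every output file byte for byte.  All outputs are plain text (FASTA, TSV,
Newick, JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import (
    community_stats,
    occurrence,
    path_model,
    phylo,
    seqops,
    synthetic_data,
    vt_delimit,
)

#: schemes for which the pipeline writes incidence matrices
PIPELINE_SCHEMES = (
    "host_order", "functional_group", "ecosystem", "continent", "realm",
    "climate", "supercontinent", "location",
)


def location_category_counts(meta_df: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """locations x categories sequence-count table from the metadata frame."""
    if scheme == "supercontinent":
        cats = meta_df.apply(
            lambda r: occurrence.map_supercontinent(r["continent"], r["realm"]), axis=1
        )
    else:
        cats = meta_df[scheme]
    tab = pd.crosstab(meta_df["location_id"], cats)
    tab.index.name = "location_id"
    return tab.sort_index().sort_index(axis=1)


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    synth_cfg: synthetic_data.SynthConfig | None = None,
    meta_cfg: synthetic_data.MetaConfig | None = None,
    vt_cfg: vt_delimit.VTConfig | None = None,
    n_rarefaction_iter: int = 1000,
    n_mantel_perm: int = 999,
) -> dict:
    """Run the full analysis chain on synthetic data; returns a result dict
    and writes all artifacts under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    synth_cfg = synth_cfg or synthetic_data.SynthConfig(
        n_taxa=12, members_per_taxon=6, seq_length=400,
        intra_mut=0.02, inter_div=0.20, seed=seed,
    )
    meta_cfg = meta_cfg or synthetic_data.MetaConfig(
        endemism_fraction=0.8, n_locations=30, seed=seed + 1
    )
    vt_cfg = vt_cfg or vt_delimit.VTConfig(seed=seed + 2)

    # --- simulate -----------------------------------------------------------
    records, truth = synthetic_data.generate_taxa(synth_cfg)
    meta_df = synthetic_data.attach_metadata(truth, meta_cfg)
    seqops.write_fasta(records, out / "sequences.fasta")
    synthetic_data.write_metadata(meta_df, out / "metadata.tsv")
    synthetic_data.write_truth(truth, synth_cfg, out / "truth.json")

    # --- delimit ------------------------------------------------------------
    assignment = vt_delimit.delimit_vts(records, vt_cfg)
    vt_delimit.write_vt_tsv(assignment, out / "vts.tsv")
    vt_delimit.write_vt_summary(assignment, out / "vt_summary.json")
    by_id = {r.id: r for r in records}
    seqops.write_fasta(
        [by_id[assignment.representatives[v]] for v in sorted(assignment.members)],
        out / "vt_representatives.fasta",
    )
    if assignment.tree is not None:
        phylo.write_newick(assignment.tree, out / "representatives.nwk")

    # --- matrices -----------------------------------------------------------
    meta = occurrence.validate_metadata(meta_df)
    matrices: dict[str, occurrence.IncidenceMatrix] = {}
    for scheme in PIPELINE_SCHEMES:
        m = occurrence.incidence_matrix(assignment, meta, scheme)
        matrices[scheme] = m
        m.to_tsv(out / f"incidence_{scheme}.tsv")

    # --- stats --------------------------------------------------------------
    vt_of = assignment.vt_of()
    labels = [vt_of[r.id] for r in records]
    curve = community_stats.rarefaction(
        labels, n_iter=n_rarefaction_iter, seed=seed + 3
    )
    curve.to_frame().to_csv(out / "rarefaction.tsv", sep="\t", index=False)

    spec_results = {}
    for scheme in ("host_order", "functional_group", "ecosystem", "continent",
                   "realm", "climate", "supercontinent"):
        overall, per_col = community_stats.specificity(matrices[scheme])
        spec_results[scheme] = {"overall": overall, "per_category": per_col}

    vt_by_loc = matrices["location"]
    bc_vt = community_stats.bray_curtis(vt_by_loc, by="columns")
    meta_frame = occurrence.metadata_frame(meta)
    plant_by_loc = location_category_counts(meta_frame, "host_order")
    bc_plant = community_stats.bray_curtis(
        plant_by_loc.T[list(bc_vt.ids)], by="columns"
    )
    ordination = community_stats.nmds(bc_vt, k=2, seed=seed + 4)
    ordination.to_frame().to_csv(out / "nmds_locations.tsv", sep="\t", index_label="location_id")
    mres = community_stats.mantel(
        bc_vt, bc_plant, n_perm=n_mantel_perm, seed=seed + 5
    )
    reg = community_stats.host_range_vs_geo(assignment, meta)

    stats_payload = {
        "specificity": spec_results,
        "nmds_stress": ordination.stress,
        "mantel": {"r": mres.r, "p": mres.p, "n_perm": mres.n_perm},
        "host_range_vs_geo": vars(reg),
    }
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # --- sem ----------------------------------------------------------------
    scores = {}
    scores["amf"] = path_model.composition_scores(vt_by_loc.counts.T)
    scores["plant"] = path_model.composition_scores(plant_by_loc)
    for var, scheme in (
        ("ecosystem", "ecosystem"), ("climate", "climate"),
        ("continent", "continent"), ("biogeography", "realm"),
    ):
        scores[var] = path_model.composition_scores(
            location_category_counts(meta_frame, scheme)
        )
    table = pd.DataFrame(
        {v: s.to_series() for v, s in scores.items()}
    ).dropna()
    table = table[list(path_model.PathSpec().variables)]
    table.to_csv(out / "sem_scores.tsv", sep="\t", index_label="location_id")
    sem = path_model.fit_path_model(table, path_model.PathSpec())
    sem_payload = {
        "n": sem.n,
        "direct": {f"{s}->{d}": v for (s, d), v in sorted(sem.direct.items())},
        "indirect": {f"{s}->{d}": v for (s, d), v in sorted(sem.indirect.items())},
        "total": {f"{s}->{d}": v for (s, d), v in sorted(sem.total.items())},
        "r_squared": sem.r_squared,
        "fit": sem.fit,
    }
    with open(out / "sem.json", "w") as fh:
        json.dump(sem_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "records": records,
        "truth": truth,
        "assignment": assignment,
        "matrices": matrices,
        "rarefaction": curve,
        "specificity": spec_results,
        "ordination": ordination,
        "mantel": mres,
        "host_range_vs_geo": reg,
        "sem": sem,
    }
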