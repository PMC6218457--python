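"""End-to-end stages wiring simulation, measurement and reporting.

Each stage reads/writes plain files under the configured directories so
runs are resumable and auditable; a manifest with SHA-256 checksums and
the effective config is written next to the outputs.  Per-neuron
failures in the analysis stages are collected into a failure manifest
instead of aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import morphometry, projection, stats, swc
from .atlas import LabelVolume, MidlinePlane, RegionOntology, read_nrrd, write_nrrd
from .config import RunConfig
from .errors import MissingUpstream, ProjectomeError
from .synthetic import SyntheticAtlas, make_atlas, simulate_population

log = logging.getLogger("projectome")

MORPHOMETRY_CSV = "morphometry.csv"
MATRIX_CSV = "projection_matrix.csv"
REGIONS_CSV = "region_lengths.csv"
HEMI_CSV = "hemisphere_split.csv"
CLASSES_CSV = "class_records.csv"
SUMMARY_CSV = "group_summary.csv"
COMPARISONS_CSV = "group_comparisons.csv"
REPORT_MD = "report.md"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: str, files: List[str], config: RunConfig, name: str) -> None:
    manifest = {
        "config": config.to_dict(),
        "files": {os.path.relpath(f, out_dir): _sha256(f) for f in sorted(files)},
    }
    path = os.path.join(out_dir, name)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def cmd_simulate(config: RunConfig, out_dir: str) -> Dict[str, str]:
    """Write the synthetic atlas and demo population to ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    swc_dir = os.path.join(out_dir, config.swc_dir)
    gt_dir = os.path.join(out_dir, config.ground_truth_dir)
    os.makedirs(swc_dir, exist_ok=True)
    os.makedirs(gt_dir, exist_ok=True)

    atlas = make_atlas()
    vol_path = os.path.join(out_dir, config.atlas_volume)
    ont_path = os.path.join(out_dir, config.ontology)
    write_nrrd(atlas.volume, vol_path)
    atlas.ontology.to_csv(ont_path)

    files = [vol_path, ont_path]
    offset = 0
    for regime, n in config.population.items():
        pop = simulate_population(n, regime, seed=config.seed + offset, atlas=atlas)
        offset += 1000
        for m, gt in pop:
            swc_path = os.path.join(swc_dir, f"{m.name}.swc")
            swc.write_swc(m, swc_path)
            gt_path = os.path.join(gt_dir, f"{m.name}.json")
            with open(gt_path, "w") as fh:
                fh.write(gt.to_json())
            files += [swc_path, gt_path]
        log.info("simulated %d neurons from regime %s", n, regime)
    _write_manifest(out_dir, files, config, "manifest.json")
    return {"out_dir": out_dir, "n_files": str(len(files))}


def _load_atlas(config: RunConfig, root: str) -> Tuple[LabelVolume, RegionOntology, MidlinePlane]:
    vol = read_nrrd(os.path.join(root, config.atlas_volume))
    ont = RegionOntology.from_csv(os.path.join(root, config.ontology))
    if config.downsample_factors != (1, 1, 1):
        from .atlas import downsample_labels

        vol = downsample_labels(vol, config.downsample_factors)
    # midline halfway across the first axis: the synthetic atlas is built
    # symmetric about it; real atlases supply their own config.
    mid = MidlinePlane(
        axis="x",
        coordinate=vol.origin[0] + vol.labels.shape[0] * vol.voxel_size[0] / 2.0,
    )
    return vol, ont, mid


def _load_morphologies(swc_dir: str) -> Tuple[List[swc.Morphology], Dict[str, str]]:
    neurons, failures = [], {}
    for fn in sorted(os.listdir(swc_dir)):
        if not fn.endswith(".swc"):
            continue
        try:
            neurons.append(swc.read_swc(os.path.join(swc_dir, fn)))
        except ProjectomeError as exc:
            failures[fn] = str(exc)
    return neurons, failures


def _group_label(ont: RegionOntology, soma_region: int, layer: str) -> str:
    """Table-style group label: area acronym + layer, e.g. 'MOs_L2/3'."""
    chain = [soma_region] + ont.ancestors(soma_region)
    # the area is the ancestor directly below the root
    area = chain[-2] if len(chain) >= 2 else soma_region
    tag = f"_L{layer}" if layer != "unknown" else ""
    return f"{ont.acronym(area)}{tag}"


def cmd_analyze(config: RunConfig, root: str) -> Dict[str, pd.DataFrame]:
    """Morphometry, projection, classification and group tables.

    Reads the SWC population and atlas under ``root`` and writes every
    table to ``root/output_dir``.  Per-neuron failures are recorded in
    ``failures.json`` and do not abort the other neurons.
    """
    out_dir = os.path.join(root, config.output_dir)
    os.makedirs(out_dir, exist_ok=True)
    vol, ont, mid = _load_atlas(config, root)
    neurons, failures = _load_morphologies(os.path.join(root, config.swc_dir))
    step = config.step_um

    records, profiles, class_rows, hemi_rows, region_rows = [], [], [], [], []
    try:
        cc_id = ont.id_of(config.cc_acronym) if config.cc_acronym else None
    except ProjectomeError:
        cc_id = None
    for m in neurons:
        try:
            records.append(morphometry.summarize_neuron(m))
            prof = projection.compute_profile(m, vol, mid, step)
            profiles.append(prof)
            split = projection.hemisphere_split(m, vol, mid, step)
            hemi_rows.append(
                {
                    "name": m.name,
                    "ipsi_mm": split.ipsi_length / 1000.0,
                    "contra_mm": split.contra_length / 1000.0,
                    "on_midline_mm": split.on_midline_length / 1000.0,
                    "ipsi_fraction": split.ipsi_fraction,
                    "contra_fraction": split.contra_fraction,
                }
            )
            rec = classify_mod.classify_it(
                m, vol, mid, ont, cc_id, min_contra_mm=config.min_contra_mm, step=step
            )
            class_rows.append(
                {
                    "name": m.name,
                    "soma_region": ont.acronym(rec.soma_region),
                    "soma_layer": rec.soma_layer,
                    "group": _group_label(ont, rec.soma_region, rec.soma_layer),
                    "it_subclass": rec.it_subclass,
                    "contra_axon_mm": rec.contra_axon_mm,
                    "crossed_via_cc": rec.crossed_via_cc,
                    "ap_extension_um": rec.ap_extension_um,
                }
            )
            for rid, length in sorted(prof.region_lengths.items()):
                region_rows.append(
                    {
                        "name": m.name,
                        "region": ont.acronym(rid) if rid in ont else "background",
                        "length_mm": length / 1000.0,
                        "fraction": length / prof.total_axon_length,
                        "tips": prof.region_tips.get(rid, 0),
                    }
                )
        except ProjectomeError as exc:
            failures[m.name] = str(exc)
            log.warning("neuron %s failed: %s", m.name, exc)

    tables: Dict[str, pd.DataFrame] = {}
    tables[MORPHOMETRY_CSV] = morphometry.records_to_frame(records)
    tables[REGIONS_CSV] = pd.DataFrame(region_rows)
    tables[HEMI_CSV] = pd.DataFrame(hemi_rows)
    tables[CLASSES_CSV] = pd.DataFrame(class_rows)

    matrix = projection.projection_matrix(profiles, ont, config.level)
    categories = classify_mod.categorize_profiles(
        matrix, theta=config.theta, jaccard_cutoff=config.jaccard_cutoff
    )
    tables[CLASSES_CSV]["category_id"] = [
        categories.get(n, -1) for n in tables[CLASSES_CSV]["name"]
    ]
    tables[MATRIX_CSV] = matrix

    # group summaries + the standard comparisons
    merged = tables[MORPHOMETRY_CSV].merge(
        tables[CLASSES_CSV][["name", "group", "it_subclass"]], on="name", how="left"
    )
    summaries = stats.summarize_groups(merged, group_col="group")
    tables[SUMMARY_CSV] = pd.DataFrame([s.row() for s in summaries])

    comp_frames = []
    labels = set(merged["group"])
    for a, b in [
        ("MOs_L2/3", "MOs_L5"),
        ("MOs_L2/3", "PL_L2/3"),
        ("MOs_L2/3", "ORBm_L2/3"),
        ("PL_L2/3", "ORBm_L2/3"),
    ]:
        if a in labels and b in labels:
            sub = merged[merged["group"].isin([a, b])]
            if (sub["group"] == a).sum() >= 2 and (sub["group"] == b).sum() >= 2:
                comp_frames.append(
                    stats.compare_group_table(sub, a, b, group_col="group", welch=config.welch)
                )
    # CPN vs APN within layer-2/3 cortex
    l23 = merged[merged["group"].str.endswith("L2/3", na=False)]
    if (l23["it_subclass"] == "CPN").sum() >= 2 and (l23["it_subclass"] == "APN").sum() >= 2:
        comp_frames.append(
            stats.compare_group_table(l23, "CPN", "APN", group_col="it_subclass", welch=config.welch)
        )
    comp_cols = ["metric", "group_a", "group_b", "t", "df", "p", "significance"]
    tables[COMPARISONS_CSV] = (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(columns=comp_cols)
    )

    files = []
    for fname, df in tables.items():
        path = os.path.join(out_dir, fname)
        df.to_csv(path, index=(fname == MATRIX_CSV))
        files.append(path)
    if failures:
        with open(os.path.join(out_dir, "failures.json"), "w") as fh:
            json.dump(failures, fh, indent=1, sort_keys=True)
    _write_manifest(out_dir, files, config, "analysis_manifest.json")
    return tables


def cmd_report(config: RunConfig, root: str) -> str:
    """Markdown report: group means ± s.e.m. and per-neuron hemisphere split."""
    out_dir = os.path.join(root, config.output_dir)
    needed = [SUMMARY_CSV, HEMI_CSV, COMPARISONS_CSV]
    for f in needed:
        if not os.path.exists(os.path.join(out_dir, f)):
            raise MissingUpstream(f"run the analysis first: missing {f}")
    summary = pd.read_csv(os.path.join(out_dir, SUMMARY_CSV))
    hemi = pd.read_csv(os.path.join(out_dir, HEMI_CSV))
    comps = pd.read_csv(os.path.join(out_dir, COMPARISONS_CSV))

    lines = ["# Projectome analysis report", "", "## Group summaries (mean ± s.e.m.)", ""]
    metric_labels = {
        "axonal_length_mm": "Axonal length (mm)",
        "axonal_branches": "Axonal branches",
        "axonal_tips": "Terminal tips of axon",
        "dendritic_length_mm": "Dendritic length (mm)",
        "dendritic_branches": "Dendritic branches",
        "dendritic_tips": "Terminal tips of dendrite",
    }
    header = "| Metric | " + " | ".join(
        f"{r['group']} (n={r['n']})" for _, r in summary.iterrows()
    ) + " |"
    lines += [header, "|" + "---|" * (len(summary) + 1)]
    for metric, label in metric_labels.items():
        cells = []
        for _, r in summary.iterrows():
            mean, se = r.get(f"{metric}_mean"), r.get(f"{metric}_sem")
            if pd.isna(mean):
                cells.append("flagged (empty)")
            elif pd.isna(se):
                cells.append(f"{mean:.2f} (n=1, s.e.m. undefined)")
            else:
                cells.append(f"{mean:.2f} ± {se:.2f}")
        lines.append(f"| {label} | " + " | ".join(cells) + " |")

    lines += ["", "## Per-neuron hemisphere decomposition", ""]
    lines += ["| Neuron | ipsi % | contra % |", "|---|---|---|"]
    for _, r in hemi.iterrows():
        lines.append(
            f"| {r['name']} | {100 * r['ipsi_fraction']:.1f} | {100 * r['contra_fraction']:.1f} |"
        )

    if len(comps):
        lines += ["", "## Group comparisons (Student's t)", ""]
        lines += ["| Metric | Groups | t | df | p | |", "|---|---|---|---|---|---|"]
        for _, r in comps.iterrows():
            lines.append(
                f"| {r['metric']} | {r['group_a']} vs {r['group_b']} | "
                f"{r['t']:.3f} | {r['df']:.0f} | {r['p']:.4g} | {r['significance']} |"
            )

    text = "\n".join(lines) + "\n"
    with open(os.path.join(out_dir, REPORT_MD), "w") as fh:
        fh.write(text)
    return text
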