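"""End-to-end driver: synthesis → registration → segmentation →
quantification → atlas report.

``run_pipeline`` executes the whole chain on synthetic specimens and writes
a run directory containing the resolved config, CSV tables, a Markdown
report (atlas census block + phantom-recovery metrics) and a log.  Outputs
are deterministic given the config seeds.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantification as qn
from . import registration as rg
from . import segmentation as sg
from .atlas import queries
from .atlas.records import load_atlas
from .config import PipelineConfig, stage_seed
from .phantom import (
    COMPARTMENT_IDS,
    NucleiSpec,
    PhantomSpec,
    default_pa_cells,
    make_nucleus_field,
    make_photoactivation_pair,
    make_specimen,
    make_standard_brain,
    random_specimen_transform,
)
from .volume import Volume

__all__ = ["run_pipeline", "atlas_census", "census_markdown"]

log = logging.getLogger("mbatlas.pipeline")


def atlas_census() -> dict:
    """The printed count arithmetic of the packaged atlas."""
    atlas = load_atlas()
    return {
        "mbon_cells": queries.total_cells("MBON", atlas),
        "mbon_types": len(atlas.of_class("MBON")),
        "mbon_multiplicity": queries.count_by_compartment_multiplicity("MBON", atlas),
        "dan_types": len(atlas.of_class("DAN")),
        "dan_multiplicity": queries.count_by_compartment_multiplicity("DAN", atlas),
        "mbon_transmitters": queries.transmitter_census("MBON", atlas),
        "dan_transmitters": queries.transmitter_census("DAN", atlas),
        "kc_cells": queries.total_cells("KC", atlas),
        "kc_cells_rounded": queries.total_cells("KC", atlas, round_to=100),
        "subdivisions": len(atlas.catalog),
        "pam_split_gal4": queries.sum_pam_counts("split_gal4", atlas),
        "pam_pa_gfp": queries.sum_pam_counts("pa_gfp", atlas),
        "feedforward_depth": queries.feedforward_depth(atlas),
        "mbons_without_mbon_input": len(queries.mbons_without_mbon_input(atlas)),
        "convergence_a2p3p": queries.convergence_ratio("MBON-a2p3p", atlas),
        "convergence_b2bp2a": queries.convergence_ratio("MBON-b2bp2a", atlas),
    }


def census_markdown(census: dict) -> str:
    lines = [
        "## Atlas census",
        "",
        f"- MBONs: {census['mbon_cells']} cells of {census['mbon_types']} types; "
        f"dendritic compartments per type: {census['mbon_multiplicity']}",
        f"- DANs: {census['dan_types']} types; terminal compartments per type: "
        f"{census['dan_multiplicity']}",
        f"- MBON transmitters (types): {census['mbon_transmitters']}",
        f"- DAN transmitters (types): {census['dan_transmitters']}",
        f"- KCs: {census['kc_cells']} cells (~{census['kc_cells_rounded']}) of 7 types",
        f"- Elemental subdivisions: {census['subdivisions']}",
        f"- PAM-cluster sums: split-GAL4 {census['pam_split_gal4']}, "
        f"PA-GFP {census['pam_pa_gfp']}",
        f"- Feedforward network depth: {census['feedforward_depth']} MBON layers; "
        f"{census['mbons_without_mbon_input']} MBON types read out KCs only",
        f"- KC→MBON convergence: {census['convergence_b2bp2a']}:1 down to "
        f"{census['convergence_a2p3p']}:1",
        "",
    ]
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full chain; returns the run directory.

    Any stage failure raises with the stage named in the log; partial
    outputs already written are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "resolved_config.yaml")
        report = ["# mb-atlas pipeline report", ""]
        census = atlas_census()
        report.append(census_markdown(census))

        # --- stage: synthesis -------------------------------------------------
        log.info("stage synth: standard brain %s", config.grid_shape)
        if config.standard_brain_path is not None:
            p = Path(config.standard_brain_path)
            if not p.exists():
                raise FileNotFoundError(
                    f"standard_brain_path does not exist: {p}"
                )
        spec = PhantomSpec(
            shape=config.grid_shape,
            spacing_um=config.spacing_um,
            border_dip_factor=config.border_dip_factor,
            seed=stage_seed(config.seed, "standard"),
        )
        std = make_standard_brain(spec)
        atlas = load_atlas()

        specimens = []
        for i in range(config.n_specimens):
            t = random_specimen_transform(
                config.grid_shape, config.spacing_um,
                stage_seed(config.seed, "transform", i), spec.deformation,
            )
            types = (config.expressed_types[i % len(config.expressed_types)],)
            specimens.append(
                make_specimen(std, t, types, spec.noise,
                              stage_seed(config.seed, "specimen", i), atlas)
            )
        log.info("stage synth: %d specimens", len(specimens))

        # --- stage: registration ----------------------------------------------
        scores = []
        transforms = []
        for i, sp in enumerate(specimens):
            affine, sc_a = rg.register_affine(
                sp.reference, std.reference,
                metric_weight=config.metric_weight,
                pyramid=config.registration_pyramid,
                maxiter=config.affine_maxiter,
            )
            if config.deform_iterations:
                total, sc = rg.register_deformable(
                    sp.reference, std.reference, affine,
                    metric_weight=config.metric_weight,
                    iterations=config.deform_iterations,
                    pyramid=config.registration_pyramid[: len(config.deform_iterations)],
                )
            else:
                total, sc = affine, sc_a
            scores.append(sc)
            transforms.append(total)
            log.info("stage register: specimen %d blended=%.4f", i, sc.blended)
        pd.DataFrame(
            {
                "specimen": range(len(scores)),
                "ncc": [s.ncc for s in scores],
                "mi": [s.mi for s in scores],
                "blended": [s.blended for s in scores],
            }
        ).to_csv(tables / "registration_scores.csv", index=False)

        selected = rg.gate_specimens(scores, config.keep_fraction)
        log.info("stage gate: kept %s of %d", selected, len(specimens))
        report.append(
            f"## Registration\n\n- {len(specimens)} specimens registered; "
            f"kept {len(selected)} (keep_fraction={config.keep_fraction}): "
            f"{sorted(selected)}\n"
        )

        # --- stage: segmentation ----------------------------------------------
        nuclei = make_nucleus_field(
            NucleiSpec(n=config.n_nuclei, touching_fraction=config.touching_fraction),
            seed=stage_seed(config.seed, "nuclei"),
        )
        gate = sg.NucleusSizeGate(config.gate_mean_um, config.gate_sd_um)
        counted = sg.count_nuclei_two_pass(
            nuclei.nuclear, nuclei.membrane, gate, config.t_low, config.t_high
        )
        log.info("stage count: %d nuclei (true %d)", counted.total, nuclei.true_count)
        pd.DataFrame(
            [
                {"label": o.label, "voxels": o.voxels, "volume_um3": o.volume_um3,
                 "z_um": o.centroid_um[0], "y_um": o.centroid_um[1],
                 "x_um": o.centroid_um[2], "pass": o.pass_id}
                for o in counted.objects
            ]
        ).to_csv(tables / "nuclei.csv", index=False)

        cells, region = default_pa_cells(
            shape=config.grid_shape, seed=stage_seed(config.seed, "photoactivation")
        )
        pair = make_photoactivation_pair(
            region, cells, seed=stage_seed(config.seed, "photoactivation", 1)
        )
        _shift, aligned, _low = rg.align_before_after(pair.pre, pair.post)
        candidates = {f"cell{i:02d}": c.soma_mask(region.shape)
                      for i, c in enumerate(pair.cells)}
        calls = sg.detect_photoactivated(pair.pre, aligned, pair.roi_mask, candidates)
        n_true = sum(pair.activated_truth)
        n_called = sum(calls.values())
        log.info("stage detect-pa: %d called (true %d)", n_called, n_true)
        report.append(
            f"## Segmentation\n\n- nucleus counter: {counted.total} of "
            f"{nuclei.true_count} (passes {counted.pass_counts})\n"
            f"- photoactivated cells: {n_called} called, {n_true} true\n"
        )

        # --- stage: quantification --------------------------------------------
        per_comp: dict[str, list[Volume]] = {}
        dendrite_masks: dict[str, np.ndarray] = {}
        assigned: dict[str, set[str]] = {}
        groups: dict[str, list[Volume]] = {}
        masks_by_type: dict[str, list[np.ndarray]] = {}
        for i in selected:
            sp = specimens[i]
            t = transforms[i]
            membrane_std = t.apply(sp.membrane, std.reference)
            presyn_std = t.apply(sp.presynaptic, std.reference)
            terminal, dendrite = sg.split_terminals_dendrites(
                membrane_std, presyn_std, config.enrichment_min
            )
            for tname in sp.ground_truth.expressed_types:
                rec = atlas[tname]
                comps = atlas.catalog.compartments_of(
                    rec.dendrite_regions if rec.cell_class == "MBON"
                    else rec.axon_regions_in_lobes
                )
                assigned[tname] = set(comps)
                sig = membrane_std.with_data(
                    membrane_std.data * (dendrite | terminal)
                )
                for comp in comps:
                    per_comp.setdefault(comp, []).append(
                        membrane_std.with_data(
                            membrane_std.data * std.compartment_mask(comp)
                        )
                    )
                dendrite_masks.setdefault(tname, dendrite.copy())
                groups.setdefault(rec.transmitter, []).append(sig)
                masks_by_type.setdefault(tname, []).append(membrane_std.data > 0.5)

        if per_comp:
            labels, id_map = qn.build_compartment_masks(
                per_comp, std.lobe_mask, config.sigma_blur
            )
            metrics = qn.tiling_metrics(
                dendrite_masks, assigned, std.compartment_labels.data,
                COMPARTMENT_IDS, coverage=std.reference.data,
            )
            pd.Series(metrics["cross_compartment_fraction"]).to_csv(
                tables / "cross_compartment_fraction.csv", header=["fraction"]
            )
            pd.Series(
                {f"{a}|{b}": flag for (a, b), flag in metrics["border_gap"].items()}
            ).to_csv(tables / "border_gaps.csv", header=["gap"])

            fractions = qn.neuropil_fractions(
                groups, std.neuropil_labels, std.neuropil_id_map,
                region_order=atlas.neuropil_regions,
            )
            fractions.to_csv(tables / "neuropil_fractions.csv")
            grid = qn.density_grid(
                {g: vols[0] for g, vols in groups.items()}, config.cube_voxels
            )
            grid.to_frame().to_csv(tables / "density_grid.csv")
            if len(masks_by_type) >= 2:
                om = qn.build_overlap_matrix(masks_by_type, config.tolerance_radius_vox)
                om.scores.to_csv(tables / "overlap_scores.csv")
                k = min(config.k_clusters, len(om.scores))
                clusters = qn.cluster_matrix(om, k)
                pd.Series(clusters).to_csv(tables / "clusters.csv", header=["group"])
            report.append("## Quantification\n\n- tables written under tables/\n")

        (out / "report.md").write_text("\n".join(report))
        log.info("pipeline complete: %s", out)
        return out
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
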