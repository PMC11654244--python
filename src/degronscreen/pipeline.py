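"""End-to-end synthetic screen pipeline.

Chains the stages — growth scoring, responsiveness classification, decay
fitting, GO-slim recovery, grouped responsiveness, montage — on synthetic
inputs generated from the run config's seeds, and writes one
provenance-stamped output directory.  Identical config => byte-identical
outputs; all randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import enrichment, fluorescence_screen as fluor, grouping, growth_screen as growth
from . import io as dio
from . import kinetics, montage as mont, synthetic_data as sim
from .config import RunConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger("degronscreen")


def _stage_logger(stage: str) -> logging.LoggerAdapter:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[degronscreen:%(stage)s] %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    return logging.LoggerAdapter(logger, {"stage": stage})


def _seed(config: RunConfig, offset: int) -> int:
    return (config.seed * 1000 + offset) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns a result bundle of key outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash(), "version": __version__}
    summary: dict = {"config_hash": results["config_hash"], "version": __version__}
    s = config.sim

    try:
        if "growth" in config.stages:
            log = _stage_logger("growth")
            screen = sim.ScreenSimConfig(
                layout=(s.layout_rows, s.layout_cols),
                n_strains=s.n_strains,
                lethal_fraction=s.lethal_fraction,
                effect_size=s.effect_size,
                noise_cv=s.noise_cv,
                edge_boost=s.edge_boost,
                seed=_seed(config, 1),
            )
            ind1, unind1, truth = sim.gen_plate_pair(screen, replicate=1)
            ind2, unind2, _ = sim.gen_plate_pair(screen, replicate=2)
            scores = growth.score_relative_growth(
                [ind1, ind2], [unind1, unind2],
                presence_threshold=config.growth.presence_threshold,
            )
            scores = growth.normalize_scores(scores, trim_k=config.growth.trim_k)
            calls = growth.classify_essentiality(
                scores, permissive=config.growth.permissive, stringent=config.growth.stringent
            )
            dio.write_plate_table([ind1, unind1, ind2, unind2], outdir / "plates.tsv")
            dio.write_growth_calls(scores, calls, outdir / "growth_calls.tsv")
            results["growth"] = {"scores": scores, "calls": calls, "truth": truth}
            n_severe = sum(c.severe for c in calls)
            summary["growth"] = {"n_strains": len(calls), "n_severe": n_severe}
            log.info("scored %d strains, %d severe", len(calls), n_severe)

        if "fluor" in config.stages:
            log = _stage_logger("fluor")
            rng = np.random.default_rng(_seed(config, 2))
            n_panel = min(s.n_strains, 200)
            pairs, truth_resp = [], []
            for i in range(n_panel):
                responder = bool(rng.random() < 0.5)
                cfg = sim.CellSimConfig(
                    n_cells=s.n_cells,
                    depletion_factor=s.depletion_factor if responder else 1.0,
                    seed=int(rng.integers(2**31 - 1)),
                )
                sid = f"FLU{i + 1:04d}"
                pairs.append(
                    (
                        sim.gen_cell_population(cfg, induced=False, strain_id=sid),
                        sim.gen_cell_population(cfg, induced=True, strain_id=sid),
                    )
                )
                truth_resp.append(responder)
            controls = [
                sim.gen_cell_population(
                    sim.CellSimConfig(
                        n_cells=s.n_cells, log_mean=0.0, log_sd=0.0,
                        depletion_factor=1.0, seed=int(rng.integers(2**31 - 1)),
                    ),
                    induced=False, strain_id=f"CTRL{j}",
                )
                for j in range(6)
            ]
            band = fluor.autofluorescence_band([c.summary.geo_mean for c in controls])
            calls = fluor.classify_panel(
                pairs, band,
                alpha=config.fluor.alpha, min_effect=config.fluor.min_effect,
                death_fraction=config.fluor.death_fraction, trim_k=config.fluor.trim_k,
            )
            dio.write_cell_table([p for pair in pairs for p in pair], outdir / "cells.tsv")
            dio.write_strain_calls(calls, outdir / "fluor_calls.tsv")
            results["fluor"] = {
                "calls": calls, "band": band,
                "truth_responder": dict(zip([c.strain_id for c in calls], truth_resp)),
            }
            summary["fluor"] = fluor.library_summary(calls)
            log.info("classified %d strains", len(calls))

        if "kinetics" in config.stages:
            log = _stage_logger("kinetics")
            times = [0.0, 15.0, 30.0, 60.0, 90.0, 120.0]
            fits: dict[str, kinetics.DecayFit] = {}
            for j, modality in enumerate((kinetics.MODALITY_MICROSCOPY, kinetics.MODALITY_WESTERN)):
                t, raw = sim.gen_timecourse(
                    s.t50_min, s.plateau, times, s.tc_noise_cv,
                    n_rep=3, seed=_seed(config, 3 + j),
                )
                tc = kinetics.normalize_timecourse(t, raw, "SIMTC", modality)
                fits[modality] = kinetics.fit_one_phase_decay(
                    tc, min_amplitude=config.kinetics.min_amplitude, seed=_seed(config, 30 + j)
                )
            conc = kinetics.compare_modalities(
                fits[kinetics.MODALITY_MICROSCOPY], fits[kinetics.MODALITY_WESTERN]
            )
            dio.write_decay_fits(fits, outdir / "kinetics_fits.tsv")
            results["kinetics"] = {"fits": fits, "concordance": conc}
            summary["kinetics"] = {
                m: {"t50": f.t50, "ci": [f.ci_low, f.ci_high]} for m, f in fits.items()
            }
            summary["kinetics"]["t50M_over_t50W"] = conc.ratio
            log.info("fit both modalities; ratio %.3f", conc.ratio)

        if "goslim" in config.stages and "growth" in results:
            log = _stage_logger("goslim")
            calls = results["growth"]["calls"]
            severe = {c.strain_id for c in calls if c.severe}
            strains = sorted({c.strain_id for c in calls})
            terms = [(f"GO:{7000 + i:07d}", max(5, int(len(strains) * frac)))
                     for i, frac in enumerate((0.05, 0.1, 0.15))]
            annot_df = sim.gen_annotation_table(len(strains), terms, seed=_seed(config, 5))
            # re-key synthetic gene ids onto the screen's strain ids
            width = len(str(len(strains)))
            gene_to_strain = {f"G{i + 1:0{width}d}": sid for i, sid in enumerate(strains)}
            annot_df["gene_id"] = annot_df["gene_id"].map(gene_to_strain)
            annot = enrichment.AnnotationTable(annot_df)
            recs = enrichment.shared_hits_recovery(severe, annot)
            pd.DataFrame(
                [
                    {
                        "term_id": r.term_id, "all_hits_count": r.all_hits_count,
                        "term_size": r.term_size, "recovery_pct": r.recovery_pct,
                    }
                    for r in recs
                ]
            ).to_csv(outdir / "goslim.tsv", sep="\t", index=False)
            results["goslim"] = recs
            summary["goslim"] = {r.term_id: r.recovery_pct for r in recs}
            log.info("recovered %d terms", len(recs))

        if "group" in config.stages and "fluor" in results:
            log = _stage_logger("group")
            calls = results["fluor"]["calls"]
            rng = np.random.default_rng(_seed(config, 6))
            cats = ["cytosol", "nucleus", "mitochondria", "ER", "early Golgi", "nucleolus"]
            meta = pd.DataFrame(
                {
                    "strain_id": [c.strain_id for c in calls],
                    "compartment": [
                        grouping.collapse_compartment(cats[int(rng.integers(len(cats)))])
                        for _ in calls
                    ],
                }
            )
            groups = grouping.group_responsiveness(calls, meta, "compartment")
            groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
            results["group"] = groups
            summary["group"] = {
                str(r["group"]): r["pct"] for _, r in groups.iterrows()
            }
            log.info("grouped responsiveness over %d compartments", len(groups))

        if "montage" in config.stages:
            log = _stage_logger("montage")
            img, cents = sim.gen_cell_image(
                s.n_montage_cells, image_size=(640, 640), seed=_seed(config, 7)
            )
            crops = mont.crop_cells(
                img, cents, box_size=config.montage.box_size, strain_id="SIMMONT"
            )
            grid = mont.assemble_grid(
                crops, grid_dims=(config.montage.grid_rows, config.montage.grid_cols)
            )
            adjusted = mont.adjust_contrast(grid, config.montage.saturate_fraction)
            dio.write_image(img, outdir / "cells.tif")
            dio.write_centroids(cents, outdir / "centroids.tsv")
            dio.write_image(adjusted.pixels, outdir / "montage.tif")
            results["montage"] = adjusted
            summary["montage"] = {
                "shape": list(adjusted.pixels.shape),
                "n_cells_placed": adjusted.n_cells_placed,
            }
            log.info("montage %s from %d cells", adjusted.pixels.shape, grid.n_cells_placed)
    except Exception as exc:  # tag failures with their stage for diagnosis
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    config.to_yaml(outdir / "run_config.yaml")
    return results
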