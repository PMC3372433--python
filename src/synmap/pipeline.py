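"""End-to-end runs driven by one YAML config: simulate (or load inputs),
assign orthologs, detect and summarize syntenic blocks, optionally
triangulate a third lineage on the shared reference and compare annotated
segments.  All randomness flows from the config seed; reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import formats_io, macrosynteny, microsynteny, orthology, synthetic_data

logger = logging.getLogger(__name__)

_PATH_KEYS = ("genetic_map", "hits", "unplaced_list", "position_unknown_list")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


def load_config(path: str | Path) -> dict:
    """Load a YAML run config, resolving relative paths against its folder."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = path.parent
    inputs = cfg.get("comparison", {}).get("inputs")
    if inputs:
        for key in _PATH_KEYS:
            if key in inputs:
                inputs[key] = str((base / inputs[key]).resolve())
    micro = cfg.get("microsynteny")
    if micro and "segments" in micro:
        micro["segments"] = [str((base / p).resolve()) for p in micro["segments"]]
    return cfg


def validate(config: Mapping[str, Any]) -> list[str]:
    """Validate a run config; returns all problems at once (empty = ok)."""
    errors: list[str] = []
    comparison = config.get("comparison") or {}
    sim = comparison.get("simulation")
    inputs = comparison.get("inputs")
    if (sim is None) == (inputs is None):
        errors.append("comparison: exactly one of 'simulation' or 'inputs' required")
    if sim is not None and config.get("seed") is None:
        errors.append("seed: required when simulating")
    if sim is not None:
        for key in ("n_chromosomes", "markers_per_chromosome"):
            if key in sim and (not isinstance(sim[key], int) or sim[key] < 1):
                errors.append(f"simulation.{key}: must be a positive integer")
        for key in ("marker_loss_rate", "paralog_rate"):
            if key in sim and not (0.0 <= float(sim[key]) <= 1.0):
                errors.append(f"simulation.{key}: must be in [0, 1]")
    if inputs is not None:
        for key in ("genetic_map", "hits"):
            if key not in inputs:
                errors.append(f"inputs.{key}: required")
            elif not Path(inputs[key]).exists():
                errors.append(f"inputs.{key}: file not found: {inputs[key]}")
    synteny = config.get("synteny") or {}
    for key in ("max_gap_target_bp", "max_gap_query_cM"):
        if key in synteny and float(synteny[key]) <= 0:
            errors.append(f"synteny.{key}: must be positive")
    if "min_markers" in synteny and int(synteny["min_markers"]) < 2:
        errors.append("synteny.min_markers: must be >= 2")
    cascade = config.get("cascade") or {}
    for key in ("e_strict", "e_primary"):
        if key in cascade and float(cascade[key]) <= 0:
            errors.append(f"cascade.{key}: must be positive")
    micro = config.get("microsynteny")
    if micro is not None:
        segs = micro.get("segments") or []
        if len(segs) < 2:
            errors.append("microsynteny.segments: need at least two segment files")
        for p in segs:
            if not Path(p).exists():
                errors.append(f"microsynteny.segments: file not found: {p}")
    return errors


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run(
    config: Mapping[str, Any],
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Execute a full run; returns the output directory.

    ``output_dir`` and ``seed`` override the config.  A stage failure
    aborts with a stage-named :class:`PipelineError` after removing the
    partially written run directory.
    """
    problems = validate(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    out = Path(output_dir or config["output_dir"])
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("synmap")
    root.addHandler(handler)
    root.setLevel(config.get("log_level", "INFO"))

    stage = "setup"
    try:
        cascade_cfg = dict(config.get("cascade") or {})
        thresholds = orthology.CascadeThresholds(
            e_strict=float(cascade_cfg.get("e_strict", 1e-10)),
            e_primary=float(cascade_cfg.get("e_primary", 1e-6)),
            e_est_fallbacks=tuple(
                float(x) for x in cascade_cfg.get("e_est_fallbacks", (1e-30, 1e-20, 1e-5))
            ),
            hsp_merge_window=float(cascade_cfg.get("hsp_merge_window", 50_000)),
        )
        syn_cfg = dict(config.get("synteny") or {})
        syn_th = macrosynteny.SyntenyThresholds(
            min_markers=int(syn_cfg.get("min_markers", 3)),
            max_gap_target_bp=float(syn_cfg.get("max_gap_target_bp", 3_200_000)),
            max_gap_query_cM=float(syn_cfg.get("max_gap_query_cM", 12.0)),
            max_interspersed=syn_cfg.get("max_interspersed"),
        )

        comparison = config["comparison"]
        truth = None
        blocks_cb = None
        chrom_lengths = None
        if "simulation" in comparison and comparison["simulation"] is not None:
            stage = "simulate"
            sim = dict(comparison["simulation"])
            rng = np.random.default_rng(seed)
            n_lineages = 3 if sim.get("triangulate") else 2
            ancestor = synthetic_data.simulate_ancestor(
                n_chromosomes=int(sim.get("n_chromosomes", 11)),
                markers_per_chromosome=int(sim.get("markers_per_chromosome", 40)),
                mean_gap_bp=float(sim.get("mean_gap_bp", 1_100_000)),
                seed=int(rng.integers(2**31)),
            )
            genomes, events, paralogs = synthetic_data.evolve_multi(
                ancestor,
                n_lineages=n_lineages,
                n_events_per_lineage=int(sim.get("n_events_per_lineage", 8)),
                marker_loss_rate=float(sim.get("marker_loss_rate", 0.0)),
                paralog_rate=float(sim.get("paralog_rate", 0.0)),
                seed=int(rng.integers(2**31)),
                mean_gap_bp=float(sim.get("mean_gap_bp", 1_100_000)),
            )
            query_g, target_g = genomes[0], genomes[1]
            truth = synthetic_data.build_truth(
                ancestor, query_g, target_g,
                events_a=events[0], events_b=events[1],
                paralogs_a=paralogs[0], paralogs_b=paralogs[1],
            )
            query_map = synthetic_data.project_genetic(
                query_g,
                cM_per_Mb_mean=float(sim.get("cM_per_Mb_mean", 2.8)),
                cM_per_Mb_sd=float(sim.get("cM_per_Mb_sd", 0.4)),
                seed=int(rng.integers(2**31)),
                map_name="simulated_query",
            )
            place = synthetic_data.placements(target_g)
            hits = synthetic_data.emit_hits(
                truth,
                place,
                seed=int(rng.integers(2**31)),
                n_spurious_multihit=int(sim.get("n_spurious_multihit", 0)),
                n_weak_only=int(sim.get("n_weak_only", 0)),
                n_split_hsp=int(sim.get("n_split_hsp", 0)),
            )
            formats_io.write_genetic_map(query_map, out / "genetic_map.tsv")
            formats_io.write_physical_bed(place, out / "placements.bed")
            formats_io.write_hit_table(hits, out / "hits.tsv")
            _json_dump(
                {
                    "n_markers_ancestor": len(ancestor.marker_ids()),
                    "n_ortholog_pairs": len(truth.pairs),
                    "true_blocks": truth.true_blocks,
                },
                out / "truth.json",
            )
            logger.info("SIMULATED_MARKERS=%d", len(ancestor.marker_ids()))
            query_ids = query_g.marker_ids()
            unplaced, pos_unknown = (), ()
            chrom_lengths = {
                c.name: c.length_bp + 1_000_000 for c in target_g.chromosomes
            }
            if n_lineages == 3:
                third_map = synthetic_data.project_genetic(
                    genomes[2],
                    cM_per_Mb_mean=float(sim.get("cM_per_Mb_mean", 2.8)),
                    cM_per_Mb_sd=float(sim.get("cM_per_Mb_sd", 0.4)),
                    seed=int(rng.integers(2**31)),
                    map_name="simulated_query2",
                )
                truth_cb = synthetic_data.build_truth(ancestor, genomes[2], target_g)
                hits_cb = synthetic_data.emit_hits(
                    truth_cb, place, seed=int(rng.integers(2**31))
                )
        else:
            stage = "load_inputs"
            inputs = comparison["inputs"]
            query_map = formats_io.read_genetic_map(inputs["genetic_map"])
            hits = formats_io.read_hit_table(inputs["hits"])
            unplaced = _read_id_list(inputs.get("unplaced_list"))
            pos_unknown = _read_id_list(inputs.get("position_unknown_list"))
            query_ids = list(query_map.df["marker"])
            chrom_lengths = None

        stage = "assign"
        assignments, tally = orthology.assign(
            hits,
            thresholds=thresholds,
            unplaced_ids=unplaced,
            position_unknown_ids=pos_unknown,
            query_ids=query_ids,
        )
        orthology.write_assignments(assignments, out / "assignments.tsv")
        _json_dump(tally, out / "tally.json")
        for key in sorted(tally):
            logger.info("ASSIGN_%s=%d", key.upper(), tally[key])

        stage = "detect"
        blocks = macrosynteny.detect_css(assignments, query_map, syn_th)
        logger.info("N_CSS=%d", len(blocks))

        stage = "summarize"
        summary = macrosynteny.summarize(blocks, assignments)
        params = {
            "e_primary": thresholds.e_primary,
            "hsp_merge_window": thresholds.hsp_merge_window,
            "min_markers": syn_th.min_markers,
            "max_gap_target_bp": syn_th.max_gap_target_bp,
            "max_gap_query_cM": syn_th.max_gap_query_cM,
            "seed": seed,
        }
        formats_io.write_block_report(
            blocks, out / "blocks.tsv", stats=summary.to_dict(), params=params
        )
        formats_io.write_links(blocks, out / "links.tsv")
        _json_dump(summary.to_dict(), out / "summary.json")

        if truth is not None:
            stage = "score_recovery"
            recovery = synthetic_data.score_recovery(truth, blocks)
            _json_dump(recovery, out / "recovery.json")
            logger.info("PAIR_COVERAGE=%.4f", recovery["pair_coverage"])
            logger.info("FALSE_MERGES=%d", recovery["false_merges"])

        if truth is not None and "simulation" in comparison and comparison[
            "simulation"
        ].get("triangulate"):
            stage = "triangulate"
            assign_cb, _tally_cb = orthology.assign(
                hits_cb, thresholds=thresholds, query_ids=genomes[2].marker_ids()
            )
            blocks_cb = macrosynteny.detect_css(assign_cb, third_map, syn_th)
            overlaps, coverage = macrosynteny.project_multiway(
                blocks, blocks_cb, chrom_lengths
            )
            overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False)
            coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
            logger.info("N_CSS_THIRD=%d", len(blocks_cb))
            logger.info(
                "REFERENCE_CHROMS_COVERED=%d/%d",
                int((~coverage["zero_coverage"]).sum()),
                len(coverage),
            )

        micro_cfg = config.get("microsynteny")
        if micro_cfg:
            stage = "microsynteny"
            segs = [
                microsynteny.segment_from_gff3(
                    p, family_attribute=micro_cfg.get("family_attribute", "family")
                )
                for p in micro_cfg["segments"]
            ]
            matrix = microsynteny.multi_segment_matrix(
                segs, allow_reverse_reading=bool(micro_cfg.get("allow_reverse_reading", True))
            )
            reports = [matrix[k] for k in sorted(matrix) if k[0] != k[1]]
            microsynteny.write_report(reports, out / "microsynteny.tsv")
            _json_dump(
                {f"{a}|{b}": matrix[(a, b)].to_dict() for a, b in sorted(matrix)},
                out / "microsynteny.json",
            )
            for r in reports:
                logger.info(
                    "MICRO_%s_%s_SAME=%d",
                    r.segment_a.segment_id,
                    r.segment_b.segment_id,
                    r.same_order_and_orientation,
                )
    except PipelineError:
        raise
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _read_id_list(path: str | None) -> tuple[str, ...]:
    if not path:
        return ()
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())
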