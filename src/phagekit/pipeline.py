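"""End-to-end pipeline: kinetic scores -> matrix -> cocktail report."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

from . import cocktail as ck
from . import host_range as hr
from . import io as pio
from .config import RunConfig
from .kinetics import compute_iauc

logger = logging.getLogger("phagekit")

__all__ = ["score_kinetic_table", "design_report", "run_pipeline"]


def score_kinetic_table(series_list, config: RunConfig) -> list:
    """Pair each treated well with its strain/replicate-matched control and score it."""
    controls = {}
    for s in series_list:
        if s.is_control:
            controls[(s.strain_id, s.replicate)] = s
    scores = []
    for s in series_list:
        if s.is_control:
            continue
        control = controls.get((s.strain_id, s.replicate))
        if control is None:
            raise ValueError(
                f"no control well for strain {s.strain_id!r} "
                f"replicate {s.replicate}"
            )
        scores.append(
            compute_iauc(
                s,
                control,
                threshold=config.iauc_threshold,
                baseline_window=config.baseline_window_h,
            )
        )
    return scores


def design_report(matrix, config: RunConfig, cocktail_size: Optional[int] = None) -> dict:
    """Coverage, ranking and redundancy report for one susceptibility matrix."""
    size = cocktail_size or config.cocktail_size
    base_sizes = config.base_sizes or None
    logger.info(
        "designing cocktail: size=%d, ancestor exclusion=%s, iauc threshold=%g",
        size,
        config.exclude_shared_ancestor,
        config.iauc_threshold,
    )
    ranking = ck.rank_caps(
        matrix,
        base_sizes=base_sizes,
        exclude_shared_ancestor=config.exclude_shared_ancestor,
    )
    # walk the ranking, honoring the same-ancestor exclusion in the pick
    top = []
    used_ancestors = set()
    for cap, _ in ranking:
        anc = matrix.ancestors.get(cap, cap)
        if config.exclude_shared_ancestor and anc in used_ancestors:
            logger.info("skipping %s: ancestor %s already represented", cap, anc)
            continue
        top.append(cap)
        used_ancestors.add(anc)
        if len(top) == size:
            break
    combos = ck.enumerate_combinations(
        {a: matrix.ancestors.get(a, a) for a in matrix.agents},
        sizes=[size],
        exclude_shared_ancestor=config.exclude_shared_ancestor,
    )
    logger.info("evaluating %d admissible size-%d combinations", len(combos), size)
    combo_rows = []
    for combo in combos:
        est = ck.combination_coverage(matrix, combo)
        combo_rows.append(
            {
                "agents": list(combo.sorted_ids()),
                "coverage_mean": est.mean_fraction,
                "coverage_sd": est.sd_fraction,
            }
        )
    combo_rows.sort(key=lambda r: (-r["coverage_mean"], r["agents"]))
    top_combo = sorted(top)
    redundancy = hr.redundancy_distribution(matrix, top_combo).tolist()
    report = {
        "config": config.to_dict(),
        "n_strains": len(matrix.strains),
        "agents": list(matrix.agents),
        "host_range": {
            a: {
                "mean": hr.host_range(matrix, a).mean_fraction,
                "sd": hr.host_range(matrix, a).sd_fraction,
            }
            for a in matrix.agents
        },
        "ranking": [
            {
                "cap_id": cap,
                "marginal_mode": dist.mode,
                "marginal_mean": float(dist.values.mean()),
                "n_bases": int(len(dist.values)),
            }
            for cap, dist in ranking
        ],
        "selected_cocktail": top_combo,
        "selected_coverage": ck.combination_coverage(
            matrix, top_combo
        ).mean_fraction,
        "combinations": combo_rows,
        "redundancy": redundancy,
    }
    return report


def run_pipeline(
    config: RunConfig,
    kinetic_path=None,
    plaquing_path=None,
    strains_path=None,
    agents_path=None,
    outdir=".",
    consensus: bool = False,
) -> dict:
    """score-kinetics -> build-matrix -> design-cocktail, with per-stage CSVs.

    Exactly one of ``kinetic_path`` / ``plaquing_path`` must be given.
    Writes scores.csv (kinetic route), matrix.csv and report.json under
    ``outdir`` and returns the report dict.  Identical config and inputs
    give identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if (kinetic_path is None) == (plaquing_path is None):
        raise ValueError("provide exactly one of kinetic_path / plaquing_path")
    for p in (kinetic_path, plaquing_path, strains_path, agents_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")
    strains = pio.read_strain_table(strains_path) if strains_path else None
    ancestors = pio.read_agent_table(agents_path) if agents_path else None

    if kinetic_path is not None:
        series = pio.read_kinetic_table(kinetic_path)
        logger.info("scoring %d wells from %s", len(series), kinetic_path)
        scores = score_kinetic_table(series, config)
        pio.write_score_table(scores, outdir / "scores.csv")
        matrix = hr.matrix_from_iauc(
            scores,
            threshold=config.iauc_threshold,
            strains=strains,
            ancestors=ancestors,
        )
    else:
        obs = pio.read_plaquing_table(plaquing_path)
        logger.info("building matrix from %d plaquing observations", len(obs))
        matrix = hr.matrix_from_plaquing(
            obs, consensus=consensus, strains=strains, ancestors=ancestors
        )
    pio.write_matrix_csv(matrix, outdir / "matrix.csv")

    report = design_report(matrix, config)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "selected cocktail %s with coverage %.3f",
        report["selected_cocktail"],
        report["selected_coverage"],
    )
    return report
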