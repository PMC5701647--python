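"""End-to-end orchestration: simulate -> build -> metrics -> asymmetry -> NBS -> stats.

The structural arm computes metrics once on the unthresholded
streamline-density network; the functional arm computes them at every
level of the sparsity grid and integrates over the grid.  NBS runs on
the unthresholded hemispheric networks of both modalities.  Every stage
writes diff-able TSV/JSON outputs, and a manifest records the seed,
config hash and per-file checksums so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as hio
from .asymmetry import GLOBAL_AS_METRICS, subject_asymmetry_profile
from .build import (
    HemiNetwork,
    functional_connectivity,
    sparsity_grid,
    split_hemispheres,
    threshold_sparsity,
)
from .metrics import (
    GlobalMetrics,
    integrate_over_sparsity,
    nodal_efficiency,
    normalize_weights_joint,
    shortest_paths,
    small_worldness,
)
from .nbs import nbs_paired
from .regions import AAL90_REGIONS, node_labels
from .stats import association_scan, hemisphere_effect_scan
from .synth import simulate_cohort

logger = logging.getLogger(__name__)

REGION_ABBRS = [abbr for abbr, _ in AAL90_REGIONS]

DEFAULT_PIPELINE_CONFIG: dict[str, Any] = {
    "n_subjects": 20,
    "modalities": ["structural", "functional"],
    "sparsity": {"min": 0.10, "max": 0.35, "step": 0.01},
    # null networks per small-worldness estimate for the default run;
    # hemilat.metrics.small_worldness itself defaults to 100
    "n_null": 10,
    "nbs": {"t_threshold": 3.0, "n_perm": 500},
    "fdr_q": 0.05,
    "cohort": {},
}

_HEMI_CODE = {"L": 0, "R": 1}
_MODALITY_CODE = {"structural": 0, "functional": 1}


def _merge_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _stage_seed(master_seed: int, *fields: int) -> int:
    return int(np.random.SeedSequence([master_seed, *fields]).generate_state(1)[0] % (2**31))


def _metrics_of(gm: GlobalMetrics) -> dict[str, float]:
    return {
        "c_w": gm.c_w,
        "l_w": gm.l_w,
        "gamma": gm.gamma,
        "lambda": gm.lam,
        "sigma": gm.sigma,
        "e_global": gm.e_global,
        "e_local": gm.e_local,
        "n_unreachable_pairs": float(gm.n_unreachable_pairs),
    }


def hemisphere_metrics_row(
    hn: HemiNetwork,
    functional: bool,
    grid: np.ndarray,
    n_null: int,
    seed: int,
) -> dict[str, float]:
    """All global metrics plus the 45 regional efficiencies for one network.

    Functional networks are evaluated at each sparsity level and every
    metric (including the null-referenced gamma/lambda/sigma) is
    integrated over the grid; structural networks are evaluated once,
    unthresholded.
    """
    if functional:
        per_level: list[dict[str, float]] = []
        enodal_levels = []
        for k, s in enumerate(grid):
            thresholded = threshold_sparsity(hn, float(s))
            gm = small_worldness(thresholded, n_null=n_null, seed=_stage_seed(seed, k))
            per_level.append(_metrics_of(gm))
            enodal_levels.append(nodal_efficiency(shortest_paths(thresholded)))
        levels = np.asarray(grid, dtype=float)
        row = {
            name: integrate_over_sparsity([m[name] for m in per_level], levels)
            for name in per_level[0]
        }
        enodal = np.vstack(enodal_levels)
        enodal = np.array(
            [integrate_over_sparsity(enodal[:, i], levels) for i in range(enodal.shape[1])]
        )
    else:
        gm = small_worldness(hn, n_null=n_null, seed=seed)
        row = _metrics_of(gm)
        enodal = nodal_efficiency(shortest_paths(hn))
    for abbr, value in zip(REGION_ABBRS, enodal):
        row[f"e_nodal_{abbr}"] = float(value)
    return row


def compute_metrics_table(
    hemi_networks: dict[str, dict[str, tuple[HemiNetwork, HemiNetwork]]],
    grid: np.ndarray,
    n_null: int,
    seed: int,
) -> pd.DataFrame:
    """Long metrics table: one row per subject x modality x hemisphere.

    ``hemi_networks[modality][subject_id] = (left, right)`` with raw
    (unnormalized) weights; each pair is jointly normalized here before
    metric computation.
    """
    rows = []
    for modality, per_subject in hemi_networks.items():
        functional = modality == "functional"
        for subj_idx, (subject_id, (left, right)) in enumerate(sorted(per_subject.items())):
            nl, nr = normalize_weights_joint(left, right)
            for hn in (nl, nr):
                row_seed = _stage_seed(
                    seed, 1, subj_idx, _HEMI_CODE[hn.hemisphere], _MODALITY_CODE[modality]
                )
                row = {
                    "subject_id": subject_id,
                    "modality": modality,
                    "hemisphere": hn.hemisphere,
                }
                row.update(hemisphere_metrics_row(hn, functional, grid, n_null, row_seed))
                rows.append(row)
    return pd.DataFrame(rows)


def compute_asymmetry_table(metrics_table: pd.DataFrame) -> pd.DataFrame:
    """Long AS table (subject, modality, metric, X_L, X_R, AS) from metrics."""
    value_cols = list(GLOBAL_AS_METRICS) + [f"e_nodal_{a}" for a in REGION_ABBRS]
    rows = []
    for (subject_id, modality), group in metrics_table.groupby(["subject_id", "modality"]):
        left = group[group["hemisphere"] == "L"].iloc[0]
        right = group[group["hemisphere"] == "R"].iloc[0]
        gm_l = GlobalMetrics(
            c_w=left["c_w"], l_w=left["l_w"], e_global=left["e_global"],
            e_local=left["e_local"], sigma=left["sigma"], gamma=left["gamma"],
            lam=left["lambda"],
        )
        gm_r = GlobalMetrics(
            c_w=right["c_w"], l_w=right["l_w"], e_global=right["e_global"],
            e_local=right["e_local"], sigma=right["sigma"], gamma=right["gamma"],
            lam=right["lambda"],
        )
        enodal_l = left[[f"e_nodal_{a}" for a in REGION_ABBRS]].to_numpy(dtype=float)
        enodal_r = right[[f"e_nodal_{a}" for a in REGION_ABBRS]].to_numpy(dtype=float)
        for score in subject_asymmetry_profile(
            gm_l, gm_r, enodal_l, enodal_r,
            subject_id=subject_id, modality=modality, region_names=REGION_ABBRS,
        ):
            rows.append(
                {
                    "subject_id": subject_id,
                    "modality": modality,
                    "metric": score.metric,
                    "X_L": score.x_left,
                    "X_R": score.x_right,
                    "AS": score.as_value,
                }
            )
    return pd.DataFrame(rows)


def _sorted_stacks(
    per_subject: dict[str, tuple[HemiNetwork, HemiNetwork]]
) -> tuple[np.ndarray, np.ndarray]:
    subjects = sorted(per_subject)
    left = np.stack([per_subject[s][0].weights for s in subjects])
    right = np.stack([per_subject[s][1].weights for s in subjects])
    return left, right


def nbs_result_to_dict(result, region_names: list[str]) -> dict:
    """JSON-ready summary of an NBS run with region-abbreviation edges."""
    return {
        "t_threshold": result.t_threshold,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "exhaustive": result.exhaustive,
        "null_max_size_histogram": {
            tail: {
                str(k): int(v)
                for k, v in zip(*np.unique(result.null_max_sizes[:, col], return_counts=True))
            }
            for col, tail in enumerate(("left>right", "right>left"))
        },
        "n_zero_variance_edges": len(result.zero_variance_edges),
        "components": [
            {
                "tail": c.tail,
                "n_edges": c.n_edges,
                "nodes": [region_names[i] for i in c.nodes],
                "edges": [[region_names[i], region_names[j]] for i, j in c.edges],
                "p_corrected": c.p_corrected,
            }
            for c in result.components
        ],
    }


def run_pipeline(config: dict | None, out_dir, seed: int = 0) -> dict:
    """Run the full analysis on a synthetic cohort; return the manifest."""
    config = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    modalities = list(config["modalities"])
    grid = sparsity_grid(
        config["sparsity"]["min"], config["sparsity"]["max"], config["sparsity"]["step"]
    )
    meta = {"seed": seed, "config_hash": hio.config_hash(config)}

    # --- simulate ---------------------------------------------------------
    logger.info("stage simulate: %d subjects", config["n_subjects"])
    cohort = simulate_cohort(int(config["n_subjects"]), config["cohort"], seed=seed)
    labels = node_labels(cohort.node_table)
    for subj in cohort.subjects:
        p = out / f"{subj.subject_id}_structural.tsv"
        hio.write_matrix(p, subj.structural, labels, meta)
        outputs.append(p)
        p = out / f"{subj.subject_id}_timeseries.tsv"
        hio.write_timeseries(p, subj.timeseries, labels, meta)
        outputs.append(p)
    cohort_table = cohort.covariates.merge(cohort.behavior, on="subject_id")
    hio.write_table(out / "cohort.tsv", cohort_table, meta)
    outputs.append(out / "cohort.tsv")
    with (out / "truth.json").open("w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True, default=str)
    outputs.append(out / "truth.json")

    # --- build ------------------------------------------------------------
    logger.info("stage build: hemispheric networks (%s)", ", ".join(modalities))
    hemi_networks: dict[str, dict[str, tuple[HemiNetwork, HemiNetwork]]] = {
        m: {} for m in modalities
    }
    for subj in cohort.subjects:
        if "structural" in modalities:
            hemi_networks["structural"][subj.subject_id] = split_hemispheres(
                subj.structural, cohort.node_table, subj.subject_id, "structural"
            )
        if "functional" in modalities:
            fc = functional_connectivity(subj.timeseries)
            p = out / f"{subj.subject_id}_functional.tsv"
            hio.write_matrix(p, fc, labels, meta)
            outputs.append(p)
            hemi_networks["functional"][subj.subject_id] = split_hemispheres(
                fc, cohort.node_table, subj.subject_id, "functional"
            )

    # --- metrics ----------------------------------------------------------
    logger.info("stage metrics: n_null=%d, %d sparsity levels", config["n_null"], len(grid))
    metrics_table = compute_metrics_table(
        hemi_networks, grid, int(config["n_null"]), _stage_seed(seed, 100)
    )
    hio.write_table(out / "metrics.tsv", metrics_table, meta)
    outputs.append(out / "metrics.tsv")

    # --- asymmetry --------------------------------------------------------
    as_table = compute_asymmetry_table(metrics_table)
    hio.write_table(out / "asymmetry.tsv", as_table, meta)
    outputs.append(out / "asymmetry.tsv")

    # --- nbs --------------------------------------------------------------
    nbs_cfg = config["nbs"]
    for m_idx, modality in enumerate(modalities):
        logger.info("stage nbs: %s (%d permutations)", modality, nbs_cfg["n_perm"])
        left, right = _sorted_stacks(hemi_networks[modality])
        result = nbs_paired(
            left,
            right,
            t_threshold=float(nbs_cfg["t_threshold"]),
            n_perm=int(nbs_cfg["n_perm"]),
            seed=_stage_seed(seed, 200, m_idx),
        )
        hio.write_matrix(out / f"nbs_tmap_{modality}.tsv", result.t_map, REGION_ABBRS, meta)
        outputs.append(out / f"nbs_tmap_{modality}.tsv")
        summary = nbs_result_to_dict(result, REGION_ABBRS)
        summary["t_map_file"] = f"nbs_tmap_{modality}.tsv"
        with (out / f"nbs_{modality}.json").open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        outputs.append(out / f"nbs_{modality}.json")

    # --- stats ------------------------------------------------------------
    logger.info("stage stats: ANCOVA + FDR + association scan")
    covariates = cohort.covariates
    hemi_rows, assoc_rows = [], []
    for modality in modalities:
        sub = metrics_table[metrics_table["modality"] == modality]
        families = {
            "global": list(GLOBAL_AS_METRICS),
            "regional": [f"e_nodal_{a}" for a in REGION_ABBRS],
        }
        selected: list[str] = []
        for family, cols in families.items():
            scan = hemisphere_effect_scan(sub, covariates, cols, q_level=float(config["fdr_q"]))
            scan.insert(0, "modality", modality)
            scan.insert(1, "family", family)
            hemi_rows.append(scan)
            if family == "global":
                selected = scan.loc[scan["significant"], "target"].tolist()
        assoc = association_scan(
            as_table[as_table["modality"] == modality],
            cohort.behavior,
            covariates,
            selected,
        )
        assoc.insert(0, "modality", modality)
        assoc_rows.append(assoc)
    hemi_stats = pd.concat(hemi_rows, ignore_index=True)
    assoc_stats = pd.concat(assoc_rows, ignore_index=True)
    hio.write_table(out / "stats_hemisphere.tsv", hemi_stats, meta)
    outputs.append(out / "stats_hemisphere.tsv")
    hio.write_table(out / "stats_association.tsv", assoc_stats, meta)
    outputs.append(out / "stats_association.tsv")

    return hio.write_manifest(out / "manifest.json", config, seed, outputs)
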