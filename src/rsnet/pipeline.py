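"""End-to-end orchestration: simulate/load -> clean -> connect -> grid
networks -> metrics -> modules -> similarity tests -> mixed models.

Every stage's randomness derives from ``master_seed`` through named
``numpy`` seed sequences, so a rerun with an identical config reproduces
identical numbers. Artifacts are TSVs plus a JSON run summary carrying
the config echo and seed (provenance sidecar).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    COVARIATE_NAMES,
    CohortConfig,
    SubjectRecord,
    generate_cohort,
)
from .config import PipelineConfig
from .connectivity import build_networks_over_grid, connectivity_from_series
from .datatypes import CostGrid
from .inference import (
    MixedModelResult,
    PowerSpec,
    fit_mixed_model,
    mde_independent,
    mde_paired,
    nodewise_analysis,
)
from .io import read_manifest
from .metrics import global_metrics, nodal_metrics
from .modularity import (
    detect_modules,
    nmi_matrix,
    permutation_similarity_test,
)
from .preprocess import clean

log = logging.getLogger("rsnet")

GLOBAL_METRIC_NAMES = ("cp", "lp", "e_glob", "e_loc", "q", "n_modules")


def _stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _cohort_records(config: PipelineConfig) -> list[SubjectRecord]:
    if config.manifest is not None:
        return read_manifest(config.manifest, tr_seconds=config.tr_seconds)
    cc = CohortConfig(
        n_group1=config.n_group1,
        n_group2=config.n_group2,
        n_parcels=config.n_parcels,
        n_samples=config.n_samples,
        tr_seconds=config.tr_seconds,
        seed=_stage_seed(config.master_seed, "simulate"),
    )
    return generate_cohort(cc)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run summary dict (also
    written to ``run_summary.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info(
        "run config: filter order 2 (zero-phase Butterworth), NMI variant "
        "2I/(H1+H2), MST tie-break lexicographic, FDR per cost level"
    )

    records = _cohort_records(config)
    log.info("cohort: %d subject-phase records", len(records))

    global_grid = CostGrid(config.global_grid, "global")
    regional_grid = CostGrid(config.regional_grid, "regional")

    metric_rows = []
    nodal_rows = []
    partitions: dict[tuple[str, float], dict[tuple[str, str], list]] = {}
    subject_meta: dict[str, tuple[str, str]] = {}

    for rec in records:
        try:
            cleaned = clean(rec.series, rec.nuisance, config.low_hz, config.high_hz)
            conn = connectivity_from_series(cleaned)
        except Exception as exc:
            raise RuntimeError(
                f"stage prep/connect failed for subject {rec.subject_id} "
                f"({rec.phase}): {exc}"
            ) from exc
        subject_meta[rec.subject_id] = (rec.group, rec.phase)
        for mode in config.modes:
            nets = build_networks_over_grid(conn, global_grid, mode)
            for net in nets:
                seed = _stage_seed(
                    config.master_seed,
                    f"modules:{rec.subject_id}:{rec.phase}:{mode}:{net.cost}",
                )
                part = detect_modules(net, n_restarts=config.n_restarts, seed=seed)
                partitions.setdefault((mode, net.cost), {}).setdefault(
                    (rec.group, rec.phase), []
                ).append((rec.subject_id, part))
                gm = global_metrics(
                    net,
                    sigma=config.compute_sigma and mode == "binary",
                    n_null=config.n_null,
                    seed=_stage_seed(
                        config.master_seed,
                        f"sigma:{rec.subject_id}:{rec.phase}:{mode}:{net.cost}",
                    ),
                )
                gm["q"] = part.q
                gm["n_modules"] = part.n_modules
                for name, value in gm.items():
                    metric_rows.append(
                        dict(
                            subject_id=rec.subject_id,
                            group=rec.group,
                            phase=rec.phase,
                            mode=mode,
                            cost=net.cost,
                            metric=name,
                            node="",
                            value=value,
                            **rec.covariates,
                        )
                    )
                if net.cost in regional_grid.costs:
                    nm = nodal_metrics(net)
                    for mname, vals in nm.items():
                        for node, value in zip(net.parcel_labels, vals):
                            nodal_rows.append(
                                dict(
                                    subject_id=rec.subject_id,
                                    group=rec.group,
                                    phase=rec.phase,
                                    mode=mode,
                                    cost=net.cost,
                                    metric=mname,
                                    node=node,
                                    value=float(value),
                                    **rec.covariates,
                                )
                            )

    metrics_df = pd.DataFrame(metric_rows)
    nodal_df = pd.DataFrame(nodal_rows)
    metrics_df.to_csv(outdir / "global_metrics.tsv", sep="\t", index=False)
    nodal_df.to_csv(outdir / "nodal_metrics.tsv", sep="\t", index=False)

    similarity_rows = _similarity_tests(partitions, config)
    sim_df = pd.DataFrame(similarity_rows)
    sim_df.to_csv(outdir / "similarity_tests.tsv", sep="\t", index=False)

    mm_rows = _global_mixed_models(metrics_df, config)
    mm_df = pd.DataFrame(mm_rows)
    mm_df.to_csv(outdir / "mixed_models_global.tsv", sep="\t", index=False)

    nodewise_df = pd.DataFrame()
    if not nodal_df.empty:
        nodewise_df = nodewise_analysis(
            nodal_df[nodal_df["mode"] == config.modes[0]],
            CostGrid(config.regional_grid),
            fdr_q=config.fdr_q,
        )
        nodewise_df.to_csv(outdir / "nodewise_results.tsv", sep="\t", index=False)

    n1 = len({s for s, (g, _) in subject_meta.items() if g == "PDM"})
    n2 = len({s for s, (g, _) in subject_meta.items() if g == "CON"})
    power = {
        "mde_independent": mde_independent(
            PowerSpec("independent", n1=max(n1, 2), n2=max(n2, 2), alpha=config.alpha)
        ),
        "mde_paired": mde_paired(
            PowerSpec("paired", n1=max((n1 + n2) // 2, 2), alpha=config.alpha)
        ),
    }

    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": config.master_seed,
        "n_subjects": len(subject_meta),
        "n_records": len(records),
        "n_cost_levels_global": len(global_grid),
        "n_cost_levels_regional": len(regional_grid),
        "n_significant_similarity": int((sim_df["p_value"] < config.alpha).sum())
        if not sim_df.empty
        else 0,
        "n_significant_nodewise_fdr": int(nodewise_df["significant_fdr"].sum())
        if not nodewise_df.empty
        else 0,
        "power": power,
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _similarity_tests(partitions, config: PipelineConfig) -> list[dict]:
    """NMI permutation tests: group contrast within each phase, and phase
    contrast within each group, per mode x cost."""
    rows = []
    for (mode, cost), cells in partitions.items():
        contrasts = []
        # between-group, within-phase
        for phase in ("MENS", "POV"):
            a = cells.get(("PDM", phase), [])
            b = cells.get(("CON", phase), [])
            if len(a) >= 2 and len(b) >= 2:
                contrasts.append((f"group@{phase}", a, b, "PDM", "CON"))
        # between-phase, within-group
        for group in ("PDM", "CON"):
            a = cells.get((group, "MENS"), [])
            b = cells.get((group, "POV"), [])
            if len(a) >= 2 and len(b) >= 2:
                contrasts.append((f"phase@{group}", a, b, "MENS", "POV"))
        for name, a, b, la, lb in contrasts:
            parts = [p for _, p in a] + [p for _, p in b]
            labels = np.array([la] * len(a) + [lb] * len(b))
            sim = nmi_matrix(parts)
            seed = _stage_seed(config.master_seed, f"perm:{mode}:{cost}:{name}")
            res = permutation_similarity_test(
                sim, labels, n_perm=config.n_perm, seed=seed, statistic_kind="NMI"
            )
            rows.append(
                dict(
                    mode=mode,
                    cost=cost,
                    contrast=name,
                    observed_within=res.observed_within,
                    p_value=res.p_value,
                    n_perm=res.n_perm,
                    seed=seed,
                )
            )
    return rows


def _global_mixed_models(metrics_df: pd.DataFrame, config: PipelineConfig) -> list[dict]:
    rows = []
    if metrics_df.empty:
        return rows
    for mode in config.modes:
        for metric in GLOBAL_METRIC_NAMES:
            sub = metrics_df[
                (metrics_df["mode"] == mode) & (metrics_df["metric"] == metric)
            ]
            for cost, sub_c in sub.groupby("cost"):
                if sub_c["value"].std() == 0:
                    continue
                try:
                    res = fit_mixed_model(sub_c, outcome=f"{mode}:{metric}@{cost}")
                except ValueError:
                    continue
                for effect, pv in res.pvalues.items():
                    if effect == "intercept":
                        continue
                    rows.append(
                        dict(
                            mode=mode,
                            metric=metric,
                            cost=cost,
                            effect=effect,
                            estimate=res.params[effect],
                            se=res.bse[effect],
                            p=pv,
                            converged=res.converged,
                        )
                    )
    return rows
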