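"""End-to-end orchestration: synthesize or load data, then run every stage.

A run is described by one config mapping (usually loaded from YAML) with
exactly one data source — a ``synth`` block of generator parameters or an
``inputs`` block of file paths — plus a ``model`` block, an optional
``fingerprint`` block, an output directory and a seed that is propagated to
every stochastic stage.  Each stage writes its tables atomically (tmp file
then rename) so a failed stage never leaves a truncated table behind.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from connpredict import __version__, metrics as _metrics
from connpredict.cpm import (
    ModelConfig,
    PredictionReport,
    external_validation,
    loo_cv,
)
from connpredict.features import FeatureSet
from connpredict.fingerprint import fingerprint_report
from connpredict.synth import SynthConfig, SynthCohort, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["run", "load_cohort_dir"]

DEFAULT_STAGES = (
    "check_motion", "fingerprint", "cpm_loo", "cpm_external", "apm_loo", "apm_external",
)


def _atomic_write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, **kwargs)
    os.replace(tmp, path)


def load_cohort_dir(directory) -> SynthCohort:
    """Read back a cohort written by :func:`connpredict.synth.write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SynthConfig(**manifest["config"])
    pheno = pd.read_csv(manifest["paths"]["phenotypes"], sep="\t")
    subject_ids = pheno["subject_id"].tolist()

    def _feats(name, kind, ids):
        df = pd.read_csv(manifest["paths"][name], sep="\t", header=None, index_col=0)
        return FeatureSet(df.to_numpy(dtype=float), ids, kind, list(df.index))

    from connpredict.features import edge_ids

    eids = edge_ids(config.n_nodes)
    mask = np.loadtxt(manifest["paths"]["vertex_mask"], dtype=int).astype(bool)
    vids = [int(i) for i in np.flatnonzero(mask)]
    signal_idx = np.atleast_1d(
        np.loadtxt(manifest["paths"]["signal_edges"], dtype=int)
    )
    return SynthCohort(
        phenotypes=pheno,
        edges_session1=_feats("edges_session1", "edges", eids),
        edges_session2=_feats("edges_session2", "edges", eids),
        anat_session1=_feats("anat_session1", "vertices", vids),
        anat_session2=_feats("anat_session2", "vertices", vids),
        vertex_mask=mask,
        signal_edge_idx=signal_idx,
        config=config,
    )


def _report_tables(report: PredictionReport, prefix: str, outdir: Path, feature_ids):
    _atomic_write(report.to_frame(), outdir / f"{prefix}_predictions.tsv")
    m = pd.DataFrame(
        {
            "metric": ["mae", "r", "r2"],
            "value": [report.mae, report.r, report.r2],
            "ci_lower": [report.ci_mae[0], report.ci_r[0], report.ci_r2[0]],
            "ci_upper": [report.ci_mae[1], report.ci_r[1], report.ci_r2[1]],
        }
    )
    _atomic_write(m, outdir / f"{prefix}_metrics.tsv")
    if report.selection_frequency is not None:
        nz = np.flatnonzero(report.selection_frequency > 0)
        sel = pd.DataFrame(
            {
                "feature_id": [feature_ids[i] for i in nz],
                "frequency": report.selection_frequency[nz],
            }
        ).sort_values("frequency", ascending=False)
        _atomic_write(sel, outdir / f"{prefix}_selection_frequency.tsv")
    return {
        "mae": report.mae, "r": report.r, "r2": report.r2,
        "flagged_folds": report.flagged_folds,
    }


def run(config: dict) -> dict:
    """Execute the configured stages; returns the manifest (also written).

    ``config`` keys: ``output_dir``; exactly one of ``synth`` (generator
    parameters) or ``inputs`` (directory with a cohort manifest); optional
    ``model`` (second-stage configuration), ``fingerprint``
    (``kind``: edges | anatomy), ``stages``, ``seed``, ``n_boot``.
    """
    if ("synth" in config) == ("inputs" in config):
        raise ValueError("config must contain exactly one of 'synth' or 'inputs'")
    outdir = Path(config.get("output_dir", "connpredict_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_boot = int(config.get("n_boot", 1000))
    stages = list(config.get("stages", DEFAULT_STAGES))
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}
    t0 = time.time()

    if "synth" in config:
        synth_cfg = SynthConfig(**{**config["synth"], "seed": seed})
        cohort = generate_cohort(synth_cfg)
        write_cohort(cohort, outdir / "cohort")
        manifest["stages"]["synth"] = {
            "n_subjects": len(cohort.phenotypes),
            "n_edges": cohort.edges_session1.n_features,
            "n_active_vertices": cohort.anat_session1.n_features,
        }
    else:
        cohort = load_cohort_dir(config["inputs"])

    model_cfg = ModelConfig(**{**config.get("model", {}), "seed": seed})
    pheno = cohort.phenotypes
    in_a, in_b = cohort.dataset("A"), cohort.dataset("B")

    if "check_motion" in stages:
        r, p = _metrics.motion_check(
            pheno.loc[in_a, "mean_fd"], pheno.loc[in_a, "pars_post"], seed=seed
        )
        manifest["stages"]["check_motion"] = {"r": r, "p": p}
        _atomic_write(pd.DataFrame({"r": [r], "p": [p]}), outdir / "motion_check.tsv")

    if "fingerprint" in stages:
        kind = config.get("fingerprint", {}).get("kind", "edges")
        if kind == "edges":
            s1, s2 = cohort.edges_session1, cohort.edges_session2
        else:
            s1, s2 = cohort.anat_session1, cohort.anat_session2
        rep = fingerprint_report(s1, s2)
        rows = []
        for d in ("baseline_to_followup", "followup_to_baseline"):
            rows.append(
                {
                    "direction": d,
                    "n_correct": rep[d]["n_correct"],
                    "n_subjects": rep["n_subjects"],
                    "accuracy": rep[d]["accuracy"],
                    "pvalue": rep[d]["pvalue"],
                }
            )
        _atomic_write(pd.DataFrame(rows), outdir / f"fingerprint_{kind}.tsv")
        dp = rep["dp"]
        dp_df = pd.DataFrame(
            {"feature_id": s1.feature_ids, "dp": dp.dp, "dp_pvalue": dp.dp_pvalue}
        )
        _atomic_write(dp_df, outdir / f"dp_{kind}.tsv")
        manifest["stages"]["fingerprint"] = {
            "kind": kind,
            **{d: {"n_correct": rep[d]["n_correct"], "pvalue": rep[d]["pvalue"]}
               for d in ("baseline_to_followup", "followup_to_baseline")},
        }

    stage_data = {
        "cpm": (cohort.edges_session1, cohort.edges_session1.feature_ids),
        "apm": (cohort.anat_session1, cohort.anat_session1.feature_ids),
    }
    for modality in ("cpm", "apm"):
        fs, fids = stage_data[modality]
        if f"{modality}_loo" in stages:
            rep = loo_cv(fs.matrix[in_a], pheno[in_a], model_cfg,
                         n_boot=n_boot, seed=seed)
            manifest["stages"][f"{modality}_loo"] = _report_tables(
                rep, f"{modality}_loo", outdir, fids
            )
        if f"{modality}_external" in stages:
            rep = external_validation(
                fs.matrix[in_a], pheno[in_a], fs.matrix[in_b], pheno[in_b],
                model_cfg, n_boot=n_boot, seed=seed,
            )
            manifest["stages"][f"{modality}_external"] = _report_tables(
                rep, f"{modality}_external", outdir, fids
            )

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    manifest["model_config"] = asdict(model_cfg)
    tmp = outdir / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    os.replace(tmp, outdir / "manifest.json")
    return manifest
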