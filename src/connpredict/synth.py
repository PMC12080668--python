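"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates two pediatric-anxiety treatment datasets (a larger
training set and a small external-validation set): a phenotype table (age,
sex, scanner, baseline and post-treatment symptom scores on a 0-25
instrument, mean framewise displacement), per-subject edgewise connectivity
on the Fisher-z scale for two sessions, and per-subject vertexwise
morphometric maps for two sessions with a cortex mask.

Across sessions, each feature value is the sum of a shared group mean, a
subject-specific stable offset, and independent session noise; the ratio of
the subject-effect SD to the session-noise SD controls how identifiable
subjects are (connectivity is generated less stable than anatomy, whose
near-deterministic session structure yields near-100% identification).

The outcome is linear in the sum of a sparse set of planted signal edges
plus age, sex, and baseline-severity effects and Gaussian noise, clipped to
the instrument range [0, 25].  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from connpredict.features import FeatureSet, edge_ids

__all__ = ["SynthConfig", "SynthCohort", "generate_cohort", "generate_time_series"]

PARS_MIN, PARS_MAX = 0.0, 25.0
BASELINE_CUTOFF = 9.0  # clinical cut-off: baseline severity of nine or higher


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Sizes default to the study layout: a larger dataset A (n=54) and a
    small dataset B (n=15); 216 nodes giving n(n-1)/2 = 23,220 edges; a
    20,484-vertex mesh with 18,742 active (cortical) vertices.
    """

    n_subjects_A: int = 54
    n_subjects_B: int = 15
    n_nodes: int = 216
    n_vertices: int = 20_484
    n_active_vertices: int = 18_742
    n_timepoints: int = 150
    n_signal_edges: int = 10
    intercept: float = 2.0
    beta_strength: float = 0.5    # outcome units per unit summed-z
    beta_age: float = 0.1
    beta_sex: float = 0.5
    beta_baseline: float = 0.4
    noise_sd: float = 2.0
    subject_effect_sd_fc: float = 0.10
    session_noise_sd_fc: float = 0.10
    subject_effect_sd_anat: float = 0.50
    session_noise_sd_anat: float = 0.01
    scanner_effect: float = 0.0   # additive site offset on edge values
    baseline_brain_corr: float = 0.0  # couple baseline severity to the planted signal
    seed: int = 0

    def __post_init__(self):
        counts = dict(
            n_subjects_A=self.n_subjects_A, n_subjects_B=self.n_subjects_B,
            n_nodes=self.n_nodes, n_vertices=self.n_vertices,
            n_active_vertices=self.n_active_vertices,
            n_timepoints=self.n_timepoints, n_signal_edges=self.n_signal_edges,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_signal_edges > n_edges:
            raise ValueError(
                f"n_signal_edges={self.n_signal_edges} exceeds the "
                f"{n_edges} edges available with n_nodes={self.n_nodes}"
            )
        if self.n_active_vertices > self.n_vertices:
            raise ValueError(
                f"n_active_vertices={self.n_active_vertices} exceeds "
                f"n_vertices={self.n_vertices}"
            )
        for name in (
            "noise_sd", "subject_effect_sd_fc", "session_noise_sd_fc",
            "subject_effect_sd_anat", "session_noise_sd_anat",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2


@dataclass
class SynthCohort:
    """Everything one synthetic run produces, for both datasets."""

    phenotypes: pd.DataFrame           # one row per subject, both datasets
    edges_session1: FeatureSet         # all subjects (A then B)
    edges_session2: FeatureSet
    anat_session1: FeatureSet          # masked vertex features
    anat_session2: FeatureSet
    vertex_mask: np.ndarray            # full-mesh boolean mask
    signal_edge_idx: np.ndarray        # planted signal edges (indices into edges)
    config: SynthConfig

    def dataset(self, which: str) -> np.ndarray:
        """Boolean row selector for dataset 'A' or 'B'."""
        return (self.phenotypes["dataset"] == which).to_numpy()

    def subset_edges(self, which: str, session: int = 1) -> FeatureSet:
        fs = self.edges_session1 if session == 1 else self.edges_session2
        sel = self.dataset(which)
        return FeatureSet(
            matrix=fs.matrix[sel],
            feature_ids=fs.feature_ids,
            kind="edges",
            subject_ids=[s for s, keep in zip(fs.subject_ids, sel) if keep],
        )

    def subset_anat(self, which: str, session: int = 1) -> FeatureSet:
        fs = self.anat_session1 if session == 1 else self.anat_session2
        sel = self.dataset(which)
        return FeatureSet(
            matrix=fs.matrix[sel],
            feature_ids=fs.feature_ids,
            kind="vertices",
            subject_ids=[s for s, keep in zip(fs.subject_ids, sel) if keep],
        )


def _two_session_features(
    rng: np.random.Generator,
    n_subjects: int,
    n_features: int,
    group_mean: np.ndarray,
    subject_sd: float,
    session_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """session value = group mean + stable subject offset + session noise."""
    stable = group_mean + subject_sd * rng.standard_normal((n_subjects, n_features))
    s1 = stable + session_sd * rng.standard_normal((n_subjects, n_features))
    s2 = stable + session_sd * rng.standard_normal((n_subjects, n_features))
    return stable, s1, s2


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Draw one full synthetic cohort (datasets A and B, two sessions)."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_subjects_A + config.n_subjects_B
    n_edges = config.n_edges

    # --- phenotypes -------------------------------------------------------
    age = rng.uniform(8.0, 17.0, n_total)
    sex = rng.integers(0, 2, n_total).astype(float)
    scanner = np.where(np.arange(n_total) < config.n_subjects_A, 0, 1)
    baseline = rng.uniform(BASELINE_CUTOFF, PARS_MAX, n_total)
    mean_fd = rng.lognormal(mean=np.log(0.12), sigma=0.4, size=n_total)

    # --- connectivity edges ----------------------------------------------
    edge_mean = rng.normal(0.3, 0.2, n_edges)
    _, edges1, edges2 = _two_session_features(
        rng, n_total, n_edges, edge_mean,
        config.subject_effect_sd_fc, config.session_noise_sd_fc,
    )
    if config.scanner_effect:
        edges1 += config.scanner_effect * scanner[:, None]
        edges2 += config.scanner_effect * scanner[:, None]

    signal_idx = rng.choice(n_edges, size=config.n_signal_edges, replace=False)
    signal_idx.sort()
    signal_sum = edges1[:, signal_idx].sum(axis=1)

    if config.baseline_brain_corr:
        # mix a standardized copy of the signal into baseline severity
        z = (signal_sum - signal_sum.mean()) / max(signal_sum.std(), 1e-12)
        span = (PARS_MAX - BASELINE_CUTOFF) / 2.0
        baseline = np.clip(
            baseline + config.baseline_brain_corr * span * z,
            BASELINE_CUTOFF, PARS_MAX,
        )

    # --- outcome ----------------------------------------------------------
    y = (
        config.intercept
        + config.beta_strength * signal_sum
        + config.beta_age * age
        + config.beta_sex * sex
        + config.beta_baseline * baseline
        + config.noise_sd * rng.standard_normal(n_total)
    )
    y = np.clip(y, PARS_MIN, PARS_MAX)

    # --- anatomy ----------------------------------------------------------
    n_act = config.n_active_vertices
    vert_mean = rng.normal(2.5, 0.5, n_act)
    _, anat1, anat2 = _two_session_features(
        rng, n_total, n_act, vert_mean,
        config.subject_effect_sd_anat, config.session_noise_sd_anat,
    )
    mask = np.zeros(config.n_vertices, dtype=bool)
    mask[: n_act] = True  # trailing vertices are constant (non-cortical)

    subject_ids = [
        f"sub-{'A' if i < config.n_subjects_A else 'B'}{i:03d}" for i in range(n_total)
    ]
    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "dataset": ["A"] * config.n_subjects_A + ["B"] * config.n_subjects_B,
            "age_years": age,
            "sex": sex.astype(int),
            "scanner": scanner,
            "pars_baseline": baseline,
            "pars_post": y,
            "mean_fd": mean_fd,
        }
    )

    eids = edge_ids(config.n_nodes)
    vids = [int(i) for i in np.flatnonzero(mask)]
    return SynthCohort(
        phenotypes=pheno,
        edges_session1=FeatureSet(edges1, eids, "edges", subject_ids),
        edges_session2=FeatureSet(edges2, eids, "edges", subject_ids),
        anat_session1=FeatureSet(anat1, vids, "vertices", subject_ids),
        anat_session2=FeatureSet(anat2, vids, "vertices", subject_ids),
        vertex_mask=mask,
        signal_edge_idx=signal_idx,
        config=config,
    )


def generate_time_series(
    config: SynthConfig,
    n_subjects: int | None = None,
    n_latent: int = 10,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Per-subject node time series from a latent-factor model.

    Each node's series is a loading-weighted mixture of shared latent
    series plus node noise, so the resulting correlation matrices have
    realistic off-diagonal structure for exercising the functional
    connectivity path.  Returns one (n_timepoints x n_nodes) array per
    subject.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_sub = n_subjects if n_subjects is not None else config.n_subjects_A
    out = []
    loadings = rng.normal(0, 1, (n_latent, config.n_nodes))
    for _ in range(n_sub):
        latent = rng.standard_normal((config.n_timepoints, n_latent))
        noise = rng.standard_normal((config.n_timepoints, config.n_nodes))
        subj_load = loadings + 0.3 * rng.normal(0, 1, loadings.shape)
        out.append(latent @ subj_load + noise)
    return out


def write_cohort(cohort: SynthCohort, outdir) -> dict:
    """Write phenotypes, feature tables, mask and a manifest as TSV/plain text."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"phenotypes": str(outdir / "phenotypes.tsv")}
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    for name, fs in [
        ("edges_session1", cohort.edges_session1),
        ("edges_session2", cohort.edges_session2),
        ("anat_session1", cohort.anat_session1),
        ("anat_session2", cohort.anat_session2),
    ]:
        p = outdir / f"{name}.tsv"
        pd.DataFrame(fs.matrix, index=fs.subject_ids).to_csv(
            p, sep="\t", header=False, float_format="%.8g"
        )
        paths[name] = str(p)
    mask_path = outdir / "vertex_mask.tsv"
    np.savetxt(mask_path, cohort.vertex_mask.astype(int), fmt="%d")
    paths["vertex_mask"] = str(mask_path)
    sig_path = outdir / "signal_edges.tsv"
    np.savetxt(sig_path, cohort.signal_edge_idx, fmt="%d")
    paths["signal_edges"] = str(sig_path)
    manifest = {
        "config": {k: (v.item() if hasattr(v, "item") else v)
                   for k, v in vars(cohort.config).items()},
        "paths": paths,
        "n_subjects": int(len(cohort.phenotypes)),
        "n_edges": int(cohort.edges_session1.n_features),
        "n_active_vertices": int(cohort.anat_session1.n_features),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
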