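"""Feature construction: connectivity matrices, edge vectors, vertex masks.

Connectivity features are Fisher-z transformed Pearson correlations between
node time series, flattened to the row-major upper triangle (i < j) so that
edge identity is stable across subjects and sessions.  Anatomical features
are vertexwise morphometric scalars restricted to a cortex mask built by
removing vertices with zero across-subject variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "VertexMap",
    "FeatureSet",
    "compute_fc",
    "unwrap",
    "rewrap",
    "edge_ids",
    "build_vertex_mask",
    "icosphere_vertex_count",
    "fsaverage5_vertex_count",
]

_SYM_TOL = 1e-10
_R_CLIP = 1.0 - 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric node-by-node matrix of Fisher-z connectivity values.

    The diagonal is undefined and never enters feature vectors.
    """

    values: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v[~np.eye(v.shape[0], dtype=bool)])):
            raise ValueError("off-diagonal entries must be finite")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError(f"matrix asymmetric beyond {_SYM_TOL}")
        self.values = v
        if self.node_labels is not None and len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class VertexMap:
    """One morphometric scalar per mesh vertex, with a cortex mask."""

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        self.values = v
        if self.mask is None:
            self.mask = np.ones(v.size, dtype=bool)
        else:
            m = np.asarray(self.mask, dtype=bool).ravel()
            if m.size != v.size:
                raise ValueError("mask length does not match values")
            self.mask = m


@dataclass
class FeatureSet:
    """Per-subject flat feature vectors with stable feature identity.

    ``kind`` is ``"edges"`` (upper-triangle connectivity) or ``"vertices"``
    (masked morphometry); ``feature_ids`` are node-pair strings for edges
    and vertex indices for anatomy.
    """

    matrix: np.ndarray
    feature_ids: list = field(default_factory=list)
    kind: str = "edges"
    subject_ids: list | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x features)")
        self.matrix = m
        if self.feature_ids and len(self.feature_ids) != m.shape[1]:
            raise ValueError("feature_ids length does not match matrix columns")
        if self.subject_ids is not None and len(self.subject_ids) != m.shape[0]:
            raise ValueError("subject_ids length does not match matrix rows")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def compute_fc(
    time_series: np.ndarray,
    gsr: bool = False,
    partial: bool = False,
    node_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Functional connectivity from node time series.

    Pearson correlation between every pair of node series, Fisher-z
    transformed (``z = atanh(r)``).  With ``gsr`` the across-node mean
    series (the global signal) is regressed out of every node series first.
    With ``partial`` correlations come from the inverse covariance; when the
    covariance is ill-conditioned (few timepoints relative to nodes) a
    Ledoit-Wolf shrinkage estimate is used in its place.

    Correlations of magnitude 1 arising from degenerate series are clipped
    just inside (-1, 1) before the transform; constant node series are
    rejected with the offending node named.
    """
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time_series must be 2-D (timepoints x nodes)")
    n_t, n_nodes = ts.shape
    if n_t < 3:
        raise ValueError("need at least 3 timepoints")
    sds = ts.std(axis=0)
    if np.any(sds == 0):
        bad = int(np.argmax(sds == 0))
        name = node_labels[bad] if node_labels else str(bad)
        raise ValueError(f"node {name} has a constant time series")

    if gsr:
        g = ts.mean(axis=1)
        g = g - g.mean()
        denom = float(g @ g)
        if denom > 0:
            x = ts - ts.mean(axis=0)
            beta = (g @ x) / denom
            ts = x - np.outer(g, beta)
        sds = ts.std(axis=0)
        if np.any(sds == 0):
            bad = int(np.argmax(sds == 0))
            name = node_labels[bad] if node_labels else str(bad)
            raise ValueError(
                f"node {name} became constant after global signal regression"
            )

    if partial:
        cov = np.cov(ts, rowvar=False)
        # ridge toward the Ledoit-Wolf shrinkage target when singular or
        # under-determined; exact inverse otherwise
        if n_t <= n_nodes or np.linalg.cond(cov) > 1e12:
            from sklearn.covariance import LedoitWolf

            cov = LedoitWolf().fit(ts).covariance_
        try:
            prec = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "covariance is singular; rerun with more timepoints or rely on "
                "the shrinkage path (n_timepoints <= n_nodes)"
            ) from exc
        d = np.sqrt(np.diag(prec))
        r = -prec / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    else:
        r = np.corrcoef(ts, rowvar=False)

    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z, node_labels=node_labels)


def edge_ids(n_nodes: int, node_labels: Sequence[str] | None = None) -> list[str]:
    """Edge identifiers in the fixed row-major upper-triangle order (i < j)."""
    labels = node_labels if node_labels is not None else [str(i) for i in range(n_nodes)]
    iu, ju = np.triu_indices(n_nodes, k=1)
    return [f"{labels[i]}-{labels[j]}" for i, j in zip(iu, ju)]


def unwrap(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its row-major upper triangle (i < j).

    Length is ``n (n - 1) / 2``; for the 216-node parcellation that is the
    23,220 unique edges.  Round-trips with :func:`rewrap`.
    """
    if isinstance(matrix, ConnectivityMatrix):
        v = matrix.values
    else:
        v = np.asarray(matrix, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError(f"matrix asymmetric beyond {_SYM_TOL}")
    iu, ju = np.triu_indices(v.shape[0], k=1)
    return v[iu, ju].copy()


def rewrap(vector: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Rebuild the symmetric matrix from an unwrapped edge vector (diagonal 0)."""
    vec = np.asarray(vector, dtype=float).ravel()
    if n_nodes is None:
        n_nodes = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n_nodes * (n_nodes - 1) // 2 != vec.size:
        raise ValueError(f"vector length {vec.size} is not n(n-1)/2 for any n")
    out = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def build_vertex_mask(maps: Sequence[VertexMap | np.ndarray], tol: float = 1e-12):
    """Mask out vertices with zero variance across subjects.

    Vertices whose across-subject variance is 0 (within ``tol``) carry no
    information and correspond to non-cortical mesh regions; they are
    excluded.  Returns ``(mask, n_in, n_out)``.
    """
    arrays = [m.values if isinstance(m, VertexMap) else np.asarray(m, float).ravel()
              for m in maps]
    if len(arrays) < 2:
        raise ValueError("need at least 2 subjects to assess variance")
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent vertex-map lengths: {sorted(lengths)}")
    stacked = np.vstack(arrays)
    mask = stacked.var(axis=0) > tol
    return mask, int(mask.sum()), int((~mask).sum())


def stack_edge_features(
    matrices: Sequence[ConnectivityMatrix | np.ndarray],
    node_labels: Sequence[str] | None = None,
    subject_ids: Sequence | None = None,
) -> FeatureSet:
    """Stack per-subject connectivity matrices into an edge FeatureSet."""
    rows = [unwrap(m) for m in matrices]
    n = len(rows)
    if n == 0:
        raise ValueError("no matrices given")
    first = matrices[0]
    n_nodes = first.n_nodes if isinstance(first, ConnectivityMatrix) else np.asarray(first).shape[0]
    return FeatureSet(
        matrix=np.vstack(rows),
        feature_ids=edge_ids(n_nodes, node_labels),
        kind="edges",
        subject_ids=list(subject_ids) if subject_ids is not None else None,
    )


def stack_vertex_features(
    maps: Sequence[VertexMap | np.ndarray],
    mask: np.ndarray,
    subject_ids: Sequence | None = None,
) -> FeatureSet:
    """Stack per-subject vertex maps, keeping only masked-in vertices."""
    mask = np.asarray(mask, dtype=bool).ravel()
    rows = []
    for m in maps:
        v = m.values if isinstance(m, VertexMap) else np.asarray(m, float).ravel()
        if v.size != mask.size:
            raise ValueError("vertex map length does not match mask")
        rows.append(v[mask])
    ids = [int(i) for i in np.flatnonzero(mask)]
    return FeatureSet(
        matrix=np.vstack(rows),
        feature_ids=ids,
        kind="vertices",
        subject_ids=list(subject_ids) if subject_ids is not None else None,
    )


def icosphere_vertex_count(n_subdivisions: int) -> int:
    """Vertex count of an icosahedron after recursive 4-fold face subdivision.

    The mesh is actually constructed: starting from the 12-vertex, 20-face
    icosahedron, each subdivision splits every triangle into four by
    inserting deduplicated edge midpoints.
    """
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be >= 0")
    phi = (1 + 5**0.5) / 2
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.asarray(v, dtype=float) for v in verts]
    for _ in range(n_subdivisions):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint_cache:
                verts.append((verts[a] + verts[b]) / 2.0)
                midpoint_cache[key] = len(verts) - 1
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return len(verts)


def fsaverage5_vertex_count() -> int:
    """Whole-brain vertex count of the fsaverage5 mesh (both hemispheres).

    Each hemisphere is a geodesic sphere from 5 recursive subdivisions of an
    icosahedron (10,242 vertices); two hemispheres give 20,484.
    """
    return 2 * icosphere_vertex_count(5)


# ---------------------------------------------------------------------------
# plain-text IO (tab-separated); surface-standard formats (GIFTI/CIFTI) are
# out of scope — convert externally and feed the resulting tables in here.

def read_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def write_matrix_tsv(path, matrix: np.ndarray) -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.10g"
    )
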