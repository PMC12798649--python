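"""Vertex-to-region functional connectivity.

Pipeline: (optional) compartment-PC nuisance regression → region mean
timecourses → vertex×region Pearson correlation → Fisher z transform →
two-stage averaging (runs within subject, then subjects). All averaging is
done in z-space; no inverse transform is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import DataError
from .parcellation import Parcellation

#: correlations are clipped to this magnitude before atanh
R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Group-average vertices × targets Fisher-z connectivity fingerprints."""

    values: np.ndarray
    target_region_ids: np.ndarray
    n_subjects: int = 1
    n_runs: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.target_region_ids = np.asarray(self.target_region_ids, dtype=np.int64)
        if self.values.ndim != 2:
            raise DataError("connectivity values must be 2-D (vertices × targets)")
        if self.values.shape[1] != self.target_region_ids.shape[0]:
            raise DataError("column count must match number of target regions")
        if not np.all(np.isfinite(self.values)):
            raise DataError("connectivity matrix contains non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def save(self, path: str | Path) -> None:
        """Write as compressed dense array + JSON sidecar (region order, provenance)."""
        path = Path(path)
        np.savez_compressed(path, values=self.values)
        sidecar = {
            "target_region_ids": self.target_region_ids.tolist(),
            "n_subjects": self.n_subjects,
            "n_runs": self.n_runs,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
        values = np.load(npz)["values"]
        sidecar = json.loads(npz.with_suffix(".json").read_text())
        return cls(
            values,
            np.asarray(sidecar["target_region_ids"]),
            sidecar["n_subjects"],
            sidecar["n_runs"],
        )


def _top_temporal_pcs(compartment: np.ndarray, n_components: int) -> np.ndarray:
    """Top temporal principal components (time × k) of a compartment."""
    comp = np.asarray(compartment, dtype=np.float64)
    if comp.ndim != 2:
        raise DataError("compartment matrix must be 2-D (rows × time)")
    centered = comp - comp.mean(axis=1, keepdims=True)
    # temporal PCs = right singular vectors of the rows × time matrix
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"compartment rank {rank} < requested {n_components} components; "
            f"using {k}",
            RuntimeWarning,
            stacklevel=3,
        )
    return vt[:k].T


def nuisance_regress(
    vertex_ts: np.ndarray,
    compartments: Sequence[np.ndarray],
    n_components: int = 5,
) -> np.ndarray:
    """Regress compartment principal components out of vertex timecourses.

    The top ``n_components`` temporal PCs are extracted from each noise
    compartment (white-matter-like, CSF-like, ...) *separately*, concatenated
    with an intercept column, and every vertex timecourse is replaced by its
    least-squares residual. Residuals are orthogonal to all regressors.
    """
    vertex_ts = np.asarray(vertex_ts, dtype=np.float64)
    t = vertex_ts.shape[1]
    regressors = [np.ones((t, 1))]
    for comp in compartments:
        comp = np.asarray(comp, dtype=np.float64)
        if comp.shape[1] != t:
            raise DataError(
                f"compartment time length {comp.shape[1]} != vertex time length {t}"
            )
        regressors.append(_top_temporal_pcs(comp, n_components))
    design = np.hstack(regressors)
    beta, *_ = np.linalg.lstsq(design, vertex_ts.T, rcond=None)
    return vertex_ts - (design @ beta).T


def region_mean_timecourses(
    vertex_ts: np.ndarray, parcellation: Parcellation
) -> np.ndarray:
    """Unweighted mean timecourse of every vertex-bearing target region.

    Rows follow ``parcellation.vertex_bearing_region_ids``. A modeled region
    without vertices is an error naming the region.
    """
    vertex_ts = np.asarray(vertex_ts, dtype=np.float64)
    if vertex_ts.shape[0] != parcellation.n_vertices:
        raise DataError(
            f"vertex_ts has {vertex_ts.shape[0]} rows but parcellation has "
            f"{parcellation.n_vertices} vertices"
        )
    out = []
    for r in parcellation.vertex_bearing_region_ids:
        idx = parcellation.vertices_of(r)
        if idx.size == 0:  # pragma: no cover - filtered by vertex_bearing ids
            raise DataError(f"region {r} has no vertices")
        out.append(vertex_ts[idx].mean(axis=0))
    if not out:
        raise DataError("no vertex-bearing regions in parcellation")
    return np.vstack(out)


def vertex_region_connectivity(
    vertex_ts: np.ndarray, region_ts: np.ndarray
) -> np.ndarray:
    """Pearson correlation of every vertex with every region mean timecourse.

    Zero-variance rows are a hard error (identified by index) rather than a
    silent NaN.
    """
    v = np.asarray(vertex_ts, dtype=np.float64)
    r = np.asarray(region_ts, dtype=np.float64)
    if v.shape[1] != r.shape[1]:
        raise DataError("vertex and region timecourses differ in length")
    vc = v - v.mean(axis=1, keepdims=True)
    rc = r - r.mean(axis=1, keepdims=True)
    vsd = np.sqrt((vc**2).sum(axis=1))
    rsd = np.sqrt((rc**2).sum(axis=1))
    bad_v = np.flatnonzero(vsd == 0)
    if bad_v.size:
        raise DataError(f"zero-variance vertex timecourse at rows {bad_v[:5].tolist()}")
    bad_r = np.flatnonzero(rsd == 0)
    if bad_r.size:
        raise DataError(f"zero-variance region timecourse at rows {bad_r[:5].tolist()}")
    corr = (vc @ rc.T) / np.outer(vsd, rsd)
    return np.clip(corr, -1.0, 1.0)


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """Fisher z transform, atanh(r), with |r| clipped to 1 − 1e−7.

    Values beyond ±1 by more than 1e−12 are invalid correlations and raise.
    """
    r = np.asarray(r_matrix, dtype=np.float64)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise DataError("correlation values outside [-1, 1]")
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def group_average(
    per_run_z: Sequence[Sequence[np.ndarray]],
    target_region_ids: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Two-stage mean: over runs within subject, then over subjects (z-space).

    ``per_run_z[s][r]`` is the z-matrix of subject ``s``, run ``r``.
    """
    if len(per_run_z) == 0:
        raise DataError("no subjects to average")
    subject_means = []
    shape = None
    for runs in per_run_z:
        if len(runs) == 0:
            raise DataError("subject with no runs")
        mats = [np.asarray(m, dtype=np.float64) for m in runs]
        for m in mats:
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise DataError(f"shape mismatch: {m.shape} vs {shape}")
        subject_means.append(np.mean(mats, axis=0))
    group = np.mean(subject_means, axis=0)
    if target_region_ids is None:
        target_region_ids = np.arange(group.shape[1])
    return ConnectivityMatrix(
        group,
        target_region_ids,
        n_subjects=len(per_run_z),
        n_runs=len(per_run_z[0]),
    )


def compute_connectivity(
    timeseries: Sequence[Sequence[np.ndarray]],
    parcellation: Parcellation,
    noise_compartments: Sequence[Sequence[Sequence[np.ndarray]]] | None = None,
    extra_target_ts: Sequence[Sequence[np.ndarray]] | None = None,
    n_components: int = 5,
) -> ConnectivityMatrix:
    """Full preprocessing chain over a multi-subject, multi-run dataset.

    ``extra_target_ts[s][r]`` supplies timecourses (targets × time) for
    connectivity targets that carry no vertices; they are stacked under the
    vertex-derived region means so the fingerprint has one column per target.
    Nuisance regression, when compartments are given, is applied per run.
    """
    per_run_z: list[list[np.ndarray]] = []
    for s, runs in enumerate(timeseries):
        z_runs = []
        for r, vts in enumerate(runs):
            if noise_compartments is not None:
                vts = nuisance_regress(
                    vts, noise_compartments[s][r], n_components=n_components
                )
            region_ts = region_mean_timecourses(vts, parcellation)
            if extra_target_ts is not None:
                region_ts = np.vstack([region_ts, extra_target_ts[s][r]])
            z_runs.append(fisher_z(vertex_region_connectivity(vts, region_ts)))
        per_run_z.append(z_runs)
    n_cols = per_run_z[0][0].shape[1]
    ids = parcellation.target_region_ids
    if ids.shape[0] != n_cols:
        ids = np.arange(n_cols)
    return group_average(per_run_z, ids)
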