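"""Synthetic resting-state + activation datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes,
without any cortical geometry:

* region-level latent AR(1) timecourses, fresh per (subject, run);
* vertex timecourses = own-region latent + dense cross-region mixing
  (per-vertex loadings fixed across subjects/runs, so group fingerprints are
  stable and heterogeneous within a region) + shared noise-compartment
  components (WM-/CSF-like) + white noise;
* extra connectivity targets without vertices, whose reference timecourses
  are their latents directly;
* per-domain activation maps planted as noisy linear functions of the
  group-average Fisher-z fingerprints, with noise calibrated so the
  generative R² of every (region, domain) model equals its planted value.

All randomness flows from the config seed through named substreams, so any
stage can be regenerated independently and identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping
import json

import numpy as np

from ._seeds import (
    STREAM_ACTIVATION_NOISE,
    STREAM_MIXING,
    STREAM_PLANTED_R2,
    STREAM_TIMESERIES,
    STREAM_WEIGHTS,
    substream,
)
from .config import SyntheticConfig
from .connectivity import ConnectivityMatrix, compute_connectivity
from .exceptions import ConfigError, DataError
from .parcellation import Parcellation, make_domain_table, make_parcellation


@dataclass
class GroundTruth:
    """Planted parameters per (region, domain): weights, noise SD, achieved R²."""

    weights: dict[tuple[int, int], np.ndarray]
    noise_sd: dict[tuple[int, int], float]
    achieved_r2: dict[tuple[int, int], float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            f"{r},{d}": {
                "weights": self.weights[(r, d)].tolist(),
                "noise_sd": self.noise_sd[(r, d)],
                "achieved_r2": self.achieved_r2[(r, d)],
            }
            for (r, d) in self.weights
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        w, sd, r2 = {}, {}, {}
        for key, rec in payload.items():
            r, d = (int(x) for x in key.split(","))
            w[(r, d)] = np.asarray(rec["weights"])
            sd[(r, d)] = float(rec["noise_sd"])
            r2[(r, d)] = float(rec["achieved_r2"])
        return cls(w, sd, r2)


@dataclass
class SyntheticDataset:
    """Everything the analysis consumes, plus the planted truth."""

    config: SyntheticConfig
    parcellation: Parcellation
    #: timeseries[subject][run] → vertices × timepoints
    timeseries: list[list[np.ndarray]]
    #: noise_compartments[subject][run] → [WM-like, CSF-like] rows × timepoints
    noise_compartments: list[list[list[np.ndarray]]]
    #: extra_target_ts[subject][run] → n_extra_targets × timepoints
    extra_target_ts: list[list[np.ndarray]]
    #: activation[domain_id] → vertex vector (z-like scale)
    activation: dict[int, np.ndarray] = field(default_factory=dict)
    domain_table: "object" = None
    ground_truth: GroundTruth | None = None
    connectivity: ConnectivityMatrix | None = None


def _ar1(rng: np.random.Generator, n_series: int, n_timepoints: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series, one per row."""
    innov_sd = np.sqrt(1.0 - phi**2) if phi > 0 else 1.0
    x = np.empty((n_series, n_timepoints))
    x[:, 0] = rng.standard_normal(n_series)
    eps = rng.standard_normal((n_series, n_timepoints - 1)) * innov_sd
    for t in range(1, n_timepoints):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def _mixing_loadings(parcellation: Parcellation, config: SyntheticConfig):
    """Per-vertex loadings, fixed by seed across subjects and runs."""
    n_v = parcellation.n_vertices
    rng = substream(config.seed, STREAM_MIXING)
    mix = rng.standard_normal((n_v, config.n_targets)) * config.mixing_sd
    comp = rng.standard_normal((n_v, 2, config.n_compartment_sources))
    comp *= config.compartment_loading
    return mix, comp


def simulate_timeseries(
    parcellation: Parcellation, config: SyntheticConfig, seed: int | None = None
) -> SyntheticDataset:
    """Generate multi-subject, multi-run vertex timeseries and compartments.

    ``seed`` defaults to ``config.seed``; identical (parcellation, config,
    seed) reproduce the dataset bit for bit.
    """
    if config.n_timepoints <= 0:
        raise ConfigError("n_timepoints must be positive")
    seed = config.seed if seed is None else seed
    mix, comp_load = _mixing_loadings(parcellation, config)
    n_targets = config.n_targets
    n_extra = config.n_extra_targets
    own = np.zeros((parcellation.n_vertices, n_targets))
    own[np.arange(parcellation.n_vertices), parcellation.vertex_region] = (
        config.own_loading
    )

    timeseries: list[list[np.ndarray]] = []
    compartments: list[list[list[np.ndarray]]] = []
    extra_ts: list[list[np.ndarray]] = []
    for s in range(config.n_subjects):
        ts_runs, comp_runs, extra_runs = [], [], []
        for r in range(config.n_runs):
            rng = substream(seed, STREAM_TIMESERIES, s, r)
            latents = _ar1(rng, n_targets, config.n_timepoints, config.noise_ar_coefficient)
            sources = _ar1(rng, 2 * config.n_compartment_sources, config.n_timepoints,
                           config.noise_ar_coefficient)
            sources = sources.reshape(2, config.n_compartment_sources, -1)
            vts = (own + mix) @ latents
            for c in range(2):
                vts += comp_load[:, c, :] @ sources[c]
            if config.white_noise_sd > 0:
                vts += config.white_noise_sd * rng.standard_normal(vts.shape)
            # observed compartment matrices: rows load on that compartment's
            # sources, plus measurement noise
            comps = []
            for c in range(2):
                rows = rng.standard_normal(
                    (config.n_compartment_rows, config.n_compartment_sources)
                ) @ sources[c]
                rows += 0.2 * rng.standard_normal(rows.shape)
                comps.append(rows)
            ts_runs.append(vts)
            comp_runs.append(comps)
            extra_runs.append(latents[n_targets - n_extra:] if n_extra else
                              np.empty((0, config.n_timepoints)))
        timeseries.append(ts_runs)
        compartments.append(comp_runs)
        extra_ts.append(extra_runs)
    return SyntheticDataset(
        config=config,
        parcellation=parcellation,
        timeseries=timeseries,
        noise_compartments=compartments,
        extra_target_ts=extra_ts,
        domain_table=make_domain_table(config),
    )


def _resolve_planted_r2(
    config: SyntheticConfig, parcellation: Parcellation
) -> dict[tuple[int, int], float]:
    """Expand the planted_r2 config field to a full (region, domain) map.

    A (low, high) range is filled with a linspace over all cells, assigned in
    seeded-shuffled order, so the planted values span the bounds exactly.
    """
    regions = [int(r) for r in parcellation.modeled_region_ids]
    cells = [(r, d) for r in regions for d in range(config.n_domains)]
    pr = config.planted_r2
    if isinstance(pr, Mapping):
        missing = [c for c in cells if c not in pr]
        if missing:
            raise ConfigError(f"planted_r2 map missing cells, e.g. {missing[:3]}")
        return {c: float(pr[c]) for c in cells}
    if isinstance(pr, tuple):
        low, high = pr
        values = np.linspace(low, high, len(cells))
        rng = substream(config.seed, STREAM_PLANTED_R2)
        order = rng.permutation(len(cells))
        return {cells[i]: float(values[j]) for j, i in enumerate(order)}
    return {c: float(pr) for c in cells}


def plant_activation(
    fingerprints: ConnectivityMatrix,
    parcellation: Parcellation,
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[dict[int, np.ndarray], GroundTruth]:
    """Plant per-domain activation maps as noisy linear fingerprint readouts.

    For each (region, domain): draw a weight vector w over all connectivity
    targets, form the signal s = X_r w on the region's vertices, rescale w so
    var(s) = planted_r2 · scale², and add Gaussian noise with
    noise_sd = √(1 − planted_r2) · scale, so that
    var(s)/(var(s) + noise_sd²) = planted_r2 exactly.
    """
    seed = config.seed if seed is None else seed
    if fingerprints.n_vertices != parcellation.n_vertices:
        raise DataError("fingerprints not computed for all vertices")
    planted = _resolve_planted_r2(config, parcellation)
    scale = config.activation_scale
    activation = {d: np.zeros(parcellation.n_vertices) for d in range(config.n_domains)}
    weights, noise_sds, achieved = {}, {}, {}
    for (r, d), rho in planted.items():
        if not (0.0 <= rho <= 1.0):
            raise ConfigError(f"planted_r2[{r},{d}]={rho} outside [0, 1]")
        idx = parcellation.vertices_of(r)
        X = fingerprints.values[idx]
        wrng = substream(seed, STREAM_WEIGHTS, r, d)
        nrng = substream(seed, STREAM_ACTIVATION_NOISE, r, d)
        if rho == 0.0:
            w = np.zeros(fingerprints.values.shape[1])
            s = np.zeros(idx.size)
            noise_sd = scale
        else:
            w = wrng.standard_normal(fingerprints.values.shape[1])
            s = X @ w
            sd_s = float(np.std(s))
            if sd_s == 0.0:
                raise DataError(
                    f"zero-variance signal in region {r}: cannot plant r2={rho}"
                )
            w = w * (np.sqrt(rho) * scale / sd_s)
            s = X @ w
            noise_sd = float(np.sqrt(1.0 - rho) * scale)
        y = s + noise_sd * nrng.standard_normal(idx.size)
        activation[d][idx] = y
        var_s = float(np.var(s))
        weights[(r, d)] = w
        noise_sds[(r, d)] = noise_sd
        achieved[(r, d)] = var_s / (var_s + noise_sd**2) if (var_s + noise_sd**2) else 0.0
    return activation, GroundTruth(weights, noise_sds, achieved)


def generate_dataset(
    config: SyntheticConfig, nuisance: bool = True
) -> SyntheticDataset:
    """Full generator: parcellation → timeseries → fingerprints → activation."""
    parc = make_parcellation(config)
    ds = simulate_timeseries(parc, config)
    ds.connectivity = compute_connectivity(
        ds.timeseries,
        parc,
        noise_compartments=ds.noise_compartments if nuisance else None,
        extra_target_ts=ds.extra_target_ts,
    )
    ds.activation, ds.ground_truth = plant_activation(ds.connectivity, parc, config)
    return ds


def make_region_dataset(
    n_vertices: int,
    n_targets: int = 89,
    planted_r2: float = 0.5,
    seed: int = 0,
    n_timepoints: int = 300,
    noise_ar_coefficient: float = 0.6,
    mixing_sd: float = 0.2,
    white_noise_sd: float = 0.5,
    activation_scale: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Single-region shortcut: fingerprints X, activation y, and the truth.

    Simulates one region of ``n_vertices`` vertices against ``n_targets``
    latent targets through the same latent/mixing/correlation machinery as
    the full generator (single subject/run, no compartments), then plants a
    linear activation at the requested generative R².

    Returns ``(X, y, weights, noise_sd)`` with X the vertices × targets
    Fisher-z fingerprint matrix.
    """
    from .connectivity import fisher_z, vertex_region_connectivity

    rng = substream(seed, STREAM_TIMESERIES)
    latents = _ar1(rng, n_targets, n_timepoints, noise_ar_coefficient)
    mix = rng.standard_normal((n_vertices, n_targets)) * mixing_sd
    mix[:, 0] += 1.0  # the region's own latent
    vts = mix @ latents + white_noise_sd * rng.standard_normal((n_vertices, n_timepoints))
    X = fisher_z(vertex_region_connectivity(vts, latents))

    if not (0.0 <= planted_r2 <= 1.0):
        raise ConfigError(f"planted_r2={planted_r2} outside [0, 1]")
    wrng = substream(seed, STREAM_WEIGHTS)
    nrng = substream(seed, STREAM_ACTIVATION_NOISE)
    if planted_r2 == 0.0:
        w = np.zeros(n_targets)
        noise_sd = activation_scale
        y = noise_sd * nrng.standard_normal(n_vertices)
    else:
        w = wrng.standard_normal(n_targets)
        s = X @ w
        sd_s = float(np.std(s))
        if sd_s == 0.0:
            raise DataError("zero-variance signal; cannot plant requested r2")
        w = w * (np.sqrt(planted_r2) * activation_scale / sd_s)
        noise_sd = float(np.sqrt(1.0 - planted_r2) * activation_scale)
        y = X @ w + noise_sd * nrng.standard_normal(n_vertices)
    return X, y, w, noise_sd


def write_fixture(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a dataset to disk: TSV tables, compressed arrays, JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.parcellation.to_tsv(out / "parcellation.tsv", out / "regions.tsv")
    ds.domain_table.to_csv(out / "domains.tsv", sep="\t", index=False)
    arrays = {}
    for s, runs in enumerate(ds.timeseries):
        for r, vts in enumerate(runs):
            arrays[f"ts_s{s}_r{r}"] = vts
            arrays[f"extra_s{s}_r{r}"] = ds.extra_target_ts[s][r]
            for c, comp in enumerate(ds.noise_compartments[s][r]):
                arrays[f"comp_s{s}_r{r}_c{c}"] = comp
    np.savez_compressed(out / "timeseries.npz", **arrays)
    if ds.activation:
        np.savez_compressed(
            out / "activation.npz",
            **{f"domain_{d}": v for d, v in ds.activation.items()},
        )
    if ds.connectivity is not None:
        ds.connectivity.save(out / "connectivity.npz")
    if ds.ground_truth is not None:
        ds.ground_truth.to_json(out / "ground_truth.json")
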