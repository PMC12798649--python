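"""Configuration dataclasses for the synthetic generator and the ridge fits.

Defaults mirror the study design this package emulates: 41 modeled regions
per hemisphere (34 cortical + 7 subcortical, mirrored left/right → 82
models), 7 additional connectivity-only targets (89 predictor columns in
total), 4 resting-state runs per subject, 33 cognitive domains grouped into
7 categories, 5-fold cross-validation with a budget of 100 penalty
evaluations, and 1,000 permutations per model. Vertex counts, subjects and
timepoints default to desk-scale values; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple, Union

import numpy as np

from .exceptions import ConfigError

PlantedR2 = Union[float, Tuple[float, float], Mapping[Tuple[int, int], float]]

#: Lobe labels cycled over homologous region pairs.
LOBES = ("occipital", "temporal", "parietal", "frontal", "cingulate", "subcortical")

#: Cognitive-domain categories; domains are assigned round-robin.
CATEGORIES = (
    "sensory",
    "somatosensory",
    "language",
    "social",
    "decision_making",
    "memory",
    "executive_function",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-subject resting-state dataset.

    The generator produces, per subject and run, vertex×time signals built
    from region-level latent AR(1) timecourses plus dense cross-region
    mixing, white noise and shared noise-compartment (WM-/CSF-like)
    components, together with per-domain activation maps that are noisy
    linear functions of the resulting connectivity fingerprints.
    """

    n_vertices: int = 1640
    n_regions_per_hemisphere: int = 41
    n_extra_targets: int = 7
    n_subjects: int = 4
    n_runs: int = 4
    n_timepoints: int = 200
    n_domains: int = 33
    n_categories: int = 7
    #: Generative R² of each (region, domain) activation model: a scalar, a
    #: (low, high) range filled deterministically so the planted values span
    #: the bounds exactly, or an explicit {(region_id, domain_id): value} map.
    planted_r2: PlantedR2 = (0.2, 0.95)
    noise_ar_coefficient: float = 0.6
    #: Loading of each vertex on its own region's latent signal.
    own_loading: float = 1.0
    #: SD of the per-vertex dense loadings onto all target latents.
    mixing_sd: float = 0.2
    white_noise_sd: float = 0.5
    #: Loading of vertices on the shared noise-compartment sources.
    compartment_loading: float = 0.3
    n_compartment_sources: int = 5
    n_compartment_rows: int = 20
    #: 0 → near-equal region sizes; larger values spread sizes multiplicatively.
    region_size_dispersion: float = 0.0
    #: SD scale of activation maps (z-statistic-like).
    activation_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints <= 10:
            raise ConfigError("n_timepoints must exceed 10")
        if self.n_regions_per_hemisphere < 1 or self.n_extra_targets < 0:
            raise ConfigError("region counts must be positive")
        if not (0.0 <= self.noise_ar_coefficient < 1.0):
            raise ConfigError("noise_ar_coefficient must lie in [0, 1)")
        if self.n_subjects < 1 or self.n_runs < 1:
            raise ConfigError("need at least one subject and one run")
        if self.n_domains < 1 or not (1 <= self.n_categories <= self.n_domains):
            raise ConfigError("need 1 <= n_categories <= n_domains")
        for v in self._planted_r2_values():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"planted_r2 value {v} outside [0, 1]")

    def _planted_r2_values(self):
        if isinstance(self.planted_r2, Mapping):
            return list(self.planted_r2.values())
        if isinstance(self.planted_r2, tuple):
            return list(self.planted_r2)
        return [float(self.planted_r2)]

    @property
    def n_modeled_regions(self) -> int:
        return 2 * self.n_regions_per_hemisphere

    @property
    def n_targets(self) -> int:
        """Connectivity targets: modeled regions plus extra targets."""
        return self.n_modeled_regions + self.n_extra_targets

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["planted_r2"], Mapping):
            d["planted_r2"] = {f"{r},{dm}": v for (r, dm), v in d["planted_r2"].items()}
        elif isinstance(d["planted_r2"], tuple):
            d["planted_r2"] = list(d["planted_r2"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        pr = d.get("planted_r2")
        if isinstance(pr, Mapping):
            d["planted_r2"] = {
                tuple(int(x) for x in k.split(",")): float(v) for k, v in pr.items()
            }
        elif isinstance(pr, (list, tuple)):
            d["planted_r2"] = tuple(float(v) for v in pr)
        return cls(**d)


@dataclass
class RidgeFitSpec:
    """How each (region, domain) ridge model selects and applies its penalty.

    ``lambda_grid_bounds`` are relative: the evaluated grid is
    ``logspace(low, high, max_evaluations) * mean(diag(Xc'Xc))`` so the
    search window tracks the scale of the design matrix.
    """

    n_folds: int = 5
    max_evaluations: int = 100
    lambda_grid_bounds: Tuple[float, float] = (1e-6, 1e4)
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.max_evaluations < 1:
            raise ConfigError("max_evaluations must be >= 1")
        low, high = self.lambda_grid_bounds
        if not (0 < low < high):
            raise ConfigError("lambda_grid_bounds must satisfy 0 < low < high")

    def grid(self, scale: float = 1.0) -> np.ndarray:
        low, high = self.lambda_grid_bounds
        return np.logspace(np.log10(low), np.log10(high), self.max_evaluations) * scale

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda_grid_bounds"] = list(d["lambda_grid_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RidgeFitSpec":
        d = dict(d)
        if "lambda_grid_bounds" in d:
            d["lambda_grid_bounds"] = tuple(d["lambda_grid_bounds"])
        return cls(**d)
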