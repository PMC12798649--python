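"""End-to-end orchestration: simulate/ingest → connectivity → fits →
permutations → group stats → report bundle, with deterministic seeding,
structured logging and a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .config import RidgeFitSpec, SyntheticConfig
from .connectivity import ConnectivityMatrix, compute_connectivity
from .exceptions import ConfigError, DataError
from .parcellation import Parcellation, make_domain_table
from .permutation import PermutationResult, permutation_distribution
from .ridge import ModelFitResult, fit_region_domain
from .stats import build_fit_table, run_group_stats
from .synthetic import SyntheticDataset, generate_dataset

log = logging.getLogger("connfit")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "real"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    ridge: RidgeFitSpec = field(default_factory=RidgeFitSpec)
    n_permutations: int = 1000
    master_seed: int = 0
    out_dir: str | None = None
    n_jobs: int = 1
    nuisance: bool = True
    laterality_domains: list[int] | None = None
    # real-data mode inputs
    connectivity_path: str | None = None
    activation_dir: str | None = None
    parcellation_path: str | None = None
    region_meta_path: str | None = None
    domain_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.mode == "real":
            for name in (
                "connectivity_path",
                "activation_dir",
                "parcellation_path",
                "region_meta_path",
                "domain_table_path",
            ):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"real mode requires existing path for {name}")

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("synthetic", "ridge")
        }
        d["synthetic"] = self.synthetic.to_dict()
        d["ridge"] = self.ridge.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "ridge" in d:
            d["ridge"] = RidgeFitSpec.from_dict(d["ridge"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML or JSON config file."""
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config file {path}: {e}") from e
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, dtype=np.float64).tobytes()).hexdigest()[:16]


def enumerate_models(
    parcellation: Parcellation, domain_table: pd.DataFrame
) -> list[tuple[int, int]]:
    """All (region_id, domain_id) model cells of the design."""
    return [
        (int(r), int(d))
        for r in parcellation.modeled_region_ids
        for d in domain_table["domain_id"]
    ]


def _fit_one(
    conn: ConnectivityMatrix,
    activation: np.ndarray,
    parcellation: Parcellation,
    region_id: int,
    domain_id: int,
    ridge_spec: RidgeFitSpec,
    n_permutations: int,
    master_seed: int,
) -> tuple[ModelFitResult, PermutationResult]:
    try:
        fit = fit_region_domain(
            conn, activation, parcellation, region_id, ridge_spec, domain_id=domain_id
        )
        idx = parcellation.vertices_of(region_id)
        perm = permutation_distribution(
            conn.values[idx],
            np.asarray(activation)[idx],
            fit.lambda_selected,
            n_permutations=n_permutations,
            seed=master_seed,
            region_id=region_id,
            domain_id=domain_id,
            standardize=ridge_spec.standardize,
        )
    except Exception as e:
        raise DataError(
            f"stage failed at (region={region_id}, domain={domain_id}): {e}"
        ) from e
    return fit, perm


def _load_real_inputs(config: RunConfig):
    parc = Parcellation.from_tsv(config.parcellation_path, config.region_meta_path)
    conn = ConnectivityMatrix.load(config.connectivity_path)
    domain_table = pd.read_csv(config.domain_table_path, sep="\t")
    act_npz = np.load(Path(config.activation_dir) / "activation.npz")
    activation = {
        int(k.split("_")[1]): act_npz[k] for k in act_npz.files
    }
    for d, v in activation.items():
        if v.shape[0] != parc.n_vertices:
            raise DataError(
                f"activation for domain {d} has {v.shape[0]} vertices, "
                f"parcellation has {parc.n_vertices}"
            )
    return parc, conn, activation, domain_table


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the result bundle (and write it if asked).

    The bundle maps stage names to in-memory results: ``dataset`` (synthetic
    mode), ``connectivity``, ``fits``, ``permutations``, ``fit_table``,
    ``stats``, ``manifest``. With ``config.out_dir`` set, tables are written
    as TSV, matrices as compressed arrays, and the manifest as JSON.
    """
    t0 = time.perf_counter()
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    bundle: dict = {"manifest": manifest}

    if config.mode == "synthetic":
        ds: SyntheticDataset = generate_dataset(
            config.synthetic, nuisance=config.nuisance
        )
        parc, conn = ds.parcellation, ds.connectivity
        activation, domain_table = ds.activation, ds.domain_table
        bundle["dataset"] = ds
        manifest.timings["simulate"] = time.perf_counter() - t0
        log.info("simulated dataset: %d vertices, %d targets", parc.n_vertices, conn.values.shape[1])
    else:
        parc, conn, activation, domain_table = _load_real_inputs(config)
        manifest.timings["load"] = time.perf_counter() - t0
    manifest.checksums["connectivity"] = _checksum(conn.values)

    t1 = time.perf_counter()
    cells = enumerate_models(parc, domain_table)
    jobs = (
        delayed(_fit_one)(
            conn, activation[d], parc, r, d,
            config.ridge, config.n_permutations, config.master_seed,
        )
        for r, d in cells
    )
    results = Parallel(n_jobs=config.n_jobs)(jobs)
    fits = [f for f, _ in results]
    perms = [p for _, p in results]
    bundle["fits"], bundle["permutations"] = fits, perms
    manifest.timings["fit_and_permute"] = time.perf_counter() - t1
    log.info("fit %d models", len(fits))

    t2 = time.perf_counter()
    fit_table = build_fit_table(fits, perms, parc, domain_table)
    manifest.checksums["fit_table"] = _checksum(
        fit_table[["r2", "p_perm", "q99"]].to_numpy()
    )
    lat = config.laterality_domains
    if lat is None and parc.homolog_pairs():
        lat = [int(d) for d in domain_table["domain_id"].head(6)]
    stats = run_group_stats(
        fit_table, parc, laterality_domains=lat, seed=config.master_seed
    )
    bundle["fit_table"], bundle["stats"] = fit_table, stats
    manifest.timings["stats"] = time.perf_counter() - t2
    manifest.timings["total"] = time.perf_counter() - t0

    if config.out_dir:
        _write_bundle(config, parc, conn, fit_table, stats, manifest, bundle)
    return bundle


def _contrasts_frame(contrasts) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": c.pair[0],
                "group_b": c.pair[1],
                "t": c.t_stat,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_holm": c.p_holm,
                "cohen_d": c.cohen_d,
                "cohen_d_av": c.cohen_d_av,
                "test_kind": c.test_kind,
            }
            for c in contrasts
        ]
    )


def _write_bundle(config, parc, conn, fit_table, stats, manifest, bundle) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parc.to_tsv(out / "parcellation.tsv", out / "regions.tsv")
    conn.save(out / "connectivity.npz")
    fit_table.to_csv(out / "fits.tsv", sep="\t", index=False)
    for key in ("median_by_domain", "median_by_category", "median_by_lobe"):
        if key in stats:
            stats[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    report: dict = {"n_models": len(bundle["fits"])}
    if "anova" in stats:
        report["anova"] = stats["anova"].__dict__
        _contrasts_frame(stats["pairwise"]).to_csv(
            out / "contrasts.tsv", sep="\t", index=False
        )
    if "laterality" in stats:
        _contrasts_frame(stats["laterality"]).to_csv(
            out / "laterality.tsv", sep="\t", index=False
        )
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    manifest.to_json(out / "manifest.json")


def read_activation_volume(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex scalar map from NIfTI or GIFTI (adapter).

    The file must hold exactly one scalar per vertex, already aligned to the
    parcellation's vertex order; a vertex-count mismatch is an error that
    prints both counts. Masked vertices stored as exact zeros are passed
    through unmodified (their count is logged).
    """
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    if isinstance(img, nib.gifti.GiftiImage):
        arrays = [d.data.ravel() for d in img.darrays]
        if len(arrays) != 1:
            raise DataError(f"{path}: expected one scalar array, found {len(arrays)}")
        vec = np.asarray(arrays[0], dtype=np.float64)
    else:
        vec = np.asarray(img.get_fdata(), dtype=np.float64).ravel()
    if n_vertices is not None and vec.shape[0] != n_vertices:
        raise DataError(
            f"{path}: file has {vec.shape[0]} vertices but parcellation "
            f"has {n_vertices}"
        )
    n_zero = int(np.sum(vec == 0.0))
    if n_zero:
        log.info("%s: %d exact-zero (masked?) vertices passed through", path, n_zero)
    return vec
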