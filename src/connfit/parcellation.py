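"""Vertex parcellation and region metadata.

A parcellation assigns every vertex to exactly one *modeled* region (the
regions whose activation is fitted). Connectivity *targets* are the modeled
regions plus a handful of extra targets that carry no vertices of their own
— reference structures outside the modeled vertex domain whose timecourses
are supplied separately (in synthetic mode, by the generator).

Region metadata: hemisphere (``L``/``R``/``midline``), lobe, modeled flag,
and homolog pairing (left region i ↔ right region i, a bijection).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import STREAM_PARCELLATION, substream
from .config import LOBES, SyntheticConfig
from .exceptions import ConfigError, DataError

META_COLUMNS = ["region_id", "hemisphere", "lobe", "homolog_id", "modeled"]


@dataclass
class Parcellation:
    """Dense 0-based vertex→region map plus per-region metadata.

    ``vertex_region[v]`` is the region id of vertex ``v``. ``region_meta``
    has one row per connectivity target (modeled regions first, then extra
    targets), indexed by ``region_id``; ``homolog_id`` is −1 for unpaired
    regions.
    """

    vertex_region: np.ndarray
    region_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.vertex_region = np.asarray(self.vertex_region, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        meta = self.region_meta
        if list(meta.columns) != META_COLUMNS:
            raise DataError(f"region_meta must have columns {META_COLUMNS}")
        modeled = set(self.modeled_region_ids)
        present, counts = np.unique(self.vertex_region, return_counts=True)
        if not set(present) <= set(meta["region_id"]):
            raise DataError("vertex_region references unknown region ids")
        empties = modeled - set(present)
        if empties:
            raise DataError(f"modeled regions without vertices: {sorted(empties)}")
        # homolog pairing must be an involution restricted to paired regions
        hom = dict(zip(meta["region_id"], meta["homolog_id"]))
        for r, h in hom.items():
            if h >= 0 and hom.get(h, -1) != r:
                raise DataError(f"homolog pairing not symmetric at region {r}")

    @property
    def n_vertices(self) -> int:
        return self.vertex_region.shape[0]

    @property
    def modeled_region_ids(self) -> np.ndarray:
        m = self.region_meta
        return m.loc[m["modeled"], "region_id"].to_numpy()

    @property
    def target_region_ids(self) -> np.ndarray:
        """All connectivity targets, in the canonical column order."""
        return self.region_meta["region_id"].to_numpy()

    @property
    def vertex_bearing_region_ids(self) -> np.ndarray:
        present = np.unique(self.vertex_region)
        return np.array(
            [r for r in self.target_region_ids if r in set(present)], dtype=np.int64
        )

    def vertices_of(self, region_id: int) -> np.ndarray:
        return np.flatnonzero(self.vertex_region == region_id)

    def homolog_pairs(self) -> list[tuple[int, int]]:
        """(left, right) homologous modeled region pairs."""
        m = self.region_meta
        pairs = []
        for _, row in m[m["modeled"] & (m["hemisphere"] == "L")].iterrows():
            if row["homolog_id"] >= 0:
                pairs.append((int(row["region_id"]), int(row["homolog_id"])))
        return pairs

    # ---- TSV round trip -------------------------------------------------

    def to_tsv(self, vertex_path: str | Path, meta_path: str | Path) -> None:
        pd.DataFrame(
            {"vertex_id": np.arange(self.n_vertices), "region_id": self.vertex_region}
        ).to_csv(vertex_path, sep="\t", index=False)
        self.region_meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, vertex_path: str | Path, meta_path: str | Path) -> "Parcellation":
        vtab = pd.read_csv(vertex_path, sep="\t").sort_values("vertex_id")
        meta = pd.read_csv(meta_path, sep="\t")
        meta["modeled"] = meta["modeled"].astype(bool)
        return cls(vtab["region_id"].to_numpy(), meta[META_COLUMNS])


def make_parcellation(config: SyntheticConfig) -> Parcellation:
    """Partition vertices into mirrored modeled regions plus extra targets.

    Vertices are split near-equally (or with multiplicative size dispersion)
    across the ``2 × n_regions_per_hemisphere`` modeled regions. Left region
    ``i`` is paired with right region ``n_regions_per_hemisphere + i``; each
    homologous pair shares a lobe, assigned round-robin from the six lobes.
    Extra targets carry no vertices and are flagged unmodeled.
    """
    n_modeled = config.n_modeled_regions
    if config.n_vertices < 4 * n_modeled:
        raise ConfigError(
            f"n_vertices={config.n_vertices} too small: need >= 4 vertices per "
            f"modeled region ({4 * n_modeled} total)"
        )

    # region sizes: proportional shares, largest-remainder rounding
    rng = substream(config.seed, STREAM_PARCELLATION)
    if config.region_size_dispersion > 0:
        weights = np.exp(config.region_size_dispersion * rng.standard_normal(n_modeled))
    else:
        weights = np.ones(n_modeled)
    shares = weights / weights.sum() * config.n_vertices
    sizes = np.floor(shares).astype(int)
    remainder = config.n_vertices - sizes.sum()
    order = np.argsort(-(shares - sizes))
    sizes[order[:remainder]] += 1
    if sizes.min() < 1:
        sizes = np.maximum(sizes, 1)
        while sizes.sum() > config.n_vertices:
            sizes[np.argmax(sizes)] -= 1

    vertex_region = np.repeat(np.arange(n_modeled), sizes)

    nrh = config.n_regions_per_hemisphere
    rows = []
    for i in range(n_modeled):
        left = i < nrh
        pair_index = i if left else i - nrh
        rows.append(
            {
                "region_id": i,
                "hemisphere": "L" if left else "R",
                "lobe": LOBES[pair_index % len(LOBES)],
                "homolog_id": i + nrh if left else i - nrh,
                "modeled": True,
            }
        )
    for j in range(config.n_extra_targets):
        rows.append(
            {
                "region_id": n_modeled + j,
                "hemisphere": "midline",
                "lobe": "subcortical",
                "homolog_id": -1,
                "modeled": False,
            }
        )
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return Parcellation(vertex_region, meta)


def make_domain_table(config: SyntheticConfig) -> pd.DataFrame:
    """Domain→category label table (round-robin category assignment)."""
    cats = [f"category_{c}" for c in range(config.n_categories)]
    from .config import CATEGORIES

    if config.n_categories == len(CATEGORIES):
        cats = list(CATEGORIES)
    return pd.DataFrame(
        {
            "domain_id": np.arange(config.n_domains),
            "domain": [f"domain_{d:02d}" for d in range(config.n_domains)],
            "category": [cats[d % config.n_categories] for d in range(config.n_domains)],
        }
    )
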