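"""Group-level inference over the table of model fits.

The observational unit is one (region, domain) model fit. Fits are
arcsine-square-root transformed before parametric tests, compared across
cognitive-domain categories with a one-way ANOVA (effect size η²) and
Holm-corrected pairwise t tests (Cohen's d), and compared across hemispheres
with paired t tests over homologous region pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from ._seeds import STREAM_BOOTSTRAP, substream
from .exceptions import DataError
from .parcellation import Parcellation

FIT_TABLE_COLUMNS = [
    "region_id",
    "domain_id",
    "category",
    "lobe",
    "hemisphere",
    "r2",
    "r2_transformed",
    "p_perm",
    "q99",
]


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    eta_squared: float


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    t_stat: float
    df: float
    p_raw: float
    p_holm: float
    cohen_d: float
    test_kind: str  # "independent" or "paired"
    cohen_d_av: float | None = None


def arcsine_sqrt(values: np.ndarray) -> np.ndarray:
    """Variance-stabilizing asin(√x) transform of R² values in [0, 1]."""
    x = np.asarray(values, dtype=np.float64)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise DataError("arcsine-sqrt transform requires values in [0, 1]")
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def build_fit_table(
    fits: Sequence,
    perms: Sequence,
    parcellation: Parcellation,
    domain_table: pd.DataFrame,
) -> pd.DataFrame:
    """Join fit results, permutation summaries and labels into one table."""
    meta = parcellation.region_meta.set_index("region_id")
    cat = domain_table.set_index("domain_id")["category"]
    perm_by_key = {(p.region_id, p.domain_id): p for p in perms} if perms else {}
    rows = []
    for f in fits:
        p = perm_by_key.get((f.region_id, f.domain_id))
        rows.append(
            {
                "region_id": f.region_id,
                "domain_id": f.domain_id,
                "category": cat.loc[f.domain_id],
                "lobe": meta.loc[f.region_id, "lobe"],
                "hemisphere": meta.loc[f.region_id, "hemisphere"],
                "r2": f.r_squared,
                "r2_transformed": float(arcsine_sqrt(np.array([f.r_squared]))[0]),
                "p_perm": p.p_value if p else np.nan,
                "q99": p.q99 if p else np.nan,
                "lambda": f.lambda_selected,
                "n_vertices": f.n_vertices,
            }
        )
    return pd.DataFrame(rows)


def median_by(
    fit_table: pd.DataFrame,
    grouping: str,
    value: str = "r2",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group medians of model fit with bootstrap SE and IQR.

    ``grouping`` is one of ``domain`` (``domain_id``), ``category``, ``lobe``.
    The SE is the standard deviation of the median over ``n_boot`` seeded
    bootstrap resamples within each group.
    """
    keys = {"domain": "domain_id", "category": "category", "lobe": "lobe"}
    if grouping not in keys and grouping not in fit_table.columns:
        raise DataError(f"unknown grouping {grouping!r}; expected one of {list(keys)}")
    col = keys.get(grouping, grouping)
    rows = []
    for gi, (name, grp) in enumerate(fit_table.groupby(col, sort=True)):
        vals = grp[value].to_numpy()
        rng = substream(seed, STREAM_BOOTSTRAP, gi)
        boots = np.median(
            vals[rng.integers(0, vals.size, size=(n_boot, vals.size))], axis=1
        )
        q1, q3 = np.percentile(vals, [25, 75])
        rows.append(
            {
                col: name,
                "n": vals.size,
                "median": float(np.median(vals)),
                "se_boot": float(np.std(boots, ddof=1)) if n_boot > 1 else 0.0,
                "iqr": float(q3 - q1),
            }
        )
    return pd.DataFrame(rows)


def one_way_anova(values: np.ndarray, labels: Sequence) -> AnovaResult:
    """Classical one-way ANOVA with η² = SS_between / SS_total.

    Observations are transformed fits; ``labels`` are the category of each.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise DataError("one-way ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise DataError("every group needs at least 2 observations")
    grand = values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_between = len(groups) - 1
    df_within = values.size - len(groups)
    if ss_within == 0:
        raise DataError("zero within-group variance: F undefined")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(scipy.stats.f.sf(f_stat, df_between, df_within))
    eta2 = ss_between / (ss_between + ss_within)
    return AnovaResult(float(f_stat), df_between, df_within, p, float(eta2))


def eta_squared_from_f(f_stat: float, df_between: int, df_within: int) -> float:
    """η² recovered from an F statistic: df₁F / (df₁F + df₂)."""
    num = df_between * f_stat
    return num / (num + df_within)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment.

    Sort ascending, multiply the i-th smallest by (m − i), enforce a running
    maximum, cap at 1, and restore the input order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _cohen_d_independent(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def pairwise_t_tests(
    values: np.ndarray,
    labels: Sequence,
    welch: bool = False,
) -> list[ContrastResult]:
    """All-pairs two-tailed t tests with Holm correction and Cohen's d.

    Pooled-variance Student t by default; Welch with ``welch=True``. The Holm
    family is the full set of C(k, 2) pairs.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise DataError("need at least 2 groups for pairwise tests")
    data = {g: values[labels == g] for g in names}
    for g, v in data.items():
        if v.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
    results = []
    for a_name, b_name in combinations(sorted(map(str, names)), 2):
        a, b = data[a_name], data[b_name]
        if welch:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
            df = _welch_df(a, b)
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
            df = a.size + b.size - 2
        results.append(
            ContrastResult(
                pair=(a_name, b_name),
                t_stat=float(t),
                df=float(df),
                p_raw=float(p),
                p_holm=np.nan,
                cohen_d=_cohen_d_independent(a, b),
                test_kind="independent",
            )
        )
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_holm = float(pa)
    return results


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))


def laterality_tests(
    fit_table: pd.DataFrame,
    domains: Sequence[int],
    parcellation: Parcellation,
    value: str = "r2_transformed",
) -> list[ContrastResult]:
    """Paired left-vs-right tests of model fit over homologous region pairs.

    For each requested domain, left-hemisphere fits are paired with their
    right homologs and compared with a two-tailed paired t test; p-values are
    Holm-corrected over the requested family. Effect sizes: d_z =
    mean(diff)/sd(diff) (primary) and d_av (mean diff over the average of the
    two SDs).

    All-zero differences yield t = 0, p = 1; a constant nonzero difference
    has zero variance and raises.
    """
    pairs = parcellation.homolog_pairs()
    if len(pairs) < 2:
        raise DataError("need at least 2 homologous pairs for a paired test")
    by_key = fit_table.set_index(["region_id", "domain_id"])[value]
    results = []
    for d in domains:
        try:
            lh = np.array([by_key.loc[(l, d)] for l, _ in pairs])
            rh = np.array([by_key.loc[(r, d)] for _, r in pairs])
        except KeyError as e:
            raise DataError(f"domain {d}: missing fit for region pair ({e})") from e
        diff = lh - rh
        sd = diff.std(ddof=1)
        n = diff.size
        if sd == 0:
            if np.all(diff == 0):
                t, p, dz = 0.0, 1.0, 0.0
            else:
                raise DataError(
                    f"domain {d}: zero-variance nonzero difference; paired t undefined"
                )
        else:
            t = diff.mean() / (sd / np.sqrt(n))
            p = float(2 * scipy.stats.t.sf(abs(t), n - 1))
            dz = diff.mean() / sd
        sd_av = (lh.std(ddof=1) + rh.std(ddof=1)) / 2
        d_av = float(diff.mean() / sd_av) if sd_av > 0 else 0.0
        results.append(
            ContrastResult(
                pair=("L", "R"),
                t_stat=float(t),
                df=float(n - 1),
                p_raw=float(p),
                p_holm=np.nan,
                cohen_d=float(dz),
                test_kind="paired",
                cohen_d_av=d_av,
            )
        )
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa, d in zip(results, adj, domains):
        r.p_holm = float(pa)
        r.pair = (f"L_domain_{d}", f"R_domain_{d}")
    return results


def run_group_stats(
    fit_table: pd.DataFrame,
    parcellation: Parcellation,
    laterality_domains: Sequence[int] | None = None,
    seed: int = 0,
    welch: bool = False,
) -> dict:
    """Medians, ANOVA, pairwise contrasts and laterality tests in one bundle."""
    out: dict = {}
    out["median_by_domain"] = median_by(fit_table, "domain", seed=seed)
    out["median_by_category"] = median_by(fit_table, "category", seed=seed)
    out["median_by_lobe"] = median_by(fit_table, "lobe", seed=seed)
    tvals = fit_table["r2_transformed"].to_numpy()
    cats = fit_table["category"].to_numpy()
    if len(pd.unique(cats)) >= 2:
        out["anova"] = one_way_anova(tvals, cats)
        out["pairwise"] = pairwise_t_tests(tvals, cats, welch=welch)
    if laterality_domains:
        out["laterality"] = laterality_tests(
            fit_table, laterality_domains, parcellation
        )
    return out
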