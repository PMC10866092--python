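"""From raw FOS counts to outlier-filtered percent-change matrices and bootstraps.

Pipeline order: per-section counts are averaged into per-animal regional
densities; each group x region value set is screened with a robust
FDR-controlled outlier rule; densities are expressed as percent change
over the saline baseline of the matching genotype x sex stratum; and
group matrices are resampled into bootstrap replicate mean vectors that
serve as brain states downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

GROUP_COLS = ["genotype", "sex", "treatment"]


def compute_densities(raw: pd.DataFrame) -> pd.DataFrame:
    """Average per-section densities into one value per animal and region.

    Expects tidy rows with ``animal_id, genotype, sex, treatment, region``
    plus either a precomputed ``density_cells_per_mm2`` column (returned
    unchanged) or ``count`` and ``area_mm2`` section columns.  Sections
    flagged in an optional boolean ``damaged`` column are excluded before
    averaging; an animal-region with no usable section yields a missing
    density rather than an error.
    """
    if "density_cells_per_mm2" in raw.columns:
        return raw.copy()
    required = {"animal_id", "region", "count", "area_mm2"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (raw["count"] < 0).any():
        raise ValueError("section counts must be >= 0")
    if (raw["area_mm2"] <= 0).any():
        raise ValueError("section areas must be positive")

    work = raw.copy()
    if "damaged" in work.columns:
        usable = work[~work["damaged"].astype(bool)]
    else:
        usable = work
    usable = usable.assign(_density=usable["count"] / usable["area_mm2"])

    keys = ["animal_id"] + [c for c in GROUP_COLS if c in raw.columns] + ["region"]
    # keep every animal-region present in the raw table, even if all its
    # sections were damaged (then density is NaN)
    grid = raw[keys].drop_duplicates()
    dens = usable.groupby(keys, sort=False)["_density"].mean().rename("density_cells_per_mm2")
    out = grid.merge(dens, on=keys, how="left")
    return out.reset_index(drop=True)


def rout_filter(values, q: float = 0.05):
    """Robust outlier screen on one group's values for one region.

    A one-sample analogue of the ROUT procedure: the robust center is the
    median, the robust scale is 1.4826 x MAD, each point gets a t-like
    statistic ``|x - median| / scale`` with a two-sided p-value from a
    t distribution on n-1 degrees of freedom, and Benjamini-Hochberg at
    rate ``q`` marks the outliers.

    Returns ``(retained, outlier_indices)`` as numpy arrays; with fewer
    than 3 values the input is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("rout_filter needs at least one value")
    if x.size < 3:
        return x.copy(), np.array([], dtype=int)
    med = np.median(x)
    resid = np.abs(x - med)
    scale = 1.4826 * np.median(resid)
    if scale == 0:
        # more than half the points coincide; anything off that value is
        # infinitely many robust SDs away
        outliers = np.flatnonzero(resid > 0)
    else:
        t = resid / scale
        p = 2.0 * stats.t.sf(t, df=x.size - 1)
        outliers = np.flatnonzero(_bh_reject(p, q))
    keep = np.setdiff1d(np.arange(x.size), outliers)
    return x[keep], outliers


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    n = p.size
    order = np.argsort(p)
    thresh = q * (np.arange(1, n + 1) / n)
    below = p[order] <= thresh
    reject = np.zeros(n, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        reject[order[: k + 1]] = True
    return reject


def apply_rout(table: pd.DataFrame, q: float = 0.05):
    """Run :func:`rout_filter` within every group x region cell of a tidy table.

    Returns the filtered table and a tidy log of removed rows.
    """
    keep_mask = np.ones(len(table), dtype=bool)
    removed = []
    for keys, sub in table.groupby(GROUP_COLS + ["region"], sort=False):
        vals = sub["density_cells_per_mm2"].to_numpy()
        finite = np.isfinite(vals)
        if finite.sum() < 3:
            continue
        _, out_idx = rout_filter(vals[finite], q=q)
        if out_idx.size:
            rows = sub.index[np.flatnonzero(finite)[out_idx]]
            keep_mask[table.index.get_indexer(rows)] = False
            for r in rows:
                removed.append(table.loc[r])
    removed_df = pd.DataFrame(removed, columns=table.columns) if removed else table.iloc[0:0]
    return table[keep_mask].reset_index(drop=True), removed_df.reset_index(drop=True)


@dataclass
class PercentChangeMatrix:
    """Per-group animal x region matrices of percent change over saline baseline.

    ``groups`` maps ``(genotype, sex, treatment)`` to a DataFrame indexed
    by animal with one column per region; ``baseline`` holds the saline
    mean density per stratum and region; ``unusable`` lists
    (stratum, region) pairs whose baseline was missing or nonpositive.
    """

    groups: Mapping[tuple[str, str, str], pd.DataFrame]
    baseline: pd.DataFrame
    unusable: list = field(default_factory=list)

    def group(self, genotype: str, sex: str, treatment: str) -> pd.DataFrame:
        return self.groups[(genotype, sex, treatment)]


def percent_change(
    table: pd.DataFrame,
    pooled_baseline: bool = False,
    include_saline: bool = True,
) -> PercentChangeMatrix:
    """Express densities as percent change over the saline baseline mean.

    The baseline is the mean saline density per region within the same
    genotype x sex stratum (``pooled_baseline=True`` pools all saline
    animals instead).  Entries are ``100 * (x - baseline) / baseline``;
    saline animals are included by default (their group mean is ~0 by
    construction).  Regions with a missing or nonpositive baseline are
    flagged unusable and their entries set missing.
    """
    dens = table.pivot_table(
        index=["genotype", "sex", "treatment", "animal_id"],
        columns="region",
        values="density_cells_per_mm2",
        aggfunc="mean",
    )
    saline = table[table["treatment"] == "saline"]
    if saline.empty:
        raise ValueError("no saline animals to form a baseline")
    if pooled_baseline:
        base = saline.groupby("region")["density_cells_per_mm2"].mean()
        baseline = pd.DataFrame({"pooled": base}).T
    else:
        baseline = saline.pivot_table(
            index=["genotype", "sex"],
            columns="region",
            values="density_cells_per_mm2",
            aggfunc="mean",
        )

    groups: dict[tuple[str, str, str], pd.DataFrame] = {}
    unusable: list[tuple] = []
    for (g, s, t), sub in dens.groupby(level=["genotype", "sex", "treatment"], sort=False):
        if t == "saline" and not include_saline:
            continue
        mat = sub.droplevel(["genotype", "sex", "treatment"])
        if pooled_baseline:
            b = baseline.loc["pooled"]
        else:
            if (g, s) not in baseline.index:
                raise ValueError(f"stratum {(g, s)} has no saline animals")
            b = baseline.loc[(g, s)]
        b = b.reindex(mat.columns)
        bad = b.isna() | (b <= 0)
        for r in mat.columns[bad]:
            unusable.append(((g, s), r))
        b = b.where(~bad)
        groups[(g, s, t)] = 100.0 * (mat - b) / b
    return PercentChangeMatrix(groups=groups, baseline=baseline, unusable=unusable)


@dataclass
class BootstrapSet:
    """Bootstrap replicate mean-vectors for one group.

    ``replicates`` has shape (n_boot, n_regions); each row is the
    region-wise mean of a with-replacement resample of animals.
    """

    replicates: np.ndarray
    regions: tuple[str, ...]
    resample_size: int
    seed: int

    @property
    def n_boot(self) -> int:
        return self.replicates.shape[0]


def bootstrap_means(
    matrix: pd.DataFrame,
    n_boot: int,
    resample_size: int | None = None,
    seed: int = 0,
    identity: bool = False,
) -> BootstrapSet:
    """Bootstrap the group mean state vector.

    ``matrix`` is animals x regions.  Each replicate draws
    ``resample_size`` animals with replacement (default: the original n)
    and records the region-wise mean (NaN-aware).  ``identity=True`` is a
    test hook that replaces every resample with the identity sample.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least 2 animals to bootstrap")
    if resample_size is None:
        resample_size = n
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        full_mean = np.nanmean(X, axis=0)
    reps = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        if identity:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, size=resample_size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(X[idx], axis=0)
        # a resample can miss every observation of a region; fall back to
        # the full-sample mean there so state vectors stay finite
        reps[b] = np.where(np.isnan(m), full_mean, m)
    return BootstrapSet(
        replicates=reps,
        regions=tuple(matrix.columns),
        resample_size=resample_size,
        seed=seed,
    )
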