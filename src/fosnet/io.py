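"""CSV readers and writers for FOS tables, connectomes, and receptor maps.

All tables are tidy UTF-8 CSV with '.' decimal; matrices are headered
CSV with region labels as both index and columns.  Readers validate
labels and invariants and raise :class:`ParseError` with the offending
line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .regions import RegionSet
from .synthio import RECEPTORS, Connectome, ReceptorMap

FOS_COLUMNS = ["animal_id", "genotype", "sex", "treatment", "region", "density_cells_per_mm2"]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line."""


def write_fos_csv(table: pd.DataFrame, path) -> None:
    table[FOS_COLUMNS].to_csv(path, index=False)


def read_fos_csv(path, regions: RegionSet | None = None) -> pd.DataFrame:
    """Read a tidy FOS density table, validating labels and uniqueness."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(FOS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dens = pd.to_numeric(df["density_cells_per_mm2"], errors="coerce")
    bad = df["density_cells_per_mm2"].notna() & dens.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ParseError(f"{path}:{line}: non-numeric density {df['density_cells_per_mm2'][bad].iloc[0]!r}")
    if (dens < 0).any():
        line = int(df.index[dens < 0][0]) + 2
        raise ParseError(f"{path}:{line}: negative density")
    df["density_cells_per_mm2"] = dens
    if regions is not None:
        unknown = ~df["region"].isin(regions.labels)
        if unknown.any():
            line = int(df.index[unknown][0]) + 2
            raise ParseError(f"{path}:{line}: unknown region {df['region'][unknown].iloc[0]!r}")
    dup = df.duplicated(subset=["animal_id", "region"], keep=False)
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}:{line}: duplicated animal-region row")
    return df


def write_matrix_csv(matrix: np.ndarray | pd.DataFrame, labels, path) -> None:
    if isinstance(matrix, pd.DataFrame):
        matrix.to_csv(path)
    else:
        pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path)


def write_connectome_csv(conn: Connectome, path) -> None:
    write_matrix_csv(conn.A, conn.regions.labels, path)


def read_connectome_csv(path, regions: RegionSet | None = None) -> Connectome:
    """Read a headered square weight matrix into a Connectome."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column labels differ")
    A = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(A)):
        raise ParseError(f"{path}: non-numeric or missing weights")
    if np.any(A < 0):
        i, j = np.argwhere(A < 0)[0]
        raise ParseError(f"{path}: negative weight at ({df.index[i]}, {df.columns[j]})")
    if regions is not None:
        labels = list(df.index)
        unknown = set(labels) - set(regions.labels)
        if unknown:
            raise ParseError(f"{path}: unknown regions {sorted(unknown)}")
        rset = regions.subset(keep=labels)
    else:
        rset = RegionSet(list(df.index))
    return Connectome(regions=rset, A=A)


def write_receptor_csv(rmap: ReceptorMap, path) -> None:
    pd.DataFrame(
        {rec: rmap.density[rec] for rec in RECEPTORS}, index=list(rmap.regions.labels)
    ).to_csv(path)


def read_receptor_csv(path, regions: RegionSet | None = None) -> ReceptorMap:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    missing = set(RECEPTORS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing receptor columns {sorted(missing)}")
    if regions is not None:
        unknown = set(df.index) - set(regions.labels)
        if unknown:
            raise ParseError(f"{path}: unknown regions {sorted(unknown)}")
        rset = regions.subset(keep=list(df.index))
    else:
        rset = RegionSet(list(df.index))
    density = {rec: df[rec].to_numpy(dtype=float) for rec in RECEPTORS}
    return ReceptorMap(regions=rset, density=density)
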