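"""Synthetic FOS datasets, structural connectomes, and receptor maps.

The generators emulate the statistical structure the downstream pipeline
assumes about the real study data:

* per-animal regional FOS densities are strictly positive, treatment-
  elevated, and share a per-meso-structure latent factor so that regions
  within an anatomical group co-fluctuate (modular covariance);
* the structural connectome is a nonnegative, zero-diagonal, directed
  weight matrix with log-normal weights;
* receptor maps are nonnegative per-region expression vectors for the
  mu-, delta-, and kappa-opioid receptors.

The FOS model is multiplicative log-normal:

    density[a, i] = baseline[i] * effect[g(a), i]
                    * exp(s_g * f[m(i), a] + eps[a, i])

with one standard-normal factor ``f`` per (animal, meso-structure),
residual ``eps ~ N(0, noise_sd^2)``, and group loading ``s_g``.  Because
the analysis only consumes percent changes and correlations, this is the
simplest generative model giving controllable modular covariance while
guaranteeing positivity.  Occasional outliers are injected
multiplicatively (a factor drawn from U[5, 10]) so robust outlier
filtering has a well-defined target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .regions import RegionSet, default_region_set

GENOTYPES = ("AA", "GG")
SEXES = ("M", "F")
TREATMENTS = ("saline", "acute", "chronic")

#: default chronic-treatment fold change per (genotype, sex); acute is a
#: uniform strong induction, chronic is group-dependent with the GG-female
#: group displaced furthest from the acute state.
DEFAULT_CHRONIC_EFFECT = {
    ("AA", "M"): 2.0,
    ("GG", "M"): 1.8,
    ("AA", "F"): 2.2,
    ("GG", "F"): 3.5,
}
DEFAULT_ACUTE_EFFECT = 3.0


def _as_group_map(value, default: float | None = None) -> dict[tuple[str, str], float]:
    """Normalize a scalar or (genotype, sex)-keyed mapping to a full map."""
    groups = [(g, s) for g in GENOTYPES for s in SEXES]
    if value is None:
        value = default
    if np.isscalar(value):
        return {gs: float(value) for gs in groups}
    out = {}
    for gs in groups:
        out[gs] = float(value[gs])
    return out


@dataclass
class SynthParams:
    """Parameters of the synthetic FOS generative model.

    Attributes
    ----------
    n_per_group : int
        Animals per genotype x sex x treatment cell (>= 3).
    baseline_mean : mapping region -> float, optional
        Saline-state density in cells/mm^2; by default drawn once,
        uniformly in [50, 400], from the generator seed and then fixed.
    treatment_effect : nested mapping, optional
        ``(genotype, sex) -> {treatment: fold}`` multiplicative fold
        change over baseline; a plain ``{treatment: fold}`` mapping is
        broadcast to every group.  Default: saline 1.0, acute 3.0,
        chronic group-dependent (see :data:`DEFAULT_CHRONIC_EFFECT`).
    module_strength : float or mapping (genotype, sex) -> float
        Loading of the shared per-meso-structure latent factor.
    noise_sd : float
        Log-scale residual standard deviation.
    outlier_prob : float
        Per-value probability of multiplicative outlier injection.
    seed : int
        RNG seed; identical parameters and seed give identical tables.
    """

    n_per_group: int = 7
    baseline_mean: Mapping[str, float] | None = None
    treatment_effect: Mapping | None = None
    module_strength: float | Mapping[tuple[str, str], float] = 1.0
    noise_sd: float = 0.5
    outlier_prob: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.outlier_prob < 1):
            raise ValueError("outlier_prob must lie in [0, 1)")
        strengths = _as_group_map(self.module_strength)
        if any(s < 0 for s in strengths.values()):
            raise ValueError("module_strength must be >= 0")

    def effect(self, genotype: str, sex: str, treatment: str) -> float:
        """Fold change over baseline for one group and treatment."""
        if treatment == "saline":
            default = 1.0
        elif treatment == "acute":
            default = DEFAULT_ACUTE_EFFECT
        else:
            default = DEFAULT_CHRONIC_EFFECT[(genotype, sex)]
        te = self.treatment_effect
        if te is None:
            return default
        if (genotype, sex) in te:
            te = te[(genotype, sex)]
        return float(te.get(treatment, default))


def generate_fos_dataset(regions: RegionSet | None = None, params: SynthParams | None = None) -> pd.DataFrame:
    """Generate a tidy per-animal, per-region FOS density table.

    Returns a DataFrame with columns ``animal_id, genotype, sex,
    treatment, region, density_cells_per_mm2`` covering every
    genotype x sex x treatment cell with ``params.n_per_group`` animals.
    """
    if regions is None:
        regions = default_region_set()
    if params is None:
        params = SynthParams()
    rng = np.random.default_rng(params.seed)

    labels = list(regions.labels)
    structures = list(regions.structures)
    struct_idx = np.array([structures.index(regions.structure_of[r]) for r in labels])

    if params.baseline_mean is None:
        baseline = rng.uniform(50.0, 400.0, size=len(labels))
    else:
        baseline = np.array([float(params.baseline_mean[r]) for r in labels])
    if np.any(baseline <= 0):
        raise ValueError("baseline densities must be positive")

    strengths = _as_group_map(params.module_strength)

    rows = []
    animal_counter = 0
    for genotype in GENOTYPES:
        for sex in SEXES:
            s_g = strengths[(genotype, sex)]
            for treatment in TREATMENTS:
                effect = params.effect(genotype, sex, treatment)
                for _ in range(params.n_per_group):
                    animal_counter += 1
                    animal = f"m{animal_counter:03d}"
                    factors = rng.standard_normal(len(structures))
                    eps = rng.normal(0.0, params.noise_sd, size=len(labels))
                    dens = baseline * effect * np.exp(s_g * factors[struct_idx] + eps)
                    if params.outlier_prob > 0:
                        hit = rng.random(len(labels)) < params.outlier_prob
                        dens = np.where(hit, dens * rng.uniform(5.0, 10.0, size=len(labels)), dens)
                    for r, d in zip(labels, dens):
                        rows.append((animal, genotype, sex, treatment, r, d))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "genotype", "sex", "treatment", "region", "density_cells_per_mm2"],
    )


@dataclass
class Connectome:
    """Directed, nonnegative structural connectivity matrix.

    ``A[i, j]`` is the projection strength from region ``j`` to region
    ``i`` (rows are targets); the diagonal is zero.
    """

    regions: RegionSet
    A: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        n = len(self.regions)
        if A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}, got {A.shape}")
        if n < 2:
            raise ValueError("connectome needs at least 2 regions")
        if np.any(A < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise ValueError("connectome diagonal must be zero")
        self.A = A

    @property
    def strongly_connected(self) -> bool:
        n_comp, _ = connected_components(self.A > 0, directed=True, connection="strong")
        return n_comp == 1


def generate_connectome(
    regions: RegionSet,
    density: float = 0.3,
    weight_scale: float = 1.0,
    seed: int = 0,
) -> Connectome:
    """Random hub-free directed connectome with log-normal weights.

    Each off-diagonal entry is nonzero independently with probability
    ``density``; nonzero weights are ``weight_scale * LogNormal(0, 1)``.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    n = len(regions)
    if n < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < density
    weights = weight_scale * rng.lognormal(mean=0.0, sigma=1.0, size=(n, n))
    A = np.where(mask, weights, 0.0)
    np.fill_diagonal(A, 0.0)
    return Connectome(regions=regions, A=A)


RECEPTORS = ("mu", "delta", "kappa")


@dataclass
class ReceptorMap:
    """Nonnegative per-region expression densities for the three opioid receptors."""

    regions: RegionSet
    density: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.regions)
        clean = {}
        for rec in RECEPTORS:
            if rec not in self.density:
                raise ValueError(f"missing receptor {rec!r}")
            v = np.asarray(self.density[rec], dtype=float)
            if v.shape != (n,):
                raise ValueError(f"receptor {rec!r} vector must have length {n}")
            if np.any(v < 0):
                raise ValueError(f"receptor {rec!r} densities must be >= 0")
            if not np.any(v > 0):
                raise ValueError(f"receptor {rec!r} must have a positive entry")
            clean[rec] = v
        self.density = clean


def generate_receptor_map(
    regions: RegionSet,
    seed: int = 0,
    uniform: bool = False,
    mu_enriched_regions: Sequence[str] | None = None,
    enrichment: float = 3.0,
) -> ReceptorMap:
    """Random receptor expression maps.

    With ``uniform=True`` every receptor vector is constant (degenerate
    mode for tests).  ``mu_enriched_regions`` multiplies the mu-receptor
    density of the named regions by ``enrichment``, producing a mu map
    correlated with a designated high-influence subset.
    """
    rng = np.random.default_rng(seed)
    n = len(regions)
    if uniform:
        density = {rec: np.full(n, 1.0) for rec in RECEPTORS}
        return ReceptorMap(regions=regions, density=density)
    density = {rec: rng.lognormal(mean=0.0, sigma=0.5, size=n) for rec in RECEPTORS}
    if mu_enriched_regions:
        idx = [regions.index(r) for r in mu_enriched_regions]
        density["mu"] = density["mu"].copy()
        density["mu"][idx] *= enrichment
    return ReceptorMap(regions=regions, density=density)
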