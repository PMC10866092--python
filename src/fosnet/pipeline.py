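"""End-to-end pipeline: simulate -> preprocess -> network -> metrics ->
control -> report, with a manifest for reproducibility.

A single global seed spawns independent per-stage substreams so any
stage can be rerun in isolation with identical results.  All tables are
tidy CSV, graphs GraphML, summaries JSON; the manifest records the
configuration, stage seeds, and a SHA-256 per artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control, graphmetrics, io, netbuild, preprocess, synthio
from .regions import DEFAULT_EXCLUDED_REGION, default_region_set
from .stats_report import factorial_anova, sigma_energy_correlation
from .synthio import GENOTYPES, RECEPTORS, SEXES, SynthParams

#: the six high-influence regions (five cortical, one thalamic) whose
#: joint suppression is compared against random subsets
TARGET_REGIONS = ("ACAd", "ACAv", "CLA", "ILA", "PL", "PVT")

_STAGES = ("simulate", "preprocess", "network", "metrics", "control", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Full-run configuration; ``seed`` is mandatory.

    ``synth`` holds :class:`~fosnet.synthio.SynthParams` overrides;
    ``control_spec`` holds :class:`~fosnet.control.ControlSpec` overrides.
    Bootstrap sizes: ``n_boot_sigma`` networks per group for the sigma
    distribution, ``n_states`` resampled brain states per condition for
    pairwise transition energies, ``n_sigma_energy`` paired replicates
    per group for the sigma-change vs energy regression.
    """

    seed: int
    synth: dict = field(default_factory=dict)
    rout_q: float = 0.05
    pooled_baseline: bool = False
    edge_threshold: float = 0.0
    n_random: int = 100
    n_boot_sigma: int = 20
    n_states: int = 200
    n_sigma_energy: int = 8
    connectome_density: float = 0.3
    connectome_weight_scale: float = 1.0
    excluded_region: str = DEFAULT_EXCLUDED_REGION
    control_spec: dict = field(default_factory=dict)
    target_regions: tuple = TARGET_REGIONS
    n_random_sets: int = 100
    posthoc: str = "tukey"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        # validate eagerly so bad configs fail before any computation
        SynthParams(**{**self.synth, "seed": 0})
        control.ControlSpec(**self.control_spec)
        if self.n_boot_sigma < 1 or self.n_states < 1 or self.n_sigma_energy < 2:
            raise ValueError("bootstrap sizes must be positive (n_sigma_energy >= 2)")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Independent 31-bit substream seed for one stage."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGES.index(stage),))
        return int(ss.generate_state(1)[0] % (2**31))


def _group_key(g: str, s: str, t: str) -> str:
    return f"{g}_{s}_{t}"


def _mean_state(df: pd.DataFrame, idx=None) -> np.ndarray:
    """Region-wise mean state; resamples missing a region fall back to the
    full-group mean so brain states stay finite."""
    import warnings as _w

    X = df.to_numpy(dtype=float)
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        full = np.nanmean(X, axis=0)
        if idx is None:
            return full
        m = np.nanmean(X[idx], axis=0)
    return np.where(np.isnan(m), full, m)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full analysis and write all artifacts under ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    Identical config and seed give identical artifact hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = default_region_set()
    conn_regions = regions.subset(drop=[config.excluded_region])
    artifacts: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, **kw):
        p = outdir / name
        df.to_csv(p, **kw)
        artifacts.append(p)

    def save_json(obj, name: str):
        p = outdir / name
        p.write_text(json.dumps(obj, indent=2, default=_jsonable))
        artifacts.append(p)

    # ---- simulate ------------------------------------------------------
    try:
        params = SynthParams(**{**config.synth, "seed": config.stage_seed("simulate")})
        fos = synthio.generate_fos_dataset(regions, params)
        conn = synthio.generate_connectome(
            conn_regions,
            density=config.connectome_density,
            weight_scale=config.connectome_weight_scale,
            seed=config.stage_seed("simulate") + 1,
        )
        rmap = synthio.generate_receptor_map(
            conn_regions,
            seed=config.stage_seed("simulate") + 2,
            mu_enriched_regions=[r for r in config.target_regions if r in conn_regions.labels],
        )
        io.write_fos_csv(fos, outdir / "fos_raw.csv")
        io.write_connectome_csv(conn, outdir / "connectome.csv")
        io.write_receptor_csv(rmap, outdir / "receptors.csv")
        artifacts += [outdir / "fos_raw.csv", outdir / "connectome.csv", outdir / "receptors.csv"]
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    # ---- preprocess ----------------------------------------------------
    try:
        filtered, removed = preprocess.apply_rout(fos, q=config.rout_q)
        pc = preprocess.percent_change(filtered, pooled_baseline=config.pooled_baseline)
        io.write_fos_csv(filtered, outdir / "fos_filtered.csv")
        artifacts.append(outdir / "fos_filtered.csv")
        save_csv(removed, "outliers_removed.csv", index=False)
        for (g, s, t), mat in pc.groups.items():
            save_csv(mat, f"percent_change_{_group_key(g, s, t)}.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e

    # ---- network -------------------------------------------------------
    net_groups = [(g, s, t) for g in GENOTYPES for s in SEXES for t in ("acute", "chronic")]
    try:
        nets = {}
        for g, s, t in net_groups:
            mat = pc.group(g, s, t)
            net = netbuild.group_network(mat, group=_group_key(g, s, t), edge_threshold=config.edge_threshold)
            nets[(g, s, t)] = net
            save_csv(net.R, f"correlation_{_group_key(g, s, t)}.csv")
            netbuild.write_graphml(net, outdir / f"network_{_group_key(g, s, t)}.graphml")
            artifacts.append(outdir / f"network_{_group_key(g, s, t)}.graphml")
    except Exception as e:  # noqa: BLE001
        raise StageError("network", e) from e

    # ---- metrics -------------------------------------------------------
    try:
        mseed = config.stage_seed("metrics")
        global_summary = {}
        nodal_frames, meso_frames, sig_rows = [], [], []
        for i, (g, s, t) in enumerate(net_groups):
            key = _group_key(g, s, t)
            G = netbuild.binarized(nets[(g, s, t)])
            sig = graphmetrics.small_world_sigma(G, n_random=config.n_random, seed=mseed + i)
            Lw, _, n_unreach = graphmetrics.average_shortest_path(nets[(g, s, t)].graph, weighted=True)
            global_summary[key] = {
                "sigma": sig.sigma,
                "C_avg": sig.C_avg,
                "L_avg": sig.L_avg,
                "C_rand": sig.C_rand,
                "L_rand": sig.L_rand,
                "L_avg_weighted": Lw,
                "unreachable_pairs": n_unreach,
                "n_edges": G.number_of_edges(),
            }
            nod = graphmetrics.nodal_metrics(G)
            nod.insert(0, "group", key)
            nodal_frames.append(nod)
            mes = graphmetrics.mesoscale_metrics(nets[(g, s, t)].graph, regions)
            mes.insert(0, "group", key)
            meso_frames.append(mes)
            boot_nets = netbuild.bootstrap_networks(
                pc.group(g, s, t), config.n_boot_sigma, seed=mseed + 100 + i, group=key
            )
            for b, bn in enumerate(boot_nets):
                bs = graphmetrics.small_world_sigma(
                    netbuild.binarized(bn), n_random=config.n_random, seed=mseed + 1000 + 50 * i + b
                )
                sig_rows.append({"group": key, "replicate": b, "sigma": bs.sigma})
        save_json(global_summary, "global_metrics.json")
        save_csv(pd.concat(nodal_frames).rename_axis("region"), "metrics_nodal.csv")
        save_csv(pd.concat(meso_frames).rename_axis("structure"), "metrics_meso.csv")
        save_csv(pd.DataFrame(sig_rows), "sigma_bootstrap.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("metrics", e) from e

    # ---- control -------------------------------------------------------
    try:
        cseed = config.stage_seed("control")
        spec = control.ControlSpec(**config.control_spec)
        Astar = control.normalize_system(conn, c=spec.c)
        sys = control.ControlSystem(Astar, spec)
        cols = list(conn_regions.labels)
        target_idx = [cols.index(r) for r in config.target_regions if r in cols]

        energy_summary = {}
        supp_rows = []
        mean_energy = {}
        for gi, (g, s) in enumerate([(g, s) for g in GENOTYPES for s in SEXES]):
            key = f"{g}_{s}"
            acute = pc.group(g, s, "acute")[cols]
            chronic = pc.group(g, s, "chronic")[cols]
            x0 = _mean_state(acute)
            xf = _mean_state(chronic)
            full = sys.energy(x0, xf)
            prof = control.suppression_profile(sys, spec, x0, xf)
            for r, p_inc in zip(cols, prof.percent_increase):
                supp_rows.append({"group": key, "region": r, "percent_increase": p_inc})
            setres = control.suppress_set(
                sys, spec, x0, xf, target_idx, n_random_sets=config.n_random_sets, seed=cseed + gi
            )
            receptor = {
                rec: control.receptor_weighted_energy(sys, rmap, x0, xf, rec).energy for rec in RECEPTORS
            }
            persist = {
                "acute": control.persistence_energy(sys, spec, x0).energy,
                "chronic": control.persistence_energy(sys, spec, xf).energy,
            }
            ab = preprocess.bootstrap_means(acute, config.n_states, seed=cseed + 10 + gi)
            cb = preprocess.bootstrap_means(chronic, config.n_states, seed=cseed + 20 + gi)
            E = sys.pairwise_energies(ab.replicates, cb.replicates)
            save_csv(pd.DataFrame(E), f"pairwise_energies_{key}.csv", index=False)
            mean_energy[key] = float(E.mean())
            energy_summary[key] = {
                "full_control_energy": full.energy,
                "gramian_cond": full.gramian_cond,
                "residual": full.residual,
                "pairwise_mean": float(E.mean()),
                "pairwise_median": float(np.median(E)),
                "target_set_percent_increase": setres.percent_increase,
                "target_set_t": setres.t_stat,
                "target_set_p": setres.p_value,
                "receptor_weighted": receptor,
                "persistence": persist,
            }
        save_json(energy_summary, "energy_summary.json")
        save_csv(pd.DataFrame(supp_rows), "suppression_profile.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("control", e) from e

    # ---- report --------------------------------------------------------
    try:
        rseed = config.stage_seed("report")
        tidy = []
        for (g, s, t), mat in pc.groups.items():
            melted = mat.reset_index().melt(id_vars="animal_id", var_name="region", value_name="value")
            melted["genotype"], melted["sex"], melted["treatment"] = g, s, t
            tidy.append(melted)
        tidy = pd.concat(tidy, ignore_index=True)
        tidy = tidy[tidy["treatment"] != "saline"]
        anova_rows = []
        for region, sub in tidy.groupby("region", sort=False):
            tab = factorial_anova(sub, dv="value", posthoc="none")
            for _, row in tab.effects.iterrows():
                anova_rows.append({"region": region, **row.to_dict()})
        save_csv(pd.DataFrame(anova_rows), "anova_regions.csv", index=False)

        # paired sigma-change vs transition-energy regression
        dsig, energ = [], []
        for gi, (g, s) in enumerate([(g, s) for g in GENOTYPES for s in SEXES]):
            acute = pc.group(g, s, "acute")[cols]
            chronic = pc.group(g, s, "chronic")[cols]
            rng = np.random.default_rng(rseed + gi)
            for b in range(config.n_sigma_energy):
                ia = rng.integers(0, len(acute), size=len(acute))
                ic = rng.integers(0, len(chronic), size=len(chronic))
                na = netbuild.group_network(acute.iloc[ia])
                nch = netbuild.group_network(chronic.iloc[ic])
                sa = graphmetrics.small_world_sigma(
                    netbuild.binarized(na), n_random=config.n_random, seed=rseed + 100 + 10 * gi + b
                )
                sc = graphmetrics.small_world_sigma(
                    netbuild.binarized(nch), n_random=config.n_random, seed=rseed + 500 + 10 * gi + b
                )
                dsig.append(sc.sigma - sa.sigma)
                x0 = _mean_state(acute, ia)
                xf = _mean_state(chronic, ic)
                energ.append(sys.energy(x0, xf).energy)
        reg = sigma_energy_correlation(np.array(dsig), np.array(energ))
        save_json(dataclasses.asdict(reg), "sigma_energy_regression.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("report", e) from e

    # ---- manifest ------------------------------------------------------
    hashes = {p.name: _sha256(p) for p in sorted(set(artifacts))}
    manifest = {
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "artifacts": hashes,
        "manifest_hash": hashlib.sha256(json.dumps(hashes, sort_keys=True).encode()).hexdigest(),
        "group_mean_energy": mean_energy,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
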