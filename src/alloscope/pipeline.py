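"""Run configuration, stage orchestration and report assembly.

``run_pipeline`` executes the requested stages in dependency order
(load -> superpose -> observables / hbonds / dfmap / network -> events) on
either a topology+trajectory pair from disk or a generated synthetic
preset, writes every artifact under the run directory with fixed names
(observables.csv, hbonds_occupancy.csv, dfmap.csv, network.graphml,
communities.csv, events.json, manifest.json) and records a machine-readable
manifest (inputs, parameters, software version, per-stage checksums and
timings). ``compare_runs`` lines up two run bundles side by side
(closed-state vs open-state comparisons).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigurationError
from . import dfmap as dfmap_mod
from . import events as events_mod
from . import geometry, hbond, network
from .structure import (
    ResidueSelection,
    Topology,
    Trajectory,
    load_domain_map,
    load_topology,
    load_trajectory,
    pi3k_domain_map,
    select_domain,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "compare_runs", "parse_window"]

logger = logging.getLogger("alloscope")

ALL_STAGES = ("superpose", "observables", "hbonds", "dfmap", "network", "events")


def parse_window(trajectory: Trajectory, spec: str | None) -> tuple[int, int] | None:
    """Parse a window spec into a frame range.

    ``None`` or ``"all"`` -> full trajectory; ``"last:200ns"`` -> trailing
    200 ns; ``"A:Bns"`` -> the time interval [A, B) ns.
    """
    if spec is None or spec == "all":
        return None
    t = trajectory.times_ns
    spec = spec.strip().lower()
    if spec.startswith("last:"):
        span = float(spec[5:].rstrip("ns"))
        start = int(np.searchsorted(t, t[-1] - span + 1e-9))
        return (start, trajectory.n_frames)
    if ":" in spec:
        a, b = spec.rstrip("ns").split(":")
        start = int(np.searchsorted(t, float(a)))
        stop = int(np.searchsorted(t, float(b)))
        return (start, stop)
    raise ConfigurationError(f"cannot parse window spec {spec!r}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; all parameters carry defaults."""

    output_dir: str | Path = "alloscope_run"
    topology_path: str | None = None
    trajectory_path: str | None = None
    domain_map_path: str | None = None  # None -> packaged PI3Kalpha map
    synthetic_preset: bool = False  # generate the pi3k-like preset instead
    preset_frames: int = 1000
    seed: int = 7
    stride: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"

    # observables
    fit_domains: tuple[str, ...] | None = None  # None -> all Calpha
    com_pairs: tuple[tuple[str, str], ...] = (
        ("nSH2", "helical"),
        ("nSH2", "C2"),
        ("nSH2", "kinase"),
    )
    angle_selections: tuple[str, str, str] | None = (
        "helix_339_347",
        "residue_545",
        "helix_400_410",
    )
    mass_weighted_com: bool = True

    # hydrogen bonds
    hbond_pair: tuple[str, str] = ("nSH2", "helical")
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    hbond_heavy_only: bool = False
    occupancy_window_ns: float = 50.0
    salt_bridges: bool = True
    salt_bridge_cutoff: float = 4.0

    # distance fluctuations
    df_domains: tuple[str, ...] = ("nSH2", "helical")
    df_window: str | None = "last:200ns"
    df_threshold: float = 0.3

    # network
    network_domains: tuple[str, ...] = ("nSH2", "helical")
    network_window: str | None = "last:200ns"
    contact_cutoff: float = 4.5
    contact_min_fraction: float = 0.75
    neighbor_exclusion: int = 1
    communities: bool = True
    community_patience: int | None = 100
    path_endpoints: tuple[str, str] | None = None  # node ids 'chain:resnum'

    # events
    baseline_window: tuple[float, float] = (0.0, 100.0)
    open_offset: float = 5.0
    smoothing_ns: float = 5.0
    dwell_ns: float = 50.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if not self.synthetic_preset:
            for attr in ("topology_path", "trajectory_path"):
                path = getattr(self, attr)
                if path is None:
                    raise ConfigurationError(
                        f"{attr} required when synthetic_preset is off"
                    )
                if not Path(path).exists():
                    raise ConfigurationError(f"{attr}: {path} does not exist")
        if self.domain_map_path is not None and not Path(self.domain_map_path).exists():
            raise ConfigurationError(f"domain map {self.domain_map_path} not found")


@dataclass
class RunResult:
    """Outcome of a pipeline run."""

    output_dir: Path
    manifest: dict
    topology: Topology | None = None
    trajectory: Trajectory | None = None
    extras: dict = field(default_factory=dict)

    @property
    def succeeded(self) -> bool:
        return all(s["status"] == "ok" for s in self.manifest["stages"].values())


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _all_ca_selection(topology: Topology) -> ResidueSelection:
    idx = np.flatnonzero(np.array([n.strip() == "CA" for n in topology.atom_names]))
    return ResidueSelection(idx, "all", np.unique(topology.atom_resindex[idx]))


def _config_dict(config: RunConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["output_dir"] = str(raw["output_dir"])
    return raw


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured stages and assemble the report bundle.

    Stage failures are recorded in the manifest (partial outputs retained)
    rather than aborting the whole run.
    """
    config.validate()
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config": _config_dict(config),
        "stages": {},
        "outputs": {},
    }

    # --- load ---------------------------------------------------------------
    if config.synthetic_preset:
        from .synthetic import generate, pi3k_like_preset

        spec = pi3k_like_preset(n_frames=config.preset_frames, seed=config.seed)
        topology, trajectory, truth = generate(spec)
        manifest["inputs"] = {
            "synthetic_preset": "pi3k-like",
            "frames": config.preset_frames,
            "seed": config.seed,
        }
    else:
        topology = load_topology(config.topology_path)
        trajectory = load_trajectory(
            topology, config.trajectory_path, stride=config.stride
        )
        truth = None
        manifest["inputs"] = {
            "topology": config.topology_path,
            "trajectory": config.trajectory_path,
            "stride": config.stride,
        }
    domain_map = (
        load_domain_map(config.domain_map_path)
        if config.domain_map_path
        else pi3k_domain_map()
    )

    def sel(name: str, subset: str = "CA") -> ResidueSelection:
        return select_domain(topology, domain_map, name, subset)

    stages = list(config.stages)
    # dependency rule: network/observables need a superposed trajectory
    if ("network" in stages or "observables" in stages) and "superpose" not in stages:
        logger.info("superpose auto-inserted (required by requested stages)")
        stages.insert(0, "superpose")
    ordered = [s for s in ALL_STAGES if s in stages]

    extras: dict = {"ground_truth": truth}
    com_series = None
    hbond_counts = None
    occupancy = None

    for stage in ordered:
        started = time.perf_counter()
        outputs: list[str] = []
        try:
            if stage == "superpose":
                if config.fit_domains:
                    fit_idx = np.concatenate(
                        [sel(d).atom_indices for d in config.fit_domains]
                    )
                    fit = ResidueSelection(
                        np.unique(fit_idx),
                        "+".join(config.fit_domains),
                        np.unique(topology.atom_resindex[np.unique(fit_idx)]),
                    )
                else:
                    fit = _all_ca_selection(topology)
                trajectory = geometry.superpose(trajectory, fit, 0)

            elif stage == "observables":
                import pandas as pd

                frames = []
                all_ca = _all_ca_selection(topology)
                rmsd = geometry.rmsd_timeseries(trajectory, all_ca, 0)
                frames.append(rmsd.to_dataframe())
                for a, b in config.com_pairs:
                    if a not in domain_map or b not in domain_map:
                        continue
                    series = geometry.com_distance_timeseries(
                        trajectory, sel(a), sel(b), config.mass_weighted_com
                    )
                    frames.append(series.to_dataframe())
                    if (a, b) == tuple(config.hbond_pair) or com_series is None:
                        com_series = series
                if config.angle_selections:
                    apex, arm_a, arm_b = config.angle_selections
                    if all(n in domain_map for n in (apex, arm_a, arm_b)):
                        hinge = geometry.hinge_angle_timeseries(
                            trajectory, sel(apex), sel(arm_a), sel(arm_b)
                        )
                        frames.append(hinge.series.to_dataframe())
                        extras["hinge"] = hinge
                path = outdir / "observables.csv"
                pd.concat(frames, ignore_index=True).to_csv(path, index=False)
                outputs.append(str(path))
                rmsf = geometry.rmsf_profile(trajectory, all_ca)
                path = outdir / "rmsf.csv"
                rmsf.to_dataframe().to_csv(path, index=False)
                outputs.append(str(path))
                extras["com_series"] = com_series

            elif stage == "hbonds":
                a, b = config.hbond_pair
                criteria = hbond.HBondCriteria(
                    distance_cutoff=config.hbond_distance,
                    angle_cutoff_deg=config.hbond_angle,
                    heavy_only=config.hbond_heavy_only,
                )
                sel_a, sel_b = sel(a, "all"), sel(b, "all")
                hbond_counts = hbond.interdomain_hbond_count(
                    trajectory, sel_a, sel_b, criteria
                )
                path = outdir / "hbond_counts.csv"
                hbond_counts.to_dataframe().to_csv(path, index=False)
                outputs.append(str(path))
                occupancy = hbond.pair_occupancy(
                    trajectory, sel_a, sel_b, criteria, config.occupancy_window_ns
                )
                path = outdir / "hbonds_occupancy.csv"
                occupancy.to_csv(path)
                outputs.append(str(path))
                extras["hbond_counts"] = hbond_counts
                extras["occupancy"] = occupancy
                if config.salt_bridges:
                    bridges = hbond.detect_salt_bridges(
                        trajectory,
                        sel_a,
                        sel_b,
                        config.salt_bridge_cutoff,
                        config.occupancy_window_ns,
                    )
                    path = outdir / "saltbridges_occupancy.csv"
                    bridges.to_csv(path)
                    outputs.append(str(path))
                    extras["salt_bridges"] = bridges

            elif stage == "dfmap":
                idx = np.concatenate([sel(d).atom_indices for d in config.df_domains])
                nodes = ResidueSelection(
                    np.unique(idx),
                    "+".join(config.df_domains),
                    np.unique(topology.atom_resindex[np.unique(idx)]),
                )
                window = parse_window(trajectory, config.df_window)
                matrix = dfmap_mod.distance_fluctuation_matrix(
                    trajectory, nodes, window
                )
                path = outdir / "dfmap.csv"
                matrix.to_csv(path)
                outputs.append(str(path))
                extras["dfmatrix"] = matrix
                if len(config.df_domains) >= 2:
                    summary = dfmap_mod.interdomain_df_summary(
                        matrix,
                        domain_map,
                        config.df_domains[0],
                        config.df_domains[1],
                        config.df_threshold,
                    )
                    extras["df_summary"] = summary
                    path = outdir / "df_summary.json"
                    with open(path, "w") as handle:
                        json.dump(
                            {
                                "domain_a": summary.domain_a,
                                "domain_b": summary.domain_b,
                                "mean_df_A2": summary.mean_df,
                                "fraction_below_threshold": summary.fraction_below_threshold,
                                "threshold_A2": summary.threshold,
                                "n_pairs": summary.n_pairs,
                            },
                            handle,
                            indent=1,
                        )
                    outputs.append(str(path))

            elif stage == "network":
                idx = np.concatenate(
                    [sel(d).atom_indices for d in config.network_domains]
                )
                nodes = ResidueSelection(
                    np.unique(idx),
                    "+".join(config.network_domains),
                    np.unique(topology.atom_resindex[np.unique(idx)]),
                )
                window = parse_window(trajectory, config.network_window)
                corr = network.correlation_matrix(trajectory, nodes, window)
                adj = network.contact_adjacency(
                    trajectory,
                    nodes,
                    cutoff=config.contact_cutoff,
                    min_fraction=config.contact_min_fraction,
                    neighbor_exclusion=config.neighbor_exclusion,
                    window=window,
                )
                graph = network.build_network(adj, corr)
                path = outdir / "network.graphml"
                network.write_graphml(graph, path)
                outputs.append(str(path))
                extras["graph"] = graph
                partition = None
                if config.communities:
                    partition = network.girvan_newman_communities(
                        graph, patience=config.community_patience
                    )
                    path = outdir / "communities.csv"
                    network.write_partition_csv(partition, path)
                    outputs.append(str(path))
                    extras["partition"] = partition
                    extras["critical_edges"] = network.critical_edges(graph, partition)
                path = outdir / "network_edges.csv"
                network.write_edge_csv(graph, path, partition)
                outputs.append(str(path))
                if config.path_endpoints:
                    src, tgt = config.path_endpoints
                    extras["path"] = network.optimal_path(graph, src, tgt)

            elif stage == "events":
                if com_series is None:
                    a, b = config.hbond_pair
                    com_series = geometry.com_distance_timeseries(
                        trajectory, sel(a), sel(b), config.mass_weighted_com
                    )
                timeline = events_mod.classify_states(
                    com_series,
                    baseline_window=config.baseline_window,
                    open_offset=config.open_offset,
                    smoothing_ns=config.smoothing_ns,
                    dwell_ns=config.dwell_ns,
                )
                if hbond_counts is not None and occupancy is not None:
                    timeline = events_mod.annotate_steps(
                        timeline, hbond_counts, occupancy
                    )
                path = outdir / "events.json"
                timeline.to_json(path)
                outputs.append(str(path))
                extras["timeline"] = timeline

            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - started, 3),
                "outputs": outputs,
            }
            logger.info("stage %s ok (%.2fs)", stage, time.perf_counter() - started)
        except Exception as exc:  # partial outputs retained, failure recorded
            manifest["stages"][stage] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "seconds": round(time.perf_counter() - started, 3),
                "outputs": outputs,
            }
            logger.error("stage %s failed: %s", stage, exc)

    for stage_info in manifest["stages"].values():
        for out in stage_info["outputs"]:
            manifest["outputs"][Path(out).name] = _sha256(Path(out))

    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)

    return RunResult(outdir, manifest, topology, trajectory, extras)


def _load_manifest(bundle: str | Path) -> dict:
    with open(Path(bundle) / "manifest.json") as handle:
        return json.load(handle)


def compare_runs(bundle_a: str | Path, bundle_b: str | Path) -> dict:
    """Side-by-side comparison of two run bundles.

    Produces COM means +- SD, hydrogen-bond totals, DF block means,
    community-partition agreement (adjusted Rand index over the shared
    node set) and optimal-path weight differences, for whatever stages the
    two bundles share. Mismatched node sets are aligned on the
    intersection with a warning in the report.
    """
    import pandas as pd

    man_a, man_b = _load_manifest(bundle_a), _load_manifest(bundle_b)
    shared = sorted(
        set(man_a["stages"]) & set(man_b["stages"]),
        key=lambda s: ALL_STAGES.index(s) if s in ALL_STAGES else 99,
    )
    report: dict = {"shared_stages": shared, "warnings": [], "comparisons": {}}

    def read_csv(bundle, name):
        path = Path(bundle) / name
        return pd.read_csv(path) if path.exists() else None

    if "observables" in shared:
        obs_a, obs_b = read_csv(bundle_a, "observables.csv"), read_csv(
            bundle_b, "observables.csv"
        )
        if obs_a is not None and obs_b is not None:
            rows = {}
            for label in sorted(set(obs_a["label"]) & set(obs_b["label"])):
                va = obs_a.loc[obs_a["label"] == label, "value"]
                vb = obs_b.loc[obs_b["label"] == label, "value"]
                rows[label] = {
                    "mean_a": float(va.mean()),
                    "sd_a": float(va.std()),
                    "mean_b": float(vb.mean()),
                    "sd_b": float(vb.std()),
                    "mean_difference": float(vb.mean() - va.mean()),
                }
            report["comparisons"]["observables"] = rows

    if "hbonds" in shared:
        cnt_a, cnt_b = read_csv(bundle_a, "hbond_counts.csv"), read_csv(
            bundle_b, "hbond_counts.csv"
        )
        if cnt_a is not None and cnt_b is not None:
            report["comparisons"]["hbond_total"] = {
                "mean_a": float(cnt_a["value"].mean()),
                "mean_b": float(cnt_b["value"].mean()),
                "mean_difference": float(cnt_b["value"].mean() - cnt_a["value"].mean()),
            }

    if "dfmap" in shared:
        for bundle, key in ((bundle_a, "a"), (bundle_b, "b")):
            path = Path(bundle) / "df_summary.json"
            if path.exists():
                with open(path) as handle:
                    report["comparisons"].setdefault("df_summary", {})[key] = json.load(
                        handle
                    )

    if "network" in shared:
        part_a, part_b = read_csv(bundle_a, "communities.csv"), read_csv(
            bundle_b, "communities.csv"
        )
        if part_a is not None and part_b is not None:
            from sklearn.metrics import adjusted_rand_score

            merged = part_a.merge(part_b, on="node", suffixes=("_a", "_b"))
            if len(merged) < max(len(part_a), len(part_b)):
                report["warnings"].append(
                    "community node sets differ; aligned on intersection"
                )
            if len(merged):
                report["comparisons"]["community_ari"] = float(
                    adjusted_rand_score(merged["community_a"], merged["community_b"])
                )

    if not report["comparisons"]:
        report["warnings"].append("no comparable outputs in the shared stages")
    return report
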