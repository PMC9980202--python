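"""End-to-end workflow orchestration: config → staged analysis → report.

Stage order: load inputs → contact-image dataset → conformational
clustering → classifier training → saliency → flexibility (RMSF/ΔRMSF)
→ contact selection → reaction-coordinate evaluation → reweighted free
energy surfaces → state counting → report. Every stage persists its
tables under the output directory, and a rerun with the same config and
seeds reproduces them byte-identically (no timestamps in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (ContactImageSet, build_dataset, map_to_image,
                       write_contact_map, write_image_png)
from .deeplearn import (ClassifierModel, ContactSelection, SaliencyMap,
                        compute_saliency, select_contacts, train_classifier)
from .ensemble import cluster_conformations, representative_contact_map
from .errors import ConfigurationError, ValidationError
from .flexibility import FlexProfile, compute_rmsf, delta_rmsf, rmsd_timecourse
from .reweighting import (CalphaDistance, LigandRmsd, count_states, evaluate_rc,
                          reweight, write_surface)
from .synthetic import SyntheticSpec, generate_ensemble, write_ground_truth
from .trajio import (BoostSeries, MolecularSystem, TrajectoryEnsemble,
                     read_boost_log, read_topology, read_topology_coordinates,
                     read_trajectory, validate_pair, write_boost_log,
                     write_topology, write_trajectory)

log = logging.getLogger("allokit")

__all__ = ["RunConfig", "AllosteryReport", "run_workflow", "selectivity_compare",
           "generate_inputs", "load_inputs"]

STAGES = ("load", "contacts", "cluster", "train", "saliency", "flex",
          "select", "reweight", "report")


@dataclass
class RunConfig:
    """Validated run configuration; see ``RunConfig.from_yaml``."""

    topology: str
    conditions: dict[str, dict]     # name -> {trajectories: [...], boost_logs: [...]}
    free_condition: str
    bound_condition: str
    temperature: float = 310.0
    role_spec: dict | None = None
    contact_cutoff: float = 4.5
    min_seq_sep: int = 3
    train_frac: float = 0.8
    epochs: int = 15
    grad_threshold: float = 0.7
    bin_size: float = 1.0
    frames_cutoff: int = 100
    state_threshold: float = 1.0
    cluster_epsilon: float = 2.5
    cluster_max_frames: int = 1500
    dl_stride: int = 10
    pad_to: int | None = None
    dt_ns: float = 0.01
    split_seed: int = 0
    train_seed: int = 0
    reaction_coordinates: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        if self.free_condition not in self.conditions:
            raise ConfigurationError(f"free_condition {self.free_condition!r} has no inputs")
        if self.bound_condition not in self.conditions:
            raise ConfigurationError(f"bound_condition {self.bound_condition!r} has no inputs")
        for cond, group in self.conditions.items():
            trajs = group.get("trajectories", [])
            boosts = group.get("boost_logs", [])
            if not trajs:
                raise ConfigurationError(f"condition {cond!r} lists no trajectories")
            if len(trajs) != len(boosts):
                raise ConfigurationError(
                    f"condition {cond!r}: {len(trajs)} trajectories but "
                    f"{len(boosts)} boost logs — every trajectory needs one")
        if not 0.5 <= self.bin_size <= 1.0:
            raise ConfigurationError("bin_size must be within [0.5, 1.0] Å")
        if not 1 <= self.frames_cutoff:
            raise ConfigurationError("frames_cutoff must be >= 1")
        if not 0 < self.grad_threshold <= 1:
            raise ConfigurationError("grad_threshold must be in (0, 1]")
        for rc in self.reaction_coordinates:
            if rc.get("kind") != "calpha_distance":
                raise ConfigurationError(
                    "config reaction_coordinates support kind=calpha_distance")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = raw.pop("params", {})
        seeds = raw.pop("seeds", {})
        cfg = cls(topology=raw["topology"],
                  conditions=raw["conditions"],
                  free_condition=raw["free_condition"],
                  bound_condition=raw["bound_condition"],
                  temperature=raw.get("temperature", 310.0),
                  role_spec=raw.get("role_spec"),
                  reaction_coordinates=raw.get("reaction_coordinates", []),
                  **params)
        cfg.split_seed = int(seeds.get("split", 0))
        cfg.train_seed = int(seeds.get("train", 0))
        # resolve paths relative to the config file
        base = path.parent
        cfg.topology = str((base / cfg.topology).resolve())
        for group in cfg.conditions.values():
            group["trajectories"] = [str((base / p).resolve()) for p in group["trajectories"]]
            group["boost_logs"] = [str((base / p).resolve()) for p in group["boost_logs"]]
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AllosteryReport:
    """Workflow output: what was selected, how flexible, how confined."""

    selected_contacts: pd.DataFrame
    flex_table: pd.DataFrame
    state_counts: dict[str, int]
    confinement_verdict: str
    final_val_accuracy: float
    training_curve: pd.DataFrame
    config_hash: str
    seeds: dict[str, int]
    version: str = __version__


# --------------------------------------------------------------------------
# input loading / synthetic input generation


def load_inputs(config: RunConfig
                ) -> tuple[MolecularSystem, list[tuple[TrajectoryEnsemble, BoostSeries]]]:
    """Read topology, trajectories and boost logs; validate the pairing."""
    system = read_topology(config.topology, config.role_spec)
    members = []
    for cond, group in config.conditions.items():
        for rep, (tpath, bpath) in enumerate(zip(group["trajectories"],
                                                 group["boost_logs"])):
            traj = read_trajectory(system, tpath, condition=cond, replica_id=rep,
                                   dt_ns=config.dt_ns)
            boost = read_boost_log(bpath, temperature=config.temperature)
            validate_pair(traj, boost)
            members.append((traj, boost))
    return system, members


def generate_inputs(spec: SyntheticSpec, outdir, traj_format: str = "dcd") -> Path:
    """Write a synthetic system to disk in the workflow's input formats.

    Emits topology.pdb, one trajectory + boost log per condition/replica,
    the analytic ground-truth sidecar, and a ready-to-run run.yaml whose
    reaction coordinate is the reporter pair. Returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    system, members, truth = generate_ensemble(spec)
    ref = members[0][0].frames[0]
    write_topology(system, ref, outdir / "topology.pdb",
                   remarks=[f"synthetic system seed={spec.seed}"])
    conditions: dict[str, dict] = {}
    for traj, boost in members:
        stem = f"{traj.condition}_rep{traj.replica_id}"
        tpath = outdir / f"{stem}.{traj_format}"
        bpath = outdir / f"{stem}.boost.txt"
        write_trajectory(system, traj.frames, tpath)
        write_boost_log(boost, bpath, remarks=[f"synthetic {stem} seed={spec.seed}"])
        group = conditions.setdefault(traj.condition,
                                      {"trajectories": [], "boost_logs": []})
        group["trajectories"].append(tpath.name)
        group["boost_logs"].append(bpath.name)
    write_ground_truth(truth, outdir / "ground_truth.txt")

    ri, rj = spec.reporter_pair
    raw = {
        "topology": "topology.pdb",
        "temperature": spec.temperature,
        "free_condition": spec.free_condition,
        "bound_condition": spec.bound_condition,
        "conditions": conditions,
        "reaction_coordinates": [
            {"kind": "calpha_distance", "res_i": int(ri), "res_j": int(rj)}],
        "params": {"dt_ns": spec.dt_ns},
        "seeds": {"split": int(spec.seed), "train": int(spec.seed)},
    }
    cfg_path = outdir / "run.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return cfg_path


# --------------------------------------------------------------------------
# workflow


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def _plot_surface(surface, path, title: str) -> None:
    """PMF figure; masked bins are rendered at max(valid PMF) + 1 kcal/mol
    (presentation only — the persisted tables keep them as missing)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ceiling = float(np.nanmax(surface.pmf[surface.valid])) + 1.0
    if surface.ndim == 1:
        shown = np.where(surface.valid, surface.pmf, ceiling)
        ax.plot(surface.bin_centers(0), shown, marker="o", ms=3)
        ax.set_xlabel("reaction coordinate (Å)")
        ax.set_ylabel("PMF (kcal/mol)")
    else:
        shown = np.where(surface.valid, surface.pmf, ceiling)
        im = ax.pcolormesh(surface.edges[0], surface.edges[1], shown.T,
                           shading="auto", cmap="viridis_r")
        fig.colorbar(im, ax=ax, label="PMF (kcal/mol)")
        ax.set_xlabel("RC 1 (Å)")
        ax.set_ylabel("RC 2 (Å)")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_workflow(config: RunConfig, outdir, upto: str = "report") -> AllosteryReport:
    """Execute the workflow through stage ``upto``, persisting intermediates.

    Raises with the failing stage's name; outputs of completed stages stay
    on disk. Idempotent for fixed config and seeds.
    """
    if upto not in STAGES:
        raise ConfigurationError(f"unknown stage {upto!r}; choose from {STAGES}")
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    last = STAGES.index(upto)
    stage_results: dict[str, object] = {}

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"workflow stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
        stage_results[name] = result
        return result

    # -- load
    system, members = _run_stage("load", lambda: load_inputs(config))
    trajs = [t for t, _ in members]
    by_condition: dict[str, list[int]] = {}
    for idx, t in enumerate(trajs):
        by_condition.setdefault(t.condition, []).append(idx)
    if last == 0:
        return None  # type: ignore[return-value]

    # -- contacts: dataset of contact-map images
    def _contacts() -> ContactImageSet:
        ds = build_dataset(trajs, train_frac=config.train_frac, seed=config.split_seed,
                           cutoff=config.contact_cutoff, min_seq_sep=config.min_seq_sep,
                           pad_to=config.pad_to, stride=config.dl_stride)
        manifest = pd.DataFrame({
            "member": [m for m, _ in ds.frame_refs],
            "frame": [f for _, f in ds.frame_refs],
            "label": [ds.class_names[c] for c in ds.labels],
            "split": ds.split})
        _csv(manifest, outdir / "dataset_manifest.csv")
        return ds

    dataset = _run_stage("contacts", _contacts)
    if last <= STAGES.index("contacts"):
        return None  # type: ignore[return-value]

    # -- cluster: per condition, pooled replicas; representative contact maps
    def _cluster():
        reps = {}
        rows_assign, rows_summary = [], []
        for cond, idxs in by_condition.items():
            group = [trajs[i] for i in idxs]
            res = cluster_conformations(group, epsilon=config.cluster_epsilon,
                                        max_frames=config.cluster_max_frames)
            rep_map = representative_contact_map(res, group, system,
                                                 cutoff=config.contact_cutoff,
                                                 min_seq_sep=config.min_seq_sep)
            write_contact_map(rep_map, outdir / f"representative_map_{cond}.txt")
            reps[cond] = rep_map
            for (mi, fi), lab in zip(res.frame_refs, res.labels):
                rows_assign.append({"condition": cond, "replica": group[mi].replica_id,
                                    "frame": fi, "cluster": int(lab)})
            for c in range(res.n_clusters):
                mi, fi = res.frame_refs[res.representatives[c]]
                rows_summary.append({"condition": cond, "cluster": c,
                                     "size": int(res.sizes[c]),
                                     "representative_replica": group[mi].replica_id,
                                     "representative_frame": fi})
        _csv(pd.DataFrame(rows_assign), outdir / "cluster_assignments.csv")
        _csv(pd.DataFrame(rows_summary), outdir / "cluster_summary.csv")
        return reps

    rep_maps = _run_stage("cluster", _cluster)
    if last <= STAGES.index("cluster"):
        return None  # type: ignore[return-value]

    # -- train
    def _train() -> ClassifierModel:
        model = train_classifier(dataset, epochs=config.epochs, seed=config.train_seed)
        _csv(model.history, outdir / "training_curve.csv")
        model.net.save(outdir / "model_checkpoint.npz")
        return model

    model = _run_stage("train", _train)
    if last <= STAGES.index("train"):
        return None  # type: ignore[return-value]

    # -- saliency on the bound condition's representative map
    def _saliency() -> SaliencyMap:
        sal = compute_saliency(model, rep_maps[config.bound_condition],
                               config.bound_condition)
        np.savetxt(outdir / "saliency.txt", sal.values, fmt="%.6f",
                   header=f"target_class {sal.target_class} n_res {sal.n_res}")
        write_image_png(sal.values, outdir / "saliency.png")
        write_image_png(map_to_image(rep_maps[config.bound_condition]),
                        outdir / f"representative_map_{config.bound_condition}.png")
        return sal

    saliency = _run_stage("saliency", _saliency)
    if last <= STAGES.index("saliency"):
        return None  # type: ignore[return-value]

    # -- flexibility
    def _flex() -> FlexProfile:
        bound_profiles = [compute_rmsf(trajs[i]) for i in by_condition[config.bound_condition]]
        free_profiles = [compute_rmsf(trajs[i]) for i in by_condition[config.free_condition]]
        profile = delta_rmsf(bound_profiles, free_profiles)
        _csv(profile.to_frame(), outdir / "delta_rmsf.csv")
        # ligand RMSD time courses vs the starting structure, per replica
        lig_heavy = np.asarray(
            [i for i, a in enumerate(system.atoms)
             if a.is_heavy and system.residues[a.residue_index].role != "receptor"],
            dtype=int)
        if len(lig_heavy):
            rows = []
            for cond, idxs in by_condition.items():
                for i in idxs:
                    series = rmsd_timecourse(trajs[i], trajs[i].frames[0], lig_heavy,
                                             selection_name="ligand-heavy")
                    rows.extend({"condition": cond, "replica": trajs[i].replica_id,
                                 "time_ns": t, "rmsd_A": v}
                                for t, v in zip(series.times, series.values))
            _csv(pd.DataFrame(rows), outdir / "ligand_rmsd_timecourse.csv")
        return profile

    flex = _run_stage("flex", _flex)
    if last <= STAGES.index("flex"):
        return None  # type: ignore[return-value]

    # -- selection
    def _select() -> ContactSelection:
        sel = select_contacts(saliency, flex, threshold=config.grad_threshold)
        _csv(sel.to_frame(), outdir / "selected_contacts.csv")
        return sel

    selection = _run_stage("select", _select)
    if last <= STAGES.index("select"):
        return None  # type: ignore[return-value]

    # -- reaction coordinates, reweighting, states
    def _reweight():
        rcs: list[tuple[str, CalphaDistance]] = []
        for rc in config.reaction_coordinates:
            rcs.append((f"d_{rc['res_i']}_{rc['res_j']}",
                        CalphaDistance(int(rc["res_i"]), int(rc["res_j"]))))
        for i, j, _ in selection.pairs:
            name = f"d_{i}_{j}"
            if name not in [n for n, _ in rcs]:
                rcs.append((name, CalphaDistance(i, j)))
        if not rcs:
            raise ValidationError("no reaction coordinates: empty selection and "
                                  "no reaction_coordinates in config")
        surfaces: dict[str, dict[str, object]] = {}
        counts: dict[str, int] = {}
        rows = []
        for cond, idxs in by_condition.items():
            vals = {name: np.concatenate([evaluate_rc(trajs[i], rc) for i in idxs])
                    for name, rc in rcs}
            dv = np.concatenate([members[i][1].delta_v_total for i in idxs])
            boost = BoostSeries(delta_v_total=dv, temperature=config.temperature)
            for name, _rc in rcs:
                surf = reweight(vals[name], boost, bin_size=config.bin_size,
                                cutoff=config.frames_cutoff, method="cumulant2")
                write_surface(surf, outdir / f"pmf_{name}_{cond}.txt")
                _plot_surface(surf, outdir / f"pmf_{name}_{cond}.png",
                              f"{name} ({cond})")
                states = count_states(surf, threshold=config.state_threshold)
                surfaces.setdefault(cond, {})[name] = (surf, states)
                for (coords, p) in states.states:
                    rows.append({"condition": cond, "rc": name,
                                 "state_center_A": coords[0], "pmf_kcal_mol": p})
            # 2D surface over the two leading coordinates (auxiliary: the
            # verdict rests on the 1D profiles, so sparse 2D bins warn only)
            if len(rcs) >= 2:
                (n1, _), (n2, _) = rcs[0], rcs[1]
                try:
                    surf2 = reweight((vals[n1], vals[n2]), boost,
                                     bin_size=config.bin_size,
                                     cutoff=config.frames_cutoff, method="cumulant2")
                    write_surface(surf2, outdir / f"pmf2d_{n1}_{n2}_{cond}.txt")
                    _plot_surface(surf2, outdir / f"pmf2d_{n1}_{n2}_{cond}.png",
                                  f"{n1} vs {n2} ({cond})")
                except ValidationError as exc:
                    log.warning("2D PMF skipped for %s: %s", cond, exc)
            primary = rcs[0][0]
            counts[cond] = len(surfaces[cond][primary][1])
        _csv(pd.DataFrame(rows, columns=["condition", "rc", "state_center_A",
                                         "pmf_kcal_mol"]),
             outdir / "states.csv")
        return surfaces, counts

    surfaces, state_counts = _run_stage("reweight", _reweight)
    if last <= STAGES.index("reweight"):
        return None  # type: ignore[return-value]

    # -- report
    def _report() -> AllosteryReport:
        free_n = state_counts[config.free_condition]
        bound_n = state_counts[config.bound_condition]
        verdict = f"{free_n} -> {bound_n} states"
        report = AllosteryReport(
            selected_contacts=selection.to_frame(),
            flex_table=flex.to_frame(),
            state_counts=state_counts,
            confinement_verdict=verdict,
            final_val_accuracy=model.final_val_accuracy,
            training_curve=model.history,
            config_hash=config.config_hash(),
            seeds={"split": config.split_seed, "train": config.train_seed},
        )
        payload = {
            "version": report.version,
            "config_hash": report.config_hash,
            "seeds": report.seeds,
            "final_val_accuracy": report.final_val_accuracy,
            "state_counts": report.state_counts,
            "confinement_verdict": report.confinement_verdict,
            "selected_contacts": [
                {"res_i": int(i), "res_j": int(j), "gradient": float(g)}
                for i, j, g in selection.pairs],
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report

    return _run_stage("report", _report)


# --------------------------------------------------------------------------
# selectivity comparison (cognate vs non-cognate receptor)


def selectivity_compare(config_cognate: RunConfig, config_noncognate: RunConfig,
                        residue_map: dict[int, int], outdir) -> pd.DataFrame:
    """ΔRMSF of the modulator-bound non-cognate receptor minus the cognate one.

    ``residue_map`` maps non-cognate residue indices to cognate ones;
    unmapped non-cognate receptor residues are excluded (and reported in
    the output's ``mapped`` column count). Also writes per-receptor
    ligand-RMSD PMFs when a ligand entity is present.
    """
    if not residue_map:
        raise ConfigurationError("empty residue correspondence map")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    results = {}
    for tag, cfg in (("cognate", config_cognate), ("noncognate", config_noncognate)):
        cfg.validate()
        system, members = load_inputs(cfg)
        bound = [t for t, _ in members if t.condition == cfg.bound_condition]
        profiles = [compute_rmsf(t) for t in bound]
        results[tag] = (system, members, profiles)

        # ligand RMSD PMF per receptor (reference: first bound frame)
        lig_roles = sorted({r.role for r in system.residues if r.role != "receptor"})
        if lig_roles and bound:
            ref = bound[0].frames[0]
            dv = np.concatenate([b.delta_v_total for t, b in members
                                 if t.condition == cfg.bound_condition])
            vals = np.concatenate([evaluate_rc(t, LigandRmsd(lig_roles[0], ref))
                                   for t in bound])
            boost = BoostSeries(delta_v_total=dv, temperature=cfg.temperature)
            try:
                surf = reweight(vals, boost, bin_size=0.5,
                                cutoff=min(100, max(1, len(vals) // 20)))
                write_surface(surf, outdir / f"pmf_ligand_rmsd_{tag}.txt")
            except ValidationError:
                log.warning("ligand-RMSD PMF skipped for %s (too few frames per bin)", tag)

    noncog_idx = sorted(residue_map)
    cog_idx = [residue_map[i] for i in noncog_idx]
    n_res_noncog = results["noncognate"][0].n_residues
    unmapped = [i for i in range(n_res_noncog) if i not in residue_map]
    if unmapped:
        log.warning("%d non-cognate residues unmapped and excluded", len(unmapped))
    noncog_profiles = [p[noncog_idx] for p in results["noncognate"][2]]
    cog_profiles = [p[cog_idx] for p in results["cognate"][2]]
    profile = delta_rmsf(noncog_profiles, cog_profiles)
    table = profile.to_frame()
    table.insert(0, "noncognate_residue", noncog_idx)
    table.insert(1, "cognate_residue", cog_idx)
    table = table.drop(columns=["residue"])
    _csv(table, outdir / "selectivity_delta_rmsf.csv")
    return table
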