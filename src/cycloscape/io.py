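"""Readers, writers and the manifest-driven pipeline runner.

Multi-model PDB is the universal interchange format for structures and
trajectories (one MODEL per frame). Reports are CSV/JSON; every output
file embeds the parameter set that produced it (``#``-comment header in
CSV, a ``parameters`` field in JSON). MODEL numbering in PDB files is
1-based as the format requires; frame indices in reports are 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import BACKBONE_ATOMS, ObservableSeries, Trajectory
from .convergence import AgreementMatrix, JSDCurve
from .landscape import FreeEnergyMap

logger = logging.getLogger("cycloscape")

__all__ = [
    "StructureParseError",
    "read_structure",
    "read_trajectory",
    "write_models_pdb",
    "write_trajectory_pdb",
    "read_temperature_series",
    "write_observables_csv",
    "write_jsd_curves_csv",
    "write_agreement_csv",
    "write_free_energy_map",
    "write_star_json",
    "write_combination_csv",
    "StudyManifest",
    "load_manifest",
    "run_pipeline",
]

# three-letter placeholder used when writing label-only synthetic structures
_DEFAULT_RESNAME = "GLY"
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


class StructureParseError(ValueError):
    """A structure file is missing required backbone atoms."""


def _param_header(params: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in params.items())


def read_structure(path) -> tuple[list[np.ndarray], list[tuple[int, str]]]:
    """Read a (multi-model) PDB into backbone coordinate sets + labels.

    Returns one ``(n_backbone_atoms, 3)`` array per MODEL and the shared
    ``(residue_index, atom_name)`` labels. Alternate locations are
    resolved to the highest occupancy; every residue must carry all four
    backbone heavy atoms (N, CA, C, O).
    """
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(altloc="occupancy")
    except Exception:
        stack = pdb.get_structure(altloc="first")
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    mask = np.isin(stack.atom_name, BACKBONE_ATOMS)
    bb = stack[..., mask]
    labels: list[tuple[int, str]] = []
    res_index = -1
    seen: dict[tuple, set] = {}
    prev_res = None
    for rid, ch, name in zip(bb.res_id, bb.chain_id, bb.atom_name):
        key = (str(ch), int(rid))
        if key != prev_res:
            res_index += 1
            prev_res = key
        seen.setdefault(key, set()).add(str(name))
        labels.append((res_index, str(name)))
    for (ch, rid), names in seen.items():
        missing = set(BACKBONE_ATOMS) - names
        if missing:
            raise StructureParseError(
                f"residue {rid} (chain {ch}) in {path} is missing backbone "
                f"atoms: {sorted(missing)}"
            )
    models = [bb.coord[i] for i in range(bb.stack_depth())]
    return models, labels


def read_trajectory(path, tag: str = "", timestep_ps: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL)."""
    models, labels = read_structure(path)
    return Trajectory(
        frames=np.array(models), atom_labels=labels, timestep_ps=timestep_ps,
        tag=tag or Path(str(path)).stem,
    )


def _as_stack(frames: np.ndarray, atom_labels) -> struc.AtomArrayStack:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    stack = struc.AtomArrayStack(frames.shape[0], n_atoms)
    stack.coord = frames
    stack.chain_id = np.array(["A"] * n_atoms)
    stack.res_id = np.array([resi + 1 for resi, _ in atom_labels])
    stack.res_name = np.array([_DEFAULT_RESNAME] * n_atoms)
    stack.atom_name = np.array([name for _, name in atom_labels])
    stack.element = np.array([_ELEMENT.get(name, name[0]) for _, name in atom_labels])
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    return stack


def write_models_pdb(frames, atom_labels, path) -> None:
    """Write coordinates (one MODEL per frame) as a multi-model PDB."""
    pdb = PDBFile()
    pdb.set_structure(_as_stack(frames, atom_labels))
    pdb.write(str(path))


def write_trajectory_pdb(
    traj, path, sidecar_csv=None, temperature_K: float = 300.0
) -> None:
    """Write a trajectory as multi-model PDB, optionally with a sidecar CSV.

    The sidecar records the per-frame ground-truth basin label (−1 when
    unknown) and temperature — constant 300 K for synthetic data.
    """
    labels = getattr(traj, "atom_labels", None) or []
    write_models_pdb(traj.frames, labels, path)
    if sidecar_csv is not None:
        true_labels = getattr(traj, "true_labels", None)
        if true_labels is None:
            true_labels = np.full(len(traj.frames), -1)
        pd.DataFrame(
            {
                "frame": np.arange(len(traj.frames)),
                "basin": np.asarray(true_labels, dtype=int),
                "temperature_K": temperature_K,
            }
        ).to_csv(sidecar_csv, index=False)


def read_temperature_series(path, column: str = "temperature_K") -> np.ndarray:
    """Per-frame temperature record from a CSV (or single-column text) file."""
    df = pd.read_csv(path, comment="#")
    if column in df.columns:
        return df[column].to_numpy(dtype=float)
    return df.iloc[:, -1].to_numpy(dtype=float)


def write_observables_csv(series: ObservableSeries, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_param_header(params or {}))
        pd.DataFrame(
            {"frame": np.arange(len(series)), "rmsd_A": series.rmsd, "rg_A": series.rg}
        ).to_csv(fh, index=False)


def write_jsd_curves_csv(curves: list[JSDCurve], path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_param_header(params or {}))
        data = {"fraction": curves[0].fractions}
        for i, c in enumerate(curves):
            data[c.tag or f"run{i + 1}"] = c.jsd
        pd.DataFrame(data).to_csv(fh, index=False)


def write_agreement_csv(matrix: AgreementMatrix, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_param_header({**(params or {}), "summary": matrix.summary}))
        pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(fh)


def write_free_energy_map(fe_map: FreeEnergyMap, path, params: dict | None = None) -> None:
    """Free-energy map as JSON: edges, F matrix (null = unoccupied), kT."""
    F = np.where(fe_map.occupied, fe_map.F, np.nan)
    payload = {
        "parameters": {**(params or {}), "kT_kJ_per_mol": fe_map.kT},
        "rg_edges_A": fe_map.rg_edges.tolist(),
        "rmsd_edges_A": fe_map.rmsd_edges.tolist(),
        "F_kJ_per_mol": [[None if np.isnan(v) else v for v in row] for row in F],
    }
    Path(path).write_text(json.dumps(payload))


def write_star_json(star, clusters, path, params: dict | None = None) -> None:
    payload = {
        "parameters": params or {},
        "star": star.as_dict(),
        "clusters": {
            "method": clusters.method,
            "populations": {str(k): v for k, v in clusters.populations.items()},
            "noise_fraction": clusters.noise_fraction,
            "centroid_frame": {str(k): int(v) for k, v in clusters.centroid_frame.items()},
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_combination_csv(reports, path, params: dict | None = None) -> None:
    rows = []
    for r in reports:
        row = {"subset": "+".join(r.subset), "size": len(r.subset)}
        row.update({f"rmsd_{p}": v for p, v in sorted(r.per_peptide_rmsd.items())})
        row.update(
            median_rmsd=r.median_rmsd, min_rmsd=r.min_rmsd, max_rmsd=r.max_rmsd
        )
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(_param_header(params or {}))
        pd.DataFrame(rows).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# manifest-driven pipeline


_ANALYSIS_DEFAULTS = {
    "skip_fraction": 0.10,
    "threshold": 0.05,
    "n_windows": 100,
    "n_bins": 100,
    "variance_target": 0.80,
    "temperature_K": 300.0,
    "clustering": {"method": "hdbscan"},
    "combine_sizes": "all",
    "seed": 0,
}


@dataclass
class SimulationEntry:
    tag: str
    trajectories: list[str]
    temperature_csv: str | None = None


@dataclass
class PeptideEntry:
    name: str
    reference_pdb: str
    simulations: list[SimulationEntry]
    nmr_ensemble_pdb: str | None = None


@dataclass
class StudyManifest:
    peptides: list[PeptideEntry]
    analysis: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        self.analysis = {**_ANALYSIS_DEFAULTS, **self.analysis}
        for pep in self.peptides:
            tags = [s.tag for s in pep.simulations]
            if len(set(tags)) != len(tags):
                raise ValueError(f"duplicate simulation tags for peptide {pep.name}")

    def resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path


def load_manifest(path) -> StudyManifest:
    """Load and validate a YAML study manifest; paths must exist."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    peptides = []
    for pep in raw.get("peptides", []):
        sims = [
            SimulationEntry(
                tag=s["tag"],
                trajectories=list(s["trajectories"]),
                temperature_csv=s.get("temperature_csv"),
            )
            for s in pep.get("simulations", [])
        ]
        peptides.append(
            PeptideEntry(
                name=pep["name"],
                reference_pdb=pep["reference_pdb"],
                simulations=sims,
                nmr_ensemble_pdb=pep.get("nmr_ensemble_pdb"),
            )
        )
    manifest = StudyManifest(
        peptides=peptides, analysis=raw.get("analysis", {}), base_dir=path.parent
    )
    missing = []
    for pep in manifest.peptides:
        for p in [pep.reference_pdb, pep.nmr_ensemble_pdb, *[
            t for s in pep.simulations for t in s.trajectories
        ]]:
            if p is not None and not manifest.resolve(p).exists():
                missing.append(p)
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    return manifest


def _load_simulation(manifest: StudyManifest, sim: SimulationEntry) -> list[Trajectory]:
    from .geometry import select_temperature_frames

    trajs = []
    for i, p in enumerate(sim.trajectories):
        traj = read_trajectory(manifest.resolve(p), tag=f"{sim.tag}/run{i + 1}")
        if sim.temperature_csv is not None:
            temps = read_temperature_series(manifest.resolve(sim.temperature_csv))
            traj = select_temperature_frames(
                traj, temps[: traj.n_frames],
                target_K=manifest.analysis["temperature_K"],
            )
        trajs.append(traj)
    return trajs


def run_pipeline(
    manifest: StudyManifest,
    stages=("convergence", "predict", "combine"),
    out_dir="cycloscape_out",
) -> dict:
    """Execute the requested stages for every peptide in the manifest.

    Per-peptide, per-stage failures are isolated: the error is recorded in
    the returned bundle and the pipeline moves on. The bundle maps
    peptide → stage → result summary, plus an ``errors`` list.
    """
    from .combine import enumerate_subsets, equalize_and_concatenate, rank_combinations
    from .convergence import agreement, converged, jsd_curves
    from .geometry import observables
    from .landscape import default_bin_edges, free_energy_map
    from .prediction import evaluate_prediction, predict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = manifest.analysis
    bundle: dict = {"errors": [], "peptides": {}}
    combo_predictions: dict = {}
    peptide_tags: list[str] | None = None

    for pep in manifest.peptides:
        pdir = out / pep.name
        pdir.mkdir(exist_ok=True)
        result: dict = {}
        bundle["peptides"][pep.name] = result
        try:
            ref_models, _ = read_structure(manifest.resolve(pep.reference_pdb))
            reference = ref_models[0]
            nmr_models = None
            if pep.nmr_ensemble_pdb:
                nmr_models, _ = read_structure(manifest.resolve(pep.nmr_ensemble_pdb))
            sims = {s.tag: _load_simulation(manifest, s) for s in pep.simulations}
        except Exception as exc:  # noqa: BLE001 - isolate per peptide
            logger.error("loading peptide %s failed: %s", pep.name, exc)
            bundle["errors"].append(f"{pep.name}/load: {exc}")
            continue

        # the equilibration skip is applied once per source run, before any
        # merging, so concatenated ensembles are never re-trimmed
        def _skip(traj: Trajectory) -> Trajectory:
            n = int(np.floor(cfg["skip_fraction"] * traj.n_frames))
            return traj.subset(np.arange(n, traj.n_frames))

        merged = {
            tag: (
                equalize_and_concatenate([_skip(r) for r in runs])
                if len(runs) > 1
                else _skip(runs[0])
            )
            for tag, runs in sims.items()
        }

        if "convergence" in stages:
            try:
                conv: dict = {}
                series_by_tag = {
                    tag: [observables(r, reference, cfg["skip_fraction"]) for r in runs]
                    for tag, runs in sims.items()
                }
                edges = default_bin_edges(
                    np.concatenate(
                        [s.rmsd for runs in series_by_tag.values() for s in runs]
                    )
                )
                for tag, series in series_by_tag.items():
                    if len(series) < 2:
                        continue
                    curves = jsd_curves(series, edges, n_windows=cfg["n_windows"])
                    per_run, overall = converged(curves, cfg["threshold"])
                    write_jsd_curves_csv(
                        curves, pdir / f"jsd_{tag}.csv",
                        {"peptide": pep.name, "simulation": tag, **_flat(cfg)},
                    )
                    conv[tag] = {"per_run": per_run, "overall": overall}
                if len(series_by_tag) >= 2:
                    for summary in ("mean", "max"):
                        mat = agreement(series_by_tag, summary=summary, bin_edges=edges)
                        write_agreement_csv(
                            mat, pdir / f"agreement_{summary}.csv",
                            {"peptide": pep.name, **_flat(cfg)},
                        )
                result["convergence"] = conv
            except Exception as exc:  # noqa: BLE001
                logger.error("convergence stage failed for %s: %s", pep.name, exc)
                bundle["errors"].append(f"{pep.name}/convergence: {exc}")

        if "predict" in stages or "combine" in stages:
            try:
                stars: dict = {}
                for tag, traj in merged.items():
                    star, clusters, _, aligned = predict(
                        traj,
                        skip_fraction=0.0,
                        variance_target=cfg["variance_target"],
                        **cfg["clustering"],
                    )
                    if reference is not None:
                        evaluate_prediction(star, aligned, reference, nmr_models)
                        series = observables(traj, reference, 0.0)
                        write_free_energy_map(
                            free_energy_map(
                                series, cfg["n_bins"], cfg["temperature_K"]
                            ),
                            pdir / f"femap_{tag}.json",
                            {"peptide": pep.name, "simulation": tag},
                        )
                    write_star_json(
                        star, clusters, pdir / f"star_{tag}.json",
                        {"peptide": pep.name, "simulation": tag, **_flat(cfg)},
                    )
                    write_models_pdb(
                        aligned.frames[star.predicted_frame],
                        aligned.atom_labels,
                        pdir / f"predicted_{tag}.pdb",
                    )
                    stars[tag] = star.as_dict()
                result["predict"] = stars
            except Exception as exc:  # noqa: BLE001
                logger.error("predict stage failed for %s: %s", pep.name, exc)
                bundle["errors"].append(f"{pep.name}/predict: {exc}")

        if "combine" in stages:
            try:
                tags = sorted(merged)
                if peptide_tags is None:
                    peptide_tags = tags
                subsets = enumerate_subsets(tags, cfg["combine_sizes"])
                subsets = [(t,) for t in tags] + list(subsets)
                for subset in subsets:
                    traj = (
                        merged[subset[0]]
                        if len(subset) == 1
                        else equalize_and_concatenate([merged[t] for t in subset])
                    )
                    star, clusters, _, aligned = predict(
                        traj,
                        skip_fraction=0.0,
                        variance_target=cfg["variance_target"],
                        **cfg["clustering"],
                    )
                    r1, _ = evaluate_prediction(star, aligned, reference, nmr_models)
                    combo_predictions[(subset, pep.name)] = r1
                result["combine"] = "evaluated"
            except Exception as exc:  # noqa: BLE001
                logger.error("combine stage failed for %s: %s", pep.name, exc)
                bundle["errors"].append(f"{pep.name}/combine: {exc}")

    if "combine" in stages and combo_predictions:
        evaluated = {s for s, _ in combo_predictions}
        peptides = {p for _, p in combo_predictions}
        complete = {
            key: v for key, v in combo_predictions.items()
            if all((key[0], p) in combo_predictions for p in peptides)
        }
        if complete:
            reports = rank_combinations(complete)
            write_combination_csv(reports, out / "combinations.csv", _flat(cfg))
            bundle["combinations"] = [
                {"subset": list(r.subset), "median_rmsd": r.median_rmsd}
                for r in reports
            ]
    return bundle


def _flat(cfg: dict) -> dict:
    return {
        k: (json.dumps(v) if isinstance(v, (dict, list)) else v) for k, v in cfg.items()
    }
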