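"""End-to-end orchestration: fingerprints -> tensor -> MPCA -> evaluation.

A run directory receives per-stage outputs (fingerprint CSVs, tensor arrays,
model arrays, feature tables, accuracy curve, scatter data) plus a manifest
recording the config, the seed, every numeric default in force and a hash of
every output file, so reruns are auditable and drift is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import MutantSpec, load_cohort_catalog, parse_mutation_name
from .evaluate import (CLASSIFIER_IDS, FeatureTable, accuracy_vs_H,
                       scatter_selected_features)
from .ifp import (GeometryParams, IFPMatrix, binding_site_residues,
                  perceive_ligand, read_frames, trajectory_ifp)
from .mpca import DiscriminantFeatureSelector, MultilinearPCA
from .synthetic import SimScenario, gen_ifp_tensor
from .tensorize import build_master_index, pad_ifp, stack_and_center

__all__ = ["RunConfig", "run_pipeline", "save_model", "load_model"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    workdir: str = "run"
    seed: int = 0
    # input: either a synthetic preset or structure files per complex
    synthetic_preset: str | None = "default"     # "default" | "null" | None
    complexes: list[dict] = field(default_factory=list)
    # {name, frames, ligand, label} per complex when synthetic_preset is None
    catalog: str | None = None
    geometry: dict = field(default_factory=dict)
    mpca: dict = field(default_factory=lambda: {
        "var_kept": 0.97, "max_iter": 20, "tol": 1e-6,
    })
    evaluation: dict = field(default_factory=lambda: {
        "H_min": 3, "H_max": 20, "folds": 10,
        "classifiers": list(CLASSIFIER_IDS),
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.synthetic_preset is None:
            if not self.complexes:
                raise ValueError(
                    "config needs either a synthetic_preset or a complexes list"
                )
            for c in self.complexes:
                for key in ("frames", "ligand"):
                    if not Path(c[key]).exists():
                        raise FileNotFoundError(
                            f"complex {c.get('name', '?')!r}: missing {key} "
                            f"file {c[key]}"
                        )
        elif self.synthetic_preset not in ("default", "null"):
            raise ValueError(
                f"unknown synthetic preset {self.synthetic_preset!r}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_model(
    out_dir: Path,
    model: MultilinearPCA,
    selector: DiscriminantFeatureSelector,
    projected: np.ndarray,
    names: list[str],
    labels: list[str],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out_dir / "model.npz",
        U1=model.U1_, U2=model.U2_, mean=model.mean_,
        gamma=selector.gamma_, order=selector.order_, projected=projected,
    )
    meta = {
        "n_components": list(model.n_components_),
        "scatter_ratio": model.scatter_ratio_,
        "mode_energy": list(model.mode_energy_),
        "names": names,
        "labels": labels,
        "params": model.get_params(),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir: Path):
    arrays = np.load(Path(model_dir) / "model.npz")
    meta = json.loads((Path(model_dir) / "meta.json").read_text())
    return arrays, meta


def _compute_ifps(config: RunConfig):
    """Stage 1: per-complex fingerprint matrices + labels + specs."""
    if config.synthetic_preset is not None:
        scenario = (SimScenario.null(seed=config.seed)
                    if config.synthetic_preset == "null"
                    else SimScenario(seed=config.seed))
        return gen_ifp_tensor(scenario)
    params = GeometryParams(**config.geometry) if config.geometry else None
    catalog = {s.name: s for s in load_cohort_catalog()}
    matrices, labels, specs = [], [], []
    for entry in config.complexes:
        name = entry["name"]
        spec = catalog.get(name) or parse_mutation_name(name)
        ligand = perceive_ligand(entry["ligand"])
        frames = read_frames(entry["frames"])
        residues = entry.get("residues") or binding_site_residues(
            frames[0], ligand
        )
        mat = trajectory_ifp(frames, residues, ligand, params,
                             complex_name=name, drug=entry.get("drug", ""))
        matrices.append(mat)
        label = entry.get("label") or (
            spec.sensitivity.value if spec.sensitivity else None
        )
        if label is None:
            raise ValueError(f"no sensitivity label for complex {name!r}")
        labels.append(label)
        specs.append(spec)
    return matrices, labels, specs


def run_synthetic_experiment(
    scenario: SimScenario,
    H_values=(3, 10),
    seed: int = 0,
    classifiers=CLASSIFIER_IDS,
):
    """Generate a synthetic cohort and run padding -> MPCA -> CV evaluation.

    Returns ``(curve, projected, labels, names)`` where ``curve`` is the
    cross-validated :class:`~tkisense.evaluate.AccuracyCurve` over
    ``H_values``.
    """
    matrices, labels, specs = gen_ifp_tensor(scenario)
    wt_residues = sorted({
        int(lbl) for m in matrices for lbl in m.residue_labels if lbl.isdigit()
    } | {p for s in specs for e in s.edits
         for p in range(e.start, e.end + 1)})
    master = build_master_index(specs, wt_residues)
    padded = [pad_ifp(m, s, master) for m, s in zip(matrices, specs)]
    tensor = stack_and_center(padded, labels, master=master)
    model = MultilinearPCA(center=False).fit(tensor.data)
    projected = model.transform(tensor.data)
    curve = accuracy_vs_H(projected, labels, names=tensor.names,
                          H_values=H_values, classifiers=classifiers,
                          seed=seed)
    return curve, projected, np.asarray(labels), tensor.names


def run_pipeline(config: RunConfig) -> Path:
    """Execute fingerprints -> padding -> MPCA -> features -> evaluation."""
    config.validate()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    log.info("stage ifp: computing fingerprint matrices")
    matrices, labels, specs = _compute_ifps(config)
    ifp_dir = workdir / "ifp"
    ifp_dir.mkdir(exist_ok=True)
    for m in matrices:
        path = ifp_dir / f"{m.complex_name}.csv"
        m.to_csv(path)
        outputs.append(path)

    log.info("stage tensorize: padding %d samples", len(matrices))
    wt_residues = sorted({
        int(lbl) for m in matrices for lbl in m.residue_labels if lbl.isdigit()
    } | {p for s in specs for e in s.edits
         for p in range(e.start, e.end + 1)})
    master = build_master_index(specs, wt_residues)
    padded = [pad_ifp(m, s, master) for m, s in zip(matrices, specs)]
    tensor = stack_and_center(padded, labels, master=master)
    tensor_dir = workdir / "tensor"
    tensor_dir.mkdir(exist_ok=True)
    np.savez_compressed(tensor_dir / "tensor.npz", data=tensor.data,
                        mean=tensor.mean)
    pd.DataFrame({"name": tensor.names, "label": tensor.labels}).to_csv(
        tensor_dir / "labels.csv", index=False
    )
    (tensor_dir / "master_index.json").write_text(json.dumps(
        [s.label() for s in master.slots], indent=0
    ))
    outputs += [tensor_dir / "tensor.npz", tensor_dir / "labels.csv",
                tensor_dir / "master_index.json"]

    log.info("stage mpca: fitting on tensor %s", tensor.shape)
    model = MultilinearPCA(center=False, **config.mpca).fit(tensor.data)
    projected = model.transform(tensor.data)
    selector = DiscriminantFeatureSelector().fit(projected, np.asarray(labels))
    model_dir = workdir / "model"
    save_model(model_dir, model, selector, projected, tensor.names, labels)
    outputs += [model_dir / "model.npz", model_dir / "meta.json"]

    ev = dict(config.evaluation)
    H_max = min(int(ev.get("H_max", 20)), selector.gamma_.size)
    H_min = min(int(ev.get("H_min", 3)), H_max)
    full = selector.transform(projected)
    table = FeatureTable(names=tensor.names, features=full[:, :H_max],
                         labels=np.asarray(labels))
    features_path = workdir / "features.csv"
    table.to_csv(features_path)
    outputs.append(features_path)

    log.info("stage evaluate: accuracy over H=%d..%d", H_min, H_max)
    curve = accuracy_vs_H(
        projected, labels, names=tensor.names,
        H_values=range(H_min, H_max + 1),
        classifiers=tuple(ev.get("classifiers", CLASSIFIER_IDS)),
        k=int(ev.get("folds", 10)), seed=config.seed,
    )
    curve_path = workdir / "accuracy_curve.csv"
    curve.to_csv(curve_path)
    outputs.append(curve_path)

    scatter_rows = []
    for pair in ((1, 2), (1, 3), (2, 3)):
        if pair[1] <= table.H:
            for cls, d in scatter_selected_features(table, pair).items():
                for x, y_ in d["points"]:
                    scatter_rows.append({
                        "pair": f"{pair[0]}-{pair[1]}", "class": cls,
                        "x": x, "y": y_, "kind": "point",
                    })
                scatter_rows.append({
                    "pair": f"{pair[0]}-{pair[1]}", "class": cls,
                    "x": d["centroid"][0], "y": d["centroid"][1],
                    "kind": "centroid",
                })
    scatter_path = workdir / "scatter.csv"
    pd.DataFrame(scatter_rows).to_csv(scatter_path, index=False)
    outputs.append(scatter_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "geometry_defaults": dataclasses.asdict(GeometryParams()),
        "stages": ["ifp", "tensorize", "mpca", "features", "evaluate"],
        "tensor_shape": list(tensor.shape),
        "n_components": list(model.n_components_),
        "outputs": {
            str(p.relative_to(workdir)): _sha256(p) for p in outputs
        },
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return workdir
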