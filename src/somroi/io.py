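"""NIfTI / CSV / JSON round-tripping for cohorts, models and reports.

Coordinates are 0-based voxel indices throughout; the NIfTI affine is
carried through unchanged but never interpreted — the method operates on a
common co-registered grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from somroi.phantom import PhantomConfig
from somroi.roi import RoiMap
from somroi.som3d import SomConfig, SomModel, lattice_coordinates
from somroi.voxelstats import VolumeStack

__all__ = [
    "save_volume",
    "load_volume",
    "write_cohort",
    "read_cohort",
    "write_roi_table",
    "write_report",
    "save_som_model",
    "load_som_model",
]


def save_volume(volume: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    """Write a 3-D array as NIfTI (identity affine unless one is given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64)


def write_cohort(
    gm_stack: VolumeStack,
    wm_stack: VolumeStack,
    outdir: str | Path,
    config: PhantomConfig | None = None,
) -> Path:
    """Write one NIfTI per subject per tissue plus a manifest CSV.

    The manifest has columns (subject_id, tissue, label, path); a JSON
    sidecar records the generating phantom configuration when given.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for stack in (gm_stack, wm_stack):
        for i in range(stack.n_subjects):
            sid = f"sub-{i:03d}"
            fname = f"{sid}_{stack.tissue}.nii"
            save_volume(stack.volumes[i], outdir / fname)
            rows.append(
                {"subject_id": sid, "tissue": stack.tissue,
                 "label": int(stack.labels[i]), "path": fname}
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if config is not None:
        (outdir / "phantom_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return manifest


def read_cohort(manifest_path: str | Path) -> tuple[VolumeStack, VolumeStack]:
    """Load (GM stack, WM stack) from a manifest CSV.

    Paths are resolved relative to the manifest.  Errors name the offending
    file on a missing volume or a grid mismatch.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "tissue", "label", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(df.columns))}")
    bad = set(df["tissue"]) - {"GM", "WM"}
    if bad:
        raise ValueError(f"unknown tissue tag(s) {sorted(bad)} in manifest")
    stacks = {}
    grid = None
    for tissue, group in df.groupby("tissue"):
        group = group.sort_values("subject_id")
        vols, labels = [], []
        for _, row in group.iterrows():
            p = manifest_path.parent / row["path"]
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
            vol = load_volume(p)
            if grid is None:
                grid = vol.shape
            elif vol.shape != grid:
                raise ValueError(f"grid mismatch in {p}: {vol.shape} vs {grid}")
            try:
                labels.append(int(row["label"]))
            except (TypeError, ValueError):
                raise ValueError(f"unknown label {row['label']!r} for {row['subject_id']}")
            vols.append(vol)
        stacks[tissue] = VolumeStack(np.stack(vols), np.array(labels), tissue)
    for tissue in ("GM", "WM"):
        if tissue not in stacks:
            raise ValueError(f"manifest has no {tissue} rows")
    return stacks["GM"], stacks["WM"]


def write_roi_table(roimap: RoiMap, lattice_coords: np.ndarray, path: str | Path) -> Path:
    """Per-ROI CSV: unit index, lattice coordinates, size, relevance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rel = roimap.relevance if roimap.relevance is not None else np.full(roimap.n_units, np.nan)
    pd.DataFrame(
        {
            "unit": np.arange(roimap.n_units),
            "lat_x": lattice_coords[:, 0],
            "lat_y": lattice_coords[:, 1],
            "lat_z": lattice_coords[:, 2],
            "size": roimap.sizes,
            "relevance": rel,
        }
    ).to_csv(path, index=False)
    return path


def write_report(report, outdir: str | Path, stem: str = "report") -> Path:
    """EvalReport -> JSON summary + per-fold CSV + ROC points CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    json_path = outdir / f"{stem}.json"
    json_path.write_text(json.dumps(d, indent=2))
    pd.DataFrame(d["fold_metrics"]).to_csv(outdir / f"{stem}_folds.csv", index=False)
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        outdir / f"{stem}_roc.csv", index=False
    )
    return json_path


def save_som_model(model: SomModel, outdir: str | Path, stem: str = "som") -> Path:
    """Serialize a SomModel as JSON (config, lattice, QE history) plus a
    plain-text prototype matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "lattice_shape": list(model.lattice_shape),
        "topology": model.topology,
        "config": model.config.to_dict(),
        "qe_history": model.qe_history,
        "scaling_signature": _jsonable(model.scaling_signature),
    }
    (outdir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(outdir / f"{stem}_prototypes.txt", model.prototypes)
    return outdir / f"{stem}.json"


def load_som_model(outdir: str | Path, stem: str = "som") -> SomModel:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}.json").read_text())
    cfg = meta["config"]
    config = SomConfig(
        lattice_shape=tuple(cfg["lattice_shape"]),
        topology=cfg["topology"],
        phase1=_phase_from_dict(cfg["phase1"]),
        phase2=_phase_from_dict(cfg["phase2"]),
        init=cfg["init"],
        seed=cfg["seed"],
        subsample=cfg["subsample"],
    )
    prototypes = np.loadtxt(outdir / f"{stem}_prototypes.txt").reshape(-1, 4)
    sig = meta["scaling_signature"]
    return SomModel(
        prototypes=prototypes,
        lattice_coords=lattice_coordinates(config.lattice_shape),
        topology=meta["topology"],
        lattice_shape=tuple(meta["lattice_shape"]),
        config=config,
        qe_history=list(meta["qe_history"]),
        scaling_signature=_tupleize(sig) if sig is not None else None,
    )


def _phase_from_dict(d: dict):
    from somroi.som3d import PhaseSchedule

    return PhaseSchedule(
        alpha0=d["alpha0"], sigma0=d["sigma0"], epochs=d["epochs"], sigma_floor=d["sigma_floor"]
    )


def _jsonable(obj):
    if isinstance(obj, tuple):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _tupleize(obj):
    if isinstance(obj, list):
        return tuple(_tupleize(o) for o in obj)
    return obj
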