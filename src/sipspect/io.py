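"""File formats: NIfTI volumes, NPZ projection stacks, JSON sidecars.

Conventions (documented in every manifest): arrays are indexed (x, y, z),
0-based, z is the scanner axis; the NIfTI affine is diagonal in the voxel
size (mm).  Projection stacks are stored as compressed NPZ with a JSON
sidecar carrying angles, per-view provenance, frame duration, time point
and any seeds used to produce them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import MASK_NAMES, PhantomConfig, PhantomVolume
from .projector import ProjectionSet
from .recon import ReconVolume
from .sip import SIPModel
from ._nn import UNet

AXIS_CONVENTION = {"axes": "(x, y, z), 0-based voxel indices", "z": "scanner axis"}


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(path: Path | str, data: np.ndarray, voxel_size_mm: float) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), _affine(voxel_size_mm)), str(path))


def load_volume(path: Path | str) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    vs = float(img.header.get_zooms()[0])
    return np.asarray(img.get_fdata(), float), vs


def save_phantom(p: PhantomVolume, outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(outdir / "activity.nii", p.activity, p.voxel_size_mm)
    save_volume(outdir / "mu_map.nii", p.mu_map, p.voxel_size_mm)
    labels = np.zeros(p.activity.shape, dtype=np.uint8)
    for i, name in enumerate(MASK_NAMES, start=1):
        labels[p.masks[name]] = i
    # per-mask files preserve overlaps (spheres inside vertebrae, organs in body)
    for name in MASK_NAMES:
        nib.save(
            nib.Nifti1Image(p.masks[name].astype(np.uint8), _affine(p.voxel_size_mm)),
            str(outdir / f"mask_{name}.nii"),
        )
    manifest = {
        "voxel_size_mm": p.voxel_size_mm,
        "labels": list(MASK_NAMES),
        "seed": p.seed,
        "config": dataclasses.asdict(p.config) if p.config else None,
        "convention": AXIS_CONVENTION,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    if p.texture is not None:
        save_volume(outdir / "texture.nii", p.texture, p.voxel_size_mm)


def load_phantom(outdir: Path | str) -> PhantomVolume:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    activity, vs = load_volume(outdir / "activity.nii")
    mu, _ = load_volume(outdir / "mu_map.nii")
    masks = {}
    for name in MASK_NAMES:
        arr, _ = load_volume(outdir / f"mask_{name}.nii")
        masks[name] = arr > 0.5
    texture = None
    if (outdir / "texture.nii").exists():
        texture, _ = load_volume(outdir / "texture.nii")
    cfg = None
    if manifest.get("config"):
        c = dict(manifest["config"])
        for key in ("shape", "body_semiaxes_frac", "kidney_offset_frac"):
            c[key] = tuple(c[key])
        c["lesion_centers_frac"] = tuple(tuple(x) for x in c["lesion_centers_frac"])
        cfg = PhantomConfig(**c)
    return PhantomVolume(
        activity=activity,
        mu_map=mu,
        voxel_size_mm=manifest["voxel_size_mm"],
        masks=masks,
        texture=texture,
        config=cfg,
        seed=manifest.get("seed"),
    )


def save_projections(p: ProjectionSet, path: Path | str, seed: int | None = None) -> None:
    """NPZ stack plus JSON sidecar (same stem, .json suffix)."""
    path = Path(path)
    np.savez_compressed(path, counts=p.counts)
    sidecar = {
        "angles_deg": p.angles_deg.tolist(),
        "provenance": list(p.provenance),
        "frame_duration_s": p.frame_duration_s,
        "time_point_h": p.time_point_h,
        "seed": seed,
        "convention": AXIS_CONVENTION,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_projections(path: Path | str) -> ProjectionSet:
    path = Path(path)
    if path.suffix != ".npz" and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    counts = np.load(path)["counts"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ProjectionSet(
        counts=counts,
        angles_deg=np.asarray(sidecar["angles_deg"], float),
        provenance=list(sidecar["provenance"]),
        frame_duration_s=sidecar["frame_duration_s"],
        time_point_h=sidecar.get("time_point_h"),
    )


def save_recon(r: ReconVolume, path: Path | str) -> None:
    path = Path(path)
    save_volume(path, r.values, r.voxel_size_mm or 1.0)
    meta = {
        "method_label": r.method_label,
        "iterations": r.iterations,
        "subsets": r.subsets,
        "calibration_factor": r.calibration_factor,
        "voxel_size_mm": r.voxel_size_mm,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_recon(path: Path | str) -> ReconVolume:
    path = Path(path)
    values, vs = load_volume(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ReconVolume(
        values=values,
        method_label=meta["method_label"],
        iterations=meta["iterations"],
        subsets=meta["subsets"],
        calibration_factor=meta["calibration_factor"],
        voxel_size_mm=meta.get("voxel_size_mm", vs),
    )


def save_sip_model(model: SIPModel, path: Path | str) -> None:
    """NPZ of all network weights with a JSON metadata block inside."""
    path = Path(path)
    arrs = {}
    metas = {}
    for o, net in model.offset_models.items():
        meta, weights = net.state_dict()
        metas[str(o)] = meta
        for k, v in weights.items():
            arrs[f"off{o}_{k}"] = v
    header = {
        "loss_tag": model.loss_tag,
        "epochs": model.epochs,
        "seed": model.seed,
        "offsets": sorted(model.offset_models),
        "nets": metas,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrs)


def load_sip_model(path: Path | str) -> SIPModel:
    data = np.load(Path(path))
    header = json.loads(bytes(data["__meta__"]).decode())
    models = {}
    for o in header["offsets"]:
        meta = header["nets"][str(o)]
        weights = {
            k[len(f"off{o}_") :]: data[k] for k in data.files if k.startswith(f"off{o}_")
        }
        models[int(o)] = UNet.from_state(meta, weights)
    return SIPModel(
        offset_models=models,
        loss_tag=header["loss_tag"],
        epochs=header["epochs"],
        seed=header["seed"],
    )
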