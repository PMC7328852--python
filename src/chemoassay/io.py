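"""File formats: TIFF B-scans and confocal stacks, CSV traces, YAML sidecars.

Conventions:

- B-scan: 16-bit greyscale TIFF plus a YAML sidecar (same stem, ``.yaml``)
  holding ``pixel_pitch_um``, ``substrate_row`` and ``refraction_index``.
- Relaxation trace: CSV with header ``time_s,stress_pa`` (or
  ``time_s,force_n`` with the plunger cross-section supplied at read time).
- Confocal stack: one TIFF of shape (3, Z, Y, X), channel order fixed as
  live (green), dead (red), EPS (blue); voxel edge lengths in a YAML
  sidecar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from chemoassay.clsm_quant import CLSMStack
from chemoassay.llct_visco import EvaporationReference, RelaxationRecord
from chemoassay.oct_quant import BScan

__all__ = [
    "write_bscan", "read_bscan",
    "write_relaxation_csv", "read_relaxation_csv",
    "write_reference_csv", "read_reference_csv",
    "write_clsm_stack", "read_clsm_stack",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_bscan(path: str | Path, scan: BScan) -> None:
    path = Path(path)
    px = scan.pixels
    if px.dtype != np.uint16:
        px = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, px)
    meta = {
        "pixel_pitch_um": float(scan.pixel_pitch_um),
        "substrate_row": int(scan.substrate_row),
        "refraction_index": float(scan.refraction_index),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_bscan(path: str | Path, meta_path: str | Path | None = None) -> BScan:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar(path)
    meta = yaml.safe_load(meta_path.read_text())
    return BScan(
        pixels=tifffile.imread(path),
        pixel_pitch_um=float(meta["pixel_pitch_um"]),
        substrate_row=int(meta["substrate_row"]),
        refraction_index=float(meta.get("refraction_index", 1.33)),
    )


def write_relaxation_csv(path: str | Path, record: RelaxationRecord) -> None:
    pd.DataFrame({"time_s": record.time_s,
                  "stress_pa": record.stress_pa}).to_csv(path, index=False)


def read_relaxation_csv(path: str | Path, strain: float = 0.2,
                        duration_s: float = 100.0,
                        plunger_area_mm2: float | None = None
                        ) -> RelaxationRecord:
    """Read a trace; ``time_s,force_n`` files need the plunger area (mm^2)."""
    df = pd.read_csv(path)
    if "stress_pa" in df.columns:
        stress = df["stress_pa"].to_numpy(dtype=float)
    elif "force_n" in df.columns:
        if plunger_area_mm2 is None:
            raise ValueError(
                "force trace needs plunger_area_mm2 to convert to stress")
        stress = df["force_n"].to_numpy(dtype=float) / (plunger_area_mm2 * 1e-6)
    else:
        raise ValueError(f"{path}: expected a stress_pa or force_n column")
    return RelaxationRecord(time_s=df["time_s"].to_numpy(dtype=float),
                            stress_pa=stress, strain=strain,
                            duration_s=duration_s)


def write_reference_csv(path: str | Path, ref: EvaporationReference) -> None:
    pd.DataFrame({"time_s": ref.time_s,
                  "stress_pa": ref.stress_pa}).to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> EvaporationReference:
    df = pd.read_csv(path)
    return EvaporationReference(time_s=df["time_s"].to_numpy(dtype=float),
                                stress_pa=df["stress_pa"].to_numpy(dtype=float))


def write_clsm_stack(path: str | Path, stack: CLSMStack) -> None:
    path = Path(path)
    arr = np.stack(stack.channels).astype(np.float32)
    arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)
    meta = {"voxel_um": [float(v) for v in stack.voxel_um],
            "channel_order": ["live", "dead", "eps"]}
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_clsm_stack(path: str | Path,
                    voxel_um: tuple[float, float, float] | None = None
                    ) -> CLSMStack:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 4 or arr.shape[0] != 3:
        raise ValueError(f"{path}: expected a (3, Z, Y, X) stack, got {arr.shape}")
    if voxel_um is None:
        meta_path = _sidecar(path)
        if meta_path.exists():
            voxel_um = tuple(yaml.safe_load(meta_path.read_text())["voxel_um"])
        else:
            voxel_um = (1.0, 1.0, 1.0)
    return CLSMStack(live=arr[0], dead=arr[1], eps=arr[2], voxel_um=voxel_um)
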