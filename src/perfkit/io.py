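"""File formats, configuration and the end-to-end pipeline.

NIfTI-1 for 4D dynamic series and 3D masks/maps (voxel-index space only;
the 4th dimension is time, with the frame interval taken from the
configuration since NIfTI time units are unreliable in the wild), CSV
for single curves (columns ``time_s,value``), JSON/YAML for
configuration, JSON for the run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .deconv import RegularizationSpec
from .kinetics import ConcentrationCurve, TimeGrid
from .params import MapConfig, ParameterMap, map_volume
from .preprocess import (
    AcquisitionSeries,
    ConversionConfig,
    ct_to_concentration,
    mr_to_concentration,
    auto_aif,
    spatial_smooth,
    tissue_mask,
)

__all__ = [
    "RunConfig",
    "read_dynamic_nifti",
    "write_parameter_maps",
    "read_curve_csv",
    "write_curve_csv",
    "load_config",
    "save_config",
    "run_pipeline",
]

log = logging.getLogger("perfkit")


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Precedence when assembled by the CLI: flag > config file > default.
    The effective config is always dumped into the run report together
    with input hashes, so every output map is reproducible.
    """

    modality: str = "CT"
    dt: float = 1.0
    baseline_frames: int = 4
    te: Optional[float] = None
    k_ct: float = 1.0
    k_mr: float = 1.0
    kappa: float = 0.73
    apply_hct: bool = True
    rho_voi: float = 1.04
    matrix: str = "toeplitz"
    filter: str = "tikhonov"
    lambda_rel: float = 0.2
    selection: str = "fixed"
    oi_threshold: float = 0.1
    lambda_grid: int = 50
    mask_lo: float = 0.0
    mask_hi: float = 100.0
    smoothing_sigma: float = 0.0
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.modality not in ("CT", "MR"):
            raise ValueError("modality must be CT or MR")
        if self.matrix not in ("toeplitz", "circulant"):
            raise ValueError("matrix must be toeplitz or circulant")
        if self.filter not in ("tsvd", "tikhonov"):
            raise ValueError("filter must be tsvd or tikhonov")
        if self.selection not in ("fixed", "oi", "lcurve"):
            raise ValueError("selection must be fixed, oi or lcurve")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.modality == "MR" and (self.te is None or self.te <= 0):
            raise ValueError("MR run needs echo time te > 0 before compute")

    def conversion_config(self) -> ConversionConfig:
        return ConversionConfig(
            k_ct=self.k_ct,
            k_mr=self.k_mr,
            kappa=self.kappa,
            apply_hct=self.apply_hct,
            smoothing_sigma_vox=self.smoothing_sigma,
        )

    def map_config(self) -> MapConfig:
        return MapConfig(
            matrix=self.matrix,
            spec=RegularizationSpec(
                method=self.filter,
                lambda_rel=self.lambda_rel,
                selection=self.selection,
                oi_threshold=self.oi_threshold,
                lcurve_grid=self.lambda_grid,
            ),
            rho=self.rho_voi,
            noise_sd=self.noise_sd,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_dynamic_nifti(path: str | Path, cfg: RunConfig) -> AcquisitionSeries:
    """Load a 4D NIfTI dynamic series; the 4th axis is time, dt and the
    acquisition metadata come from the config."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    return AcquisitionSeries(
        modality=cfg.modality,
        data=data,
        grid=TimeGrid(cfg.dt, data.shape[3]),
        baseline_frames=cfg.baseline_frames,
        te=cfg.te,
    )


def write_parameter_maps(maps: Dict[str, ParameterMap], out_dir: str | Path) -> None:
    """One 3D NIfTI per parameter plus a JSON provenance sidecar each."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, pmap in maps.items():
        img = nib.Nifti1Image(pmap.values.astype(np.float64), affine=np.eye(4))
        nib.save(img, str(out / f"{name}.nii"))
        sidecar = {"name": name, "units": pmap.units, "provenance": pmap.provenance}
        (out / f"{name}.json").write_text(json.dumps(sidecar, indent=2))


def write_mask_nifti(mask: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def read_curve_csv(path: str | Path, label: str = "tissue") -> ConcentrationCurve:
    """Read a curve CSV with header ``time_s,value`` on a uniform grid."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise ValueError(f"{path}: expected columns 'time_s,value', got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    dts = np.diff(t)
    if t.size < 2 or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column must be uniformly spaced")
    grid = TimeGrid(float(dts[0]), t.size)
    return ConcentrationCurve(grid, df["value"].to_numpy(dtype=float), label)


def write_curve_csv(curve: ConcentrationCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": curve.grid.times, "value": curve.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    payload = dataclasses.asdict(cfg)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(payload))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**payload)


def run_pipeline(
    cfg: RunConfig,
    input_path: str | Path,
    out_dir: str | Path,
    aif_csv: Optional[str | Path] = None,
) -> Dict:
    """convert -> (smooth, mask, AIF) -> deconvolve -> maps.

    Writes one NIfTI per parameter plus ``report.json`` with the
    effective config, input hash, AIF provenance and the diagnostic
    summary.  Returns the report dict.
    """
    input_path = Path(input_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("loading %s", input_path)
    series = read_dynamic_nifti(input_path, cfg)
    if cfg.smoothing_sigma > 0:
        log.info("smoothing frames with sigma=%g vox", cfg.smoothing_sigma)
        series.data = spatial_smooth(series.data, cfg.smoothing_sigma)
    mask = tissue_mask(series, cfg.mask_lo, cfg.mask_hi) if cfg.modality == "CT" else None
    conv_cfg = cfg.conversion_config()
    log.info("converting %s signal to concentration", cfg.modality)
    if cfg.modality == "CT":
        conv = ct_to_concentration(series, conv_cfg)
    else:
        conv = mr_to_concentration(series, conv_cfg)
    if mask is None:
        from .preprocess import VoxelMask

        mask = VoxelMask(conv.valid)
    aif_source = "manual-csv"
    if aif_csv is not None:
        aif = read_curve_csv(aif_csv, label="arterial")
        aif_voxels = []
    else:
        # mask the vessels out of the tissue maps but search everywhere for the AIF
        from .preprocess import VoxelMask

        search = VoxelMask(np.isfinite(conv.data).all(axis=3))
        aif, aif_voxels = auto_aif(conv.data, search, conv.grid, cfg.noise_sd)
        aif_source = "auto"
    log.info("AIF from %s (%d voxels)", aif_source, len(aif_voxels))
    conc = conv.data * (cfg.kappa if cfg.apply_hct else 1.0)
    log.info("deconvolving %d voxels", mask.count)
    maps = map_volume(conc, aif, mask, conv.grid, cfg.map_config())
    write_parameter_maps(maps, out)
    prov = next(iter(maps.values())).provenance
    report = {
        "tool": "perfkit",
        "version": __version__,
        "input": str(input_path),
        "input_sha256": _sha256(input_path),
        "config": dataclasses.asdict(cfg),
        "aif_source": aif_source,
        "aif_voxels": [list(v) for v in aif_voxels],
        "parameters": sorted(maps),
        "n_voxels": prov["n_voxels"],
        "n_failed": prov["n_failed"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("wrote %d maps to %s", len(maps), out)
    return report
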