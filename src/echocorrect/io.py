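"""Readers, writers, run configuration and the two-stage pipeline.

Formats: single/multi-page 32-bit float TIFF and NIfTI for images (with a
JSON sidecar carrying geometry and intensity-domain metadata), CSV for
profiles/gain curves/metric reports, YAML for run configuration.

The pipeline applies the two correction stages in a configurable order
(default: eccentricity first, restoring in-plane uniformity, then
inclination, restoring inter-slice consistency) and leaves the output
directory self-describing: corrected images, gain/angle artifacts, a metrics
report, a config echo and a log of all resolved parameters.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .images import ImageSlice, ImageStack
from .inclination import InclinationConfig, InclinationModel
from .metrics import comparison_table, compute_metrics, paired_compare
from .physics import AcousticInterface, AcousticMedium
from .radial import RadialCalibration, RadialGain, RadialProfile

__all__ = [
    "read_image",
    "write_image",
    "gain_to_csv",
    "gain_from_csv",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii", ".gz"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(obj: ImageSlice | ImageStack, path: str | Path, sidecar: bool = True) -> Path:
    """Write a slice or stack as 32-bit float TIFF (multi-page) or NIfTI."""
    import tifffile

    path = Path(path)
    data = obj.pixels.astype(np.float32)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, data)
    elif path.suffix.lower() in _NIFTI_SUFFIXES or path.name.endswith(".nii.gz"):
        import nibabel as nib

        vol = data[np.newaxis, ...] if data.ndim == 2 else data
        # NIfTI axis order (x, y, z); slices stacked along z
        vol = np.moveaxis(vol, 0, -1)
        dz = getattr(obj, "slice_spacing", 1.0)
        affine = np.diag([obj.pixel_spacing, obj.pixel_spacing, dz, 1.0])
        nib.save(nib.Nifti1Image(vol, affine), str(path))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    if sidecar:
        meta = {
            "center_xy": list(obj.center_xy),
            "pixel_spacing": obj.pixel_spacing,
            "domain": obj.domain,
            "tool_version": __version__,
        }
        if isinstance(obj, ImageStack):
            meta["slice_spacing"] = obj.slice_spacing
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(path: str | Path, domain: str | None = None) -> ImageSlice | ImageStack:
    """Read TIFF or NIfTI into a slice (2-D) or stack (3-D, page/z order).

    Geometry comes from the JSON sidecar when present; otherwise pixel
    spacing defaults to 1 mm/px (NIfTI headers override it) with a logged
    warning.  The intensity domain is taken from the sidecar unless the
    ``domain`` flag overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        data = tifffile.imread(path).astype(np.float64)
        spacing = meta.get("pixel_spacing")
        slice_spacing = meta.get("slice_spacing", 1.0)
    elif suffix in _NIFTI_SUFFIXES or path.name.endswith(".nii.gz"):
        import nibabel as nib

        nii = nib.load(str(path))
        vol = np.asanyarray(nii.dataobj, dtype=np.float64)
        zooms = nii.header.get_zooms()
        spacing = float(zooms[0]) if len(zooms) >= 1 else None
        slice_spacing = float(zooms[2]) if len(zooms) >= 3 else 1.0
        data = np.moveaxis(vol, -1, 0) if vol.ndim == 3 else vol
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
    else:
        raise ValueError(
            f"unsupported or unreadable file {path.name!r}: expected TIFF or NIfTI"
        )
    if spacing is None:
        log.warning("%s: no pixel spacing metadata, defaulting to 1 mm/px", path.name)
        spacing = 1.0
    domain = domain or meta.get("domain", "linear")
    center = tuple(meta["center_xy"]) if "center_xy" in meta else None
    if data.ndim == 2:
        return ImageSlice(data, center_xy=center, pixel_spacing=spacing, domain=domain)
    return ImageStack(
        data,
        center_xy=center,
        pixel_spacing=spacing,
        slice_spacing=slice_spacing,
        domain=domain,
    )


# ---------------------------------------------------------------------------
# gain serialization
# ---------------------------------------------------------------------------
def gain_to_csv(profile: RadialProfile, gain: RadialGain, path: str | Path) -> Path:
    """Serialize profile + gain as CSV with a JSON parameter sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "rho_px": gain.radii,
            "s_raw": profile.s_raw,
            "s_smooth": profile.s_smooth,
            "s_norm": profile.s_norm,
            "gain": gain.gain_curve,
            "gain_clipped": gain.gain_clipped,
        }
    )
    df.to_csv(path, index=False)
    params = {
        "epsilon": gain.epsilon,
        "g_max": gain.g_max,
        "r_eff": gain.r_eff,
        "delta": profile.delta,
        "sg_window": profile.meta.get("sg_window"),
        "sg_order": profile.meta.get("sg_order"),
        "center_xy": list(profile.meta.get("center_xy", ())) or None,
        "pixel_spacing": profile.meta.get("pixel_spacing"),
        "tool_version": __version__,
    }
    _sidecar_path(path).write_text(json.dumps(params, indent=1))
    return path


def gain_from_csv(path: str | Path) -> tuple[RadialProfile, RadialGain]:
    path = Path(path)
    df = pd.read_csv(path)
    params = {}
    if _sidecar_path(path).exists():
        params = json.loads(_sidecar_path(path).read_text())
    meta = {
        k: params.get(k)
        for k in ("sg_window", "sg_order", "pixel_spacing")
        if params.get(k) is not None
    }
    if params.get("center_xy"):
        meta["center_xy"] = tuple(params["center_xy"])
    profile = RadialProfile(
        radii=df["rho_px"].to_numpy(),
        s_raw=df["s_raw"].to_numpy(),
        counts=np.ones(len(df)),
        s_smooth=df["s_smooth"].to_numpy(),
        s_norm=df["s_norm"].to_numpy(),
        delta=params.get("delta", 0.5),
        meta=meta,
    )
    gain = RadialGain(
        radii=df["rho_px"].to_numpy(),
        gain_curve=df["gain"].to_numpy(),
        epsilon=params.get("epsilon", 0.0),
        g_max=params.get("g_max", np.inf),
        r_eff=params.get("r_eff", float(df["rho_px"].max())),
        meta=meta,
    )
    return profile, gain


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------
@dataclass
class RunConfig:
    """Configuration of one reproducible correction run.

    Serialises losslessly to/from YAML; every pipeline run echoes the
    resolved config and the tool version into the output directory.
    """

    input: str = ""
    calibration: str | None = None
    outdir: str = "out"
    order: str = "eccentricity_first"  # or inclination_first
    eccentricity_enabled: bool = True
    inclination_enabled: bool = False
    # eccentricity stage
    epsilon: float = 1e-3
    g_max: float = 1.75
    r_eff: float | None = None
    delta: float = 0.5
    sg_window: int = 33
    sg_order: int = 3
    # inclination stage
    c_incident: float = 1480.0
    rho_incident: float = 1000.0
    c_transmit: float = 1540.0
    rho_transmit: float = 1050.0
    kappa: float | str = "auto"
    inc_epsilon: float = 1e-2
    inc_g_max: float = 2.0
    mip_depth: int = 3
    smooth_sigma: float = 5.0
    mode: str = "pressure"
    # metrics
    metrics_test: str = "wilcoxon"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("eccentricity_first", "inclination_first"):
            raise ValueError(f"unknown correction order {self.order!r}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def interface(self) -> AcousticInterface:
        return AcousticInterface(
            incident=AcousticMedium(self.c_incident, self.rho_incident),
            transmit=AcousticMedium(self.c_transmit, self.rho_transmit),
        )


def _as_stack(obj: ImageSlice | ImageStack) -> ImageStack:
    if isinstance(obj, ImageStack):
        return obj
    return ImageStack(
        obj.pixels[np.newaxis],
        center_xy=obj.center_xy,
        pixel_spacing=obj.pixel_spacing,
        domain=obj.domain,
        fov_mask=obj.fov_mask,
        meta=dict(obj.meta),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured correction stages and write all artifacts.

    Returns a report dict with artifact paths, resolved parameters, and the
    metric comparison.  A stage failure aborts with the stage name in the
    exception message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("echocorrect")
    root.addHandler(handler)
    try:
        config.to_yaml(outdir / "config_echo.yaml")
        (outdir / "version.txt").write_text(__version__ + "\n")
        stack = _as_stack(read_image(config.input))
        if stack.domain == "db":
            stack = stack.to_linear()
        report: dict = {"outdir": str(outdir), "stages": [], "version": __version__}

        stages = []
        if config.eccentricity_enabled:
            stages.append("eccentricity")
        if config.inclination_enabled:
            stages.append("inclination")
        if config.order == "inclination_first":
            stages = stages[::-1]
        if not stages:
            report["identity_run"] = True
            log.info("both stages disabled: identity run")

        before = [compute_metrics(s, r_eff=config.r_eff) for s in stack]
        corrected = stack

        for stage in stages:
            try:
                if stage == "eccentricity":
                    if not config.calibration:
                        raise ValueError("eccentricity stage needs a calibration image")
                    cal = read_image(config.calibration)
                    if isinstance(cal, ImageStack):
                        cal = cal[0]
                    result = RadialCalibration(
                        cal, delta=config.delta, window=config.sg_window, order=config.sg_order
                    ).fit(epsilon=config.epsilon, g_max=config.g_max, r_eff=config.r_eff)
                    gain_to_csv(result.profile, result.gain, outdir / "gain.csv")
                    out = np.stack([result.apply(s).pixels for s in corrected])
                    fov = corrected.fov_mask & (corrected.radius_map() <= result.gain.r_eff)
                    corrected = ImageStack(
                        out,
                        center_xy=corrected.center_xy,
                        pixel_spacing=corrected.pixel_spacing,
                        slice_spacing=corrected.slice_spacing,
                        fov_mask=fov,
                        meta=corrected.meta,
                    )
                    report["stages"].append({"stage": stage, "gain_csv": str(outdir / "gain.csv")})
                else:
                    model = InclinationModel(
                        corrected,
                        interface=config.interface(),
                        config=InclinationConfig(
                            kappa=config.kappa,
                            epsilon=config.inc_epsilon,
                            g_max=config.inc_g_max,
                            mip_depth=config.mip_depth,
                            smooth_sigma=config.smooth_sigma,
                            mode=config.mode,
                        ),
                    )
                    result = model.fit()
                    corrected = result.apply()
                    for t, af in result.angle_fields.items():
                        write_image(
                            ImageSlice(af.theta_i, center_xy=corrected.center_xy,
                                       pixel_spacing=corrected.pixel_spacing,
                                       fov_mask=np.ones_like(af.valid_mask)),
                            outdir / f"angles_slice{t:03d}.tif",
                        )
                    report["stages"].append({"stage": stage, "kappa": result.kappa_})
            except Exception as exc:  # noqa: BLE001 - annotate failing stage
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        write_image(corrected, outdir / "corrected.tif")
        after = [compute_metrics(s, r_eff=config.r_eff) for s in corrected]
        if len(before) >= 2:
            table = comparison_table(paired_compare(before, after, test=config.metrics_test))
        else:
            table = pd.DataFrame(
                {
                    "metric": ["RIS", "CPR", "RNU", "CV"],
                    "before_mean": list(before[0].as_dict().values()),
                    "after_mean": list(after[0].as_dict().values()),
                }
            )
        table.to_csv(outdir / "metrics.csv", index=False)
        report["metrics_csv"] = str(outdir / "metrics.csv")
        report["corrected"] = str(outdir / "corrected.tif")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
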