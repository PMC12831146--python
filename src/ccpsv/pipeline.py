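"""End-to-end orchestration: simulate → quantify → aggregate → model.

The pipeline is driven by one declarative :class:`PipelineConfig` (YAML or
JSON on disk) so that every analysis constant — slab geometry, Phansalkar
radius and constants, ring width, grid-cell area, vessel-mask dilation,
model formula sets — is inspectable configuration rather than a buried
constant.  Every output table carries provenance columns (scene id, seed,
config hash), so the parameters behind any number are always recoverable.
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

from .images import (
    EnFaceImage,
    MaskLabel,
    Modality,
    RegionMask,
    ScanGeometry,
    load_enface,
    save_enface,
    save_mask,
)
from .metrics import fd_psv_metrics, psv_area, vfd
from .quantify import (
    PhansalkarParams,
    compensate,
    fd_percent,
    phansalkar_binarize,
    vessel_exclusion_mask,
)
from .synthetic import (
    CohortSimParams,
    SyntheticSceneParams,
    generate_cc_scene,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "ManifestError",
    "run_simulate",
    "run_quantify",
    "run_stats",
    "run_all",
]

log = logging.getLogger("ccpsv")

#: Candidate predictors screened univariably and entered together in the
#: multivariable model (age, axial length, spherical equivalent, choroidal
#: thickness, global CCFD%, PSV area, vessel-to-fovea distance).
DEFAULT_PREDICTORS = [
    "age_y",
    "axl_mm",
    "se_d",
    "ct_um",
    "global_ccfd_pct",
    "area_mm2",
    "vfd_mm",
]


class ManifestError(FileNotFoundError):
    """A scene bundle is missing a required file."""


@dataclass
class StatsConfig:
    response: str = "fd_psv"
    univariable: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    multivariable: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    power_term: str = "axl_mm"


@dataclass
class PipelineConfig:
    """Full pipeline configuration with the published analysis defaults."""

    scene: SyntheticSceneParams = field(default_factory=SyntheticSceneParams)
    cohort: CohortSimParams = field(default_factory=CohortSimParams)
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    ring_width_um: float = 250.0
    vfd_unit_area_mm2: float = 0.1
    masking_dilation_um: float = 30.0
    axl_mm: float | None = None
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self, seed=seed)
        cfg.scene = dataclasses.replace(self.scene, seed=seed)
        cfg.cohort = dataclasses.replace(self.cohort, seed=seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"]["psv_radius_um_range"] = list(d["scene"]["psv_radius_um_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d:
            sc = dict(d["scene"])
            if "psv_radius_um_range" in sc:
                sc["psv_radius_um_range"] = tuple(sc["psv_radius_um_range"])
            d["scene"] = SyntheticSceneParams(**sc)
        if "cohort" in d:
            d["cohort"] = CohortSimParams(**d["cohort"])
        if "phansalkar" in d:
            d["phansalkar"] = PhansalkarParams(**d["phansalkar"])
        if "stats" in d:
            d["stats"] = StatsConfig(**d["stats"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise ManifestError(f"scene bundle is missing the {what} file: {path}")
    return path


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate a scene + cohort fixture bundle on disk.

    Writes 16-bit TIFF slabs (quantized to the file grid), 8-bit PNG truth
    and vessel masks, a uint16 label TIFF with one integer label per PSV
    ROI, the cohort CSV, a ScanGeometry sidecar, and a JSON manifest with
    seeds, parameters and the config hash.  Deterministic: one seed, one
    byte-identical bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulate: seed=%d raster=%d px", config.scene.seed, config.scene.raster_px)
    scene = generate_cc_scene(config.scene)
    save_enface(scene.flow.quantize(16), out / "flow.tif")
    save_enface(scene.structure.quantize(16), out / "structure.tif")
    save_enface(scene.superficial.quantize(16), out / "superficial.tif")
    save_mask(scene.truth_deficit, out / "truth_deficit.png")
    save_mask(scene.vessel_mask, out / "vessel_truth.png")
    labels = np.zeros(scene.flow.shape, dtype=np.uint16)
    for i, roi in enumerate(scene.psv_rois, start=1):
        labels[roi.pixels] = i
    import tifffile

    tifffile.imwrite(out / "psv_labels.tif", labels)
    geom = dataclasses.replace(scene.geometry, axl_mm=config.axl_mm)
    geom.to_json(out / "geometry.json")
    cohort = generate_cohort(config.cohort)
    cohort.insert(0, "scene_id", f"scene-{config.scene.seed:06d}")
    cohort["seed"] = config.cohort.seed
    cohort["config_hash"] = config.config_hash
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest = {
        "scene_id": f"scene-{config.scene.seed:06d}",
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "n_psv": len(scene.psv_rois),
        "fovea_xy_mm": list(scene.fovea_xy),
        "files": [
            "flow.tif",
            "structure.tif",
            "superficial.tif",
            "truth_deficit.png",
            "vessel_truth.png",
            "psv_labels.tif",
            "geometry.json",
            "cohort.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def load_scene_bundle(
    scene_dir: str | Path,
) -> tuple[EnFaceImage, EnFaceImage, EnFaceImage, list[RegionMask], ScanGeometry, dict]:
    """Load a simulated bundle's images, PSV ROIs, geometry and manifest."""
    d = Path(scene_dir)
    manifest = json.loads(_require(d / "manifest.json", "manifest").read_text())
    geom = ScanGeometry.from_json(_require(d / "geometry.json", "geometry"))
    pitch = geom.pitch_um
    flow = load_enface(_require(d / "flow.tif", "flow slab"), pitch, Modality.FLOW)
    structure = load_enface(
        _require(d / "structure.tif", "structure slab"), pitch, Modality.STRUCTURE
    )
    superficial = load_enface(
        _require(d / "superficial.tif", "superficial slab"), pitch, Modality.SUPERFICIAL
    )
    import tifffile

    labels = tifffile.imread(_require(d / "psv_labels.tif", "PSV label mask"))
    rois = [
        RegionMask(labels == i, pitch, MaskLabel.PSV_ROI)
        for i in range(1, int(labels.max()) + 1)
    ]
    return flow, structure, superficial, rois, geom, manifest


def run_quantify(config: PipelineConfig, scene_dir: str | Path) -> pd.DataFrame:
    """Quantify a scene bundle into one row of metrics per PSV.

    Chain: compensation → Phansalkar binarization → large-vessel exclusion
    → global CCFD%, and per ROI: FDPSV, FD250, magnification-corrected
    area, VFD with X/Y offsets.  Writes ``psv_metrics.csv`` into the scene
    directory and returns the table.  Deterministic for fixed inputs.
    """
    d = Path(scene_dir)
    flow, structure, superficial, rois, geom, manifest = load_scene_bundle(d)
    comp = compensate(flow, structure)
    deficit = phansalkar_binarize(comp, config.phansalkar)
    exclusion = vessel_exclusion_mask(superficial, config.masking_dilation_um)
    global_fd = fd_percent(deficit, exclusion)
    fovea = tuple(manifest.get("fovea_xy_mm", geom.center_mm))
    log.info(
        "quantify: %s global CCFD%%=%.2f (evaluable %d px)",
        manifest["scene_id"], global_fd.ccfd_percent, global_fd.evaluable_px,
    )
    rows = []
    for i, roi in enumerate(rois, start=1):
        fd_psv, fd_250 = fd_psv_metrics(
            deficit, exclusion, roi, geom, config.ring_width_um
        )
        v = vfd(roi, fovea, geom, config.vfd_unit_area_mm2)
        rows.append(
            {
                "scene_id": manifest["scene_id"],
                "psv_id": f"{manifest['scene_id']}_P{i:02d}",
                "fd_psv": fd_psv,
                "fd_250": fd_250,
                "global_ccfd_pct": global_fd.ccfd_percent,
                "area_mm2": psv_area(roi, geom),
                "vfd_mm": v.vfd_mm,
                "x_off_mm": v.x_off_mm,
                "y_off_mm": v.y_off_mm,
                "vfd_n_cells": v.n_cells,
                "seed": config.scene.seed,
                "config_hash": config.config_hash,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "scene_id", "psv_id", "fd_psv", "fd_250", "global_ccfd_pct",
            "area_mm2", "vfd_mm", "x_off_mm", "y_off_mm", "vfd_n_cells",
            "seed", "config_hash",
        ],
    )
    table.to_csv(d / "psv_metrics.csv", index=False)
    return table


def _diagnostic_plots(result, table: pd.DataFrame, response: str, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fitted = table["_fitted"]
    resid = table[response] - fitted
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(fitted, resid, s=8, alpha=0.6)
    axes[0].axhline(0.0, color="k", lw=0.8)
    axes[0].set_xlabel("fitted (fixed effects)")
    axes[0].set_ylabel("residual")
    axes[0].set_title("Residuals vs fitted")
    from scipy import stats as sps

    sps.probplot(resid, dist="norm", plot=axes[1])
    axes[1].set_title("Normal Q-Q")
    fig.tight_layout()
    fig.savefig(out / "diagnostics.png", dpi=120)
    plt.close(fig)


def run_stats(
    config: PipelineConfig,
    cohort_csv: str | Path | pd.DataFrame,
    out_dir: str | Path | None = None,
    make_plots: bool = True,
) -> dict:
    """Run the statistical stage on a per-PSV cohort table.

    Produces the Spearman screen, one univariable mixed model per
    configured predictor, the single multivariable mixed model, the VIF
    table, a post-hoc power estimate for the configured term, and (when
    requested) residual/Q-Q diagnostic plots.  Tables are written as CSV
    and a combined JSON report when ``out_dir`` is given.
    """
    from .stats import (
        PowerInput,
        fit_mixed,
        posthoc_power,
        spearman_screen,
        vif,
    )

    table = (
        cohort_csv.copy()
        if isinstance(cohort_csv, pd.DataFrame)
        else pd.read_csv(cohort_csv)
    )
    sc = config.stats
    missing = [c for c in sc.univariable + [sc.response] if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if table["subject_id"].nunique() < 2:
        raise ValueError("at least 2 subjects are required for the mixed models")

    spearman = spearman_screen(table, sc.response, sc.univariable)
    univariable = {
        pred: fit_mixed(table, sc.response, [pred]) for pred in sc.univariable
    }
    multivariable = fit_mixed(table, sc.response, sc.multivariable)
    vifs = vif(table, sc.multivariable)

    power = None
    if sc.power_term in [t.name for t in multivariable.terms]:
        t = multivariable.term(sc.power_term)
        se = (t.ci_high - t.ci_low) / (2 * 1.959963984540054)
        power = posthoc_power(
            PowerInput(
                beta_hat=t.estimate,
                se=se,
                n_eff=multivariable.n_subjects,
                n_predictors=len(sc.multivariable),
            )
        )

    report = {
        "response": sc.response,
        "n_obs": multivariable.n_obs,
        "n_subjects": multivariable.n_subjects,
        "n_eyes": multivariable.n_eyes,
        "spearman": [dataclasses.asdict(t) for t in spearman],
        "univariable": {
            pred: [dataclasses.asdict(t) for t in m.terms]
            for pred, m in univariable.items()
        },
        "multivariable": [dataclasses.asdict(t) for t in multivariable.terms],
        "multivariable_r2": multivariable.r2,
        "variance_components": {
            "subject": multivariable.var_subject,
            "eye": multivariable.var_eye,
            "residual": multivariable.var_resid,
        },
        "vif": dict(vifs),
        "posthoc_power": power,
        "config_hash": config.config_hash,
    }
    result = {
        "spearman": spearman,
        "univariable": univariable,
        "multivariable": multivariable,
        "vif": vifs,
        "posthoc_power": power,
        "report": report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [dataclasses.asdict(t) for t in spearman]
        ).to_csv(out / "spearman.csv", index=False)
        multivariable.to_frame().to_csv(out / "multivariable.csv", index=False)
        pd.concat(
            [m.to_frame().assign(predictor=p) for p, m in univariable.items()]
        ).to_csv(out / "univariable.csv", index=False)
        pd.DataFrame(vifs, columns=["predictor", "vif"]).to_csv(
            out / "vif.csv", index=False
        )
        (out / "report.json").write_text(json.dumps(report, indent=2))
        if make_plots:
            import numpy as _np

            X = table[sc.multivariable].to_numpy(dtype=float)
            beta = {t.name: t.estimate for t in multivariable.terms}
            fitted = beta.get("Intercept", 0.0) + X @ _np.array(
                [beta[p] for p in sc.multivariable]
            )
            tmp = table.copy()
            tmp["_fitted"] = fitted
            _diagnostic_plots(multivariable, tmp, sc.response, out)
    return result


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """simulate → quantify → stats in one call; returns the stats result."""
    out = Path(out_dir)
    scene_dir = run_simulate(config, out / "scene")
    run_quantify(config, scene_dir)
    return run_stats(config, scene_dir / "cohort.csv", out / "stats")
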