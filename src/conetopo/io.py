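"""CSV readers/writers, analysis configuration and the end-to-end pipeline.

All tabular I/O is plain CSV.  Schemas:

* cone coordinates — ``x_px,y_px`` (image pixels, 0-based, x right / y down)
* biometry / cohort — ``subject,eye,axial_length_mm,corneal_radius_mm,acd_mm``
  plus optional density/displacement columns in the reference-table schema
* fixation traces — ``frame,x_arcmin,y_arcmin``

The packaged 28-eye reference cohort (biometry, RMF, peak and PRL cone
densities) loads with :func:`load_reference_cohort`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, fixation_prl, mosaic_density, sampling_limits
from .mosaic_density import ConeMosaic, DensityMap
from .fixation_prl import FixationTrace
from .schematic_eye import Biometry, SchematicConstants, rmf_from_biometry

logger = logging.getLogger("conetopo")

__all__ = [
    "AnalysisConfig",
    "SchemaError",
    "read_cone_csv",
    "read_trace_csv",
    "read_biometry_csv",
    "write_density_csv",
    "write_density_image",
    "plot_cohort_regressions",
    "load_reference_cohort",
    "EyeInput",
    "run_pipeline",
]

BIOMETRY_COLUMNS = ("subject", "eye", "axial_length_mm", "corneal_radius_mm", "acd_mm")


class SchemaError(ValueError):
    """A CSV file does not match its declared schema."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters; defaults are the reference protocol values."""

    window_diameter_arcmin: float = 10.0
    grid_step_px: int = 1
    annulus_width_arcmin: float = 5.0
    annulus_width_um: float = 25.0
    bcea_coverage: float = 0.68
    unit_mode: str = "angular-window"   # or "micron-window"
    pixels_per_arcmin: float = 9.48
    seed: int = 0
    constants: SchematicConstants = field(default_factory=SchematicConstants)
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.unit_mode not in ("angular-window", "micron-window"):
            raise ValueError("unit_mode must be 'angular-window' or 'micron-window'")
        if self.grid_step_px <= 0:
            raise ValueError("grid_step_px must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        const = raw.pop("constants", None)
        cfg = cls(**raw)
        if const:
            cfg = replace(cfg, constants=SchematicConstants(**const))
        return cfg


def _read_csv_strict(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            # +2: one for the header row, one for 1-based line numbers
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise SchemaError(f"{name}: non-numeric value(s) in '{c}' at line(s) {lines}")
        df[c] = coerced
    return df


def read_cone_csv(
    path: str | Path,
    pixels_per_arcmin: float = 9.48,
    rmf_um_per_deg: float = float("nan"),
    eye_id: str = "",
) -> ConeMosaic:
    """Load labeled cone coordinates (``x_px,y_px``) into a ConeMosaic."""
    df = _read_csv_strict(path, ("x_px", "y_px"))
    df = _require_numeric(df, ["x_px", "y_px"], Path(path).name)
    return ConeMosaic(
        cone_xy=df[["x_px", "y_px"]].to_numpy(),
        pixels_per_arcmin=pixels_per_arcmin,
        rmf_um_per_deg=rmf_um_per_deg,
        eye_id=eye_id or Path(path).stem,
    )


def write_cone_csv(mosaic: ConeMosaic, path: str | Path) -> None:
    pd.DataFrame(mosaic.cone_xy, columns=["x_px", "y_px"]).to_csv(path, index=False)


def read_trace_csv(path: str | Path, eye_id: str = "") -> FixationTrace:
    """Load a fixation trace (``frame,x_arcmin,y_arcmin``)."""
    df = _read_csv_strict(path, ("frame", "x_arcmin", "y_arcmin"))
    df = _require_numeric(df, ["x_arcmin", "y_arcmin"], Path(path).name)
    return FixationTrace(
        xy_arcmin=df[["x_arcmin", "y_arcmin"]].to_numpy(),
        eye_id=eye_id or Path(path).stem,
    )


def write_trace_csv(trace: FixationTrace, path: str | Path) -> None:
    df = pd.DataFrame(trace.xy_arcmin, columns=["x_arcmin", "y_arcmin"])
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_biometry_csv(path: str | Path) -> pd.DataFrame:
    """Load a per-eye biometry/cohort table; validates the core schema."""
    df = _read_csv_strict(path, BIOMETRY_COLUMNS)
    numeric = [c for c in df.columns if c not in ("subject", "eye", "gender", "ethnicity")]
    df = _require_numeric(df, numeric, Path(path).name)
    dup = df.duplicated(subset=["subject", "eye"])
    if dup.any():
        lines = ", ".join(str(i + 2) for i in df.index[dup][:5])
        raise SchemaError(f"{Path(path).name}: duplicate (subject, eye) at line(s) {lines}")
    return df


def write_density_csv(dmap: DensityMap, path: str | Path, which: str = "angular") -> None:
    """Export a density map as a CSV grid (rows = y, columns = x, px)."""
    if which not in ("angular", "linear"):
        raise ValueError("which must be 'angular' or 'linear'")
    grid = getattr(dmap, which)
    out = pd.DataFrame(grid, index=dmap.y_px, columns=dmap.x_px)
    out.index.name = "y_px"
    out.to_csv(path)


def write_density_image(
    dmap: DensityMap, path: str | Path, which: str = "angular", cmap: str = "viridis"
) -> None:
    """Render a density map as a colormapped image (PNG/TIFF by extension).

    Invalid (boundary-crossing) cells are masked out.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.where(dmap.valid_mask, getattr(dmap, which), np.nan)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        grid,
        origin="upper",
        cmap=cmap,
        extent=(dmap.x_px[0], dmap.x_px[-1], dmap.y_px[-1], dmap.y_px[0]),
    )
    unit = "cones/deg$^2$" if which == "angular" else "cones/mm$^2$"
    fig.colorbar(im, ax=ax, label=unit)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_cohort_regressions(
    table: pd.DataFrame, path: str | Path, x_col: str = "axial_length_mm"
) -> None:
    """Scatter + trendline panels of each headline density column vs axial
    length; trendlines are solid when p < 0.05 and dashed otherwise."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in cohort_stats.HEADLINE_REGRESSIONS if c in table.columns]
    fig, axes = plt.subplots(2, 2, figsize=(10, 8), squeeze=False)
    for ax, col in zip(axes.ravel(), cols):
        x = table[x_col].to_numpy()
        y = table[col].to_numpy()
        r = cohort_stats.ols_fit(x, y)
        ax.plot(x, y, "o", ms=4)
        xx = np.linspace(x.min(), x.max(), 2)
        style = "-" if r.significant else "--"
        ax.plot(xx, r.intercept + r.slope * xx, style, color="k")
        ax.set_title(f"{col}\nslope={r.slope:.0f}, p={r.p_value:.3g}", fontsize=9)
        ax.set_xlabel("axial length (mm)")
    for ax in axes.ravel()[len(cols):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def load_reference_cohort() -> pd.DataFrame:
    """The packaged 28-eye (16-subject) reference cohort table."""
    with resources.files("conetopo.data").joinpath("reference_cohort.csv").open("rb") as fh:
        return pd.read_csv(fh)


# ----------------------------------------------------------------- pipeline

@dataclass
class EyeInput:
    """Everything the per-eye stage needs for one eye."""

    eye_id: str
    biometry: Biometry
    mosaic: ConeMosaic | None = None
    trace: FixationTrace | None = None


def _analyze_eye(inp: EyeInput, config: AnalysisConfig) -> dict:
    rec: dict = {"eye_id": inp.eye_id}
    para = rmf_from_biometry(inp.biometry, config.constants)
    rec["axial_length_mm"] = inp.biometry.axial_length_mm
    rec["an_prime_mm"] = para.nodal_point_2_mm
    rec["rmf_um_per_deg"] = para.rmf_um_per_deg

    if inp.mosaic is not None:
        mosaic = inp.mosaic
        if not np.isfinite(mosaic.rmf_um_per_deg):
            mosaic.rmf_um_per_deg = para.rmf_um_per_deg
        dmap = mosaic_density.density_map(
            mosaic, step_px=config.grid_step_px, diameter_arcmin=config.window_diameter_arcmin
        )
        (px, py), d_ang, d_lin = mosaic_density.find_peak(dmap)
        if config.unit_mode == "micron-window":
            diameter_um = config.window_diameter_arcmin * para.rmf_um_per_deg / 60.0
            _, d_lin, _ = mosaic_density.window_density_um(mosaic, (px, py), diameter_um)
        rec.update(
            peak_x_px=px, peak_y_px=py,
            peak_angular_density=d_ang, peak_linear_density=d_lin,
        )
        est = sampling_limits.sampling_estimate(d_ang)
        rec.update(nyquist_cpd=est.nyquist_cpd, spacing_arcmin=est.spacing_arcmin)

        if inp.trace is not None:
            prl = fixation_prl.fit_fixation_ellipse(inp.trace, coverage=config.bcea_coverage)
            peak_arcmin = (px / mosaic.pixels_per_arcmin, py / mosaic.pixels_per_arcmin)
            metrics = fixation_prl.prl_metrics(
                prl, peak_arcmin, para.rmf_um_per_deg, mosaic, config.window_diameter_arcmin
            )
            rec.update(
                prl_x_arcmin=prl.centroid_arcmin[0],
                prl_y_arcmin=prl.centroid_arcmin[1],
                bcea_arcmin2=metrics["bcea_arcmin2"],
                bcea_um2=metrics["bcea_um2"],
                prl_distance_arcmin=metrics["displacement_arcmin"],
                prl_distance_um=metrics["displacement_um"],
                prl_angular_density=metrics["prl_angular_density"],
                prl_linear_density=metrics["prl_linear_density"],
            )
    return rec


def run_pipeline(
    config: AnalysisConfig, inputs: list[EyeInput]
) -> tuple[pd.DataFrame, dict[str, cohort_stats.RegressionResult], pd.DataFrame]:
    """Run every analysis stage over a list of eyes.

    Returns ``(per_eye_table, regressions, summary)``.  A failure in one eye
    is logged with its reason and recorded in the table (``error`` column);
    it does not abort the run.  Deterministic given inputs and config.
    """
    records = []
    for inp in inputs:
        try:
            records.append(_analyze_eye(inp, config))
        except Exception as exc:  # per-eye isolation is the contract
            logger.error("eye %s failed: %s", inp.eye_id, exc)
            records.append({"eye_id": inp.eye_id, "error": str(exc)})
    per_eye = pd.DataFrame(records)
    per_eye.attrs["config_hash"] = config.config_hash()
    per_eye.attrs["seed"] = config.seed

    regressions: dict[str, cohort_stats.RegressionResult] = {}
    ok = per_eye[per_eye.get("error").isna()] if "error" in per_eye else per_eye
    for col in cohort_stats.HEADLINE_REGRESSIONS:
        if col in ok.columns and ok[col].notna().sum() >= 3:
            regressions[col] = cohort_stats.ols_fit(
                ok["axial_length_mm"][ok[col].notna()], ok[col].dropna()
            )
    numeric = ok.select_dtypes(include=[np.number])
    summary = cohort_stats.cohort_summary(ok) if len(numeric) else pd.DataFrame()
    logger.info(
        "pipeline complete: %d eyes, config %s, seed %d",
        len(per_eye), config.config_hash(), config.seed,
    )
    return per_eye, regressions, summary
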