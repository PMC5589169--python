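"""Seeded synthetic cohorts of Laurdan-imaged red blood cells.

No public image data exist for this problem, so every downstream stage is
exercised against a simulator that emulates the study design:

* three clinical groups — G0 (healthy control), G1 (type-1 diabetes, no
  complications, < 15 years since diagnosis) and G2 (complications,
  >= 15 years);
* per cell, an annular membrane footprint (the dye labels only the plasma
  membrane) carrying a spatially smooth GP field around a group-dependent
  base level, on which circular *fluid domains* (GP lowered inside a disc of
  diameter 0.5–1 µm) nucleate with a group-dependent Poisson density —
  domains increase in number from G0 to G2, shifting the GP distribution
  down and widening it;
* a two-channel renderer that inverts the GP definition to per-band photon
  rates and applies Poisson shot noise;
* class-conditional clinical covariates: HbA1c separates controls from
  diabetics but G1 and G2 are matched for metabolic control; cholesterol and
  LDL drift upward with disease stage; disease duration respects the
  <15 / >=15 year split; diabetics receive MDI or CSII insulin therapy, with
  CSII associated with a more fluid membrane (a configurable GP offset).

All ground truth (cluster geometry, true per-image GP statistics) is kept in
a ledger so tests can compare estimates against it.  A cohort is a pure
function of its :class:`CohortConfig`, including the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateInputError, ParameterError, ShapeMismatchError
from .gp_imaging import BLUE_BAND, GREEN_BAND, ChannelImage

GROUPS = ("G0", "G1", "G2")
THERAPIES = ("none", "MDI", "CSII")

#: Expected fluid-domain counts per cell used for the default densities.
DEFAULT_CLUSTERS_PER_CELL = {"G0": 0.0, "G1": 40.0, "G2": 120.0}


def _annulus_area_um2(outer_um: float, inner_um: float) -> float:
    return float(np.pi * (outer_um**2 - inner_um**2))


@dataclass(frozen=True)
class MembraneFieldParams:
    """Ground-truth membrane GP field parameters (per-group where dicts).

    ``base_gp_mean`` defaults (0.45 / 0.40 / 0.33) are declared simulation
    values chosen to reproduce the qualitative group ordering — absolute GP
    levels per group are not published for this assay.
    """

    base_gp_mean: dict[str, float] = field(
        default_factory=lambda: {"G0": 0.45, "G1": 0.40, "G2": 0.33}
    )
    base_gp_sd: float = 0.03
    gp_correlation_length_um: float = 1.0
    cluster_density_per_um2: dict[str, float] = field(default_factory=dict)
    cluster_diameter_nm: tuple[float, float] = (500.0, 1000.0)
    cluster_gp_drop: float = 0.2
    cell_outer_radius_um: float = 3.5
    cell_inner_radius_um: float = 2.5
    photon_budget: float = 2000.0
    background_level: float = 20.0
    g_factor: float = 1.0
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.cluster_density_per_um2:
            area = self.membrane_area_um2
            object.__setattr__(
                self,
                "cluster_density_per_um2",
                {g: n / area for g, n in DEFAULT_CLUSTERS_PER_CELL.items()},
            )
        lo, hi = self.cluster_diameter_nm
        if not (0 < lo < hi):
            raise ParameterError("cluster_diameter_nm must satisfy 0 < low < high")
        if self.cluster_gp_drop <= 0:
            raise ParameterError("cluster_gp_drop must be positive")
        if not (0 < self.cell_inner_radius_um < self.cell_outer_radius_um):
            raise ParameterError("need 0 < inner radius < outer radius")
        if self.photon_budget <= 0:
            raise ParameterError("photon_budget must be positive")
        if self.g_factor <= 0:
            raise ParameterError("g_factor must be positive")
        if self.base_gp_sd < 0 or self.background_level < 0 or self.read_noise_sd < 0:
            raise ParameterError("sd and background parameters must be non-negative")
        dens = self.cluster_density_per_um2
        if any(dens[g] < 0 for g in GROUPS):
            raise ParameterError("cluster densities must be non-negative")
        if not dens["G0"] <= dens["G1"] <= dens["G2"]:
            raise ParameterError("cluster density must be non-decreasing G0 -> G2")

    @property
    def membrane_area_um2(self) -> float:
        return _annulus_area_um2(self.cell_outer_radius_um, self.cell_inner_radius_um)

    def with_expected_clusters(
        self, counts: tuple[float, float, float]
    ) -> "MembraneFieldParams":
        """Return params whose densities give the stated expected counts per cell."""
        area = self.membrane_area_um2
        return replace(
            self,
            cluster_density_per_um2={g: c / area for g, c in zip(GROUPS, counts)},
        )


@dataclass(frozen=True)
class CovariateParams:
    """Class-conditional clinical covariate distributions (Gaussian unless noted).

    G1 and G2 share the same HbA1c distribution: the emulated cohorts are
    matched for metabolic control, so HbA1c separates only controls from
    diabetics.  HbA1c spread gives the control group a coefficient of
    variation near 0.2, an order of magnitude wider (relative to trend) than
    the GP readout.
    """

    hba1c_mean: dict[str, float] = field(
        default_factory=lambda: {"G0": 5.3, "G1": 7.9, "G2": 7.9}
    )
    hba1c_sd: dict[str, float] = field(
        default_factory=lambda: {"G0": 1.05, "G1": 1.2, "G2": 1.2}
    )
    cholesterol_mean: dict[str, float] = field(
        default_factory=lambda: {"G0": 170.0, "G1": 185.0, "G2": 205.0}
    )
    cholesterol_sd: dict[str, float] = field(
        default_factory=lambda: {"G0": 25.0, "G1": 28.0, "G2": 30.0}
    )
    ldl_mean: dict[str, float] = field(
        default_factory=lambda: {"G0": 95.0, "G1": 108.0, "G2": 122.0}
    )
    ldl_sd: dict[str, float] = field(
        default_factory=lambda: {"G0": 20.0, "G1": 22.0, "G2": 24.0}
    )
    duration_years_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"G1": (1.0, 14.0), "G2": (15.0, 34.0)}
    )
    p_csii: float = 0.5
    insulin_mean: dict[str, float] = field(
        default_factory=lambda: {"MDI": 0.62, "CSII": 0.45}
    )
    insulin_sd: dict[str, float] = field(
        default_factory=lambda: {"MDI": 0.15, "CSII": 0.12}
    )
    insulin_floor: float = 0.1
    therapy_gp_offset: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "MDI": 0.0, "CSII": -0.08}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.p_csii <= 1:
            raise ParameterError("p_csii must lie in [0, 1]")
        lo1, hi1 = self.duration_years_range["G1"]
        lo2, _ = self.duration_years_range["G2"]
        if hi1 >= 15.0 or lo2 < 15.0 or lo1 < 0:
            raise ParameterError("duration ranges must respect the <15 / >=15 split")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to deterministically generate one cohort."""

    n_per_group: tuple[int, int, int] = (8, 11, 7)
    images_per_patient: int = 10
    image_size_px: int = 256
    pixel_size_nm: float = 200.0
    field_params: MembraneFieldParams = field(default_factory=MembraneFieldParams)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group):
            raise ParameterError("n_per_group counts must be >= 0")
        if self.images_per_patient <= 0 or self.image_size_px <= 0:
            raise ParameterError("images_per_patient and image_size_px must be positive")
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        d["field_params"]["cluster_diameter_nm"] = list(
            self.field_params.cluster_diameter_nm
        )
        d["covariate_params"]["duration_years_range"] = {
            k: list(v) for k, v in self.covariate_params.duration_years_range.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        fp = dict(d.pop("field_params", {}))
        if "cluster_diameter_nm" in fp:
            fp["cluster_diameter_nm"] = tuple(fp["cluster_diameter_nm"])
        cp = dict(d.pop("covariate_params", {}))
        if "duration_years_range" in cp:
            cp["duration_years_range"] = {
                k: tuple(v) for k, v in cp["duration_years_range"].items()
            }
        return cls(
            n_per_group=tuple(d.pop("n_per_group", (8, 11, 7))),
            field_params=MembraneFieldParams(**fp),
            covariate_params=CovariateParams(**cp),
            **d,
        )


@dataclass(frozen=True)
class GPField:
    """One simulated ground-truth membrane GP field."""

    values: np.ndarray
    mask: np.ndarray
    cluster_centers_px: np.ndarray  # (n, 2) row/col
    cluster_radii_px: np.ndarray
    true_mean_gp: float
    true_var_gp: float

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_radii_px.size)


@dataclass
class PatientRecord:
    """Clinical covariates plus an ordered z-stack of two-channel image pairs."""

    id: str
    group: str
    hba1c_pct: float
    cholesterol_mg_dl: float
    ldl_mg_dl: float
    insulin_u_per_kg: float
    therapy: str
    duration_years: float
    stack: list[tuple[ChannelImage, ChannelImage]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}")
        if self.therapy not in THERAPIES:
            raise ParameterError(f"therapy must be one of {THERAPIES}")
        if (self.therapy == "none") != (self.group == "G0"):
            raise ParameterError("therapy is 'none' iff group is G0")
        if self.group == "G0" and (self.duration_years != 0 or self.insulin_u_per_kg != 0):
            raise ParameterError("G0 patients have zero duration and insulin dose")
        if self.group == "G1" and not 0 <= self.duration_years < 15:
            raise ParameterError("G1 duration must be < 15 years")
        if self.group == "G2" and not self.duration_years >= 15:
            raise ParameterError("G2 duration must be >= 15 years")

    def covariates(self) -> dict:
        return {
            "patient": self.id,
            "group": self.group,
            "hba1c_pct": self.hba1c_pct,
            "cholesterol_mg_dl": self.cholesterol_mg_dl,
            "ldl_mg_dl": self.ldl_mg_dl,
            "insulin_u_per_kg": self.insulin_u_per_kg,
            "therapy": self.therapy,
            "duration_years": self.duration_years,
        }


@dataclass
class Cohort:
    patients: list[PatientRecord]
    ledger: dict
    config: CohortConfig

    def covariate_frame(self):
        import pandas as pd

        return pd.DataFrame([p.covariates() for p in self.patients])


# --------------------------------------------------------------------------
# Field simulation
# --------------------------------------------------------------------------

def simulate_gp_field(
    group: str,
    params: MembraneFieldParams,
    rng: np.random.Generator,
    image_size_px: int = 256,
    pixel_size_nm: float = 200.0,
    gp_offset: float = 0.0,
) -> GPField:
    """Ground-truth GP field for one cell of the given group.

    An annular cell footprint is placed centrally with jitter; the membrane
    GP is a smooth field around the group base level; fluid domains are
    circular discs (Poisson count proportional to membrane area, diameters
    uniform in the configured range) each lowering GP by ``cluster_gp_drop``;
    overlaps stack and values are clamped to [-1, 1].
    """
    if group not in GROUPS:
        raise ParameterError(f"group must be one of {GROUPS}")
    px_um = pixel_size_nm / 1000.0
    outer_px = params.cell_outer_radius_um / px_um
    inner_px = params.cell_inner_radius_um / px_um

    jitter = rng.uniform(-0.05, 0.05, size=2) * image_size_px
    center = image_size_px / 2.0 + jitter
    rows, cols = np.ogrid[:image_size_px, :image_size_px]
    dist = np.hypot(rows - center[0], cols - center[1])
    mask = (dist >= inner_px) & (dist <= outer_px)
    if not mask.any():
        raise DegenerateInputError(
            "cell footprint has zero area at this image size / pixel pitch"
        )

    # smooth background GP: low-pass filtered white noise at the configured
    # correlation length, rescaled to base_gp_sd
    white = rng.standard_normal((image_size_px, image_size_px))
    sigma_px = params.gp_correlation_length_um / px_um
    smooth = gaussian_filter(white, sigma=sigma_px)
    sd = smooth.std()
    if sd > 0 and params.base_gp_sd > 0:
        smooth = smooth * (params.base_gp_sd / sd)
    else:
        smooth = np.zeros_like(smooth)
    values = params.base_gp_mean[group] + gp_offset + smooth

    area_um2 = float(mask.sum()) * px_um**2
    lam = params.cluster_density_per_um2[group] * area_um2
    n_clusters = int(rng.poisson(lam)) if lam > 0 else 0
    mask_idx = np.argwhere(mask)
    centers = np.empty((0, 2), dtype=float)
    radii = np.empty(0, dtype=float)
    if n_clusters > 0:
        centers = mask_idx[rng.integers(0, mask_idx.shape[0], n_clusters)].astype(float)
        lo, hi = params.cluster_diameter_nm
        radii = rng.uniform(lo, hi, n_clusters) / 2.0 / pixel_size_nm  # px
        for (cr, cc), r in zip(centers, radii):
            r_int = int(np.ceil(r))
            r0, r1 = max(0, int(cr) - r_int), min(image_size_px, int(cr) + r_int + 1)
            c0, c1 = max(0, int(cc) - r_int), min(image_size_px, int(cc) + r_int + 1)
            sub_r, sub_c = np.ogrid[r0:r1, c0:c1]
            inside = np.hypot(sub_r - cr, sub_c - cc) <= r
            values[r0:r1, c0:c1][inside] -= params.cluster_gp_drop

    np.clip(values, -1.0, 1.0, out=values)
    masked = values[mask]
    return GPField(
        values=values,
        mask=mask,
        cluster_centers_px=centers,
        cluster_radii_px=radii,
        true_mean_gp=float(masked.mean()),
        true_var_gp=float(masked.var()),
    )


def render_channels(
    true_gp: np.ndarray,
    mask: np.ndarray,
    params: MembraneFieldParams,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    pixel_size_nm: float = 200.0,
) -> tuple[ChannelImage, ChannelImage]:
    """Render a GP field into the two Laurdan emission channels.

    Per membrane pixel the total signal is the photon budget S, split so that
    the GP definition inverts exactly: I_blue = S(1+gp)/2 and
    I_green = S(1−gp)/(2·G).  Off-membrane pixels carry the background level.
    Shot noise is Poisson per channel; optional Gaussian read noise (off by
    default) is added afterwards and clamped at zero.
    """
    true_gp = np.asarray(true_gp, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if true_gp.shape != mask.shape:
        raise ShapeMismatchError("GP field and mask shapes differ")
    if not np.all(np.isfinite(true_gp[mask])):
        raise ShapeMismatchError("GP field contains non-finite membrane values")
    if noise and rng is None:
        raise ParameterError("a random generator is required when noise is on")

    s = params.photon_budget
    blue = np.where(mask, s * (1.0 + true_gp) / 2.0, params.background_level)
    green = np.where(
        mask, s * (1.0 - true_gp) / (2.0 * params.g_factor), params.background_level
    )
    if noise:
        blue = rng.poisson(blue).astype(np.float64)
        green = rng.poisson(green).astype(np.float64)
        if params.read_noise_sd > 0:
            blue += rng.normal(0.0, params.read_noise_sd, blue.shape)
            green += rng.normal(0.0, params.read_noise_sd, green.shape)
            np.maximum(blue, 0.0, out=blue)
            np.maximum(green, 0.0, out=green)
    return (
        ChannelImage(blue, BLUE_BAND, pixel_size_nm),
        ChannelImage(green, GREEN_BAND, pixel_size_nm),
    )


# --------------------------------------------------------------------------
# Covariates and whole-cohort assembly
# --------------------------------------------------------------------------

def simulate_covariates(
    group: str, params: CovariateParams, rng: np.random.Generator
) -> dict:
    """Draw one patient's clinical covariates for the given group."""
    if group not in GROUPS:
        raise ParameterError(f"group must be one of {GROUPS}")
    hba1c = float(
        max(3.5, rng.normal(params.hba1c_mean[group], params.hba1c_sd[group]))
    )
    chol = float(
        max(60.0, rng.normal(params.cholesterol_mean[group], params.cholesterol_sd[group]))
    )
    ldl = float(max(30.0, rng.normal(params.ldl_mean[group], params.ldl_sd[group])))
    if group == "G0":
        therapy, insulin, duration = "none", 0.0, 0.0
    else:
        therapy = "CSII" if rng.random() < params.p_csii else "MDI"
        insulin = float(
            max(
                params.insulin_floor,
                rng.normal(params.insulin_mean[therapy], params.insulin_sd[therapy]),
            )
        )
        lo, hi = params.duration_years_range[group]
        duration = float(rng.uniform(lo, hi))
    return {
        "group": group,
        "hba1c_pct": hba1c,
        "cholesterol_mg_dl": chol,
        "ldl_mg_dl": ldl,
        "insulin_u_per_kg": insulin,
        "therapy": therapy,
        "duration_years": duration,
    }


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort (images + covariates + ground-truth ledger).

    Deterministic: the same config (including seed) yields bit-identical
    rasters and covariates.
    """
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    ledger: dict = {"seed": config.seed, "patients": {}}
    for group, n in zip(GROUPS, config.n_per_group):
        for i in range(n):
            pid = f"{group}-{i:02d}"
            cov = simulate_covariates(group, config.covariate_params, rng)
            gp_offset = config.covariate_params.therapy_gp_offset[cov["therapy"]]
            stack = []
            image_truth = []
            for z in range(config.images_per_patient):
                fld = simulate_gp_field(
                    group,
                    config.field_params,
                    rng,
                    image_size_px=config.image_size_px,
                    pixel_size_nm=config.pixel_size_nm,
                    gp_offset=gp_offset,
                )
                pair = render_channels(
                    fld.values,
                    fld.mask,
                    config.field_params,
                    rng,
                    noise=True,
                    pixel_size_nm=config.pixel_size_nm,
                )
                stack.append(pair)
                image_truth.append(
                    {
                        "z": z,
                        "true_mean_gp": fld.true_mean_gp,
                        "true_var_gp": fld.true_var_gp,
                        "n_clusters": fld.n_clusters,
                    }
                )
            patients.append(PatientRecord(id=pid, stack=stack, **cov))
            ledger["patients"][pid] = {
                "group": group,
                "gp_offset": gp_offset,
                "images": image_truth,
            }
    return Cohort(patients=patients, ledger=ledger, config=config)


# --------------------------------------------------------------------------
# Disk layout
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort to the documented directory layout.

    ``cohort.csv`` (one row per patient), per-channel 16-bit TIFFs under
    ``{patient}/{z:03d}_{band}.tif``, the ground-truth ledger as JSON and the
    generating config as YAML.
    """
    import tifffile
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.covariate_frame().to_csv(directory / "cohort.csv", index=False)
    (directory / "ground_truth.json").write_text(json.dumps(cohort.ledger, indent=2))
    (directory / "config.yaml").write_text(yaml.safe_dump(cohort.config.to_dict()))
    for patient in cohort.patients:
        pdir = directory / patient.id
        pdir.mkdir(exist_ok=True)
        for z, (blue, green) in enumerate(patient.stack):
            for img in (blue, green):
                data = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
                tifffile.imwrite(str(pdir / f"{z:03d}_{img.band}.tif"), data)
    return directory


def read_cohort(directory: str | Path, max_skip_fraction: float = 0.2) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`.

    Unreadable image pairs are skipped with a logged reason; if more than
    ``max_skip_fraction`` of the pairs fail, the whole load aborts.
    """
    import logging

    import pandas as pd
    import yaml

    from .gp_imaging import read_channel_tiff

    log = logging.getLogger(__name__)
    directory = Path(directory)
    config_path = directory / "config.yaml"
    if config_path.exists():
        config = CohortConfig.from_dict(yaml.safe_load(config_path.read_text()))
    else:
        config = CohortConfig()
    table = pd.read_csv(directory / "cohort.csv")
    ledger_path = directory / "ground_truth.json"
    ledger = json.loads(ledger_path.read_text()) if ledger_path.exists() else {}

    patients: list[PatientRecord] = []
    n_total = n_skipped = 0
    for _, row in table.iterrows():
        pdir = directory / str(row["patient"])
        stack = []
        blue_files = sorted(pdir.glob(f"*_{BLUE_BAND}.tif"))
        for bf in blue_files:
            z_tag = bf.name.split("_")[0]
            gf = pdir / f"{z_tag}_{GREEN_BAND}.tif"
            n_total += 1
            try:
                blue = read_channel_tiff(bf, BLUE_BAND, config.pixel_size_nm)
                green = read_channel_tiff(gf, GREEN_BAND, config.pixel_size_nm)
                if blue.shape != green.shape:
                    raise ShapeMismatchError("channel shapes differ")
            except Exception as exc:  # noqa: BLE001 - per-image skip is the contract
                n_skipped += 1
                log.warning("skipping %s/%s: %s", row["patient"], z_tag, exc)
                continue
            stack.append((blue, green))
        patients.append(
            PatientRecord(
                id=str(row["patient"]),
                group=str(row["group"]),
                hba1c_pct=float(row["hba1c_pct"]),
                cholesterol_mg_dl=float(row["cholesterol_mg_dl"]),
                ldl_mg_dl=float(row["ldl_mg_dl"]),
                insulin_u_per_kg=float(row["insulin_u_per_kg"]),
                therapy=str(row["therapy"]),
                duration_years=float(row["duration_years"]),
                stack=stack,
            )
        )
    if n_total and n_skipped / n_total > max_skip_fraction:
        raise DegenerateInputError(
            f"{n_skipped}/{n_total} image pairs unreadable — aborting load"
        )
    return Cohort(patients=patients, ledger=ledger, config=config)
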