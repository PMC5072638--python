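"""Synthetic paired-eye macular cohort generator.

Builds 31×31 thickness grids for both eyes and all four layers (RNFL,
GCIPL, GCC = RNFL + GCIPL, total retina = GCC + outer retina) with the
statistical structure the asymmetry analysis assumes:

* a radially symmetric layer profile (foveal dip, perifoveal ganglion-cell
  ring, peripheral plateau);
* subject-, eye- and superpixel-level Gaussian variance components, with
  configurable correlation between mirrored fellow-eye superpixels
  (``inter_eye_corr``) and between vertically mirrored superpixels within
  an eye (``inter_hemi_corr``);
* spatial smoothness from a moving-average kernel applied to the
  superpixel noise (real 200 μm superpixels are spatially correlated);
* for glaucoma subjects, a fovea-anchored angular wedge of thinning
  restricted to one hemifield, mimicking arcuate nerve-fiber-bundle loss,
  with a linear taper at the wedge border.

GCC and total-retina grids are sums of the simulated source layers, so the
compositional identities GCC = RNFL + GCIPL and TOTAL >= GCC hold exactly.

Randomness: a single integer seed; each subject draws from an independent
substream keyed by (seed, subject counter), so cohorts are reproducible
and subjects are order-independent.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .grids import (
    CohortManifest,
    DiseaseLaterality,
    Eye,
    Group,
    Layer,
    SubjectRecord,
    ThicknessGrid,
    write_grid_csv,
)

__all__ = [
    "RadialProfile",
    "LayerNoise",
    "DefectConfig",
    "SimulationConfig",
    "SourceLayer",
    "Hemifield",
    "simulate_subject",
    "simulate_records",
    "simulate_cohort",
    "wedge_weights",
]


class SourceLayer(str, enum.Enum):
    """Independently simulated layers; GCC and TOTAL_RETINA are sums."""

    RNFL = "RNFL"
    GCIPL = "GCIPL"
    OUTER = "OUTER"  # total retina minus GCC


class Hemifield(str, enum.Enum):
    SUPERIOR = "SUPERIOR"
    INFERIOR = "INFERIOR"
    RANDOM = "RANDOM"


@dataclass(frozen=True)
class RadialProfile:
    """Rotationally symmetric baseline thickness profile, μm.

    thickness(d) = plateau + ring_amplitude * exp(-((d - ring_radius)/ring_width)^2)
                   - foveal_dip * exp(-(d/dip_width)^2),   d in mm from the fovea.
    """

    plateau_um: float
    ring_amplitude_um: float = 0.0
    ring_radius_mm: float = 1.2
    ring_width_mm: float = 1.0
    foveal_dip_um: float = 0.0
    dip_width_mm: float = 0.5

    def __call__(self, d_mm: np.ndarray) -> np.ndarray:
        d = np.asarray(d_mm, dtype=float)
        out = np.full_like(d, self.plateau_um)
        if self.ring_amplitude_um:
            out = out + self.ring_amplitude_um * np.exp(-(((d - self.ring_radius_mm) / self.ring_width_mm) ** 2))
        if self.foveal_dip_um:
            out = out - self.foveal_dip_um * np.exp(-((d / self.dip_width_mm) ** 2))
        return out


@dataclass(frozen=True)
class LayerNoise:
    """Superpixel noise field parameters for one source layer."""

    superpixel_sd_um: float
    inter_eye_corr: float = 0.5
    inter_hemi_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.superpixel_sd_um < 0:
            raise ValueError("superpixel_sd_um must be >= 0")
        for name in ("inter_eye_corr", "inter_hemi_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class DefectConfig:
    """Fovea-anchored wedge defect applied to glaucomatous eyes.

    The wedge is an angular sector of half-angle ``half_angle_deg`` about a
    center direction ``center_angle_deg`` above (superior) or below
    (inferior) the horizontal, restricted to the annulus
    ``[r_min_mm, r_max_mm]``. Depth tapers linearly to zero over
    ``taper_superpixels`` at the wedge border.

    Disease severity varies across patients (clinical cohorts mix early,
    moderate and severe defects): each glaucoma subject's target-eye depth
    is scaled by a multiplier drawn uniformly from ``severity_range``. The
    fellow eye is also affected with probability ``bilateral_fraction``,
    with an independent hemifield/side and the target severity further
    scaled by a factor from ``fellow_severity_range`` (bilateral glaucoma
    is typically asymmetric; an identical mirrored defect would be
    invisible to inter-ocular comparison).
    """

    depth_um: dict = field(default_factory=lambda: {SourceLayer.RNFL: 55.0, SourceLayer.GCIPL: 25.0})
    hemifield: Hemifield = Hemifield.RANDOM
    center_angle_deg: float = 45.0
    half_angle_deg: float = 22.5
    r_min_mm: float = 0.6
    r_max_mm: float = 3.0
    taper_superpixels: float = 1.0
    bilateral_fraction: float = 52.0 / 62.0
    severity_range: tuple[float, float] = (0.3, 1.1)
    fellow_severity_range: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        depth = {SourceLayer(k): float(v) for k, v in self.depth_um.items()}
        if any(v < 0 for v in depth.values()):
            raise ValueError("defect depth_um must be >= 0")
        object.__setattr__(self, "depth_um", depth)
        if not 0.0 <= self.bilateral_fraction <= 1.0:
            raise ValueError("bilateral_fraction must be in [0, 1]")
        object.__setattr__(self, "hemifield", Hemifield(self.hemifield))


def _default_profiles() -> dict:
    return {
        SourceLayer.RNFL: RadialProfile(plateau_um=38.0, ring_amplitude_um=18.0,
                                        ring_radius_mm=2.6, ring_width_mm=1.2,
                                        foveal_dip_um=30.0, dip_width_mm=0.8),
        SourceLayer.GCIPL: RadialProfile(plateau_um=68.0, ring_amplitude_um=40.0,
                                         ring_radius_mm=1.2, ring_width_mm=1.0,
                                         foveal_dip_um=45.0, dip_width_mm=0.5),
        SourceLayer.OUTER: RadialProfile(plateau_um=195.0),
    }


def _default_noise() -> dict:
    # superpixel SDs and correlations solved from the normal-group
    # average-negative-difference magnitudes via E[avg] = -sigma_d*sqrt(2/pi);
    # see docs/methods.md for the algebra.
    return {
        SourceLayer.RNFL: LayerNoise(superpixel_sd_um=3.24, inter_eye_corr=0.655, inter_hemi_corr=0.04),
        SourceLayer.GCIPL: LayerNoise(superpixel_sd_um=3.10, inter_eye_corr=0.41, inter_hemi_corr=0.04),
        SourceLayer.OUTER: LayerNoise(superpixel_sd_um=1.5, inter_eye_corr=0.5, inter_hemi_corr=0.5),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_normal: int = 70
    n_glaucoma: int = 62
    grid_size: int = 31
    superpixel_size_mm: float = 0.2
    base_profiles: dict = field(default_factory=_default_profiles)
    noise: dict = field(default_factory=_default_noise)
    subject_sd_um: float = 5.0
    eye_sd_um: float = 0.8
    smoothing_kernel_radius: int = 2
    defect: DefectConfig = field(default_factory=DefectConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size % 2 == 0 or self.grid_size < 3:
            raise ValueError("grid_size must be odd and >= 3")
        if min(self.subject_sd_um, self.eye_sd_um) < 0:
            raise ValueError("variance components must be >= 0")
        if self.smoothing_kernel_radius < 0:
            raise ValueError("smoothing_kernel_radius must be >= 0")
        object.__setattr__(self, "base_profiles",
                           {SourceLayer(k): v for k, v in self.base_profiles.items()})
        object.__setattr__(self, "noise", {SourceLayer(k): v for k, v in self.noise.items()})

    # -- JSON round-trip for the CLI ------------------------------------
    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {(k.value if isinstance(k, enum.Enum) else k): enc(v) for k, v in obj.items()}
            if isinstance(obj, enum.Enum):
                return obj.value
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return json.dumps(enc(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        if "base_profiles" in raw:
            raw["base_profiles"] = {SourceLayer(k): RadialProfile(**v)
                                    for k, v in raw["base_profiles"].items()}
        if "noise" in raw:
            raw["noise"] = {SourceLayer(k): LayerNoise(**v) for k, v in raw["noise"].items()}
        if "defect" in raw:
            d = dict(raw["defect"])
            for key in ("severity_range", "fellow_severity_range"):
                if key in d:
                    d[key] = tuple(d[key])
            raw["defect"] = DefectConfig(**d)
        return cls(**raw)


# ---------------------------------------------------------------------------
# geometry

def _grid_coords(n: int, pitch_mm: float):
    c = n // 2
    y = (c - np.arange(n))[:, None] * pitch_mm  # + = superior
    x = (np.arange(n) - c)[None, :] * pitch_mm  # + = display right
    return x, y


def wedge_weights(n: int, pitch_mm: float, defect: DefectConfig,
                  hemifield: Hemifield, side: int) -> np.ndarray:
    """Per-superpixel defect weight in [0, 1] for one wedge realization.

    ``side`` is +1 for a wedge on the display-right of the fovea, -1 for
    display-left. With ``taper_superpixels == 0`` the weight is a hard
    indicator of the wedge support.
    """
    if hemifield is Hemifield.RANDOM:
        raise ValueError("hemifield must be resolved to SUPERIOR or INFERIOR")
    x, y = _grid_coords(n, pitch_mm)
    d = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x))  # 0 = right, +90 = superior
    theta_c = defect.center_angle_deg if side > 0 else 180.0 - defect.center_angle_deg
    if hemifield is Hemifield.INFERIOR:
        theta_c = -theta_c
    dtheta = np.abs((theta - theta_c + 180.0) % 360.0 - 180.0)
    # signed distance (mm) to the nearest wedge boundary; >0 inside
    margin = np.minimum.reduce([
        (defect.half_angle_deg - dtheta) * np.pi / 180.0 * d,
        d - defect.r_min_mm,
        defect.r_max_mm - d,
    ])
    if defect.taper_superpixels <= 0:
        return (margin >= 0).astype(float)
    return np.clip(margin / (defect.taper_superpixels * pitch_mm), 0.0, 1.0)


# ---------------------------------------------------------------------------
# noise fields

def _smooth_unit(fld: np.ndarray, radius: int) -> np.ndarray:
    """Moving-average smooth, rescaled to keep interior marginal SD ~1."""
    if radius == 0:
        return fld
    size = 2 * radius + 1
    return uniform_filter(fld, size=size, mode="nearest") * size


def _hemi_mixed(rng: np.random.Generator, n: int, rho_h: float) -> np.ndarray:
    a = rng.standard_normal((n, n))
    b = rng.standard_normal((n, n))
    sym = (a + a[::-1, :]) / np.sqrt(2.0)
    return np.sqrt(rho_h) * sym + np.sqrt(1.0 - rho_h) * b


def _eye_fields(rng: np.random.Generator, n: int, nz: LayerNoise, radius: int):
    """Unit-SD noise fields for (OD, OS) with the configured correlations.

    The shared component is column-mirrored for the fellow eye so that the
    correlation acts between anatomically corresponding (mirrored)
    superpixels.
    """
    shared = _hemi_mixed(rng, n, nz.inter_hemi_corr)
    own_a = _hemi_mixed(rng, n, nz.inter_hemi_corr)
    own_b = _hemi_mixed(rng, n, nz.inter_hemi_corr)
    re = nz.inter_eye_corr
    f_a = np.sqrt(re) * shared + np.sqrt(1.0 - re) * own_a
    f_b = np.sqrt(re) * shared[:, ::-1] + np.sqrt(1.0 - re) * own_b
    return _smooth_unit(f_a, radius), _smooth_unit(f_b, radius)


# ---------------------------------------------------------------------------
# subject and cohort

def _base_grids(cfg: SimulationConfig) -> dict:
    x, y = _grid_coords(cfg.grid_size, cfg.superpixel_size_mm)
    d = np.hypot(x, y)
    return {src: cfg.base_profiles[src](d) for src in SourceLayer}


def simulate_subject(cfg: SimulationConfig, group: Group, rng: np.random.Generator,
                     subject_id: str = "S000") -> SubjectRecord:
    """Draw one subject's paired-eye four-layer grids.

    Glaucoma subjects receive a wedge defect in the target eye; the fellow
    eye is affected (scaled, independent wedge) with probability
    ``defect.bilateral_fraction``, which sets ``disease_laterality``.
    """
    group = Group(group)
    n = cfg.grid_size
    base = _base_grids(cfg)

    target_eye = Eye.OD if rng.random() < 0.5 else Eye.OS
    eyes = (Eye.OD, Eye.OS)

    source: dict[tuple[Eye, SourceLayer], np.ndarray] = {}
    for src in SourceLayer:
        nz = cfg.noise[src]
        subj_eff = rng.normal(0.0, cfg.subject_sd_um)
        z = rng.standard_normal(3)
        re = nz.inter_eye_corr
        eye_eff = {
            Eye.OD: cfg.eye_sd_um * (np.sqrt(re) * z[0] + np.sqrt(1 - re) * z[1]),
            Eye.OS: cfg.eye_sd_um * (np.sqrt(re) * z[0] + np.sqrt(1 - re) * z[2]),
        }
        f_od, f_os = _eye_fields(rng, n, nz, cfg.smoothing_kernel_radius)
        fields = {Eye.OD: f_od, Eye.OS: f_os}
        for eye in eyes:
            source[(eye, src)] = base[src] + subj_eff + eye_eff[eye] + nz.superpixel_sd_um * fields[eye]

    laterality = DiseaseLaterality.NONE
    if group is Group.GLAUCOMA:
        target_sev = rng.uniform(*cfg.defect.severity_range)
        affected: list[tuple[Eye, float]] = [(target_eye, target_sev)]
        bilateral = rng.random() < cfg.defect.bilateral_fraction
        laterality = DiseaseLaterality.BILATERAL if bilateral else DiseaseLaterality.UNILATERAL
        # draw fellow-eye parameters unconditionally to keep the stream aligned
        fellow_sev = target_sev * rng.uniform(*cfg.defect.fellow_severity_range)
        if bilateral:
            affected.append((target_eye.fellow, fellow_sev))
        for eye, severity in affected:
            if cfg.defect.hemifield is Hemifield.RANDOM:
                hemi = Hemifield.SUPERIOR if rng.random() < 0.5 else Hemifield.INFERIOR
            else:
                hemi = cfg.defect.hemifield
            side = 1 if rng.random() < 0.5 else -1
            w = wedge_weights(n, cfg.superpixel_size_mm, cfg.defect, hemi, side)
            for src, depth in cfg.defect.depth_um.items():
                source[(eye, src)] = source[(eye, src)] - severity * depth * w

    grids: dict[tuple[Eye, Layer], ThicknessGrid] = {}
    for eye in eyes:
        rnfl = np.clip(source[(eye, SourceLayer.RNFL)], 0.0, None)
        gcipl = np.clip(source[(eye, SourceLayer.GCIPL)], 0.0, None)
        outer = np.clip(source[(eye, SourceLayer.OUTER)], 0.0, None)
        per_layer = {
            Layer.RNFL: rnfl,
            Layer.GCIPL: gcipl,
            Layer.GCC: rnfl + gcipl,
            Layer.TOTAL_RETINA: rnfl + gcipl + outer,
        }
        for layer, vals in per_layer.items():
            grids[(eye, layer)] = ThicknessGrid(
                values=vals, layer=layer, laterality=eye,
                superpixel_size_mm=cfg.superpixel_size_mm,
            )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        target_eye=target_eye,
        disease_laterality=laterality,
        grids=grids,
    )


def _subject_rng(cfg: SimulationConfig, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(counter)]))


def simulate_records(cfg: SimulationConfig) -> list[SubjectRecord]:
    """In-memory cohort: n_normal normals then n_glaucoma glaucoma subjects."""
    records = []
    for i in range(cfg.n_normal + cfg.n_glaucoma):
        group = Group.NORMAL if i < cfg.n_normal else Group.GLAUCOMA
        records.append(
            simulate_subject(cfg, group, _subject_rng(cfg, i), subject_id=f"S{i:03d}")
        )
    return records


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> CohortManifest:
    """Persist a simulated cohort: one CSV per eye/layer plus manifest.csv.

    Deterministic given ``cfg.seed``: the same config writes a
    byte-identical output tree.
    """
    out_dir = Path(out_dir)
    grids_dir = out_dir / "grids"
    grids_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in simulate_records(cfg):
        paths = {}
        for (eye, layer), grid in rec.grids.items():
            rel = f"grids/{rec.subject_id}_{eye.value}_{layer.value}.csv"
            write_grid_csv(grid, out_dir / rel)
            paths[(eye, layer)] = rel
        rows.append(CohortManifest.row_for(rec, paths))
    manifest = CohortManifest(table=pd.DataFrame(rows), root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    return manifest
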