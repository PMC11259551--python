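"""Synthetic paired proton / hyperpolarized-gas phantoms and cohorts.

Real hyperpolarized He-3 ventilation MRI of the study population is not
publicly deposited, so every downstream stage is exercised on phantoms
with known ground truth:

* a torso ellipsoid (bright on the proton image) containing two lung
  half-ellipsoids (the thoracic cavity);
* smoothly varying ventilated signal inside the cavity, built from a
  Gaussian random field with configurable correlation length and
  heterogeneity amplitude;
* ventilation defects planted as unions of disjoint discrete balls of
  known odd diameters plus scattered single voxels, recorded exactly in a
  truth inventory so sphere-packing recovery can be tested voxel-for-voxel;
* Rician (magnitude-MRI) noise at a configurable SNR.

The cohort generator emulates an 88-subject ex-smoker study arm: 57
"stable" and 31 "rapid decliner" subjects whose spirometry/demographic
covariates are drawn from group-specific normal distributions and whose
two-visit FEV1 pairs are constructed to honour the >= 60 mL/year decline
rule.  Rapid decliners carry a larger planted defect burden and a rougher,
higher-amplitude ventilation texture, reproducing the direction of the
group differences in low-gray-level emphasis and homogeneity features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Volume3D, Mask3D
from .spherepack import discrete_ball_offsets

__all__ = ["GroupEffects", "EffectConfig", "PhantomCase", "make_phantom", "make_cohort"]

logger = logging.getLogger(__name__)

RAPID_DECLINE_ML_PER_YEAR = 60.0

#: Group-specific covariate (mean, SD) pairs.  Units: age yr, height m,
#: bmi kg/m^2, spo2 %, pack_years, years_since_quit yr, fev1/fvc/tlc/ic/svc L,
#: rv_tlc %, adc cm^2/s.
_STABLE_COVARIATES = {
    "age": (70.0, 9.0),
    "height_m": (1.68, 0.08),
    "bmi": (28.0, 4.0),
    "spo2": (95.0, 4.0),
    "pack_years": (37.0, 26.0),
    "years_since_quit": (14.0, 14.0),
    "fev1_baseline": (2.2, 0.8),
    "fvc": (3.4, 0.9),
    "tlc": (6.5, 1.3),
    "ic": (2.8, 0.7),
    "svc": (3.5, 0.9),
    "rv_tlc": (45.0, 10.0),
    "adc": (0.33, 0.08),
}
_RAPID_COVARIATES = {
    "age": (68.0, 9.0),
    "height_m": (1.71, 0.07),
    "bmi": (29.0, 5.0),
    "spo2": (96.0, 2.0),
    "pack_years": (35.0, 21.0),
    "years_since_quit": (16.0, 13.0),
    "fev1_baseline": (2.5, 0.8),
    "fvc": (3.9, 0.8),
    "tlc": (7.0, 1.2),
    "ic": (3.0, 0.7),
    "svc": (3.9, 0.8),
    "rv_tlc": (42.0, 9.0),
    "adc": (0.36, 0.12),
}


@dataclass(frozen=True)
class GroupEffects:
    """Per-group generative parameters for phantoms and covariates.

    defect_burden is the fraction of thoracic voxels that are unventilated;
    sphere_mix gives the number of planted balls per odd diameter (the rest
    of the burden is scattered single voxels); smoothness_vox is the
    Gaussian correlation length of the ventilated texture in voxels;
    heterogeneity the relative amplitude of that texture; snr the Rician
    signal-to-noise ratio; decline_* parameterise the annualized FEV1
    decline in mL/year (truncated away from the 60 mL/yr boundary so the
    labeling rule reproduces the group assignment exactly).
    """

    defect_burden_mean: float
    defect_burden_sd: float
    sphere_mix: dict[int, int]
    smoothness_vox: float
    heterogeneity: float
    snr: float
    decline_mean_ml_yr: float
    decline_sd_ml_yr: float
    decline_range_ml_yr: tuple[float, float]
    female_fraction: float
    covariates: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (_, sd) in self.covariates.items():
            if sd < 0:
                raise ValueError(f"negative SD for covariate {name}")
        if self.defect_burden_sd < 0:
            raise ValueError("defect_burden_sd must be >= 0")


@dataclass(frozen=True)
class EffectConfig:
    """Cohort-level generative configuration: one GroupEffects per group."""

    stable: GroupEffects
    rapid: GroupEffects
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "EffectConfig":
        """Study-condition defaults: rapid decliners carry a larger defect
        burden and a rougher, higher-amplitude ventilation texture."""
        stable = GroupEffects(
            defect_burden_mean=0.10,
            defect_burden_sd=0.04,
            sphere_mix={7: 1, 5: 2, 3: 4},
            smoothness_vox=3.0,
            heterogeneity=0.20,
            snr=15.0,
            decline_mean_ml_yr=15.0,
            decline_sd_ml_yr=25.0,
            decline_range_ml_yr=(-80.0, 55.0),
            female_fraction=0.39,
            covariates=dict(_STABLE_COVARIATES),
        )
        rapid = GroupEffects(
            defect_burden_mean=0.18,
            defect_burden_sd=0.05,
            sphere_mix={7: 2, 5: 4, 3: 8},
            smoothness_vox=2.0,
            heterogeneity=0.40,
            snr=15.0,
            decline_mean_ml_yr=120.0,
            decline_sd_ml_yr=45.0,
            decline_range_ml_yr=(65.0, 300.0),
            female_fraction=0.23,
            covariates=dict(_RAPID_COVARIATES),
        )
        return cls(stable=stable, rapid=rapid, seed=seed)

    @classmethod
    def null(cls, seed: int = 0) -> "EffectConfig":
        """Identical group distributions (apart from the decline rule):
        a null cohort for type-I-error checks on covariate comparisons."""
        base = cls.default(seed=seed)
        rapid_null = GroupEffects(
            defect_burden_mean=base.stable.defect_burden_mean,
            defect_burden_sd=base.stable.defect_burden_sd,
            sphere_mix=dict(base.stable.sphere_mix),
            smoothness_vox=base.stable.smoothness_vox,
            heterogeneity=base.stable.heterogeneity,
            snr=base.stable.snr,
            decline_mean_ml_yr=base.rapid.decline_mean_ml_yr,
            decline_sd_ml_yr=base.rapid.decline_sd_ml_yr,
            decline_range_ml_yr=base.rapid.decline_range_ml_yr,
            female_fraction=base.stable.female_fraction,
            covariates=dict(base.stable.covariates),
        )
        return cls(stable=base.stable, rapid=rapid_null, seed=seed)

    def to_json(self) -> str:
        d = asdict(self)
        for grp in ("stable", "rapid"):
            d[grp]["sphere_mix"] = {str(k): v for k, v in d[grp]["sphere_mix"].items()}
        return json.dumps(d, sort_keys=True, indent=2)


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic subject: paired volumes, truth masks, sphere inventory."""

    subject_id: str
    proton: Volume3D
    he3: Volume3D
    truth_thoracic: Mask3D
    truth_defect: Mask3D
    truth_spheres: tuple[tuple[tuple[int, int, int], int], ...]
    record: Optional[dict] = None

    @property
    def lung_seed_points(self) -> list[tuple[int, int, int]]:
        """One interior seed per lung (connected component centroid),
        usable to seed thoracic region growing without manual input."""
        lab, n = ndimage.label(self.truth_thoracic.voxels)
        seeds = []
        for i in range(1, n + 1):
            com = ndimage.center_of_mass(lab == i)
            cand = tuple(int(round(c)) for c in com)
            if not self.truth_thoracic.voxels[cand]:
                idx = np.argwhere(lab == i)
                cand = tuple(idx[np.argmin(((idx - com) ** 2).sum(axis=1))])
                cand = tuple(int(c) for c in cand)
            seeds.append(cand)
        return seeds


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape, dtype=float)
    for g, c, s in zip(grids, center, semi):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def _lung_geometry(shape) -> tuple[np.ndarray, np.ndarray]:
    """Torso ellipsoid and two lung half-ellipsoids, scaled to the grid."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    torso = _ellipsoid(shape, (cx, cy, cz), (0.44 * nx, 0.46 * ny, 0.52 * nz))
    semi = (0.15 * nx, 0.32 * ny, 0.40 * nz)
    off = 0.21 * nx
    lungs = _ellipsoid(shape, (cx - off, cy, cz), semi) | _ellipsoid(shape, (cx + off, cy, cz), semi)
    # keep a bright body shell of at least 2 voxels around the cavity
    lungs &= ndimage.binary_erosion(torso, iterations=2)
    return torso, lungs


def _smooth_field(shape, correlation_vox: float, rng: np.random.Generator) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=correlation_vox)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def _cube_slice(center, radius, shape):
    return tuple(
        slice(max(c - radius, 0), min(c + radius + 1, n)) for c, n in zip(center, shape)
    )


def _place_defects(
    lungs: np.ndarray,
    inventory: list[tuple[int, int]],
    rng: np.random.Generator,
    min_gap: int = 1,
    max_retries: int = 2000,
) -> tuple[np.ndarray, list[tuple[tuple[int, int, int], int]]]:
    """Plant disjoint discrete balls and scattered unit voxels in the lungs.

    Balls (diameter >= 3) keep a Chebyshev gap of ``min_gap`` voxels from
    each other and from the lung boundary; one voxel of background between
    balls keeps each ball's interior distance transform identical to an
    isolated ball, so each planted sphere is recoverable exactly by the
    packing algorithm.  Diameter-1 entries are
    scattered single voxels: disjoint from the balls' isolation zone and
    from each other, but free to be mutually adjacent.  Placement is
    rejection sampling with a retry cap; an inventory that does not fit
    raises ValueError.
    """
    defect = np.zeros(lungs.shape, dtype=bool)
    blocked = np.zeros(lungs.shape, dtype=bool)  # balls dilated by min_gap
    edt = ndimage.distance_transform_edt(lungs)
    spheres: list[tuple[tuple[int, int, int], int]] = []

    n_units = 0
    for diameter, count in inventory:
        if diameter < 1 or diameter % 2 == 0:
            raise ValueError(f"planted sphere diameters must be odd positive, got {diameter}")
        if count < 0:
            raise ValueError("sphere counts must be >= 0")
        if diameter == 1:
            n_units += count

    for diameter, count in sorted(inventory, key=lambda t: -t[0]):
        if diameter == 1 or count == 0:
            continue
        r = (diameter - 1) // 2
        offsets = discrete_ball_offsets(diameter)
        eligible = np.argwhere((edt > r + min_gap) & lungs)
        if len(eligible) == 0:
            raise ValueError(f"inventory does not fit: no room for diameter-{diameter} sphere")
        for _ in range(count):
            placed = False
            for _try in range(max_retries):
                center = eligible[rng.integers(len(eligible))]
                vox = offsets + center
                sl = tuple(vox.T)
                if blocked[sl].any():
                    continue
                defect[sl] = True
                # block a bounding cube grown by min_gap (superset of the
                # dilated ball): conservative but cheap
                blocked[_cube_slice(center, r + min_gap, lungs.shape)] = True
                spheres.append((tuple(int(c) for c in center), diameter))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"inventory does not fit: could not place diameter-{diameter} sphere "
                    f"after {max_retries} attempts"
                )

    if n_units:
        eligible = np.argwhere(lungs & ~blocked & ~defect)
        if len(eligible) < n_units:
            raise ValueError(
                f"inventory does not fit: {n_units} unit voxels requested, "
                f"{len(eligible)} eligible positions"
            )
        chosen = eligible[rng.choice(len(eligible), size=n_units, replace=False)]
        defect[tuple(chosen.T)] = True
        spheres.extend((tuple(int(c) for c in center), 1) for center in chosen)
    return defect, spheres


def make_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 14),
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0),
    defect_inventory: list[tuple[int, int]] | None = None,
    smoothness_vox: float = 3.0,
    heterogeneity: float = 0.2,
    snr: float = 15.0,
    seed: int = 0,
    subject_id: str = "phantom",
    record: Optional[dict] = None,
) -> PhantomCase:
    """Generate one paired proton/He-3 phantom with planted defects.

    The proton volume has a bright body and darker thoracic cavity; the
    He-3 volume has smoothly varying ventilated signal inside the cavity
    and noise-only signal inside the planted defects.  ``defect_inventory``
    lists (odd diameter, count) pairs; diameter-1 entries are scattered
    single voxels.  Generation is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    inventory = list(defect_inventory or [])
    torso, lungs = _lung_geometry(grid_shape)
    defect, spheres = _place_defects(lungs, inventory, rng)

    body_signal, lung_signal, vent_signal = 200.0, 60.0, 100.0
    proton = np.zeros(grid_shape, dtype=float)
    proton[torso] = body_signal
    proton[lungs] = lung_signal
    proton = _rician(proton, body_signal / (4.0 * snr), rng)

    texture = _smooth_field(grid_shape, smoothness_vox, rng)
    he3 = np.zeros(grid_shape, dtype=float)
    ventilated = lungs & ~defect
    he3[ventilated] = np.maximum(vent_signal * (1.0 + heterogeneity * texture[ventilated]), 5.0)
    he3 = _rician(he3, vent_signal / snr, rng)

    return PhantomCase(
        subject_id=subject_id,
        proton=Volume3D(proton, spacing_mm),
        he3=Volume3D(he3, spacing_mm),
        truth_thoracic=Mask3D(lungs, spacing_mm),
        truth_defect=Mask3D(defect, spacing_mm),
        truth_spheres=tuple(spheres),
        record=record,
    )


def _truncated_normal(rng, mean, sd, lo, hi, max_draws=1000):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_draws):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _subject_inventory(
    group: GroupEffects, burden: float, lung_count: int
) -> list[tuple[int, int]]:
    target = int(round(burden * lung_count))
    inventory = [(d, c) for d, c in sorted(group.sphere_mix.items(), reverse=True) if c > 0]
    ball_vox = sum(len(discrete_ball_offsets(d)) * c for d, c in inventory)
    units = max(target - ball_vox, 0)
    if units:
        inventory.append((1, units))
    return inventory


def make_cohort(
    n_stable: int,
    n_rapid: int,
    effects: EffectConfig | None = None,
    seed: int | None = None,
    grid_shape: tuple[int, int, int] = (64, 64, 14),
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0),
    generate_images: bool = True,
    allow_empty_group: bool = False,
) -> tuple[pd.DataFrame, list[PhantomCase]]:
    """Generate a labelled cohort table and (optionally) its phantoms.

    Covariates are drawn from the group-specific normals in ``effects``;
    FEV1 follow-up values are constructed from a truncated-normal
    annualized decline so that the >= 60 mL/year labeling rule reproduces
    each row's group exactly.  Defect burden and texture parameters differ
    by group so planted effect directions match the clinical pattern
    (rapid decliners: more low-signal structure, lower local homogeneity).
    """
    if allow_empty_group:
        if n_stable < 0 or n_rapid < 0 or n_stable + n_rapid < 1:
            raise ValueError("need at least one subject")
    elif n_stable < 1 or n_rapid < 1:
        raise ValueError("need at least one subject per group")
    effects = effects or EffectConfig.default()
    master_seed = effects.seed if seed is None else seed
    rng = np.random.default_rng(master_seed)

    _, lungs = _lung_geometry(grid_shape)
    lung_count = int(lungs.sum())

    rows = []
    cases: list[PhantomCase] = []
    labels = ["stable"] * n_stable + ["rapid"] * n_rapid
    for i, label in enumerate(labels):
        grp = effects.stable if label == "stable" else effects.rapid
        sid = f"S{i + 1:03d}"
        row: dict = {"id": sid, "label": label}
        row["sex"] = "F" if rng.random() < grp.female_fraction else "M"
        for name, (mean, sd) in grp.covariates.items():
            if name == "fev1_baseline":
                lo = 1.0  # keeps room for the steepest rapid-decline draws
            elif name in {"fvc", "tlc", "ic", "svc"}:
                lo = 0.5
            elif name == "age":
                lo = 40.0
            else:
                lo = 0.0
            hi = np.inf
            if name == "spo2":
                hi = 100.0
            row[name] = round(_truncated_normal(rng, mean, sd, lo, hi), 4)

        interval = _truncated_normal(rng, 31.0, 7.0, 18.0, 48.0)
        years = interval / 12.0
        lo_r, hi_r = grp.decline_range_ml_yr
        # keep follow-up FEV1 physically positive without crossing 60 mL/yr
        hi_r = min(hi_r, (row["fev1_baseline"] - 0.3) / years * 1000.0)
        rate = _truncated_normal(rng, grp.decline_mean_ml_yr, grp.decline_sd_ml_yr, lo_r, hi_r)
        row["interval_months"] = round(interval, 2)
        row["fev1_followup"] = round(row["fev1_baseline"] - rate * years / 1000.0, 4)
        # re-derive the realized annualized decline after rounding and keep
        # it on the correct side of the 60 mL/yr boundary
        realized = (row["fev1_baseline"] - row["fev1_followup"]) / years * 1000.0
        if label == "stable" and realized >= RAPID_DECLINE_ML_PER_YEAR:
            row["fev1_followup"] = round(row["fev1_baseline"] - 0.055 * years, 4)
        if label == "rapid" and realized < RAPID_DECLINE_ML_PER_YEAR:
            row["fev1_followup"] = round(row["fev1_baseline"] - 0.065 * years, 4)

        burden = _truncated_normal(
            rng, grp.defect_burden_mean, grp.defect_burden_sd, 0.02, 0.40
        )
        row["planted_defect_fraction"] = round(burden, 4)
        rows.append(row)

        if generate_images:
            inventory = _subject_inventory(grp, burden, lung_count)
            case = make_phantom(
                grid_shape=grid_shape,
                spacing_mm=spacing_mm,
                defect_inventory=inventory,
                smoothness_vox=grp.smoothness_vox,
                heterogeneity=grp.heterogeneity,
                snr=grp.snr,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=sid,
                record=row,
            )
            cases.append(case)

    return pd.DataFrame(rows), cases
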