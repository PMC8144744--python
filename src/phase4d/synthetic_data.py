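"""Synthetic cohorts with known ground truth for every pipeline stage.

Three generators cover the pipeline's inputs:

* :func:`gen_phase_features` — a phase-feature table in which each
  patient-feature follows a smooth cyclic trajectory over the respiratory
  cycle whose local variation is minimal at a designed stable phase, plus
  white noise, optional single-phase artifact spikes at non-designed phases,
  inter-feature correlation blocks, and volume-coupled features.
* :func:`gen_outcomes` — survival times from an exponential-baseline Cox model
  on a planted feature subset with independent uniform censoring tuned to a
  target event fraction, plus clinical covariates drawn to mimic an
  early-stage NSCLC SABR cohort (sex ~52/48, median age 76, median volume
  ~4 cm^3, median motion ~5.5 mm).
* :func:`gen_phantom_4d` — a 4D CT phantom: lung-density background with a
  soft-tissue sphere translating sinusoidally in z, a high-density "chest
  wall" slab near the trajectory, and an optional duplicated-slice artifact
  at a chosen phase.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DEFAULT_PHASES, PhaseFeatureTable
from .roi_geometry import BinaryMask, ImageVolume, translate_mask

LUNG_HU = -750.0
TISSUE_HU = 20.0
SLAB_HU = 300.0


@dataclass
class SimulationDesign:
    n_patients: int = 100
    n_phases: int = 10
    n_features: int = 186          # per ROI, both ROIs generated
    seed: int = 0
    trajectory_scale: float = 1.0  # amplitude of the cyclic component
    noise_sd: float = 0.1
    artifact_rate: float = 0.3     # fraction of patients with an artifact phase
    artifact_magnitude: float = 1.0   # absolute spike size (default 10x noise_sd)
    artifact_feature_fraction: float = 0.8
    block_size: int = 6            # correlated feature block width
    block_loading: float = 0.7
    volume_coupled_fraction: float = 0.45
    volume_coupling: float = 1.0
    planted_features: list[str] = field(default_factory=list)
    planted_log_hr: list[float] = field(default_factory=list)
    clinical_log_hr_volume: float = 0.4   # per SD of log-volume
    event_fraction: float = 0.18
    baseline_median_months: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.event_fraction < 1):
            raise ValueError("event_fraction must be in [0, 1)")
        if len(self.planted_features) != len(self.planted_log_hr):
            raise ValueError("planted features and log-HRs must align")


@dataclass
class PhaseTruth:
    designed_phase: pd.Series          # patient -> phase label
    artifact_phase: pd.Series          # patient -> phase label or None
    volume: pd.Series                  # patient -> cm^3


def _cyclic_dist(i: np.ndarray, j: int, P: int) -> np.ndarray:
    d = np.abs(i - j)
    return np.minimum(d, P - d)


def feature_names(n: int, roi: str) -> list[str]:
    return [f"{roi}|f{i:04d}" for i in range(n)]


def gen_phase_features(design: SimulationDesign
                       ) -> tuple[PhaseFeatureTable, PhaseTruth]:
    """Phase-feature table plus the ground truth used to build it.

    The designed stable phase is drawn near exhale (phase index P/2) for most
    patients.  The cyclic trajectory is quadratic in cyclic distance from the
    designed phase, so the summed neighbour difference is strictly smallest at
    that phase for noise-free features.
    """
    rng = np.random.default_rng(design.seed)
    P = design.n_phases
    phases = tuple(f"{int(100 * i / P)}%" for i in range(P)) \
        if P != 10 else DEFAULT_PHASES
    n, F = design.n_patients, design.n_features
    patients = [f"P{i:03d}" for i in range(n)]
    # designed phase: concentrated near exhale with full-range support
    centre = P // 2
    offs = rng.choice(np.arange(-P // 2, P // 2), size=n,
                      p=_phase_prior(P))
    designed = (centre + offs) % P
    volume = np.exp(rng.normal(np.log(4.0), 0.9, size=n))  # cm^3
    log_vol_z = (np.log(volume) - np.log(4.0)) / 0.9

    artifact = np.full(n, -1)
    has_art = rng.random(n) < design.artifact_rate
    for i in np.flatnonzero(has_art):
        choices = [q for q in range(P)
                   if _cyclic_dist(np.array([q]), designed[i], P)[0] >= 2]
        artifact[i] = rng.choice(choices)

    frames = []
    idx = np.arange(P)
    for roi in ("tumour", "peritumour"):
        names = feature_names(F, roi)
        n_blocks = int(np.ceil(F / design.block_size))
        latent = rng.normal(size=(n, n_blocks))
        block_of = np.arange(F) // design.block_size
        indep = rng.normal(size=(n, F))
        lam = design.block_loading
        base = lam * latent[:, block_of] + np.sqrt(1 - lam ** 2) * indep
        vc = rng.random(F) < design.volume_coupled_fraction
        base[:, vc] += design.volume_coupling * log_vol_z[:, None]
        amp = design.trajectory_scale * (0.5 + rng.random(F))
        # X[n, F, P]
        d2 = np.empty((n, P))
        for i in range(n):
            d2[i] = (_cyclic_dist(idx, designed[i], P) / (P / 2)) ** 2
        X = base[:, :, None] + amp[None, :, None] * d2[:, None, :]
        X += rng.normal(scale=design.noise_sd, size=X.shape)
        for i in np.flatnonzero(artifact >= 0):
            hit = rng.random(F) < design.artifact_feature_fraction
            sign = rng.choice([-1.0, 1.0], size=int(hit.sum()))
            X[i, hit, artifact[i]] += design.artifact_magnitude * sign
        df = pd.DataFrame({
            "patient": np.repeat(patients, F * P),
            "phase": np.tile(np.repeat(list(phases), 1), n * F),
            "roi": roi,
            "feature": np.tile(np.repeat(names, P), n),
            "value": X.reshape(-1),
        })
        frames.append(df)
    table = PhaseFeatureTable(pd.concat(frames, ignore_index=True),
                              phases=phases)
    truth = PhaseTruth(
        designed_phase=pd.Series([phases[d] for d in designed], index=patients),
        artifact_phase=pd.Series(
            [phases[a] if a >= 0 else None for a in artifact], index=patients),
        volume=pd.Series(volume, index=patients))
    return table, truth


def _phase_prior(P: int) -> np.ndarray:
    """Probability of the designed-phase offset from exhale: peaked at 0."""
    offs = np.arange(-P // 2, P // 2)
    w = np.exp(-0.5 * (offs / 1.5) ** 2) + 0.04
    return w / w.sum()


def gen_outcomes(matrix: pd.DataFrame, design: SimulationDesign,
                 volume: pd.Series | None = None,
                 seed_offset: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival and clinical tables for the patients of a feature matrix.

    ``matrix`` is a patient x feature frame; planted features (named in the
    design) contribute their log hazard ratios per SD.  Survival times follow
    an exponential baseline; censoring is uniform on (0, c_max) with c_max
    tuned by bisection so the realised event fraction approximates the target.
    """
    rng = np.random.default_rng(design.seed + seed_offset)
    patients = list(matrix.index)
    n = len(patients)
    missing = set(design.planted_features) - set(matrix.columns)
    if missing:
        raise ValueError(f"planted features absent from matrix: {sorted(missing)}")
    lp = np.zeros(n)
    for feat, beta in zip(design.planted_features, design.planted_log_hr):
        x = matrix[feat].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd > 0:
            lp += beta * (x - x.mean()) / sd
    if volume is None:
        volume = pd.Series(np.exp(rng.normal(np.log(4.0), 0.9, n)),
                           index=patients)
    log_vol_z = (np.log(volume.loc[patients].to_numpy())
                 - np.log(4.0)) / 0.9
    lp += design.clinical_log_hr_volume * log_vol_z
    lam0 = np.log(2) / design.baseline_median_months
    T = rng.exponential(1.0, n) / (lam0 * np.exp(lp))
    target = design.event_fraction
    if target == 0:
        time, event = T, np.zeros(n, dtype=int)
    else:
        u = rng.random(n)
        lo_c, hi_c = 1e-3, 100.0 * design.baseline_median_months
        for _ in range(60):
            mid = 0.5 * (lo_c + hi_c)
            frac = np.mean(T <= u * mid)
            if frac < target:
                lo_c = mid
            else:
                hi_c = mid
        C = u * 0.5 * (lo_c + hi_c)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    time = np.maximum(time, 1e-6)
    survival = pd.DataFrame({"patient": patients, "time": time, "event": event})
    clinical = _gen_clinical(patients, volume, rng)
    return survival, clinical


def _gen_clinical(patients, volume: pd.Series, rng) -> pd.DataFrame:
    n = len(patients)
    return pd.DataFrame({
        "patient": patients,
        "sex": rng.choice(["male", "female"], size=n, p=[0.515, 0.485]),
        "age": np.clip(rng.normal(75, 8, n), 45, 93).round(0),
        "t_stage": rng.choice(["T1", "T2", "T3"], size=n,
                              p=[0.66, 0.335, 0.005]),
        "ecog": rng.choice([0, 1, 2, 3], size=n, p=[0.013, 0.347, 0.52, 0.12]),
        "lobe": rng.choice(["lower", "middle", "upper"], size=n,
                           p=[0.333, 0.052, 0.615]),
        "tumour_volume": volume.loc[patients].to_numpy(),
        "motion_amplitude": np.exp(rng.normal(np.log(5.5), 0.8, n)),
    })


@dataclass
class PhantomDesign:
    shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_mm: float = 6.0
    amplitude_mm: float = 5.0      # peak-to-peak z motion
    n_phases: int = 10
    slab_x_mm: float | None = None     # x position of the chest-wall slab
    artifact_phase: int | None = None  # duplicated-slice artifact
    noise_sd: float = 15.0
    texture_period_mm: float = 4.0
    seed: int = 0


def gen_phantom_4d(design: PhantomDesign):
    """4D phantom: per-phase images, reference GTV mask, translations.

    Returns ``(images, gtv_ref, translations, phases)`` where ``images`` maps
    phase label to :class:`ImageVolume`, ``gtv_ref`` is the reference (50%)
    phase tumour mask, and ``translations`` is a (P, 3) array in mm relative
    to the reference phase.
    """
    rng = np.random.default_rng(design.seed)
    nx, ny, nz = design.shape
    sp = np.asarray(design.spacing)
    P = design.n_phases
    phases = tuple(f"{int(100 * i / P)}%" for i in range(P)) \
        if P != 10 else DEFAULT_PHASES
    centre = np.array([nx / 2, ny / 2, nz / 2]) * sp
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in design.shape],
                                  indexing="ij"), axis=-1) * sp
    # z position per phase: cosine, peak inhale at phase 0
    ref = P // 2
    z_of = 0.5 * design.amplitude_mm * np.cos(2 * np.pi * np.arange(P) / P)
    translations = np.zeros((P, 3))
    translations[:, 2] = z_of - z_of[ref]

    def sphere_mask(c):
        d = np.sqrt(((coords - c) ** 2).sum(axis=-1))
        return d <= design.radius_mm

    gtv_ref = BinaryMask(sphere_mask(centre + [0, 0, z_of[ref]]),
                         tuple(sp))
    images = {}
    for p, label in enumerate(phases):
        arr = np.full(design.shape, LUNG_HU)
        c = centre + [0, 0, z_of[p]]
        sph = sphere_mask(c)
        # soft-tissue sphere with a smooth internal intensity texture
        tex = 30.0 * np.sin(2 * np.pi * coords[..., 0]
                            / design.texture_period_mm) \
            + 20.0 * np.cos(2 * np.pi * coords[..., 2]
                            / design.texture_period_mm)
        arr[sph] = TISSUE_HU + tex[sph]
        if design.slab_x_mm is not None:
            slab = coords[..., 0] >= design.slab_x_mm
            arr[slab] = SLAB_HU
        arr += rng.normal(scale=design.noise_sd, size=arr.shape)
        if design.artifact_phase is not None and p == design.artifact_phase:
            k = nz // 2
            arr[:, :, k] = arr[:, :, k - 1]   # duplicated-slice artifact
        images[label] = ImageVolume(np.clip(arr, -1090, 3090), tuple(sp))
    return images, gtv_ref, translations, phases


def phantom_masks(gtv_ref: BinaryMask, translations: np.ndarray,
                  images: dict, phases, inner: float = 3.0, outer: float = 3.0,
                  hu_threshold: float = 0.0) -> dict:
    """Per-phase tumour and corrected peritumour masks from the reference GTV."""
    from .roi_geometry import correct_high_density, peritumour_band
    out = {}
    for p, label in enumerate(phases):
        gtv = translate_mask(gtv_ref, translations[p])
        band = peritumour_band(gtv, inner=inner, outer=outer)
        band = correct_high_density(band, gtv, images[label],
                                    hu_threshold=hu_threshold)
        out[label] = {"tumour": gtv, "peritumour": band}
    return out
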