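"""Synthetic phantom cohorts with the statistical structure of a two-center
breast DCE-MRI study.

Each case is a 3-D volume holding a smooth background, an ellipsoidal tumor
filled with a stationary correlated random field (Gaussian-smoothed white
noise, so the correlation length and contrast are directly controllable),
and an additive peritumoral rim of configurable width and amplitude just
outside the tumor surface.  The three molecular-subtype profiles differ in
intratumoral texture, rim signal, and clinical-covariate log-odds, at
prevalences matching the modeled cohort (HR-positive 69.4%, HER2-enriched
14.0%, TNBC 16.6%).

Grids are anisotropic on purpose (default 96x96x48 at 0.9x0.9x2.0 mm) so
isotropic resampling does real work downstream.  A configurable fraction of
cases (default 10%) carries duplicate segmentations from a second session
and a second reader, feeding the ICC reproducibility stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import RoiMask, Volume

logger = logging.getLogger(__name__)

BPE_LEVELS = ("minimal", "mild", "moderate", "marked")
CATEGORICAL_COVARIATES = {
    # name: (reference category, alternative category, baseline log-odds of alt)
    "fgt": ("dense", "non-dense", 0.92),          # ~71.6% non-dense
    "margin": ("clear", "blurry", 1.39),          # ~80.1% blurry
    "aln_short_diameter": ("<=5mm", ">5mm", -0.70),  # ~33.2% >5mm
    "firmness": ("soft", "hard", 1.67),           # ~84.1% hard
    "mobility": ("pushable", "non-pushable", 1.02),  # ~73.5% non-pushable
    "menopause": ("pre", "post", -0.05),          # ~48.8% post
}


@dataclass(frozen=True)
class SubtypeProfile:
    """Generative parameters of one molecular subtype."""

    label: str
    prevalence: float
    texture_corr_length: float      # mm, spatial correlation of the tumor field
    texture_contrast: float         # intensity std of the tumor field
    rim_width: float                # mm, peritumoral enhancing rim
    rim_amplitude: float            # intensity units added in the rim
    covariate_logodds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.texture_corr_length <= 0:
            raise ValueError("texture correlation length must be > 0 mm")
        if self.texture_contrast < 0 or self.rim_width < 0:
            raise ValueError("texture contrast and rim width must be >= 0")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")


def default_profiles() -> tuple[SubtypeProfile, SubtypeProfile, SubtypeProfile]:
    """The three subtype profiles at the modeled cohort prevalences.

    Rim width/amplitude increase from HR-positive to TNBC, emulating the
    more pronounced peritumoral edema/angiogenesis of aggressive subtypes;
    ALN and palpation log-odds follow the reported directions of
    association (HR-positive with small nodes, TNBC/HER2 with large).
    """
    return (
        SubtypeProfile("HR-positive", 0.694, texture_corr_length=3.0,
                       texture_contrast=30.0, rim_width=2.0, rim_amplitude=40.0,
                       covariate_logodds={"aln_short_diameter": -0.9,
                                          "mobility": -0.6, "margin": 0.0,
                                          "fgt": 0.0, "firmness": 0.0,
                                          "menopause": 0.0, "bpe": 0.0}),
        SubtypeProfile("HER2-enriched", 0.140, texture_corr_length=4.5,
                       texture_contrast=60.0, rim_width=3.5, rim_amplitude=80.0,
                       covariate_logodds={"aln_short_diameter": 0.9,
                                          "mobility": 0.3, "margin": 0.6,
                                          "fgt": 0.0, "firmness": 0.3,
                                          "menopause": 0.0, "bpe": 0.3}),
        SubtypeProfile("TNBC", 0.166, texture_corr_length=6.0,
                       texture_contrast=90.0, rim_width=5.0, rim_amplitude=120.0,
                       covariate_logodds={"aln_short_diameter": 1.1,
                                          "mobility": 0.5, "margin": -0.6,
                                          "fgt": 0.0, "firmness": 0.5,
                                          "menopause": 0.0, "bpe": 0.5}),
    )


@dataclass(frozen=True)
class ImageParams:
    """Grid geometry and tumor size range for phantom generation."""

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (0.9, 0.9, 2.0)
    tumor_semiaxis_range_mm: tuple[float, float] = (5.0, 12.0)
    background_level: float = 200.0
    background_noise_std: float = 5.0
    min_inplane_diameter_mm: float = 10.0   # exclusion rule: tumors < 1 cm


@dataclass(frozen=True)
class ClinicalRecord:
    age: float
    tumor_size: float               # longest in-plane diameter, mm
    bpe: str
    fgt: str
    margin: str
    aln_short_diameter: str
    firmness: str
    mobility: str
    menopause: str

    def __post_init__(self):
        if self.bpe not in BPE_LEVELS:
            raise ValueError(f"unknown BPE level {self.bpe!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("age", "tumor_size", "bpe", "fgt", "margin",
                 "aln_short_diameter", "firmness", "mobility", "menopause")}


@dataclass(frozen=True)
class PhantomCase:
    case_id: str
    volume: Volume
    tumor_mask_r1s1: RoiMask
    clinical: ClinicalRecord
    subtype: str
    seed: int
    tumor_mask_r1s2: RoiMask | None = None   # reader 1, second session
    tumor_mask_r2: RoiMask | None = None     # reader 2

    @property
    def has_resegmentation(self) -> bool:
        return self.tumor_mask_r1s2 is not None and self.tumor_mask_r2 is not None


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _correlated_field(shape, spacing, corr_length_mm, std, rng) -> np.ndarray:
    """Stationary random field: Gaussian-smoothed white noise at unit variance
    rescaled to ``std``; kernel width = correlation length in voxels."""
    noise = rng.standard_normal(shape)
    sig = [corr_length_mm / s for s in spacing]
    sm = ndimage.gaussian_filter(noise, sigma=sig, mode="reflect")
    s = sm.std()
    return sm / s * std if s > 0 else sm


def generate_case(profile: SubtypeProfile, image_params: ImageParams,
                  seed: int, case_id: str = "",
                  with_resegmentation: bool = False,
                  perturb_magnitude: float = 0.1) -> PhantomCase:
    """One phantom case; a pure function of (profile, image_params, seed)."""
    rng = np.random.default_rng(seed)
    shape = image_params.shape
    spacing = np.asarray(image_params.spacing)
    extent = (np.asarray(shape) - 1) * spacing

    lo, hi = image_params.tumor_semiaxis_range_mm
    for attempt in range(20):
        semi = rng.uniform(lo, hi, size=3)  # mm
        if 2 * max(semi[0], semi[1]) >= image_params.min_inplane_diameter_mm:
            break
        logger.info("case %s: tumor below the 10 mm in-plane rule, resampled "
                    "(attempt %d)", case_id, attempt + 1)
    needed = 2 * (semi + profile.rim_width + 4.0)
    for ax in range(3):
        if needed[ax] > extent[ax]:
            raise ValueError(
                f"tumor (+rim) extent {needed[ax]:.1f} mm exceeds grid extent "
                f"{extent[ax]:.1f} mm along axis {ax}")

    center = extent / 2.0
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    tumor = d2 <= 1.0

    values = (image_params.background_level
              + rng.standard_normal(shape) * image_params.background_noise_std)
    if profile.texture_contrast > 0:
        tex = _correlated_field(shape, spacing, profile.texture_corr_length,
                                profile.texture_contrast, rng)
        values[tumor] += tex[tumor] + 100.0  # tumor enhances over background
    else:
        values[tumor] += 100.0
    if profile.rim_width > 0 and profile.rim_amplitude != 0:
        dist = ndimage.distance_transform_edt(~tumor, sampling=spacing)
        rim = (dist > 0) & (dist <= profile.rim_width)
        values[rim] += profile.rim_amplitude
    np.clip(values, 1e-3, None, out=values)

    mask = RoiMask(tumor, tuple(spacing), role="intratumoral")
    r1s2 = r2 = None
    if with_resegmentation:
        r1s2 = perturb_mask(mask, perturb_magnitude,
                            int(rng.integers(0, 2 ** 31)))
        r2 = perturb_mask(mask, perturb_magnitude,
                          int(rng.integers(0, 2 ** 31)))
    tumor_size = float(2 * max(semi[0], semi[1]))
    clinical = sample_clinical(profile, tumor_size,
                               int(rng.integers(0, 2 ** 31)))
    return PhantomCase(case_id=case_id,
                       volume=Volume(values, tuple(spacing)),
                       tumor_mask_r1s1=mask, tumor_mask_r1s2=r1s2,
                       tumor_mask_r2=r2, clinical=clinical,
                       subtype=profile.label, seed=seed)


def perturb_mask(mask: RoiMask, magnitude: float, seed: int) -> RoiMask:
    """Flip boundary voxels with probability ``magnitude``.

    Stands in for a second reader/session segmentation: only voxels on the
    inner or outer boundary (6-connectivity) can change, so expected Dice
    decreases monotonically with the magnitude.  Output is never empty.
    """
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask")
    if not 0 <= magnitude <= 0.5:
        raise ValueError(f"perturbation magnitude must be in [0, 0.5], got {magnitude}")
    m = mask.values
    if magnitude == 0:
        return mask
    rng = np.random.default_rng(seed)
    inner = m & ~ndimage.binary_erosion(m)
    outer = ndimage.binary_dilation(m) & ~m
    boundary = inner | outer
    flip = boundary & (rng.random(m.shape) < magnitude)
    out = np.where(flip, ~m, m)
    if not out.any():
        out = m.copy()  # post-condition: nonempty
    return RoiMask(out, mask.spacing, mask.origin, role=mask.role,
                   ring_distance=mask.ring_distance)


def dice(a: RoiMask, b: RoiMask) -> float:
    inter = (a.values & b.values).sum()
    return 2.0 * inter / (a.values.sum() + b.values.sum())


def sample_clinical(profile: SubtypeProfile, tumor_size: float,
                    seed: int, age_bounds: tuple[float, float] = (25.0, 80.0)
                    ) -> ClinicalRecord:
    """Draw the clinical-radiological covariates from the profile's logistic
    shifts; deterministic in the seed."""
    rng = np.random.default_rng(seed)
    shifts = profile.covariate_logodds
    cats = {}
    for name, (ref, alt, base) in CATEGORICAL_COVARIATES.items():
        p_alt = _sigmoid(base + shifts.get(name, 0.0))
        cats[name] = alt if rng.random() < p_alt else ref
    # BPE: 4-level baseline (4.3 / 54 / 29.1 / 12.6 %) tilted by the profile
    # shift through exponential reweighting of the upper levels
    base_p = np.array([0.043, 0.540, 0.291, 0.126])
    w = base_p * np.exp(shifts.get("bpe", 0.0) * np.arange(4) / 3.0)
    w /= w.sum()
    bpe = BPE_LEVELS[rng.choice(4, p=w)]
    age = float(np.clip(rng.normal(50.0, 9.3), *age_bounds))
    return ClinicalRecord(age=age, tumor_size=tumor_size, bpe=bpe,
                          fgt=cats["fgt"], margin=cats["margin"],
                          aln_short_diameter=cats["aln_short_diameter"],
                          firmness=cats["firmness"], mobility=cats["mobility"],
                          menopause=cats["menopause"])


def generate_cohort(profiles=None, n_cases: int = 100, seed: int = 0,
                    image_params: ImageParams | None = None,
                    resegmentation_fraction: float = 0.1,
                    center: str = "center1") -> tuple[list[PhantomCase], pd.DataFrame]:
    """A cohort of phantom cases plus the flat cohort table.

    Subtype counts are multinomial in the profile prevalences; an exact
    round(fraction x n) subset carries the duplicate r1s2/r2 segmentations.
    """
    if profiles is None:
        profiles = default_profiles()
    if n_cases < 30:
        raise ValueError("cohort size must be >= 30")
    prev = np.array([p.prevalence for p in profiles])
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError(f"profile prevalences sum to {prev.sum():.4f}, not 1")
    if image_params is None:
        image_params = ImageParams()
    rng = np.random.default_rng(seed)
    assignments = rng.choice(len(profiles), size=n_cases, p=prev)
    n_reseg = int(round(resegmentation_fraction * n_cases))
    reseg_idx = set(rng.choice(n_cases, size=n_reseg, replace=False).tolist())
    case_seeds = np.random.SeedSequence(seed).spawn(n_cases)
    cases: list[PhantomCase] = []
    rows = []
    for i in range(n_cases):
        prof = profiles[assignments[i]]
        cid = f"{center}_{i:04d}"
        cseed = int(case_seeds[i].generate_state(1)[0] % (2 ** 31))
        case = generate_case(prof, image_params, cseed, case_id=cid,
                             with_resegmentation=(i in reseg_idx))
        cases.append(case)
        row = {"case_id": cid, "subtype": case.subtype, "center": center,
               "has_resegmentation": case.has_resegmentation}
        row.update(case.clinical.to_dict())
        rows.append(row)
    return cases, pd.DataFrame(rows)
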