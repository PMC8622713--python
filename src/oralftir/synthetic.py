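"""Seeded synthetic FTIR imaging cohorts with known ground truth.

The generator emulates transmission-mode FTIR imaging of deparaffinized oral
biopsy sections: 16x16-pixel imaging areas whose pixel spectra are sums of
Gaussian fingerprint-region bands, degraded by multiplicative scatter, a
polynomial baseline, and additive noise, then converted to transmission
(T = 10^-A). Three epithelial disease profiles (hyperkeratosis, dysplasia,
carcinoma) follow the band-intensity orderings seen in diseased oral
epithelium: protein amide I/II bands fall and nucleic-acid/carbohydrate
bands (1240, 1154, 1080, 1030, 966 cm^-1) rise with malignant progression,
and the amide II right shoulder red-shifts for dysplastic and malignant
tissue. Dysplasia is split into two latent sub-profiles (HK-like vs
OSCC-like) so that grading recovery can be scored against ground truth.
No band is placed in 1750-1700 cm^-1: free lipids are removed by
deparaffinization in the tissue preparation this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import SpectrumSet, WavenumberGrid, concat, make_grid, make_meta

#: Spectral profiles the generator knows about. HK/OSCC are the two training
#: classes; the two OED_* profiles are latent dysplasia grades; STROMA is the
#: non-epithelial tissue mixed into imaging areas.
PROFILES = ("HK", "OED_HKlike", "OED_OSCClike", "OSCC", "STROMA")

#: Pixels per imaging area edge (100 um x 100 um at 6.25 um pixels).
AREA_EDGE = 16

#: Floor applied when converting absorbance to transmission, so that
#: log10(1/T) stays finite. Test-visible, documented behaviour.
TRANSMISSION_FLOOR = 1e-6

#: Tissue labels carried as per-pixel ground truth.
TISSUE_LABELS = ("epithelium", "stroma", "outlier")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band with per-profile amplitudes."""

    center: float
    fwhm: float
    amplitude_by_class: Mapping[str, float]

    def __post_init__(self) -> None:
        if not (950.0 <= self.center <= 1800.0):
            raise ValueError(f"band center {self.center} outside 1800-950 cm^-1")
        if 1700.0 < self.center < 1750.0:
            raise ValueError(
                "no bands allowed in 1750-1700 cm^-1: the free-lipid band is "
                "absent after deparaffinization"
            )
        if self.fwhm < 8.0:
            raise ValueError("band FWHM must be >= 8 cm^-1 (instrument-limited width)")
        for profile, amp in self.amplitude_by_class.items():
            if profile not in PROFILES:
                raise ValueError(f"unknown profile {profile!r}")
            if amp < 0:
                raise ValueError(f"negative amplitude for {profile}")

    def amplitude(self, profile: str) -> float:
        return float(self.amplitude_by_class.get(profile, 0.0))


def default_band_table(
    amideII_redshift_oed: float = 8.0, amideII_redshift_oscc: float = 14.0
) -> list[BandSpec]:
    """Fingerprint-region band table for the five tissue profiles.

    Amplitudes are in absorbance units, chosen so that amide I/II and the
    amide III band (1650, 1548, 1310 cm^-1) descend HK > OED_* > OSCC while
    phosphate and carbohydrate bands (1240, 1154, 1080, 1030, 966 cm^-1)
    descend OSCC > OED_* > HK. The amide II red shift is realized as a small
    shoulder sub-band at 1548 minus the per-profile shift. Stroma gets a
    collagen-like profile with a distinctive 1204 cm^-1 band so clustering
    can separate it from epithelium.
    """

    def amps(hk: float, hkl: float, osccl: float, oscc: float, stroma: float) -> dict:
        return {
            "HK": hk,
            "OED_HKlike": hkl,
            "OED_OSCClike": osccl,
            "OSCC": oscc,
            "STROMA": stroma,
        }

    table = [
        # protein bands: fall with malignant progression
        BandSpec(1650.0, 45.0, amps(1.00, 0.88, 0.62, 0.45, 1.10)),  # amide I
        BandSpec(1548.0, 35.0, amps(0.62, 0.55, 0.42, 0.33, 0.70)),  # amide II
        BandSpec(1310.0, 30.0, amps(0.30, 0.26, 0.20, 0.15, 0.25)),  # amide III
        # amide II red-shifted right shoulder (dysplastic / malignant only)
        BandSpec(
            1548.0 - amideII_redshift_oed,
            30.0,
            {"OED_HKlike": 0.05, "OED_OSCClike": 0.06},
        ),
        BandSpec(1548.0 - amideII_redshift_oscc, 30.0, {"OSCC": 0.10}),
        # nucleic-acid / carbohydrate bands: rise with malignant progression
        BandSpec(1240.0, 30.0, amps(0.22, 0.30, 0.40, 0.50, 0.50)),  # PO2- asym
        BandSpec(1154.0, 25.0, amps(0.10, 0.14, 0.20, 0.26, 0.10)),  # C-O carbohydrate
        BandSpec(1080.0, 30.0, amps(0.25, 0.33, 0.45, 0.55, 0.28)),  # PO2- sym
        BandSpec(1030.0, 30.0, amps(0.20, 0.28, 0.40, 0.50, 0.12)),  # glycogen
        BandSpec(966.0, 25.0, amps(0.06, 0.10, 0.16, 0.22, 0.08)),  # DNA backbone
        # broad unspecific CH-deformation background common to all tissue
        BandSpec(1400.0, 120.0, amps(0.30, 0.30, 0.30, 0.30, 0.35)),
        # collagen triplet, essentially stroma-only (dense connective tissue)
        BandSpec(1204.0, 25.0, amps(0.03, 0.03, 0.03, 0.03, 0.65)),
        BandSpec(1280.0, 25.0, amps(0.02, 0.02, 0.02, 0.02, 0.40)),
        BandSpec(1338.0, 22.0, amps(0.02, 0.02, 0.02, 0.02, 0.30)),
    ]
    return table


@dataclass(frozen=True)
class DistortionConfig:
    """Instrumental / physical artifacts applied to clean absorbance spectra.

    ``scatter_scale_range`` is the interval of per-pixel multiplicative
    factors (light scattering / thickness); the polynomial baseline is drawn
    on a Legendre basis with per-order coefficient SDs; ``baseline_offset``
    is a constant substrate absorbance keeping transmission below 1 for
    ordinary pixels; outlier pixels get their baseline coefficients and
    noise inflated by ``outlier_boost``.
    """

    scatter_scale_range: tuple[float, float] = (0.85, 1.15)
    baseline_poly_order: int = 2
    baseline_coeff_sd: tuple[float, ...] = (0.04, 0.03, 0.02)
    baseline_offset: float = 0.25
    noise_sd: float = 0.01
    outlier_pixel_fraction: float = 0.02
    outlier_boost: float = 10.0
    amideII_redshift: tuple[float, float] = (8.0, 14.0)  # (OED, OSCC) cm^-1
    band_jitter_sd: float = 0.05  # per-pixel biological amplitude variation
    area_jitter_sd: float = 0.05  # per-area (shared) amplitude variation

    def __post_init__(self) -> None:
        lo, hi = self.scatter_scale_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("scatter_scale_range must be a positive interval")
        if not (0.0 <= self.outlier_pixel_fraction < 1.0):
            raise ValueError("outlier_pixel_fraction must lie in [0, 1)")
        if len(self.baseline_coeff_sd) != self.baseline_poly_order + 1:
            raise ValueError("need one baseline coefficient SD per polynomial order")


def zero_distortion() -> DistortionConfig:
    """A config that applies no artifact at all (clean round-trip)."""
    return DistortionConfig(
        scatter_scale_range=(1.0, 1.0),
        baseline_coeff_sd=(0.0, 0.0, 0.0),
        baseline_offset=0.0,
        noise_sd=0.0,
        outlier_pixel_fraction=0.0,
        band_jitter_sd=0.0,
        area_jitter_sd=0.0,
    )


#: Latent dysplasia grades a cohort scenario can assign.
OED_GRADES = ("HKlike", "OSCClike", "borderline")

#: Default per-sample latent grades for the 11 dysplasia samples, indexed
#: D-01..D-11: six HK-like, four OSCC-like, one borderline.
DEFAULT_OED_GROUND_TRUTH = (
    "OSCClike",  # D-01
    "HKlike",    # D-02
    "HKlike",    # D-03
    "OSCClike",  # D-04
    "HKlike",    # D-05
    "OSCClike",  # D-06
    "HKlike",    # D-07
    "OSCClike",  # D-08
    "HKlike",    # D-09
    "borderline",  # D-10
    "HKlike",    # D-11
)


@dataclass(frozen=True)
class CohortScenario:
    """Cohort design: how many samples of each class, areas per sample, seed.

    The default mirrors the study design this pipeline targets: 12 HK, 11
    OSCC and 11 OED biopsy samples, the OED latent grades being 6 HK-like,
    4 OSCC-like and 1 borderline.
    """

    n_hk_samples: int = 12
    n_oscc_samples: int = 11
    oed_ground_truth: tuple[str, ...] = DEFAULT_OED_GROUND_TRUTH
    areas_per_sample: int = 3
    stroma_fraction: float = 0.2
    seed: int = 42
    grid_high: float = 1800.0
    grid_low: float = 950.0
    grid_step: float = 2.0

    def __post_init__(self) -> None:
        if self.areas_per_sample < 2:
            raise ValueError("areas_per_sample must be >= 2 (two representatives per sample)")
        if not (0.0 <= self.stroma_fraction < 1.0):
            raise ValueError("stroma_fraction must lie in [0, 1)")
        for grade in self.oed_ground_truth:
            if grade not in OED_GRADES:
                raise ValueError(f"unknown OED grade {grade!r}")

    @property
    def n_samples(self) -> int:
        return self.n_hk_samples + self.n_oscc_samples + len(self.oed_ground_truth)

    def grid(self) -> WavenumberGrid:
        return make_grid(self.grid_high, self.grid_low, self.grid_step)

    def sample_table(self) -> pd.DataFrame:
        """One row per sample: id, class label, latent grade (OED only)."""
        rows = []
        for i in range(self.n_hk_samples):
            rows.append({"sample_id": f"H-{i + 1:02d}", "class_label": "H", "latent_grade": ""})
        for i, grade in enumerate(self.oed_ground_truth):
            rows.append({"sample_id": f"D-{i + 1:02d}", "class_label": "D", "latent_grade": grade})
        for i in range(self.n_oscc_samples):
            rows.append({"sample_id": f"C-{i + 1:02d}", "class_label": "C", "latent_grade": ""})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectrum construction
# ---------------------------------------------------------------------------


def _gaussian_basis(band_table: Sequence[BandSpec], grid: WavenumberGrid) -> np.ndarray:
    """(n_bands, n_points) matrix of unit-amplitude Gaussians."""
    x = grid.values[None, :]
    centers = np.array([b.center for b in band_table])[:, None]
    sigmas = np.array([b.fwhm for b in band_table])[:, None] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if len(band_table) == 0:
        return np.zeros((0, len(grid)))
    return np.exp(-0.5 * ((x - centers) / sigmas) ** 2)


def build_clean_spectrum(
    class_label: str, band_table: Sequence[BandSpec], grid: WavenumberGrid
) -> np.ndarray:
    """Noise-free absorbance spectrum of one tissue profile.

    ``class_label`` is one of the generator profiles (``HK``, ``OED_HKlike``,
    ``OED_OSCClike``, ``OSCC``, ``STROMA``). The result is a sum of Gaussian
    bands and is nonnegative everywhere.
    """
    if class_label not in PROFILES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {PROFILES}")
    basis = _gaussian_basis(band_table, grid)
    amps = np.array([b.amplitude(class_label) for b in band_table])
    if amps.size == 0:
        return np.zeros(len(grid))
    return amps @ basis


def _legendre_basis(order: int, n_points: int) -> np.ndarray:
    """(order+1, n_points) Legendre polynomials on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_points)
    return np.polynomial.legendre.legvander(x, order).T


def absorbance_to_transmission(absorbance: np.ndarray) -> np.ndarray:
    """T = 10^-A, clipped to [TRANSMISSION_FLOOR, 1] so log stays defined."""
    return np.clip(10.0 ** (-np.asarray(absorbance, dtype=float)), TRANSMISSION_FLOOR, 1.0)


def distort_to_transmission(
    clean: np.ndarray,
    cfg: DistortionConfig,
    rng: np.random.Generator,
    outlier: np.ndarray | bool = False,
) -> np.ndarray:
    """Apply scatter scale, polynomial baseline and noise, then T = 10^-A.

    Accepts a single spectrum or a (n, p) stack; ``outlier`` marks rows whose
    baseline coefficients and noise are inflated by ``cfg.outlier_boost``.
    """
    rows = np.atleast_2d(np.asarray(clean, dtype=float))
    n, p = rows.shape
    outlier = np.broadcast_to(np.asarray(outlier, dtype=bool), (n,)).astype(float)
    boost = 1.0 + (cfg.outlier_boost - 1.0) * outlier  # 1 or outlier_boost

    lo, hi = cfg.scatter_scale_range
    scale = rng.uniform(lo, hi, size=n)

    basis = _legendre_basis(cfg.baseline_poly_order, p)
    sds = np.asarray(cfg.baseline_coeff_sd)
    coeffs = rng.normal(0.0, 1.0, size=(n, len(sds))) * sds * boost[:, None]
    baseline = cfg.baseline_offset + coeffs @ basis

    noise = rng.normal(0.0, 1.0, size=(n, p)) * cfg.noise_sd * boost[:, None]

    absorbance = scale[:, None] * rows + baseline + noise
    t = absorbance_to_transmission(absorbance)
    return t[0] if np.asarray(clean).ndim == 1 else t


# ---------------------------------------------------------------------------
# areas and cohorts
# ---------------------------------------------------------------------------


def generate_area(
    sample_id: str,
    class_label: str,
    scenario: CohortScenario,
    cfg: DistortionConfig,
    rng: np.random.Generator,
    area_id: str | None = None,
    band_table: Sequence[BandSpec] | None = None,
    sample_class: str | None = None,
) -> SpectrumSet:
    """One 16x16 imaging area of transmission pixel spectra with ground truth.

    ``class_label`` selects the epithelium profile; stroma pixels are drawn
    from the STROMA profile at ``scenario.stroma_fraction``; outlier pixels
    are injected at ``cfg.outlier_pixel_fraction`` with inflated baseline and
    noise. Ground-truth tissue labels ride along in the metadata ``tissue``
    column; ``sample_class`` (H/D/C) defaults to H for HK, C for OSCC, D for
    the dysplasia profiles.
    """
    if class_label not in PROFILES:
        raise ValueError(f"unknown class label {class_label!r}")
    if band_table is None:
        band_table = default_band_table(*cfg.amideII_redshift)
    grid = scenario.grid()
    n_pix = AREA_EDGE * AREA_EDGE

    stroma = rng.random(n_pix) < scenario.stroma_fraction
    outlier = rng.random(n_pix) < cfg.outlier_pixel_fraction

    basis = _gaussian_basis(band_table, grid)
    n_bands = len(band_table)
    amp_by_profile = {
        prof: np.array([b.amplitude(prof) for b in band_table])
        for prof in (class_label, "STROMA")
    }
    base_amps = np.where(
        stroma[:, None],
        amp_by_profile["STROMA"][None, :],
        amp_by_profile[class_label][None, :],
    )
    area_jitter = 1.0 + cfg.area_jitter_sd * rng.normal(size=n_bands)
    pixel_jitter = 1.0 + cfg.band_jitter_sd * rng.normal(size=(n_pix, n_bands))
    amps = np.clip(base_amps * area_jitter[None, :] * pixel_jitter, 0.0, None)
    clean = amps @ basis

    transmission = distort_to_transmission(clean, cfg, rng, outlier=outlier)

    tissue = np.where(outlier, "outlier", np.where(stroma, "stroma", "epithelium"))
    if sample_class is None:
        sample_class = {"HK": "H", "OSCC": "C"}.get(class_label, "D")
    if area_id is None:
        area_id = f"{sample_id}_a01"
    meta = make_meta(
        sample_id,
        area_id,
        sample_class,
        role="pixel",
        n=n_pix,
        tissue=tissue,
        profile=class_label,
        row=np.repeat(np.arange(AREA_EDGE), AREA_EDGE),
        col=np.tile(np.arange(AREA_EDGE), AREA_EDGE),
    )
    return SpectrumSet(grid=grid, intensities=transmission, meta=meta, mode="transmission")


@dataclass
class Cohort:
    """A generated cohort: all pixel spectra plus sample-level metadata."""

    pixels: SpectrumSet
    samples: pd.DataFrame
    scenario: CohortScenario
    distortion: DistortionConfig

    @property
    def areas(self) -> list[str]:
        return sorted(self.pixels.meta["area_id"].unique())


def _area_profiles(class_label: str, latent_grade: str, n_areas: int) -> list[str]:
    """Epithelium profile for each imaging area of one sample.

    A borderline dysplasia sample draws half its areas (rounding up) from the
    HK-like profile and the rest from the OSCC-like profile; every other
    sample uses a single profile throughout.
    """
    if class_label == "H":
        return ["HK"] * n_areas
    if class_label == "C":
        return ["OSCC"] * n_areas
    if latent_grade == "HKlike":
        return ["OED_HKlike"] * n_areas
    if latent_grade == "OSCClike":
        return ["OED_OSCClike"] * n_areas
    n_hk = (n_areas + 1) // 2
    return ["OED_HKlike"] * n_hk + ["OED_OSCClike"] * (n_areas - n_hk)


def generate_cohort(
    scenario: CohortScenario | None = None,
    cfg: DistortionConfig | None = None,
    band_table: Sequence[BandSpec] | None = None,
) -> Cohort:
    """Generate the full seeded cohort (one set of areas per sample).

    Deterministic: the same scenario seed reproduces the cohort bit for bit.
    """
    scenario = scenario or CohortScenario()
    cfg = cfg or DistortionConfig()
    if band_table is None:
        band_table = default_band_table(*cfg.amideII_redshift)
    rng = np.random.default_rng(scenario.seed)

    samples = scenario.sample_table()
    area_sets: list[SpectrumSet] = []
    for rec in samples.itertuples(index=False):
        profiles = _area_profiles(rec.class_label, rec.latent_grade, scenario.areas_per_sample)
        for j, profile in enumerate(profiles):
            area_sets.append(
                generate_area(
                    rec.sample_id,
                    profile,
                    scenario,
                    cfg,
                    rng,
                    area_id=f"{rec.sample_id}_a{j + 1:02d}",
                    band_table=band_table,
                    sample_class=rec.class_label,
                )
            )
    return Cohort(pixels=concat(area_sets), samples=samples, scenario=scenario, distortion=cfg)
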