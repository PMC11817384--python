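"""Seeded synthetic SWIR cubes of dried laver sheets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: 288-band reflectance spectra on a 980–2576 nm axis whose
absorption-band depths track three quality indices (moisture, crude
protein, cutting stress), sheets imaged as ``lines x samples`` cubes with
a smooth illumination field, bright spectrally-flat pore pixels at a
controlled area fraction, and a matching white-reference cube per sheet.

Spectra follow a Beer–Lambert-style model: a smooth quadratic baseline
attenuated by ``exp(-sum_k c_k A_k(lambda))`` where ``A_k`` is a sum of
Gaussian absorption bands for constituent ``k`` and ``c_k`` its
concentration.  Cutting stress enters through a latent polysaccharide
density: the texture of the sheet is carried by polysaccharide C=O / C=C
bands in the 2045–2261 nm and 2554–2576 nm regions, so the kg·mm cutting
stress value is used directly as the concentration of that constituent.

Quality-index values are drawn per grade as truncated normals clustered
away from the grading cut points — dried-laver products are discrete
articles whose replicate spread is far smaller than the between-product
spread, so grades correspond to separated clusters rather than uniform
fills of each grade interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.stats import truncnorm

from .cube_io import SpectralCube
from .grading import DEFAULT_CRITERIA, assign_grades, assign_zone

__all__ = [
    "AbsorptionBand",
    "QualityRecord",
    "GeneratorConfig",
    "GroundTruth",
    "DatasetItem",
    "DEFAULT_BANDS",
    "DEFAULT_CLASS_MIX",
    "CONSTITUENT_RANGES",
    "wavelength_axis",
    "class_counts",
    "make_spectrum",
    "generate_cube",
    "generate_dataset",
]

N_BANDS = 288
LAMBDA_MIN = 980.0
LAMBDA_MAX = 2576.0


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption feature of a constituent.

    ``strength`` is the peak absorbance contributed per unit constituent
    concentration (g/100 g for moisture/protein, kg·mm for the
    polysaccharide latent behind cutting stress).
    """

    center_nm: float
    width_nm: float  # Gaussian sigma
    strength: float
    constituent: str

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")


@dataclass(frozen=True)
class QualityRecord:
    """Reference quality-index values for one dried-laver sheet."""

    sample_id: str
    moisture: float  # g/100 g
    protein: float  # g/100 g
    cutting_stress: float  # kg·mm, on the grading scale

    def __post_init__(self) -> None:
        if min(self.moisture, self.protein, self.cutting_stress) <= 0:
            raise ValueError("quality-index values must be positive")

    def concentration(self, constituent: str) -> float:
        if constituent == "moisture":
            return self.moisture
        if constituent == "protein":
            return self.protein
        if constituent == "polysaccharide":
            # latent texture constituent; identity map onto the kg·mm scale
            return self.cutting_stress
        raise KeyError(f"unknown constituent {constituent!r}")


# Band library.  Moisture: O-H bands at 1396–1468, 1885–1984 and
# 2543–2576 nm.  Protein: amide/carboxyl bands at 1691–1746, 1896–2032 and
# 2455–2576 nm.  Polysaccharide (texture): C=O / C=C at 2045–2261 and
# 2554–2576 nm.  Centers sit mid-range; sigmas keep most mass inside.
DEFAULT_BANDS: tuple[AbsorptionBand, ...] = (
    AbsorptionBand(1432.0, 16.0, 0.010, "moisture"),
    AbsorptionBand(1935.0, 22.0, 0.022, "moisture"),
    AbsorptionBand(2560.0, 9.0, 0.012, "moisture"),
    AbsorptionBand(1718.0, 12.0, 0.0040, "protein"),
    AbsorptionBand(1964.0, 30.0, 0.0050, "protein"),
    AbsorptionBand(2515.0, 26.0, 0.0045, "protein"),
    AbsorptionBand(2150.0, 48.0, 0.45, "polysaccharide"),
    AbsorptionBand(2565.0, 7.0, 0.35, "polysaccharide"),
)

# Critical wavelength ranges (nm) each index should light up under VIP.
INDEX_BAND_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "moisture": ((1396.0, 1468.0), (1885.0, 1984.0), (2543.0, 2576.0)),
    "protein": ((1691.0, 1746.0), (1896.0, 2032.0), (2455.0, 2576.0)),
    "cutting_stress": ((2045.0, 2261.0), (2554.0, 2576.0)),
}

# Default grade-combination mix: six (moisture, protein, cutting) grade
# triples spanning both quality zones, equal weights.
DEFAULT_CLASS_MIX: dict[tuple[int, int, int], float] = {
    (1, 1, 1): 1 / 6,
    (1, 1, 2): 1 / 6,
    (3, 1, 1): 1 / 6,
    (1, 2, 2): 1 / 6,
    (1, 2, 3): 1 / 6,
    (1, 3, 3): 1 / 6,
}

# Per-grade concentration clusters: (mean, sd, low, high) truncated normals.
# Dried-laver articles are discrete products whose grade groups separate
# under one-way ANOVA + Tukey HSD, so adjacent grade clusters keep margins
# of >~1.5 within-cluster sd around the grading cut points — products do
# not straddle a cut.
CONSTITUENT_RANGES: dict[str, dict[int, tuple[float, float, float, float]]] = {
    "moisture": {
        1: (8.5, 1.2, 6.07, 11.3),
        3: (12.5, 0.25, 12.15, 13.0),
    },
    "protein": {
        1: (39.0, 2.0, 36.0, 45.0),
        2: (32.5, 1.0, 30.5, 34.5),
        3: (28.8, 0.5, 28.0, 29.7),
    },
    "cutting_stress": {
        1: (0.50, 0.035, 0.47, 0.62),
        2: (0.39, 0.025, 0.345, 0.435),
        3: (0.28, 0.025, 0.20, 0.315),
    },
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults mirror the imaging setup being emulated: 288 bands over
    980–2576 nm, a sheet big enough for the 50 x 300 ROI, ~3% pore area,
    additive reflectance noise of 0.01 per pixel-band.
    """

    n_samples: int = 100
    lines: int = 64
    samples_px: int = 320
    n_bands: int = N_BANDS
    lambda_min: float = LAMBDA_MIN
    lambda_max: float = LAMBDA_MAX
    pore_fraction: float = 0.0294
    noise_sd: float = 0.01
    seed: int = 0
    class_mix: dict[tuple[int, int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    field_amplitude: float = 0.10  # smooth multiplicative spatial field
    bands: tuple[AbsorptionBand, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.lines < 50 or self.samples_px < 300:
            raise ValueError("pixel dims must fit the 50x300 ROI")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not self.lambda_min < self.lambda_max:
            raise ValueError("lambda_min must be < lambda_max")
        if not 0.0 <= self.pore_fraction < 0.5:
            raise ValueError("pore_fraction must be in [0, 0.5)")
        if self.pore_fraction > 0.2:
            raise ValueError("pore_fraction above 0.2 is outside the supported regime")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")

    def axis(self) -> np.ndarray:
        return np.linspace(self.lambda_min, self.lambda_max, self.n_bands)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    records: list[QualityRecord]
    grades: list[tuple[int, int, int]]
    zones: list[int]
    pore_masks: list[np.ndarray]
    band_centers: dict[str, tuple[float, ...]]


@dataclass
class DatasetItem:
    """One sheet: raw cube (reflectance x illumination), its white cube, record."""

    raw: SpectralCube
    white: SpectralCube
    record: QualityRecord


def wavelength_axis(
    n_bands: int = N_BANDS, lambda_min: float = LAMBDA_MIN, lambda_max: float = LAMBDA_MAX
) -> np.ndarray:
    """Uniform 288-band axis, 980–2576 nm (step ~5.57 nm)."""
    return np.linspace(lambda_min, lambda_max, n_bands)


def default_baseline(axis: np.ndarray) -> np.ndarray:
    """Smooth quadratic tissue baseline, ~0.56 at the blue end, ~0.36 at the red."""
    x = (axis - axis[0]) / (axis[-1] - axis[0])  # 0..1
    return 0.56 - 0.14 * x - 0.06 * x**2


def make_spectrum(
    record: QualityRecord,
    bands: tuple[AbsorptionBand, ...],
    axis: np.ndarray,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form reflectance spectrum of one tissue pixel.

    ``R(l) = baseline(l) * exp(-sum_k c_k sum_j s_j g(l; c_j, w_j)) + noise``,
    clipped to (0, 1.2).  Raises ``KeyError`` if a band references a
    constituent the record cannot supply.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or (axis.size > 1 and not np.all(np.diff(axis) > 0)):
        raise ValueError("wavelength axis must be 1-D strictly increasing")
    if baseline is None:
        baseline = default_baseline(axis)
    absorbance = np.zeros_like(axis)
    for b in bands:
        c = record.concentration(b.constituent)
        absorbance += c * b.strength * np.exp(-((axis - b.center_nm) ** 2) / (2 * b.width_nm**2))
    refl = baseline * np.exp(-absorbance)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        refl = refl + rng.normal(0.0, noise_sd, size=axis.size)
    return np.clip(refl, 1e-6, 1.2)


def _smooth_field(lines: int, samples: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1-a, 1+a] via bicubic control grid."""
    if amplitude == 0:
        return np.ones((lines, samples))
    n_ctrl = 5
    ctrl = rng.uniform(-1.0, 1.0, size=(n_ctrl, n_ctrl))
    spl = RectBivariateSpline(
        np.linspace(0, lines - 1, n_ctrl), np.linspace(0, samples - 1, n_ctrl), ctrl, kx=3, ky=3
    )
    f = spl(np.arange(lines), np.arange(samples))
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    field = 1.0 + amplitude * f
    # unit spatial mean: the field models within-sheet texture, not the
    # sheet-level brightness offset that white calibration absorbs
    return field / field.mean()


def generate_cube(
    record: QualityRecord,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[SpectralCube, np.ndarray]:
    """Reflectance cube of one sheet plus its boolean pore mask.

    Tissue pixels share the record's closed-form spectrum modulated by a
    smooth multiplicative spatial field; pore pixels are bright
    (0.9–1.0) and spectrally flat, resembling the white background seen
    through the sheet.  The realized pore-pixel count is the rounded
    target, so the realized fraction is within rounding of
    ``config.pore_fraction``.
    """
    axis = config.axis()
    lines, samples = config.lines, config.samples_px
    tissue = make_spectrum(record, config.bands, axis)
    fld = _smooth_field(lines, samples, config.field_amplitude, rng)
    data = fld[:, :, None] * tissue[None, None, :]

    mask = np.zeros((lines, samples), dtype=bool)
    n_pore = int(round(config.pore_fraction * lines * samples))
    if n_pore > 0:
        flat_idx = rng.choice(lines * samples, size=n_pore, replace=False)
        mask.flat[flat_idx] = True
        pore_levels = rng.uniform(0.9, 1.0, size=n_pore)
        data[mask] = pore_levels[:, None]
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    data = np.clip(data, 1e-6, 1.2).astype(np.float32)  # float32 keeps datasets in memory
    meta = {
        "sample id": record.sample_id,
        "description": "synthetic dried-laver sheet",
    }
    return SpectralCube(data, axis, meta), mask


def _white_cube(config: GeneratorConfig, rng: np.random.Generator) -> SpectralCube:
    """Spatially smooth white-reference cube, reflectance ~= 1."""
    fld = _smooth_field(config.lines, config.samples_px, 0.02, rng).astype(np.float32)
    # spectrally flat: keep a broadcast view, one spatial plane in memory
    data = np.broadcast_to(fld[:, :, None], (config.lines, config.samples_px, config.n_bands))
    return SpectralCube(data, config.axis(), {"description": "synthetic white reference"})


def class_counts(config: GeneratorConfig) -> dict[tuple[int, int, int], int]:
    """Largest-remainder apportionment of n_samples over the class mix."""
    combos = list(config.class_mix.items())
    if config.n_samples < sum(1 for _, p in combos if p > 0):
        raise ValueError("n_samples smaller than the number of mixed classes")
    quotas = [(combo, p * config.n_samples) for combo, p in combos]
    counts = {combo: int(np.floor(q)) for combo, q in quotas}
    short = config.n_samples - sum(counts.values())
    by_frac = sorted(quotas, key=lambda cq: cq[1] - np.floor(cq[1]), reverse=True)
    for combo, _ in by_frac[:short]:
        counts[combo] += 1
    return counts


def _draw_index(index: str, grade: int, rng: np.random.Generator) -> float:
    try:
        mean, sd, lo, hi = CONSTITUENT_RANGES[index][grade]
    except KeyError as exc:
        raise ValueError(f"no generator cluster for {index} grade {grade}") from exc
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[DatasetItem], GroundTruth]:
    """Full seeded dataset: per-sheet (raw, white, record) plus ground truth.

    Raw cubes are the reflectance cube multiplied by the white cube's
    smooth illumination field, so white-reference calibration recovers the
    reflectance.  Ground-truth grades/zones are the grading rules applied
    to the drawn records.
    """
    root = np.random.SeedSequence(config.seed)
    counts = class_counts(config)
    combo_list: list[tuple[int, int, int]] = []
    for combo in config.class_mix:  # stable insertion order
        combo_list.extend([combo] * counts[combo])

    rng_master = np.random.default_rng(root.spawn(1)[0])
    order = rng_master.permutation(len(combo_list))
    child_seeds = root.spawn(len(combo_list))

    items: list[DatasetItem] = []
    records: list[QualityRecord] = []
    grades: list[tuple[int, int, int]] = []
    zones: list[int] = []
    masks: list[np.ndarray] = []
    for i, pos in enumerate(order):
        combo = combo_list[pos]
        rng = np.random.default_rng(child_seeds[i])
        record = QualityRecord(
            sample_id=f"S{i:03d}",
            moisture=_draw_index("moisture", combo[0], rng),
            protein=_draw_index("protein", combo[1], rng),
            cutting_stress=_draw_index("cutting_stress", combo[2], rng),
        )
        cube, mask = generate_cube(record, config, rng)
        white = _white_cube(config, rng)
        raw = SpectralCube(cube.data * white.data, cube.wavelengths.copy(), dict(cube.metadata))
        g = assign_grades(record, DEFAULT_CRITERIA)
        z = assign_zone(g).zone
        items.append(DatasetItem(raw=raw, white=white, record=record))
        records.append(record)
        grades.append((g.moisture, g.protein, g.cutting_stress))
        zones.append(z)
        masks.append(mask)

    centers: dict[str, list[float]] = {}
    for b in config.bands:
        centers.setdefault(b.constituent, []).append(b.center_nm)
    truth = GroundTruth(
        records=records,
        grades=grades,
        zones=zones,
        pore_masks=masks,
        band_centers={k: tuple(v) for k, v in centers.items()},
    )
    return items, truth
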