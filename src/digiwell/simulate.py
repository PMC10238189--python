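"""Synthetic-data generator for the digital MSP pipeline.

Simulates the physics of the assay well enough to give every downstream stage
a ground truth: Poisson loading of template molecules into nanowells, ~50%
retention of master mix in wells (the rest stays in channels), per-molecule
amplification, fluorescence image rendering (flat disks + Gaussian PSF +
background + read noise + optional spectral crosstalk), and clinical cohorts
of per-marker copies-per-mL values.

Methylation-specific primers only amplify methylated template, so the
unmethylated background copies are tracked in the ground truth but never
produce signal (a ``false_amplification_rate`` switch exists for robustness
testing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import DomainError, OutOfFrameError
from .layout import ArrayLayout, GeometryMap, default_layout

__all__ = [
    "DEFAULT_CHANNELS",
    "DEFAULT_MARKER_PARAMS",
    "SimulationConfig",
    "GroundTruth",
    "partition_molecules",
    "amplified_state",
    "default_render_map",
    "image_shape_for",
    "render_image",
    "simulate_ground_truth",
    "simulate_intensity_table",
    "simulate_standard_curve",
    "StandardCurvePoint",
    "simulate_cohort",
]

DEFAULT_CHANNELS = ("FAM", "HEX", "TexasRed", "Cy5")

#: Cohort generator defaults: (case_rate, control_rate) in copies per mL of
#: plasma, one entry per marker of the lung-cancer panel.  Rates are
#: calibrated so that the four-marker panel has a population AUC of 0.86
#: (matching the clinical separation the pipeline is evaluated against);
#: controls carry a low level of biological background methylation.
DEFAULT_MARKER_PARAMS: dict[str, tuple[float, float]] = {
    "SOX17": (13.0, 4.0),
    "CDO1": (10.0, 5.0),
    "TAC1": (8.0, 2.0),
    "HOXA7": (9.0, 5.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable physics of the simulator.

    Intensities are ADU on the 16-bit scale of the scanner.  The default
    negative/positive populations are separated by far more than ten negative
    SDs, as endpoint digital PCR chemistry produces; ``retention_fraction``
    defaults to 0.5 (about half the master mix ends up in wells, the rest in
    the feed channels).
    """

    seed: int = 0
    retention_fraction: float = 0.5
    amplification_probability: float = 1.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    negative_mean: float = 800.0
    negative_sd: float = 50.0
    positive_mean: float = 12_000.0
    positive_sd: float = 800.0
    psf_sigma: float = 1.0
    read_noise_sd: float = 25.0
    background_level: float = 200.0
    crosstalk_matrix: np.ndarray | None = None
    false_amplification_rate: float = 0.0
    pixels_per_um: float = 0.1
    margin_px: int = 24

    def __post_init__(self):
        if not (0.0 < self.retention_fraction <= 1.0):
            raise DomainError("retention_fraction must be in (0, 1]")
        if not (0.0 < self.amplification_probability <= 1.0):
            raise DomainError("amplification_probability must be in (0, 1]")
        if not (0.0 <= self.false_amplification_rate < 1.0):
            raise DomainError("false_amplification_rate must be in [0, 1)")
        if self.positive_mean <= self.negative_mean + 10.0 * self.negative_sd:
            raise DomainError(
                "populations not separable: need positive_mean > "
                "negative_mean + 10 * negative_sd"
            )
        X = self.crosstalk_matrix
        if X is not None:
            X = np.asarray(X, dtype=float)
            C = len(self.channels)
            if X.shape != (C, C):
                raise DomainError("crosstalk_matrix must be channels x channels")
            if not np.allclose(np.diag(X), 1.0):
                raise DomainError("crosstalk_matrix must have unit diagonal")
            off = X[~np.eye(C, dtype=bool)]
            if np.any(off < 0.0) or np.any(off > 0.05):
                raise DomainError("crosstalk off-diagonals must lie in [0, 0.05]")
            object.__setattr__(self, "crosstalk_matrix", X)

    def crosstalk(self) -> np.ndarray:
        if self.crosstalk_matrix is None:
            return np.eye(len(self.channels))
        return self.crosstalk_matrix

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Per-well truth for one simulated module."""

    counts: np.ndarray  # (wells, channels) int molecule counts
    amplified: np.ndarray  # (wells, channels) bool
    input_copies: dict[str, float]  # nominal copies per channel
    background_copies: int = 0

    def amplified_well_counts(self) -> dict[str, int]:
        return {
            ch: int(self.amplified[:, c].sum())
            for c, ch in enumerate(self.input_copies)
        }


def partition_molecules(
    n_copies: float,
    layout: ArrayLayout,
    module_id: int = 0,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> np.ndarray:
    """Partition one target's molecules into one module's wells.

    The realized molecule number is ``M ~ Poisson(n_copies)`` (dilution of a
    synthetic stock is physically Poisson, which also gives meaning to
    fractional nominal copies such as 6.25).  Each molecule is independently
    retained in a well with probability ``retention_fraction`` and retained
    molecules land uniformly at random across the module's wells.

    With ``exact=True`` the loaded molecule number is exactly ``n_copies``
    (which must then be a non-negative integer): the deterministic-input mode
    used when characterizing detection of known loaded molecules, e.g. in
    limit-of-quantification studies.

    Returns the (wells_per_module,) integer count vector.
    """
    config = config or SimulationConfig()
    if rng is None:
        rng = config.rng()
    if n_copies < 0:
        raise DomainError("n_copies must be >= 0")
    if not (0 <= module_id < layout.n_modules):
        raise DomainError(f"module_id {module_id} out of range")
    if exact:
        if n_copies != int(n_copies):
            raise DomainError("exact=True requires an integer n_copies")
        m = int(n_copies)
    else:
        m = int(rng.poisson(n_copies))
    retained = int(rng.binomial(m, config.retention_fraction)) if m else 0
    counts = np.zeros(layout.wells_per_module, dtype=np.int64)
    if retained:
        wells = rng.integers(0, layout.wells_per_module, size=retained)
        np.add.at(counts, wells, 1)
    return counts


def amplified_state(
    counts: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-well boolean amplification from molecule counts.

    Each molecule amplifies independently with ``amplification_probability``;
    a well is positive when at least one of its molecules amplifies.  Empty
    wells may flip positive at ``false_amplification_rate`` (off by default:
    methylation-specific primers do not amplify unmethylated background).
    """
    counts = np.asarray(counts)
    if config.amplification_probability >= 1.0:
        state = counts > 0
    else:
        amplifying = rng.binomial(counts, config.amplification_probability)
        state = amplifying > 0
    if config.false_amplification_rate > 0.0:
        false_pos = rng.random(counts.shape) < config.false_amplification_rate
        state = state | (false_pos & (counts == 0))
    return state


def default_render_map(
    layout: ArrayLayout,
    config: SimulationConfig | None = None,
    module_id: int = 0,
) -> GeometryMap:
    """Similarity map used when the simulator renders its own images."""
    config = config or SimulationConfig()
    s = config.pixels_per_um
    m = float(config.margin_px)
    H = np.array([[s, 0.0, m], [0.0, s, m], [0.0, 0.0, 1.0]])
    return GeometryMap(H, module_id=module_id)


def image_shape_for(
    layout: ArrayLayout, gmap: GeometryMap, config: SimulationConfig
) -> tuple[int, int]:
    """(height, width) just large enough to hold the mapped module."""
    centers = gmap.apply(layout.well_centers_layout())
    r = _disk_radius_px(layout, gmap)
    pad = int(np.ceil(r + 3 * config.psf_sigma)) + config.margin_px
    width = int(np.ceil(centers[:, 0].max())) + pad + 1
    height = int(np.ceil(centers[:, 1].max())) + pad + 1
    return height, width


def _disk_radius_px(layout: ArrayLayout, gmap: GeometryMap) -> float:
    """Well radius in pixels, from the map's local scale at the module center."""
    c = layout.well_centers_layout().mean(axis=0)
    p = gmap.apply(np.array([c, c + [layout.well_diameter_um / 2.0, 0.0]]))
    return float(np.hypot(*(p[1] - p[0])))


def render_image(
    layout: ArrayLayout,
    gmap: GeometryMap,
    amplified: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render one module as a (channels, H, W) 16-bit grayscale stack.

    Each well is a flat disk of the well diameter at its mapped center whose
    amplitude is drawn from the positive distribution if the well amplified in
    that channel, else from the negative distribution.  A Gaussian PSF blur is
    applied, spectral crosstalk linearly mixes the channel signals, then the
    background level and per-pixel Gaussian read noise are added and the
    result is clipped to [0, 65535].
    """
    if rng is None:
        rng = config.rng()
    amplified = np.asarray(amplified, dtype=bool)
    if amplified.ndim == 1:
        amplified = amplified[:, None]
    n_wells, n_chan = amplified.shape
    if n_wells != layout.wells_per_module:
        raise DomainError("amplified state length must equal wells_per_module")
    if n_chan != len(config.channels):
        raise DomainError("amplified state channels must match config.channels")
    if shape is None:
        shape = image_shape_for(layout, gmap, config)
    height, width = shape

    centers = gmap.apply(layout.well_centers_layout())
    radius = _disk_radius_px(layout, gmap)
    bad = np.flatnonzero(
        (centers[:, 0] - radius < 0)
        | (centers[:, 1] - radius < 0)
        | (centers[:, 0] + radius > width - 1)
        | (centers[:, 1] + radius > height - 1)
    )
    if bad.size:
        raise OutOfFrameError(bad)

    # Disk stamp: integer pixel offsets whose centers lie within the radius.
    r_int = int(np.floor(radius))
    dy, dx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    inside = dy**2 + dx**2 <= radius**2
    dy, dx = dy[inside], dx[inside]
    cx = np.rint(centers[:, 0]).astype(np.int64)
    cy = np.rint(centers[:, 1]).astype(np.int64)
    flat_idx = ((cy[:, None] + dy[None, :]) * width + (cx[:, None] + dx[None, :])).ravel()

    planes = np.zeros((n_chan, height, width), dtype=np.float64)
    for c in range(n_chan):
        amp = np.where(
            amplified[:, c],
            rng.normal(config.positive_mean, config.positive_sd, size=n_wells),
            rng.normal(config.negative_mean, config.negative_sd, size=n_wells),
        )
        plane = planes[c].ravel()
        plane[flat_idx] = np.repeat(amp, dy.size)
        if config.psf_sigma > 0:
            planes[c] = gaussian_filter(planes[c], config.psf_sigma)

    planes = np.tensordot(config.crosstalk(), planes, axes=(1, 0))
    planes += config.background_level
    if config.read_noise_sd > 0:
        planes += rng.normal(0.0, config.read_noise_sd, size=planes.shape)
    return np.clip(np.rint(planes), 0, 65535).astype(np.uint16)


def simulate_ground_truth(
    copies_per_channel,
    layout: ArrayLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    module_id: int = 0,
    background_copies: int = 0,
    exact: bool = False,
) -> GroundTruth:
    """Partition and amplify every channel of one module."""
    if rng is None:
        rng = config.rng()
    if np.isscalar(copies_per_channel):
        copies_per_channel = [copies_per_channel] * len(config.channels)
    copies = list(copies_per_channel)
    if len(copies) != len(config.channels):
        raise DomainError("one nominal copy number per channel required")
    counts = np.stack(
        [
            partition_molecules(c, layout, module_id, config, rng, exact=exact)
            for c in copies
        ],
        axis=1,
    )
    amplified = np.stack(
        [amplified_state(counts[:, i], config, rng) for i in range(len(copies))],
        axis=1,
    )
    return GroundTruth(
        counts=counts,
        amplified=amplified,
        input_copies=dict(zip(config.channels, map(float, copies))),
        background_copies=int(background_copies),
    )


def simulate_intensity_table(
    truth: GroundTruth,
    layout: ArrayLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    module_id: int = 0,
) -> pd.DataFrame:
    """Per-well intensity table drawn directly from the population model.

    Shortcut past the imaging round trip: each well's mean intensity is the
    background level plus a draw from its population (positive/negative).
    Matches the schema of :func:`digiwell.extract.extract_well_intensities`.
    """
    if rng is None:
        rng = config.rng()
    ident = layout.well_identities()
    n = layout.wells_per_module
    data = {
        "module": np.full(n, module_id),
        "well_index": ident[:, 0],
        "row": ident[:, 1],
        "col": ident[:, 2],
    }
    centers = layout.well_centers_layout()
    data["x_px"] = centers[:, 0]
    data["y_px"] = centers[:, 1]
    data["aperture_pixels"] = np.full(n, 1)
    for c, ch in enumerate(config.channels):
        amp = np.where(
            truth.amplified[:, c],
            rng.normal(config.positive_mean, config.positive_sd, size=n),
            rng.normal(config.negative_mean, config.negative_sd, size=n),
        )
        data[ch] = config.background_level + amp
    return pd.DataFrame(data)


@dataclass
class StandardCurvePoint:
    """One (nominal copies, replicate) dataset of a simulated dilution series."""

    nominal_copies: float
    replicate: int
    truth: GroundTruth
    table: pd.DataFrame
    image: np.ndarray | None = None


def simulate_standard_curve(
    copies_ladder,
    replicates: int,
    background_copies: int,
    layout: ArrayLayout | None = None,
    config: SimulationConfig | None = None,
    render: bool = True,
    exact: bool = False,
) -> list[StandardCurvePoint]:
    """Simulate a co-spiked dilution series (all channels at the same nominal).

    Per ladder point and replicate, the four targets are partitioned
    independently at the same nominal copies into one module, images are
    rendered (unless ``render=False``, which samples well intensities from
    the population model directly), and intensities extracted.  Unmethylated
    background copies are recorded but never amplify.
    """
    from .extract import extract_well_intensities  # deferred: avoid cycle

    ladder = [float(c) for c in copies_ladder]
    if not ladder:
        raise DomainError("copies_ladder must be non-empty")
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    layout = layout or default_layout()
    config = config or SimulationConfig()
    rng = config.rng()
    gmap = default_render_map(layout, config)
    out: list[StandardCurvePoint] = []
    for nominal in ladder:
        for rep in range(replicates):
            truth = simulate_ground_truth(
                nominal, layout, config, rng,
                background_copies=background_copies, exact=exact,
            )
            if render:
                image = render_image(layout, gmap, truth.amplified, config, rng)
                table = extract_well_intensities(image, gmap, layout,
                                                 channels=config.channels)
            else:
                image = None
                table = simulate_intensity_table(truth, layout, config, rng)
            out.append(StandardCurvePoint(nominal, rep, truth, table, image))
    return out


def simulate_cohort(
    n_case: int,
    n_control: int,
    marker_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    plasma_volume_ml: float = 0.1,
    covariates: bool = True,
) -> pd.DataFrame:
    """Synthetic clinical cohort of per-marker copies-per-mL values.

    Per sample and marker, the measured copies-per-mL is
    ``Poisson(rate * plasma_volume_ml) / plasma_volume_ml`` — the counting
    noise of assaying a 100 uL plasma equivalent.  ``marker_params`` maps
    marker name to ``(case_rate, control_rate)`` in copies per mL; the default
    panel is calibrated to a population AUC of 0.86.  Optional covariates
    age (years) and pack_years are drawn from mildly separated normals
    (cases N(67, 8) / N(45, 25), controls N(64, 8) / N(35, 25), pack-years
    clipped at 0).
    """
    if n_case < 0 or n_control < 0:
        raise DomainError("cohort sizes must be >= 0")
    if plasma_volume_ml <= 0:
        raise DomainError("plasma_volume_ml must be > 0")
    params = marker_params or DEFAULT_MARKER_PARAMS
    for marker, (case_rate, control_rate) in params.items():
        if case_rate < 0 or control_rate < 0:
            raise DomainError(f"negative rate for marker {marker}")
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    labels = np.array(["case"] * n_case + ["control"] * n_control)
    data: dict[str, object] = {
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "label": labels,
    }
    is_case = labels == "case"
    for marker, (case_rate, control_rate) in params.items():
        rate = np.where(is_case, case_rate, control_rate)
        counts = rng.poisson(rate * plasma_volume_ml)
        data[marker] = counts / plasma_volume_ml
    if covariates:
        age = np.where(is_case, rng.normal(67, 8, n), rng.normal(64, 8, n))
        packs = np.where(is_case, rng.normal(45, 25, n), rng.normal(35, 25, n))
        data["age"] = np.round(age, 1)
        data["pack_years"] = np.round(np.clip(packs, 0, None), 1)
    return pd.DataFrame(data)
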