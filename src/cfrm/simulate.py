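"""Synthetic correlative-Raman data with full ground truth.

No public dataset of single-cell mitotic Raman maps exists, so every other
module is exercised against simulated cells whose geometry, spectral
composition, distortions, and cosmic-ray spikes are all known exactly.

A simulated pixel spectrum is

    a_px * [ reference + w_ch(px) * cytoplasm_bands + w_dna(px) * dna_peak ]
        + baseline_px + noise,

mirroring the multiplicative laser-drift / additive fluorescence-baseline
distortion model that the preprocessing stage is designed to undo.  The
DNA marker band sits at 785 cm^-1 (pyrimidine ring breathing) and the
cytoplasm bands populate 2820-3020 cm^-1 (CH2/CH3 stretches), so band
images over those intervals separate chromatin from cytoplasm.

Stage geometries are deliberately coarse archetypes of mitotic chromatin
morphology - diffuse interphase nucleus, condensing prophase blob,
prometaphase blob with a partial bar, metaphase plate, separating anaphase
masses, distant telophase masses with pinched cytoplasm.  They give the
classifier learnable, stage-ordered structure; they are not biologically
faithful images.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .errors import ParameterError, SizeError
from .classify import LabelledCell
from .preprocess import local_median_mad
from .spectral_io import (
    RamanMap,
    Spectrum,
    StageLabel,
    WavenumberAxis,
    default_axis,
    read_labels,
    read_map,
    write_labels,
    write_map,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedCell",
    "make_reference_background",
    "stage_geometry",
    "synth_cell_map",
    "inject_cosmic_rays",
    "make_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated experiment.

    Defaults match the acquisition geometry being emulated: 24x24 pixel
    maps at 1 um step, 1600 channels over 439-3228 cm^-1.  Intensities are
    arbitrary units with the reference background of order 1.
    """

    grid: tuple[int, int] = (24, 24)
    m: int = 1600
    wn_lo: float = 439.0
    wn_hi: float = 3228.0
    dna_peak_center: float = 785.0
    dna_peak_width: float = 10.0  # Gaussian sigma, cm^-1
    dna_strength: float = 1.2
    # (center, sigma, amplitude) triples inside the CH2/CH3 stretch region
    ch_band: tuple[tuple[float, float, float], ...] = (
        (2850.0, 25.0, 0.5),
        (2885.0, 20.0, 0.35),
        (2935.0, 25.0, 0.6),
        (2975.0, 20.0, 0.3),
    )
    protein_peak: float | None = 1003.0  # phenylalanine ring breathing
    protein_width: float = 6.0
    protein_strength: float = 0.4
    ch_strength: float = 0.4
    noise_sd: float = 0.01
    a_range: tuple[float, float] = (0.7, 1.4)
    baseline_coeff_range: tuple[float, float] = (-0.3, 0.3)
    baseline_order: int = 5
    spike_rate: float = 10.0
    spike_amplitude: float = 20.0  # in local-MAD multiples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid[0] < 1 or self.grid[1] < 1 or self.m < 2:
            raise ParameterError("grid and channel count must be positive")
        if self.a_range[0] > self.a_range[1] or self.baseline_coeff_range[0] > self.baseline_coeff_range[1]:
            raise ParameterError("parameter ranges must be nonempty")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ParameterError("noise_sd and spike_rate must be nonnegative")

    def axis(self) -> WavenumberAxis:
        return default_axis(self.m, self.wn_lo, self.wn_hi)


@dataclass
class SimTruth:
    """Everything the simulator knows about one generated cell."""

    stage: StageLabel
    dna_mask: np.ndarray
    cyto_mask: np.ndarray
    background_mask: np.ndarray
    per_pixel_a: np.ndarray
    per_pixel_baseline_coeffs: np.ndarray
    spike_list: tuple[tuple[int, int, int, float], ...] = ()


@dataclass
class SimulatedCell:
    cell: LabelledCell
    truth: SimTruth

    @property
    def map(self) -> RamanMap:
        return self.cell.map

    @property
    def stage(self) -> StageLabel:
        return self.cell.stage


def _gauss(axis: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((axis - center) / sigma) ** 2)


def make_reference_background(config: SimConfig, seed: int) -> Spectrum:
    """Smooth nonnegative background: polynomial, broad humps, medium features.

    The medium-width features (80-150 cm^-1, as from glass or residual
    fluorescence structure) matter: a background that a low-order
    polynomial could reproduce on its own would make the reference fit
    degenerate, since the baseline term could then mimic the reference
    without using the spectrum at all.
    """
    rng = np.random.default_rng(seed)
    axis = config.axis()
    xn = np.linspace(-1.0, 1.0, axis.m)
    y = (
        rng.uniform(0.4, 0.7)
        + rng.uniform(-0.1, 0.1) * xn
        + rng.uniform(-0.1, 0.1) * xn**2
    )
    for _ in range(int(rng.integers(2, 5))):
        center = rng.uniform(config.wn_lo, config.wn_hi)
        width = rng.uniform(300.0, 600.0)
        amp = rng.uniform(0.3, 0.5)
        y = y + amp * _gauss(axis.values, center, width)
    for _ in range(int(rng.integers(3, 6))):
        center = rng.uniform(config.wn_lo, config.wn_hi)
        width = rng.uniform(80.0, 150.0)
        amp = rng.uniform(0.15, 0.3)
        y = y + amp * _gauss(axis.values, center, width)
    return Spectrum(np.maximum(y, 0.0), axis)


def _rot_coords(grid: tuple[int, int], cy: float, cx: float, theta: float):
    yy, xx = np.mgrid[0 : grid[0], 0 : grid[1]].astype(float)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return u, v


def _ellipse(u, v, u0, v0, ru, rv):
    return ((u - u0) / ru) ** 2 + ((v - v0) / rv) ** 2 <= 1.0


def stage_geometry(
    stage: StageLabel, grid: tuple[int, int] = (24, 24), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DNA, cytoplasm, and background masks for one stage archetype.

    Randomized in position and orientation per seed.  The background is
    the complement of the dilated cell footprint, so a guard ring of
    pixels belongs to neither region.
    """
    h, w = grid
    if h < 15 or w < 15:
        raise SizeError(f"grid {grid} too small for the stage templates (need >= 15x15)")
    rng = np.random.default_rng(seed)
    s = min(h, w) / 24.0
    cy = h / 2.0 + rng.uniform(-1.5, 1.5) * s
    cx = w / 2.0 + rng.uniform(-1.5, 1.5) * s
    theta = rng.uniform(0.0, np.pi)
    u, v = _rot_coords(grid, cy, cx, theta)

    if stage == StageLabel.INTERPHASE:
        dna = _ellipse(u, v, 0, 0, 4.8 * s, 3.6 * s)
        cyto = _ellipse(u, v, 0, 0, 9.5 * s, 8.5 * s)
    elif stage == StageLabel.PROPHASE:
        dna = _ellipse(u, v, 0, 0, 3.0 * s, 2.6 * s)
        cyto = _ellipse(u, v, 0, 0, 8.0 * s, 7.5 * s)
    elif stage == StageLabel.PROMETAPHASE:
        dna = _ellipse(u, v, 0, 0, 2.8 * s, 2.4 * s) | (
            (u >= 0) & (u <= 4.5 * s) & (np.abs(v) <= 1.4 * s)
        )
        cyto = _ellipse(u, v, 0, 0, 8.0 * s, 7.5 * s)
    elif stage == StageLabel.METAPHASE:
        dna = (np.abs(u) <= 5.0 * s) & (np.abs(v) <= 1.6 * s)
        cyto = _ellipse(u, v, 0, 0, 8.0 * s, 7.5 * s)
    elif stage == StageLabel.ANAPHASE:
        half = 3.2 * s
        dna = _ellipse(u, v, -half, 0, 2.4 * s, 2.0 * s) | _ellipse(u, v, half, 0, 2.4 * s, 2.0 * s)
        cyto = _ellipse(u, v, 0, 0, 8.5 * s, 7.0 * s)
    elif stage == StageLabel.TELOPHASE:
        half = 5.2 * s
        dna = _ellipse(u, v, -half, 0, 2.4 * s, 2.0 * s) | _ellipse(u, v, half, 0, 2.4 * s, 2.0 * s)
        cyto = _ellipse(u, v, -half, 0, 4.5 * s, 3.8 * s) | _ellipse(u, v, half, 0, 4.5 * s, 3.8 * s)
    else:  # pragma: no cover - exhaustive enum
        raise ParameterError(f"unknown stage {stage}")

    cyto = cyto | dna
    background = ~binary_dilation(cyto, iterations=2)
    assert dna.any(), "stage template produced an empty DNA mask"
    return dna, cyto, background


def synth_cell_map(
    stage: StageLabel,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    reference: Spectrum | None = None,
) -> tuple[RamanMap, SimTruth]:
    """One simulated cell map plus its full ground truth (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    geom_seed = int(rng.integers(0, 2**31))
    ref_seed = int(rng.integers(0, 2**31))
    dna, cyto, background = stage_geometry(stage, config.grid, geom_seed)
    if reference is None:
        reference = make_reference_background(config, ref_seed)
    axis = reference.axis
    h, w = config.grid

    t_dna = config.dna_strength * _gauss(axis.values, config.dna_peak_center, config.dna_peak_width)
    t_cyto = np.zeros(axis.m)
    for center, sigma, amp in config.ch_band:
        t_cyto += amp * _gauss(axis.values, center, sigma)
    if config.protein_peak is not None:
        t_cyto += config.protein_strength * _gauss(
            axis.values, config.protein_peak, config.protein_width
        )
    t_cyto *= config.ch_strength

    # smooth spatial weights, strictly zero outside their masks
    w_dna = gaussian_filter(dna.astype(float), 0.7) * dna
    w_ch = gaussian_filter(cyto.astype(float), 0.9) * cyto

    a = rng.uniform(config.a_range[0], config.a_range[1], size=(h, w))
    n_coef = config.baseline_order + 1
    coeffs = rng.uniform(
        config.baseline_coeff_range[0], config.baseline_coeff_range[1], size=(h, w, n_coef)
    )
    xn = np.linspace(-1.0, 1.0, axis.m)
    vander = np.polynomial.polynomial.polyvander(xn, config.baseline_order)
    baseline = np.einsum("hwk,mk->hwm", coeffs, vander, optimize=True)
    noise = rng.normal(0.0, config.noise_sd, size=(h, w, axis.m)) if config.noise_sd > 0 else 0.0

    pure = (
        reference.intensities[None, None, :]
        + w_ch[:, :, None] * t_cyto[None, None, :]
        + w_dna[:, :, None] * t_dna[None, None, :]
    )
    cube = a[:, :, None] * pure + baseline + noise
    raman_map = RamanMap(cube, axis, label=stage.display)
    truth = SimTruth(
        stage=stage,
        dna_mask=dna,
        cyto_mask=cyto,
        background_mask=background,
        per_pixel_a=a,
        per_pixel_baseline_coeffs=coeffs,
    )
    return raman_map, truth


def inject_cosmic_rays(
    raman_map: RamanMap, config: SimConfig = SimConfig(), seed: int = 0
) -> tuple[RamanMap, tuple[tuple[int, int, int, float], ...]]:
    """Add Poisson(spike_rate) single-channel spikes at uniform positions.

    Amplitudes are ``spike_amplitude`` times the floored local MAD of the
    pre-injection spectrum - the same statistic the detector uses, so the
    amplitude is meaningful in detection units.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(config.spike_rate))
    if n == 0:
        return raman_map, ()
    h, w, m = raman_map.cube.shape
    flat = rng.choice(h * w * m, size=min(n, h * w * m), replace=False)
    _, mad = local_median_mad(raman_map.cube)
    cube = raman_map.cube.copy()
    spikes = []
    for f in sorted(int(x) for x in flat):
        r, rem = divmod(f, w * m)
        c, t = divmod(rem, m)
        amp = float(config.spike_amplitude * mad[r, c, t])
        cube[r, c, t] += amp
        spikes.append((r, c, t, amp))
    from dataclasses import replace as _replace

    return _replace(raman_map, cube=cube), tuple(spikes)


def make_dataset(
    n_per_stage: int,
    config: SimConfig = SimConfig(),
    seed: int | None = None,
    out_dir: str | None = None,
    spikes: bool = True,
) -> list[SimulatedCell]:
    """Balanced labelled dataset of 6 * n_per_stage cells sharing one reference.

    Optionally serialized to ``out_dir`` as matrix_stack maps plus
    ``labels.csv`` and a ``truth.json`` with stage and spike ground truth.
    """
    if n_per_stage < 1:
        raise ParameterError("n_per_stage must be >= 1")
    if seed is None:
        seed = config.seed
    master = np.random.default_rng(seed)
    reference = make_reference_background(config, int(master.integers(0, 2**31)))
    cells: list[SimulatedCell] = []
    i = 0
    for stage in StageLabel:
        for _ in range(n_per_stage):
            cell_seed = int(master.integers(0, 2**31))
            spike_seed = int(master.integers(0, 2**31))
            raman_map, truth = synth_cell_map(stage, config, cell_seed, reference=reference)
            if spikes and config.spike_rate > 0:
                raman_map, spike_list = inject_cosmic_rays(raman_map, config, spike_seed)
                truth.spike_list = spike_list
            raman_map.cell_id = f"cell_{i:04d}"
            cells.append(SimulatedCell(LabelledCell(raman_map, stage), truth))
            i += 1
    if out_dir is not None:
        _write_dataset(cells, out_dir)
    return cells


def _write_dataset(cells: list[SimulatedCell], out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    labels = {}
    truth_records = []
    for sc in cells:
        cid = sc.map.cell_id
        write_map(sc.map, os.path.join(out_dir, f"{cid}.txt"), dialect="matrix_stack")
        labels[cid] = sc.stage
        truth_records.append(
            {
                "cell_id": cid,
                "stage": sc.stage.display,
                "spikes": [[r, c, t, amp] for r, c, t, amp in sc.truth.spike_list],
            }
        )
    write_labels(labels, os.path.join(out_dir, "labels.csv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_records, fh)


def load_dataset(path: str) -> list[LabelledCell]:
    """Read a dataset directory written by :func:`make_dataset`."""
    labels = read_labels(os.path.join(path, "labels.csv"))
    return [
        LabelledCell(read_map(os.path.join(path, f"{cid}.txt")), stage)
        for cid, stage in labels.items()
    ]
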