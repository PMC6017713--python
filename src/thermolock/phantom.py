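"""Synthetic resistor-phantom generator.

Emulates a tissue-mimicking phantom: a 14 mm polyester slab (conductivity
0.155 W/m/K, density 1090 kg/m^3, heat capacity 1670 J/kg/K) with eleven
120-ohm thin-film resistors (3 x 1.7 mm footprint) embedded in three groups —
five at 3 mm depth spaced 4.2 mm, three at 5 mm spaced 8.4 mm, three at 7 mm
spaced 16.8 mm.  A sinusoidal voltage of amplitude A across resistance R
dissipates ``V^2/R = A^2/2R + (A^2/2R) cos(2 omega t)``: the thermal drive is
frequency-doubled and splits evenly between a DC term and an AC term at twice
the electrical frequency.

Frames are synthesised in the quasi-steady regime the acquisition protocol
records (after transients): per pixel ``baseline + tau_DC + Re{tau_AC
e^{j omega_th t}}`` with the tau fields from the spectral solver, plus
optional white sensor noise.  A time-domain variant built on the
finite-difference solver provides start-up transients for testing the
integer-cycle truncation logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lockin import ThermalFrameStack
from .model import (BoundarySpec, Layer, LayerStack, ModulationSpec,
                    SourceSpec, SpectralGrid, rect_map, surface_field)

__all__ = [
    "ResistorGroup",
    "PhantomSpec",
    "DriveSpec",
    "CameraSpec",
    "POLYESTER",
    "electrical_to_heat",
    "resistor_positions",
    "build_sources",
    "simulate_frames",
    "transient_stack",
]

#: Table of polyester-resin slab properties (SI): kappa, rho, C -> D = 8.52e-8
POLYESTER = Layer(thickness=14e-3, conductivity=0.155, density=1090.0,
                  heat_capacity=1670.0)


@dataclass(frozen=True)
class ResistorGroup:
    """A row of equally spaced resistors at one depth, laid out along x."""

    depth: float          # m below the imaged surface
    count: int
    spacing: float        # centre-to-centre along x [m]
    y_offset: float = 0.0  # row position [m]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material of the resistor phantom.

    Resistor bodies lie along the row (3 mm in x) with the 1.7 mm width
    across it (y); hotspot FWHM for the resolution metric is scanned across
    the row, where the 1.7 mm width is subtracted.  Sources
    default to planar sheets at the nominal depth; ``source_model =
    'volumetric'`` spreads them over ``source_height`` for sensitivity
    studies.
    """

    material: Layer = POLYESTER
    groups: tuple[ResistorGroup, ...] = (
        ResistorGroup(depth=3e-3, count=5, spacing=4.2e-3, y_offset=-21e-3),
        ResistorGroup(depth=5e-3, count=3, spacing=8.4e-3, y_offset=0.0),
        ResistorGroup(depth=7e-3, count=3, spacing=16.8e-3, y_offset=21e-3),
    )
    footprint_x: float = 3.0e-3
    footprint_y: float = 1.7e-3
    resistance: float = 120.0
    source_model: str = "planar"
    source_height: float = 1.0e-3
    h_up: float = 10.0   # natural convection at the imaged face [W m^-2 K^-1]
    h_dn: float = 0.0    # insulated bottom

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.depth >= self.material.thickness:
                raise ValueError("resistor depth must be inside the slab")
            if g.spacing <= min(self.footprint_x, self.footprint_y) and g.count > 1:
                raise ValueError("resistor spacing smaller than the footprint")
        if self.source_model not in ("planar", "volumetric"):
            raise ValueError("source_model must be 'planar' or 'volumetric'")

    @property
    def stack(self) -> LayerStack:
        return LayerStack([self.material])

    @property
    def boundary(self) -> BoundarySpec:
        return BoundarySpec(h_up=self.h_up, h_dn=self.h_dn)

    @property
    def n_resistors(self) -> int:
        return sum(g.count for g in self.groups)


@dataclass(frozen=True)
class DriveSpec:
    """Electrical drive shared by the active resistors.

    ``amplitude`` is the sine amplitude [V]; the thermal modulation appears at
    ``2 * f_elec``.  ``mask`` selects active resistors (flattened group order)
    and ``scales`` applies per-resistor amplitude factors.
    """

    amplitude: float = 7.2
    f_elec: float = 0.05
    mask: tuple[bool, ...] | None = None
    scales: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.f_elec <= 0:
            raise ValueError("f_elec must be > 0")

    @property
    def f_thermal(self) -> float:
        return 2.0 * self.f_elec


@dataclass(frozen=True)
class CameraSpec:
    """Thermal-camera model.

    ``frame_rate=None`` applies the acquisition rule of 75 frames per
    electrical stimulation cycle.  ``noise_sigma`` is additive white sensor
    noise per pixel per frame [K].
    """

    nx: int = 160
    ny: int = 120
    pixel_pitch: float = 0.4e-3
    frame_rate: float | None = None
    cycles: int = 12          # thermal modulation cycles recorded
    noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def rate_for(self, drive: DriveSpec) -> float:
        rate = 75.0 * drive.f_elec if self.frame_rate is None else self.frame_rate
        if rate < 2.0 * drive.f_thermal:
            raise ValueError(
                f"frame rate {rate} Hz below Nyquist for {drive.f_thermal} Hz")
        return rate

    def grid(self) -> SpectralGrid:
        return SpectralGrid(self.nx, self.ny, self.pixel_pitch)


def electrical_to_heat(amplitude: float, resistance: float, f_elec: float):
    """Decompose resistive heating of a sine drive into DC + doubled-frequency AC.

    Returns ``(q_dc, q_ac, f_thermal)`` [W, W, Hz] with
    ``q_dc = q_ac = A^2 / (2R)`` and ``f_thermal = 2 f_elec``; the total
    generated heat ``q_dc + q_ac = A^2/R`` (only half of it is in the AC
    term — resistors can only heat, never cool, so a DC pedestal is
    unavoidable).
    """
    if resistance <= 0:
        raise ValueError("resistance must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    q = amplitude ** 2 / (2.0 * resistance)
    return q, q, 2.0 * f_elec


def resistor_positions(phantom: PhantomSpec):
    """Flattened ``(x, y, depth)`` centres, group order then left-to-right."""
    out = []
    for g in phantom.groups:
        x0 = -0.5 * (g.count - 1) * g.spacing
        for i in range(g.count):
            out.append((x0 + i * g.spacing, g.y_offset, g.depth))
    return out


def _active_powers(phantom: PhantomSpec, drive: DriveSpec):
    q_dc, q_ac, _ = electrical_to_heat(drive.amplitude, phantom.resistance,
                                       drive.f_elec)
    n = phantom.n_resistors
    mask = np.ones(n, bool) if drive.mask is None else np.asarray(drive.mask, bool)
    scales = np.ones(n) if drive.scales is None else np.asarray(drive.scales, float)
    if mask.size != n or scales.size != n:
        raise ValueError(f"mask/scales must have {n} entries")
    # power scales with the square of the voltage scale factor
    return mask, q_dc * scales ** 2, q_ac * scales ** 2


def build_sources(phantom: PhantomSpec, drive: DriveSpec, grid: SpectralGrid,
                  depth: float | None = None):
    """Per-depth (DC, AC) :class:`SourceSpec` pairs for the active resistors.

    Sources at different depths cannot share one planar sheet, so the result
    is a dict ``{depth: (source_dc, source_ac)}``; ``depth`` restricts to one
    group depth.
    """
    mask, p_dc, p_ac = _active_powers(phantom, drive)
    positions = resistor_positions(phantom)
    by_depth: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for idx, (x, y, d) in enumerate(positions):
        if not mask[idx] or (depth is not None and d != depth):
            continue
        frac = rect_map(grid, (x, y), (phantom.footprint_x, phantom.footprint_y))
        area = phantom.footprint_x * phantom.footprint_y
        maps = by_depth.setdefault(d, (np.zeros(grid.shape), np.zeros(grid.shape)))
        maps[0][:] += frac * (p_dc[idx] / area)
        maps[1][:] += frac * (p_ac[idx] / area)
    out = {}
    for d, (m_dc, m_ac) in by_depth.items():
        if phantom.source_model == "planar":
            out[d] = (SourceSpec.planar(m_dc, d), SourceSpec.planar(m_ac, d))
        else:
            h = phantom.source_height
            lo = max(d - h / 2, 0.0)
            hi = min(d + h / 2, phantom.material.thickness)
            nodes = np.linspace(lo, hi, 5)
            vol_dc = np.stack([m_dc / (hi - lo)] * 5)
            vol_ac = np.stack([m_ac / (hi - lo)] * 5)
            out[d] = (SourceSpec.volumetric(vol_dc, nodes),
                      SourceSpec.volumetric(vol_ac, nodes))
    return out


def quasi_steady_fields(phantom: PhantomSpec, drive: DriveSpec,
                        grid: SpectralGrid):
    """Summed DC field (real) and complex AC field at ``2 f_elec``."""
    sources = build_sources(phantom, drive, grid)
    if not sources:
        raise ValueError("no active resistors")
    stack, bc = phantom.stack, phantom.boundary
    tau_dc = np.zeros(grid.shape)
    tau_ac = np.zeros(grid.shape, dtype=complex)
    for _, (s_dc, s_ac) in sorted(sources.items()):
        tau_dc += surface_field(stack, bc, s_dc, ModulationSpec(0.0),
                                grid).source.data.real
        tau_ac += surface_field(stack, bc, s_ac,
                                ModulationSpec(drive.f_thermal),
                                grid).source.data
    return tau_dc, tau_ac


def simulate_frames(phantom: PhantomSpec, drive: DriveSpec, camera: CameraSpec,
                    seed: int | None = None,
                    baseline: float = 0.0) -> ThermalFrameStack:
    """Quasi-steady frame stack of the driven phantom.

    Per pixel: ``baseline + tau_DC + Re{tau_AC e^{j 2 pi (2 f_elec) t}}`` plus
    white Gaussian sensor noise.  Deterministic under a fixed seed; a seed is
    required whenever ``noise_sigma > 0``.
    """
    if camera.noise_sigma > 0 and seed is None:
        raise ValueError("a seed is required for noisy simulations")
    rate = camera.rate_for(drive)
    grid = camera.grid()
    tau_dc, tau_ac = quasi_steady_fields(phantom, drive, grid)
    f_th = drive.f_thermal
    n_frames = int(round(camera.cycles * rate / f_th))
    t = np.arange(n_frames) / rate
    wt = 2.0 * np.pi * f_th * t
    frames = (baseline + tau_dc)[None, :, :] \
        + np.cos(wt)[:, None, None] * tau_ac.real[None, :, :] \
        - np.sin(wt)[:, None, None] * tau_ac.imag[None, :, :]
    if camera.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, camera.noise_sigma, frames.shape)
    return ThermalFrameStack(frames, rate, camera.pixel_pitch)


def transient_stack(phantom: PhantomSpec, drive: DriveSpec, camera: CameraSpec,
                    duration: float, nz: int = 24,
                    max_cells: int = 2_000_000) -> ThermalFrameStack:
    """Time-domain frames including the start-up transient (finite differences).

    Starts from a uniform baseline at t = 0 with the squared-voltage drive
    switched on, so early frames are not yet sinusoidal — useful for testing
    the truncation logic of the demodulator.  Grid size is guarded by
    ``max_cells``.
    """
    from .fd import FDGrid, run_transient

    rate = camera.rate_for(drive)
    if camera.nx * camera.ny * nz > max_cells:
        raise ValueError("requested finite-difference grid exceeds max_cells")
    grid = camera.grid()
    fdg = FDGrid.from_stack(phantom.stack, nx=camera.nx, ny=camera.ny, nz=nz,
                            hx=camera.pixel_pitch, hy=camera.pixel_pitch)
    q_dc, q_ac = _volumetric_drive(phantom, drive, grid, fdg)

    def q_of_t(t: float) -> np.ndarray:
        return q_dc + q_ac * np.cos(2.0 * np.pi * drive.f_thermal * t)

    frames = run_transient(fdg, phantom.boundary, q_of_t, duration, rate)
    return ThermalFrameStack(frames, rate, camera.pixel_pitch)


def _volumetric_drive(phantom: PhantomSpec, drive: DriveSpec,
                      grid: SpectralGrid, fdg) -> tuple[np.ndarray, np.ndarray]:
    """Deposit each active resistor's power into the FD cell layer at its depth."""
    mask, p_dc, p_ac = _active_powers(phantom, drive)
    q_dc = np.zeros((fdg.nz, grid.ny, grid.nx))
    q_ac = np.zeros_like(q_dc)
    area = phantom.footprint_x * phantom.footprint_y
    for idx, (x, y, d) in enumerate(resistor_positions(phantom)):
        if not mask[idx]:
            continue
        frac = rect_map(grid, (x, y), (phantom.footprint_x, phantom.footprint_y))
        k = min(int(d / fdg.hz), fdg.nz - 1)
        # areal density spread over one cell height -> volumetric density
        q_dc[k] += frac * (p_dc[idx] / area) / fdg.hz
        q_ac[k] += frac * (p_ac[idx] / area) / fdg.hz
    return q_dc, q_ac
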