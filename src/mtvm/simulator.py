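"""End-to-end crown-shape backscatter experiments.

Assembles the full chain — crown envelope -> layer slicing -> per-layer
scatterer densities -> phase matrices -> matrix doubling -> sigma0 — and
provides the comparison experiments of the crown-shape study: height sweeps
over the four named shapes, the parabolic-family sweep over feasible (a, b)
coefficients, and the mean absolute / mean relative difference metrics.

Per-plant layer counts are converted to areal number densities by dividing
by a fixed reference footprint A_ref = pi (H tan(alpha))^2, identical for
all crown shapes at a given height. Because all shapes enclose equal volume,
this makes the total number of scatterers per unit ground area equal across
shapes: the crown shape changes only the vertical distribution of the
scatterers, which is exactly the variable under study.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import crown_geometry as cg
from .matrix_doubling import AngularGrid, _HarmonicOps
from .presets import canopy_species
from .scatterer_models import SpeciesKernels, species_kernels

__all__ = [
    "SimulationConfig",
    "run_height_sweep",
    "parabola_sweep",
    "mad",
    "mrd",
    "shape_difference_report",
    "azimuth_average_and_fit",
    "BANDS",
]

#: Radar bands of the study, GHz.
BANDS = {"L": 1.2, "C": 5.3, "X": 9.6}

_SHAPES = ("cylinder", "cone", "inverted_cone", "ellipsoid")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a crown-shape simulation run.

    Heights in cm; frequencies in GHz; ``rho_v`` is the common component
    volume density in cm^-3. Numeric settings: ``dz`` layer thickness (cm),
    ``n_zenith``/``n_azimuth`` angular resolution, ``n_orient`` orientations
    for azimuth-averaged components. ``seed`` is carried for interface
    symmetry with the 3D generator; the radiative transfer chain itself is
    deterministic.
    """

    canopy: str = "A"
    frequencies: tuple[float, ...] = (5.3,)
    theta_inc_deg: float = 43.0
    channels: tuple[str, ...] = ("VV", "HH", "VH", "HV")
    shapes: tuple[str, ...] = _SHAPES
    heights: tuple[float, ...] = tuple(float(h) for h in range(80, 301, 10))
    rho_v: float = 8e-5
    alpha: float = math.pi / 4
    dz: float = 1.0
    n_zenith: int = 8
    n_azimuth: int = 16
    n_orient: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.heights):
            raise ValueError("heights must be positive")
        if self.rho_v < 0:
            raise ValueError("rho_v must be nonnegative")

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        """Load from TOML or JSON; list values become tuples."""
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        for key in ("frequencies", "channels", "shapes", "heights"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def grid(self) -> AngularGrid:
        return AngularGrid.build(self.n_zenith, self.n_azimuth,
                                 self.theta_inc_deg)


# ---------------------------------------------------------------------------
# Fast doubling engine over a density profile
# ---------------------------------------------------------------------------

class _CanopyEngine:
    """Caches per-species harmonic-domain unit blocks for one (canopy, f).

    Every slab's operators are linear combinations of per-species kernels
    scaled by the slab's areal densities, plus a diagonal Beer-Lambert term
    that is constant across azimuth harmonics; combining in the Fourier
    domain avoids any per-slab FFT.
    """

    def __init__(self, kernels: list[SpeciesKernels], grid: AngularGrid):
        self.grid = grid
        self.kernels = kernels
        nz, na = grid.mu.size, grid.n_azimuth
        n = 2 * nz
        self.n = n
        dphi_w = 2.0 * math.pi / na
        inv_mu = 1.0 / grid.mu

        def block(pk: np.ndarray, h_s: int, h_i: int) -> np.ndarray:
            blk = pk[:, :, h_s, h_i] * inv_mu[None, None, :, None, None]
            blk = blk * grid.w[None, None, None, :, None] * dphi_w
            return np.ascontiguousarray(
                blk.transpose(4, 2, 0, 3, 1).reshape(na, n, n))

        # harmonic-domain unit-areal-density blocks per species
        self.S1 = [np.fft.fft(block(k.pk, 0, 1), axis=0) for k in kernels]
        self.T1 = [np.fft.fft(block(k.pk, 1, 1), axis=0) for k in kernels]
        self.Ss1 = [np.fft.fft(block(k.pk, 1, 0), axis=0) for k in kernels]
        self.Ts1 = [np.fft.fft(block(k.pk, 0, 0), axis=0) for k in kernels]
        # extinction cross sections per species, flattened to state order
        self.sig_dn = [k.sig_e[:, 1, :].T.reshape(n) for k in kernels]
        self.sig_up = [k.sig_e[:, 0, :].T.reshape(n) for k in kernels]
        self.inv_mu_state = np.repeat(inv_mu, 2)

    def slab_ops(self, areal: np.ndarray) -> _HarmonicOps:
        """Operators of one slab from per-species areal densities (cm^-2).

        If the slab violates the thin-layer precondition (single-pass
        optical thickness above 0.1 at the most grazing node) it is
        automatically subdivided and recombined, which is equivalent to a
        locally refined dz.
        """
        from .matrix_doubling import _combine_h

        tau_max = float(sum(a * b.max() for a, b in zip(areal, self.sig_dn))
                        * self.inv_mu_state.max())
        m = max(1, int(math.ceil(tau_max / 0.1)))
        if m > 1:
            sub = self._slab_ops_thin(np.asarray(areal) / m)
            total = sub
            for _ in range(m - 1):
                total = _combine_h(total, sub)
            return total
        return self._slab_ops_thin(areal)

    def _slab_ops_thin(self, areal: np.ndarray) -> _HarmonicOps:
        s = sum(a * b for a, b in zip(areal, self.S1))
        t = sum(a * b for a, b in zip(areal, self.T1))
        ss = sum(a * b for a, b in zip(areal, self.Ss1))
        ts = sum(a * b for a, b in zip(areal, self.Ts1))
        tau_dn = sum(a * b for a, b in zip(areal, self.sig_dn))
        tau_up = sum(a * b for a, b in zip(areal, self.sig_up))
        idx = np.arange(self.n)
        t = t.copy()
        ts = ts.copy()
        t[:, idx, idx] += np.exp(-tau_dn * self.inv_mu_state)[None, :]
        ts[:, idx, idx] += np.exp(-tau_up * self.inv_mu_state)[None, :]
        return _HarmonicOps(S=s, T=t, S_star=ss, T_star=ts, dz=0.0)

    def stack(self, areal_profile: np.ndarray) -> _HarmonicOps:
        """Doubling stack over a bottom-up profile (n_layers, n_species)."""
        from .matrix_doubling import _combine_h

        total = self.slab_ops(areal_profile[-1])
        for areal in areal_profile[-2::-1]:
            total = _combine_h(total, self.slab_ops(areal))
        return total

    def sigma0(self, areal_profile: np.ndarray, theta_inc_deg: float,
               channels: tuple[str, ...]) -> dict[str, float]:
        grid = self.grid
        total = self.stack(areal_profile)
        k0 = grid.node_index(theta_inc_deg)
        l_back = grid.n_azimuth // 2
        na = grid.n_azimuth
        # inverse DFT of the S kernel at the single backscatter azimuth node
        phase = np.exp(2j * math.pi * np.arange(na) * l_back / na) / na
        s_back = np.real(np.einsum("m,mij->ij", phase, total.S))
        out = {}
        mu0 = grid.mu[k0]
        weight = grid.w[k0] * (2.0 * math.pi / na)
        for ch in channels:
            p = "VH".index(ch[0])
            q = "VH".index(ch[1])
            lin = 4.0 * math.pi * mu0 * s_back[2 * k0 + p, 2 * k0 + q] / weight
            out[ch] = 10.0 * math.log10(lin) if lin > 0 else -math.inf
        return out


def _areal_profile(envelope: cg.CrownEnvelope, mus: list[float],
                   dz: float) -> np.ndarray:
    """Bottom-up per-slab areal densities (cm^-2) for each species."""
    a_ref = math.pi * (envelope.H * math.tan(envelope.alpha)) ** 2
    slices = cg.slice_layers(envelope, dz)
    counts = np.array([
        [cg.layer_scatterer_count(envelope, mu, sl) for mu in mus]
        for sl in slices
    ])
    return counts / a_ref


def _band_engines(config: SimulationConfig) -> dict[float, _CanopyEngine]:
    grid = config.grid()
    engines = {}
    for f in config.frequencies:
        kerns = [
            species_kernels(spec, f, grid, n_orient=config.n_orient)
            for spec in canopy_species(config.canopy, f)
        ]
        engines[f] = _CanopyEngine(kerns, grid)
    return engines


def run_height_sweep(config: SimulationConfig) -> pd.DataFrame:
    """sigma0 for every (shape, height, frequency, channel) cell.

    Returns a long-format table with columns shape, height_cm, freq_ghz,
    channel, sigma0_db. Cells that fail (e.g. infeasible geometry) are
    recorded with NaN and the run continues. Deterministic for fixed
    numeric settings.
    """
    engines = _band_engines(config)
    mus = [config.rho_v] * len(next(iter(engines.values())).kernels)
    rows = []
    for shape in config.shapes:
        for h in config.heights:
            try:
                env = cg.CrownEnvelope(kind=shape, H=h, alpha=config.alpha)
                profile = _areal_profile(env, mus, config.dz)
            except Exception:
                for f in config.frequencies:
                    for ch in config.channels:
                        rows.append((shape, h, f, ch, math.nan))
                continue
            for f, engine in engines.items():
                try:
                    sig = engine.sigma0(profile, config.theta_inc_deg,
                                        config.channels)
                except Exception:
                    sig = {ch: math.nan for ch in config.channels}
                for ch in config.channels:
                    rows.append((shape, h, f, ch, sig[ch]))
    return pd.DataFrame(
        rows, columns=["shape", "height_cm", "freq_ghz", "channel",
                       "sigma0_db"])


def parabola_sweep(config: SimulationConfig,
                   a_range: tuple[float, float] = (-2.0, 1.0),
                   b_range: tuple[float, float] = (-2.0, 2.0),
                   step: float = 0.1,
                   height_cm: float = 100.0,
                   frequency_ghz: float = 5.3,
                   channel: str = "VV") -> pd.DataFrame:
    """sigma0 over the feasible (a, b) parabola grid at one height.

    The constant c is solved from the equal-volume constraint at every
    point; infeasible points (squared radius negative somewhere in the
    crown) are marked and carry NaN. Defaults follow the crown-shape
    transition experiment: C band, VV, canopy A parameters.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    cfg = replace(config, frequencies=(frequency_ghz,),
                  channels=(channel.upper(),))
    engine = _band_engines(cfg)[frequency_ghz]
    mus = [cfg.rho_v] * len(engine.kernels)
    n_a = int(round((a_range[1] - a_range[0]) / step)) + 1
    n_b = int(round((b_range[1] - b_range[0]) / step)) + 1
    rows = []
    for a in (a_range[0] + step * np.arange(n_a)):
        for b in (b_range[0] + step * np.arange(n_b)):
            a, b = round(float(a), 10), round(float(b), 10)
            c = cg.solve_constraint_c(a, b)
            if not cg.feasible(a, b, c):
                rows.append((a, b, c, False, math.nan))
                continue
            env = cg.CrownEnvelope(kind="parabolic", H=height_cm,
                                   alpha=cfg.alpha, a=a, b=b)
            profile = _areal_profile(env, mus, cfg.dz)
            sig = engine.sigma0(profile, cfg.theta_inc_deg, cfg.channels)
            rows.append((a, b, c, True, sig[channel.upper()]))
    return pd.DataFrame(rows, columns=["a", "b", "c", "feasible",
                                       "sigma0_db"])


# ---------------------------------------------------------------------------
# Comparison metrics
# ---------------------------------------------------------------------------

def mad(x, x_ref) -> float:
    """Mean absolute difference of two equal-length dB series, in dB."""
    x = np.asarray(x, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    if x.shape != x_ref.shape or x.size == 0:
        raise ValueError("series must have equal, nonzero length")
    return float(np.mean(np.abs(x - x_ref)))


def mrd(x, x_ref) -> float:
    """Mean relative difference of two dB series, in percent.

    Computed on the dB-domain values: mean of |(x_i - x_i') / x_i| * 100.
    """
    x = np.asarray(x, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    if x.shape != x_ref.shape or x.size == 0:
        raise ValueError("series must have equal, nonzero length")
    if np.any(x == 0):
        raise ValueError("zero denominator in relative difference")
    return float(np.mean(np.abs((x - x_ref) / x)) * 100.0)


def shape_difference_report(table: pd.DataFrame,
                            reference: str = "cylinder") -> pd.DataFrame:
    """MAD/MRD of every shape's height series against the reference shape.

    One row per (freq_ghz, channel, shape != reference) with columns
    ``mad_db`` and ``mrd_percent``; series are aligned on height.
    """
    if reference not in set(table["shape"]):
        raise ValueError(f"reference shape {reference!r} missing from table")
    rows = []
    for (f, ch), sub in table.groupby(["freq_ghz", "channel"], sort=True):
        ref = sub[sub["shape"] == reference].set_index("height_cm")[
            "sigma0_db"].sort_index()
        for shape in sorted(set(sub["shape"]) - {reference}):
            ser = sub[sub["shape"] == shape].set_index("height_cm")[
                "sigma0_db"].sort_index()
            if not ser.index.equals(ref.index):
                raise ValueError("height grids differ between shapes")
            rows.append((f, ch, shape, mad(ser.values, ref.values),
                         mrd(ser.values, ref.values)))
    return pd.DataFrame(rows, columns=["freq_ghz", "channel", "shape",
                                       "mad_db", "mrd_percent"])


def azimuth_average_and_fit(sigma_db: np.ndarray,
                            heights: np.ndarray) -> dict:
    """Average a per-azimuth sigma0 series and fit a quadratic height trend.

    ``sigma_db`` has shape (n_heights, n_azimuths) (an explicit azimuth
    sample list; duplicate 0/360 samples are the caller's choice). Returns
    the azimuth means and the least-squares quadratic coefficients
    (c2, c1, c0) with sigma0 ~ c2 H^2 + c1 H + c0.
    """
    sigma_db = np.atleast_2d(np.asarray(sigma_db, dtype=float))
    heights = np.asarray(heights, dtype=float)
    if sigma_db.shape[0] != heights.size:
        raise ValueError("one row of azimuth samples per height is required")
    if heights.size < 3:
        raise ValueError("quadratic fitting needs at least 3 heights")
    mean = sigma_db.mean(axis=1)
    coeffs = np.polyfit(heights, mean, deg=2)
    return {"mean_db": mean, "coefficients": coeffs,
            "fitted_db": np.polyval(coeffs, heights)}
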