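"""Scattering spectra: sine transform, analytic form factor, inversion, fitting.

The binned Debye sum turns a weighted distance histogram H into an intensity

    I(q) = sum_k H_k * sin(q r_k) / (q r_k),

with r_k the bin-center representative distance and q the scattering-vector
magnitude (4 pi / lambda) sin(theta / 2).  For the core-shell sphere the
intensity is known in closed form as the squared sum of two sphere
amplitudes, which is what the simulated spectrum is validated against —
up to a single multiplicative scale factor, since the Monte Carlo point
model fixes neither the absolute normalization nor the volume prefactors.

Distances are picometers on the histogram side and meters inside the
transforms; q is always in inverse meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histogram import WeightedHistogram
from .model import CoreShellSpec

__all__ = [
    "DEFAULT_N_Q",
    "DEFAULT_Q_MAX",
    "Spectrum",
    "ScaleFit",
    "PairDistribution",
    "default_q_grid",
    "q_from_angle",
    "sine_ft_histogram",
    "analytic_intensity",
    "inverse_ft_intensity",
    "fit_scale",
    "write_spectrum",
    "read_spectrum",
]

#: default q sampling: 4000 points up to 8e9 m^-1
DEFAULT_N_Q = 4000
DEFAULT_Q_MAX = 8.0e9

_PM = 1.0e-12  # meters per picometer


@dataclass
class Spectrum:
    """Intensity values on an ascending scattering-vector grid (q in m^-1)."""

    q_grid: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=np.float64).reshape(-1)
        self.intensity = np.asarray(self.intensity, dtype=np.float64).reshape(-1)
        if len(self.q_grid) != len(self.intensity):
            raise ValueError("q_grid and intensity must have equal length")
        if len(self.q_grid) and (
            self.q_grid[0] < 0 or (np.diff(self.q_grid) <= 0).any()
        ):
            raise ValueError("q_grid must be non-negative and strictly increasing")


@dataclass
class ScaleFit:
    """Least-squares multiplicative match of a computed to an analytic spectrum."""

    scale: float
    sse: float
    q_window: tuple[float, float]
    #: sqrt(sse) / l2-norm of the reference within the window
    rel_rms: float = float("nan")


@dataclass
class PairDistribution:
    """P(r) values on an r grid in picometers, with provenance metadata."""

    r_pm: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)


def default_q_grid(n_q: int = DEFAULT_N_Q, q_max: float = DEFAULT_Q_MAX) -> np.ndarray:
    """Linear grid of ``n_q`` points from 0 to ``q_max`` (inclusive)."""
    return np.linspace(0.0, q_max, n_q)


def q_from_angle(theta: float, wavelength: float):
    """Scattering-vector magnitude q = (4 pi / lambda) sin(theta / 2).

    ``theta`` is the total scattering angle in radians (the 2-theta of the
    diffraction convention), ``wavelength`` in meters.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if np.asarray(wavelength, dtype=np.float64) <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    if ((theta < 0) | (theta > np.pi)).any():
        raise ValueError("total scattering angle must lie in [0, pi]")
    q = (4.0 * np.pi / wavelength) * np.sin(theta / 2.0)
    return float(q) if q.ndim == 0 else q


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with the x -> 0 limit; np.sinc is normalized by pi
    return np.sinc(x / np.pi)


def sine_ft_histogram(
    hist: WeightedHistogram, q_grid: np.ndarray | None = None, _q_block: int = 256
) -> Spectrum:
    """Binned Debye sum: I(q) = sum_k H_k sinc(q r_k), r_k the bin center.

    I(0) is the sinc limit sum_k H_k.  The q grid is evaluated in blocks so
    the (n_q, n_bins) kernel matrix never fully materializes.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=np.float64)
    nz = np.flatnonzero(hist.values)
    r_m = (nz + 0.5) * hist.bin_width * _PM
    h = hist.values[nz]
    intensity = np.empty_like(q_grid)
    for a in range(0, len(q_grid), _q_block):
        b = min(a + _q_block, len(q_grid))
        intensity[a:b] = _sinc(np.outer(q_grid[a:b], r_m)) @ h
    return Spectrum(q_grid, intensity, {"provenance": "computed"})


def _sphere_kernel(x: np.ndarray) -> np.ndarray:
    """(sin x - x cos x) / x^3, the normalized sphere amplitude; -> 1/3 at 0.

    The numerator loses all precision below x ~ 1e-3, where the Taylor
    series 1/3 - x^2/30 + x^4/840 is exact to double precision.
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    small = np.abs(x) < 1.0e-3
    xs = x[small]
    out[small] = 1.0 / 3.0 - xs**2 / 30.0 + xs**4 / 840.0
    xl = x[~small]
    out[~small] = (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def analytic_intensity(
    spec: CoreShellSpec, q_grid: np.ndarray | None = None
) -> Spectrum:
    """Closed-form core-shell sphere intensity (arbitrary units).

    I(q) = [ rho_e Re^3 A(q Re) + (rho_i - rho_e) Ri^3 A(q Ri) ]^2 with
    A(x) = (sin x - x cos x)/x^3: a homogeneous sphere of radius Re at the
    shell contrast plus a core-sized sphere carrying the contrast step.
    Constant volume prefactors are omitted; comparisons are scale-fitted.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=np.float64)
    re, ri = spec.r_total, spec.r_core
    amplitude = spec.rho_shell * re**3 * _sphere_kernel(q_grid * re) + (
        spec.rho_core - spec.rho_shell
    ) * ri**3 * _sphere_kernel(q_grid * ri)
    return Spectrum(q_grid, amplitude**2, {"provenance": "analytic"})


def inverse_ft_intensity(
    spectrum: Spectrum, r_grid_pm: np.ndarray, _r_block: int = 64
) -> PairDistribution:
    """Distance distribution P(r) = (2r/pi) * integral q I(q) sin(qr) dq.

    Trapezoidal quadrature on the spectrum's own q grid; ``r_grid_pm`` in
    picometers.  P(0) = 0 identically.  Distances are resolvable only up to
    about pi / dq (the Nyquist-style bound of the q sampling); requests
    beyond it set a warning in the result metadata instead of failing.
    """
    q = spectrum.q_grid
    if len(q) < 2:
        raise ValueError("spectrum too short to integrate")
    r_m = np.asarray(r_grid_pm, dtype=np.float64) * _PM
    meta: dict = {"provenance": spectrum.meta.get("provenance", "unknown")}
    r_max_resolvable = np.pi / np.diff(q).max()
    if (r_m > r_max_resolvable).any():
        meta["warning"] = (
            f"r beyond the resolvable range {r_max_resolvable / _PM:.3g} pm "
            "for this q sampling"
        )
    qi = q * spectrum.intensity
    values = np.empty_like(r_m)
    for a in range(0, len(r_m), _r_block):
        b = min(a + _r_block, len(r_m))
        integrand = np.sin(np.outer(r_m[a:b], q)) * qi
        values[a:b] = (2.0 * r_m[a:b] / np.pi) * np.trapezoid(integrand, q, axis=1)
    return PairDistribution(np.asarray(r_grid_pm, dtype=np.float64), values, meta)


def fit_scale(
    computed: Spectrum,
    analytic: Spectrum,
    q_window: tuple[float, float] | None = None,
) -> ScaleFit:
    """Single multiplying factor s minimizing sum (analytic - s*computed)^2.

    The normal-equation solution s = sum(a c) / sum(c^2) over the window
    leaves the residual orthogonal to the computed signal.  The analytic
    spectrum is linearly resampled onto the computed grid when the grids
    differ.  ``rel_rms`` reports sqrt(sse) relative to the l2 norm of the
    analytic reference in the window.
    """
    q = computed.q_grid
    a = analytic.intensity
    if len(analytic.q_grid) != len(q) or not np.array_equal(analytic.q_grid, q):
        a = np.interp(q, analytic.q_grid, analytic.intensity)
    if q_window is None:
        q_window = (float(q[0]), float(q[-1]))
    lo, hi = q_window
    sel = (q >= lo) & (q <= hi)
    c_w = computed.intensity[sel]
    a_w = a[sel]
    denom = float(c_w @ c_w)
    if denom == 0.0:
        raise ValueError("computed spectrum is identically zero in the fit window")
    scale = float(a_w @ c_w) / denom
    resid = a_w - scale * c_w
    sse = float(resid @ resid)
    norm_a = float(a_w @ a_w)
    rel = float(np.sqrt(sse / norm_a)) if norm_a > 0 else float("nan")
    return ScaleFit(scale=scale, sse=sse, q_window=(lo, hi), rel_rms=rel)


# ---------------------------------------------------------------------------
# two-column text interchange (q in m^-1, intensity)
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# provenance={spectrum.meta.get('provenance', 'unknown')}\n")
        fh.write("# columns=q_per_m,intensity\n")
        for q, i in zip(spectrum.q_grid, spectrum.intensity):
            fh.write(f"{float(q)!r} {float(i)!r}\n")


def read_spectrum(path) -> Spectrum:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "provenance":
                    meta["provenance"] = val
            else:
                rows.append([float(tok) for tok in line.split()])
    arr = np.array(rows) if rows else np.empty((0, 2))
    return Spectrum(arr[:, 0], arr[:, 1], meta)
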