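"""Core-shell pseudo-electron point models.

A scattering object is represented by a cloud of point "pseudo-electrons",
each carrying the local electron-density contrast (excess electron density
relative to solvent, in electrons/A^3, possibly negative).  The reference
model is a sphere of total radius ``r_total`` whose inner core of radius
``r_core`` has a different contrast from the surrounding shell; the number
density of points is uniform throughout, so only the per-point weight
distinguishes core from shell.  This geometry has a closed-form scattering
intensity, which makes it the natural validation model for the whole
histogram -> spectrum pipeline.

All coordinates are handled internally in picometers (pm); meters are
accepted on input and converted once.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PM_PER_M",
    "CoreShellSpec",
    "ParticleCloud",
    "generate_core_shell",
    "cloud_extent",
    "write_xyz",
    "read_xyz",
]

#: picometers per meter
PM_PER_M = 1.0e12


@dataclass(frozen=True)
class CoreShellSpec:
    """Parameters of the two-sphere (core + shell) point model.

    Defaults reproduce the reference nanoparticle: core radius 5.4 nm with
    contrast -0.08 e/A^3 (electron-poor relative to water), total radius
    10.8 nm with shell contrast +0.07 e/A^3, and two million pseudo-electrons.

    Parameters
    ----------
    n_particles
        Number of pseudo-electrons N.
    r_core, r_total
        Core radius Ri and total radius Re, in meters.
    rho_core, rho_shell
        Electron-density contrasts of core and shell (electrons/A^3).
    seed
        Seed for the position generator; identical specs produce
        bit-identical clouds.
    """

    n_particles: int = 2_000_000
    r_core: float = 5.4e-9
    r_total: float = 10.8e-9
    rho_core: float = -0.08
    rho_shell: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_core < self.r_total):
            raise ValueError(
                f"need 0 < r_core < r_total, got r_core={self.r_core}, "
                f"r_total={self.r_total}"
            )
        if self.n_particles < 0:
            raise ValueError(f"n_particles must be >= 0, got {self.n_particles}")

    @property
    def r_core_pm(self) -> float:
        return self.r_core * PM_PER_M

    @property
    def r_total_pm(self) -> float:
        return self.r_total * PM_PER_M

    @property
    def max_distance_pm(self) -> float:
        """Largest possible inter-particle distance, 2*Re, in pm."""
        return 2.0 * self.r_total_pm


@dataclass
class ParticleCloud:
    """Point positions plus per-particle contrast weights.

    ``positions`` is an (N, 3) float array in the unit named by ``unit_tag``
    ("pm" canonically); ``weights`` holds one signed contrast value per point.
    """

    positions: np.ndarray
    weights: np.ndarray
    unit_tag: str = "pm"
    spec: CoreShellSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if len(self.positions) != len(self.weights):
            raise ValueError(
                f"positions ({len(self.positions)}) and weights "
                f"({len(self.weights)}) must have equal length"
            )
        if self.unit_tag not in ("pm", "m"):
            raise ValueError(f"unknown unit tag {self.unit_tag!r}")

    def __len__(self) -> int:
        return len(self.weights)

    def to_pm(self) -> "ParticleCloud":
        """Return this cloud with coordinates in picometers."""
        if self.unit_tag == "pm":
            return self
        return ParticleCloud(self.positions * PM_PER_M, self.weights, "pm", self.spec)


def generate_core_shell(spec: CoreShellSpec) -> ParticleCloud:
    """Draw N points uniformly in the ball of radius Re, weighted by region.

    Sampling is exact (no rejection): the radius comes from the inverse CDF
    r = Re * U^(1/3) and the direction from a normalized 3D Gaussian triple.
    A point at radius strictly below Ri gets the core contrast; a radius
    exactly equal to Ri (a probability-zero event, fixed for determinism)
    belongs to the shell.

    Returns a cloud in picometers, deterministic for a given spec.
    """
    n = spec.n_particles
    rng = np.random.default_rng(spec.seed)
    if n == 0:
        return ParticleCloud(np.empty((0, 3)), np.empty(0), "pm", spec)
    radii = spec.r_total_pm * np.cbrt(rng.random(n))
    direction = rng.standard_normal((n, 3))
    norms = np.linalg.norm(direction, axis=1)
    # resample the (measure-zero) zero-norm directions deterministically
    bad = norms == 0.0
    while bad.any():
        direction[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(direction, axis=1)
        bad = norms == 0.0
    positions = direction * (radii / norms)[:, None]
    weights = np.where(radii < spec.r_core_pm, spec.rho_core, spec.rho_shell)
    return ParticleCloud(positions, weights, "pm", spec)


def cloud_extent(cloud: ParticleCloud) -> float:
    """Upper bound on the largest pairwise distance: 2 * max radial distance.

    Returned in picometers.  For clouds centered at the origin (as generated
    here) the bound is tight up to the antipodality of the two outermost
    points.  Raises on an empty cloud.
    """
    cloud = cloud.to_pm()
    if len(cloud) == 0:
        raise ValueError("cloud_extent of an empty cloud is undefined")
    radii = np.linalg.norm(cloud.positions, axis=1)
    return float(2.0 * radii.max())


# ---------------------------------------------------------------------------
# extended-XYZ-style text format: "N\n# comment\nx y z w\n..."
# ---------------------------------------------------------------------------

def _spec_header(spec: CoreShellSpec | None) -> str:
    if spec is None:
        return ""
    return (
        f" spec: n={spec.n_particles} r_core_m={spec.r_core!r}"
        f" r_total_m={spec.r_total!r} rho_core={spec.rho_core!r}"
        f" rho_shell={spec.rho_shell!r} seed={spec.seed}"
    )


def write_xyz(cloud: ParticleCloud, path) -> None:
    """Write a cloud as extended-XYZ-style text: count, comment, x y z w rows."""
    cloud = cloud.to_pm()
    buf = io.StringIO()
    buf.write(f"{len(cloud)}\n")
    buf.write(f"# unit=pm columns=x,y,z,weight{_spec_header(cloud.spec)}\n")
    for (x, y, z), w in zip(cloud.positions, cloud.weights):
        buf.write(f"{float(x)!r} {float(y)!r} {float(z)!r} {float(w)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _parse_spec_comment(comment: str) -> CoreShellSpec | None:
    if "spec:" not in comment:
        return None
    try:
        fields = dict(
            tok.split("=", 1)
            for tok in comment.split("spec:", 1)[1].split()
            if "=" in tok
        )
        return CoreShellSpec(
            n_particles=int(fields["n"]),
            r_core=float(fields["r_core_m"]),
            r_total=float(fields["r_total_m"]),
            rho_core=float(fields["rho_core"]),
            rho_shell=float(fields["rho_shell"]),
            seed=int(fields["seed"]),
        )
    except (KeyError, ValueError):
        return None


def read_xyz(path) -> ParticleCloud:
    """Read a cloud written by :func:`write_xyz`.

    The unit tag in the comment line is honored ("unit=m" inputs are
    converted to pm); a spec echoed in the comment is re-attached.
    """
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        comment = fh.readline()
        if n == 0:
            data = np.empty((0, 4))
        else:
            data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    if data.shape != (n, 4):
        raise ValueError(
            f"expected {n} rows of 'x y z w', got array of shape {data.shape}"
        )
    unit = "m" if "unit=m" in comment else "pm"
    cloud = ParticleCloud(data[:, :3], data[:, 3], unit, _parse_spec_comment(comment))
    return cloud.to_pm()
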