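"""Three-shell spherical head model, source space, lead field and scalp EEG.

The head is modeled as three concentric spheres (brain, skull, skin) with
relative conductivities (1, 1/80, 1); the 1/80 skull conductivity is the
classical worst-case choice that maximizes skull smearing.  Sources are
current dipoles on a quasi-uniform spherical mesh inside the brain shell,
oriented along the (optionally folded) outward surface normal.  Scalp
potentials are computed from the classical multilayer-sphere spherical
harmonic series: per harmonic degree the radial two-point boundary problem
(potential and current continuity at both interfaces, insulating scalp) is
solved exactly, and the dipole's free-medium expansion supplies the source
coefficients.  The series converges geometrically at rate (b/R)^n for a
dipole at radius b and scalp radius R.

Scalp EEG is D(n) = scale * G S(n) + e(n) with average-referenced G and
white, re-referenced sensor noise scaled to a requested SNR (ratio of mean
signal power over trials/time/electrodes to the noise variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import sph_harm_y

from .ground_truth import GroundTruthModel, TrialTensor

__all__ = [
    "HeadModel",
    "SourceSpace",
    "SensorArray",
    "LeadField",
    "build_head_model",
    "compute_leadfield",
    "map_ground_truth_dipoles",
    "project_and_add_noise",
]


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell geometry (radii in mm, innermost first)."""

    shell_radii: tuple[float, float, float] = (80.0, 85.0, 92.0)
    conductivities: tuple[float, float, float] = (1.0, 1.0 / 80.0, 1.0)
    series_truncation: int = 60

    def __post_init__(self):
        r = self.shell_radii
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must be strictly increasing")
        if min(self.conductivities) <= 0:
            raise ValueError("conductivities must be positive")


@dataclass
class SourceSpace:
    """Triangulated quasi-spherical source surface with outward unit normals."""

    positions: np.ndarray  # (V, 3) mm
    normals: np.ndarray  # (V, 3) unit
    triangles: np.ndarray  # (F, 3) int

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected mesh edges, (E, 2) with e[0] < e[1]."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.triangles)


@dataclass
class SensorArray:
    positions: np.ndarray  # (E, 3) mm, on scalp shell
    labels: list[str] = field(default_factory=list)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class LeadField:
    """Sensor x dipole gain matrix for unit dipoles along source normals."""

    G: np.ndarray  # (E, V)
    referenced: bool = True

    @property
    def n_sensors(self) -> int:
        return self.G.shape[0]

    @property
    def n_sources(self) -> int:
        return self.G.shape[1]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _fold_field(directions: np.ndarray, degree: int, order: int) -> np.ndarray:
    """Smooth scalar 'cortical folding' field: a real spherical harmonic of
    the given degree, normalized to unit maximum over the vertices."""
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    g = np.real(sph_harm_y(degree, order, theta, phi))
    peak = np.max(np.abs(g))
    return g / peak if peak > 0 else g


def _vertex_normals(positions: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Outward area-weighted vertex normals of a closed star-shaped mesh."""
    v0, v1, v2 = (positions[triangles[:, k]] for k in range(3))
    fn = np.cross(v1 - v0, v2 - v0)  # area-weighted face normals
    # orient faces outward (positive radial component at centroid)
    centroid = (v0 + v1 + v2) / 3.0
    flip = np.sum(fn * centroid, axis=1) < 0
    fn[flip] *= -1.0
    normals = np.zeros_like(positions)
    for k in range(3):
        np.add.at(normals, triangles[:, k], fn)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return normals


def build_head_model(
    n_vertices: int = 2000,
    n_electrodes: int = 64,
    fold_amplitude: float = 0.0,
    seed=None,
    shell_radii: tuple[float, float, float] = (80.0, 85.0, 92.0),
    conductivities: tuple[float, float, float] = (1.0, 1.0 / 80.0, 1.0),
    source_radius: float | None = None,
    series_truncation: int = 60,
    fold_degree: int = 20,
    fold_order: int = 10,
) -> tuple[HeadModel, SourceSpace, SensorArray]:
    """Build head geometry, a quasi-cortical source mesh, and electrodes.

    The source mesh is a Fibonacci lattice triangulated by its convex hull
    on the unit sphere; a radial spherical-harmonic perturbation of amplitude
    ``fold_amplitude`` (mm) emulates cortical folding so that normals vary in
    direction (and, for strong folding, in sign between neighbours).

    Raises
    ------
    ValueError
        If the folding pushes vertices outside the brain shell, or the
        requested sizes are too small (n_vertices >= 50, n_electrodes >= 16).
    """
    if n_vertices < 50:
        raise ValueError("n_vertices must be >= 50")
    if n_electrodes < 16:
        raise ValueError("n_electrodes must be >= 16")
    head = HeadModel(
        shell_radii=tuple(shell_radii),
        conductivities=tuple(conductivities),
        series_truncation=series_truncation,
    )
    r_brain = head.shell_radii[0]
    if source_radius is None:
        source_radius = 0.85 * r_brain
    directions = fibonacci_directions(n_vertices)
    hull = ConvexHull(directions)
    triangles = hull.simplices.copy()
    radii = np.full(n_vertices, float(source_radius))
    if fold_amplitude:
        radii = radii + fold_amplitude * _fold_field(directions, fold_degree, fold_order)
    if radii.max() >= 0.98 * r_brain:
        raise ValueError(
            f"folding pushes vertices to radius {radii.max():.1f} mm, too close "
            f"to the brain shell ({r_brain} mm)"
        )
    positions = directions * radii[:, None]
    if fold_amplitude:
        normals = _vertex_normals(positions, triangles)
    else:
        normals = directions  # exact sphere normal

    sources = SourceSpace(positions=positions, normals=normals, triangles=triangles)
    elec_dirs = fibonacci_directions(n_electrodes)
    sensors = SensorArray(
        positions=elec_dirs * head.shell_radii[2],
        labels=[f"E{i + 1:03d}" for i in range(n_electrodes)],
    )
    return head, sources, sensors


# ---------------------------------------------------------------------------
# Analytic multilayer-sphere lead field
# ---------------------------------------------------------------------------

def _radial_transfer(head: HeadModel) -> np.ndarray:
    """Per-degree scalp transfer factors T_n of the three-shell model.

    For each harmonic degree n the potential in layer k is
    ``A_k r^n + B_k r^-(n+1)``; with the dipole's singular coefficient in the
    innermost layer normalized to 1, continuity of potential and radial
    current at both interfaces plus the insulating outer boundary give a
    5x5 linear system.  T_n is the resulting scalp-surface potential per
    unit source coefficient (free medium would give ``R^-(n+1)``).
    """
    r1, r2, r3 = head.shell_radii
    s1, s2, s3 = head.conductivities
    n_max = head.series_truncation
    out = np.empty(n_max + 1)
    out[0] = 0.0
    for n in range(1, n_max + 1):
        # unknowns: [A1, A2, B2, A3, B3]
        mat = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at r1: A1 r1^n + r1^-(n+1) = A2 r1^n + B2 r1^-(n+1)
        mat[0] = [r1 ** n, -(r1 ** n), -(r1 ** -(n + 1)), 0.0, 0.0]
        rhs[0] = -(r1 ** -(n + 1))
        # current continuity at r1
        mat[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0.0,
            0.0,
        ]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # potential continuity at r2
        mat[2] = [0.0, r2 ** n, r2 ** -(n + 1), -(r2 ** n), -(r2 ** -(n + 1))]
        # current continuity at r2
        mat[3] = [
            0.0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # insulating outer boundary at r3
        mat[4] = [0.0, 0.0, 0.0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)]
        sol = np.linalg.solve(mat, rhs)
        out[n] = sol[3] * r3 ** n + sol[4] * r3 ** -(n + 1)
    return out


def free_medium_potential(
    dipole_pos: np.ndarray, dipole_moment: np.ndarray, field_pos: np.ndarray,
    sigma: float = 1.0,
) -> np.ndarray:
    """Exact infinite-medium dipole potential (oracle for the expansion)."""
    d = field_pos - dipole_pos
    r = np.linalg.norm(d, axis=-1)
    return (d @ dipole_moment) / (4.0 * np.pi * sigma * r ** 3)


def compute_leadfield(
    head: HeadModel,
    sources: SourceSpace,
    sensors: SensorArray,
    average_reference: bool = True,
    transfer: np.ndarray | None = None,
) -> LeadField:
    """Lead field of unit dipoles along the source normals.

    The per-degree sums use Legendre recurrences evaluated simultaneously for
    all sensor/source pairs.  A warning is issued if the final series term is
    not negligible relative to the accumulated potential.

    Passing ``transfer`` overrides the three-shell radial factors (used by
    the free-medium validation oracle).
    """
    if transfer is None:
        transfer = _radial_transfer(head)
    n_max = len(transfer) - 1
    pos = sources.positions
    b = np.linalg.norm(pos, axis=1)  # (V,)
    bhat = pos / b[:, None]
    ehat = sensors.positions / np.linalg.norm(sensors.positions, axis=1, keepdims=True)
    x = ehat @ bhat.T  # (E, V) cos(gamma)
    m_rad = np.sum(sources.normals * bhat, axis=1)  # (V,) m . bhat
    m_e = ehat @ sources.normals.T  # (E, V) m . ehat
    sigma1 = head.conductivities[0]
    pref = 1.0 / (4.0 * np.pi * sigma1)

    g = np.zeros_like(x)
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    dp_prev = np.zeros_like(x)  # P'_0
    dp_cur = np.ones_like(x)  # P'_1
    b_pow = np.ones_like(b)  # b^(n-1)
    last_term_max = 0.0
    for n in range(1, n_max + 1):
        radial = n * m_rad[None, :] * p_cur
        tangential = dp_cur * (m_e - x * m_rad[None, :])
        term = pref * transfer[n] * b_pow[None, :] * (radial + tangential)
        g += term
        last_term_max = np.max(np.abs(term))
        if n < n_max:
            p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
            dp_next = dp_prev + (2 * n + 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            b_pow = b_pow * b
    scale = np.max(np.abs(g))
    if scale > 0 and last_term_max / scale > 1e-6:
        warnings.warn(
            f"lead-field series not converged after {n_max} terms "
            f"(relative last term {last_term_max / scale:.2e})",
            RuntimeWarning,
        )
    if average_reference:
        g = g - g.mean(axis=0, keepdims=True)
    return LeadField(G=g, referenced=average_reference)


# ---------------------------------------------------------------------------
# Ground-truth dipole placement and scalp projection
# ---------------------------------------------------------------------------

def mni_to_sphere_affine(model: GroundTruthModel, sources: SourceSpace):
    """Documented affine map from MNI mm into the spherical source space:
    center the region coordinates and scale isotropically so the farthest
    region sits at 80% of the mean source radius."""
    coords = np.array([r.mni_xyz for r in model.regions], dtype=float)
    center = coords.mean(axis=0)
    r_src = float(np.mean(np.linalg.norm(sources.positions, axis=1)))
    scale = 0.8 * r_src / np.max(np.linalg.norm(coords - center, axis=1))
    return center, scale


def map_ground_truth_dipoles(
    sources: SourceSpace, model: GroundTruthModel
) -> np.ndarray:
    """Nearest source vertex (Euclidean) for each ground-truth region.

    Ties are broken by the lowest vertex index; a collision between regions
    raises, since each region must own a distinct dipole.
    """
    center, scale = mni_to_sphere_affine(model, sources)
    coords = np.array([r.mni_xyz for r in model.regions], dtype=float)
    mapped = (coords - center) * scale
    d2 = np.sum(
        (sources.positions[None, :, :] - mapped[:, None, :]) ** 2, axis=2
    )
    idx = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    if len(set(idx.tolist())) != len(idx):
        raise ValueError(f"ground-truth regions collide on vertices: {idx.tolist()}")
    return idx


def project_and_add_noise(
    leadfield: LeadField,
    source_trials: TrialTensor,
    scalp_snr: float,
    vertex_indices: np.ndarray,
    scale: float | None = None,
    target_peak: float = 50.0,
    seed=None,
    return_components: bool = False,
):
    """Project source trials to the scalp and add white sensor noise.

    ``D = scale * G[:, idx] S + e`` with the noise variance set so that the
    mean signal power (over trials, time and electrodes) divided by the
    noise variance equals ``scalp_snr``.  The noise is re-referenced to the
    average-reference subspace after drawing, then rescaled so the realized
    variance matches the target.  When ``scale`` is None it is chosen so the
    peak absolute scalp amplitude equals ``target_peak`` (microvolt-scale
    realism; the value only sets units).
    """
    if scalp_snr <= 0:
        raise ValueError("scalp_snr must be positive")
    rng = np.random.default_rng(seed)
    g = leadfield.G[:, vertex_indices]  # (E, m)
    s = source_trials.data  # (r, m, N)
    clean = np.einsum("em,rmn->ren", g, s)
    peak = np.abs(clean).max()
    if peak == 0:
        raise ValueError("zero-power source input: scalp SNR undefined")
    if scale is None:
        scale = target_peak / peak
    clean = scale * clean
    sig_power = np.mean(clean ** 2)
    noise_var = sig_power / scalp_snr
    noise = rng.standard_normal(clean.shape)
    if leadfield.referenced:
        noise -= noise.mean(axis=1, keepdims=True)  # re-reference across sensors
    noise *= np.sqrt(noise_var / np.mean(noise ** 2))
    out = TrialTensor(
        data=clean + noise,
        fs=source_trials.fs,
        t0_ms=source_trials.t0_ms,
        labels=[f"E{i + 1:03d}" for i in range(g.shape[0])],
    )
    if return_components:
        return out, (clean, noise)
    return out
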