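"""Diffusion basis spectrum imaging: forward model, spectral fit, metrics.

The voxel signal model is a linear combination of a small number of
anisotropic (axially symmetric) tensors — the axonal fiber components —
plus a continuous spectrum of isotropic diffusivities:

    S_k = sum_i f_i exp(-b_k lperp_i) exp(-b_k (lpar_i - lperp_i) cos^2 psi_ik)
          + integral_a^b f(D) exp(-b_k D) dD

with b in s/mm^2, diffusivities in um^2/ms (exponent scaled by 1e-3), and
psi_ik the angle between gradient k and fiber i. The isotropic spectrum is
discretized on a fixed diffusivity grid and split into restricted
(D <= 0.3), hindered (0.3 < D <= 3.0) and free (D > 3.0) bands, read as
cellularity, edema/extracellular water, and CSF-like water.

Fitting is two-stage: fiber orientations are found by non-negative least
squares over a dense basis of candidate directions with provisional
diffusivities, then a bounded derivative-free search over the per-fiber
(lpar, lperp) pairs with an inner Tikhonov-regularized NNLS jointly
resolving the fiber fractions and the isotropic spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, nnls

from .acquisition import B_D_SCALE, AcquisitionScheme, VoxelSignal
from .errors import DomainError, ValidationError

RESTRICTED_MAX = 0.3  # um^2/ms, inclusive upper edge of the restricted band
HINDERED_MAX = 3.0    # um^2/ms, inclusive upper edge of the hindered band


# ---------------------------------------------------------------------------
# Spectrum grid and band fractions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumGrid:
    """Diffusivity nodes and quadrature weights for the isotropic spectrum."""

    d_values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d_values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if d.ndim != 1 or w.shape != d.shape:
            raise ValidationError("d_values and weights must be matching 1-D arrays")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("d_values must be strictly increasing")
        if d[0] < 0:
            raise ValidationError("spectrum lower limit must be >= 0")
        if d[-1] <= HINDERED_MAX:
            raise ValidationError(
                f"spectrum upper limit {d[-1]} must exceed {HINDERED_MAX} um^2/ms "
                "so the free-water band is representable"
            )
        if np.any(w <= 0):
            raise ValidationError("quadrature weights must be positive")
        object.__setattr__(self, "d_values", d)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.d_values.shape[0]

    def band_masks(self):
        """Boolean masks (restricted, hindered, free); boundary nodes go to
        the lower band (<= 0.3 restricted, <= 3.0 hindered). Comparisons use
        a small absolute tolerance so grid nodes meant to sit exactly on a
        boundary are not pushed over it by floating-point construction."""
        d = self.d_values
        eps = 1.0e-9
        restricted = d <= RESTRICTED_MAX + eps
        hindered = ~restricted & (d <= HINDERED_MAX + eps)
        free = ~restricted & ~hindered
        return restricted, hindered, free


def default_grid(d_min: float = 0.0, d_max: float = 4.0, n_nodes: int = 41) -> SpectrumGrid:
    """Uniform grid on [d_min, d_max] with trapezoidal quadrature weights."""
    d = np.linspace(d_min, d_max, n_nodes)
    h = d[1] - d[0]
    w = np.full(n_nodes, h)
    w[0] = w[-1] = h / 2
    return SpectrumGrid(d_values=d, weights=w)


def spectrum_fractions(iso_spectrum, grid: SpectrumGrid):
    """Band integrals (restricted, hindered, free) of a spectral density.

    The three values sum to the total isotropic fraction. A node exactly at a
    band edge belongs to the lower band.
    """
    spec = np.asarray(iso_spectrum, dtype=float)
    if spec.shape != grid.d_values.shape:
        raise ValidationError("spectrum length does not match grid")
    if np.any(spec < 0):
        raise ValidationError("spectrum must be non-negative")
    mass = spec * grid.weights
    r, h, f = grid.band_masks()
    return float(mass[r].sum()), float(mass[h].sum()), float(mass[f].sum())


def fiber_fa(lambda_par: float, lambda_perp: float) -> float:
    """Fractional anisotropy of an axially symmetric tensor.

    FA = (lpar - lperp) / sqrt(lpar^2 + 2 lperp^2), in [0, 1].
    """
    if lambda_par == 0 and lambda_perp == 0:
        raise DomainError("FA undefined for a zero tensor")
    if lambda_perp < 0 or lambda_par < lambda_perp:
        raise ValidationError("need 0 <= lambda_perp <= lambda_par")
    return float((lambda_par - lambda_perp) / np.sqrt(lambda_par**2 + 2 * lambda_perp**2))


# ---------------------------------------------------------------------------
# Model parameters and metrics
# ---------------------------------------------------------------------------

@dataclass
class DbsiModelParams:
    """Parameters of the multi-tensor + isotropic-spectrum model for one voxel."""

    orientations: np.ndarray          # (n_aniso, 3) unit vectors
    lambda_par: np.ndarray            # (n_aniso,) um^2/ms
    lambda_perp: np.ndarray           # (n_aniso,) um^2/ms
    fractions: np.ndarray             # (n_aniso,) signal fractions
    iso_spectrum: np.ndarray          # density on grid nodes
    grid: SpectrumGrid

    def __post_init__(self):
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.orientations.size == 0:
            self.orientations = np.zeros((0, 3))
        self.lambda_par = np.atleast_1d(np.asarray(self.lambda_par, dtype=float))
        self.lambda_perp = np.atleast_1d(np.asarray(self.lambda_perp, dtype=float))
        self.fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        self.iso_spectrum = np.asarray(self.iso_spectrum, dtype=float)
        n = self.n_aniso
        if not (len(self.lambda_par) == len(self.lambda_perp) == len(self.fractions) == n):
            raise ValidationError("per-tensor field lengths disagree")
        if np.any(self.lambda_perp < 0) or np.any(self.lambda_par < self.lambda_perp):
            raise ValidationError("need 0 <= lambda_perp <= lambda_par for every tensor")
        if np.any(self.fractions < 0) or np.any(self.iso_spectrum < 0):
            raise ValidationError("fractions and spectrum must be non-negative")
        if n and np.any(np.abs(np.linalg.norm(self.orientations, axis=1) - 1) > 1e-6):
            raise ValidationError("orientations must be unit vectors")
        if self.iso_spectrum.shape != self.grid.d_values.shape:
            raise ValidationError("iso_spectrum length does not match grid")

    @property
    def n_aniso(self) -> int:
        return self.orientations.shape[0]

    @property
    def iso_fraction(self) -> float:
        return float(np.sum(self.iso_spectrum * self.grid.weights))

    @property
    def total_fraction(self) -> float:
        return float(np.sum(self.fractions)) + self.iso_fraction

    def normalized(self) -> "DbsiModelParams":
        """Rescale so that the total signal fraction is exactly 1."""
        tot = self.total_fraction
        if tot <= 0:
            raise ValidationError("cannot normalize parameters with zero total fraction")
        return replace(
            self,
            fractions=self.fractions / tot,
            iso_spectrum=self.iso_spectrum / tot,
        )


@dataclass
class DbsiMetrics:
    """The eight voxel metrics derived from a DBSI fit.

    Fractions are unitless in [0, 1] and sum to 1; diffusivities in um^2/ms.
    ``normalized_b0`` (b0 over the CSF b0 baseline) is an intensity ratio set
    by the caller, since it needs a per-scan CSF baseline; it defaults to NaN.
    ``quality`` is "ok" for clean fits, otherwise a short diagnostic code.
    """

    fiber_fraction: float
    restricted_fraction: float
    hindered_fraction: float
    water_fraction: float
    fiber_fa: float
    fiber_ad: float
    fiber_rd: float
    normalized_b0: float = float("nan")
    quality: str = "ok"

    FIELD_ORDER = (
        "fiber_fraction", "fiber_fa", "fiber_ad", "fiber_rd",
        "restricted_fraction", "hindered_fraction", "water_fraction",
        "normalized_b0",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELD_ORDER], dtype=float)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _aniso_columns(scheme: AcquisitionScheme, orientations, lambda_par, lambda_perp):
    """Design columns exp(-b lperp) exp(-b (lpar-lperp) cos^2 psi), one per tensor."""
    orientations = np.atleast_2d(orientations)
    lambda_par = np.atleast_1d(lambda_par)
    lambda_perp = np.atleast_1d(lambda_perp)
    b = scheme.bvalues[:, None] * B_D_SCALE
    cos2 = (scheme.directions @ orientations.T) ** 2
    return np.exp(-b * lambda_perp[None, :]) * np.exp(-b * (lambda_par - lambda_perp)[None, :] * cos2)


def _iso_columns(scheme: AcquisitionScheme, d_values):
    b = scheme.bvalues[:, None] * B_D_SCALE
    return np.exp(-b * np.asarray(d_values)[None, :])


def dbsi_forward(params: DbsiModelParams, scheme: AcquisitionScheme) -> VoxelSignal:
    """Synthesize the noiseless voxel signal of a parameter set under a scheme.

    At b = 0 the signal equals the total fraction (1 for normalized params).
    """
    signal = np.zeros(scheme.K)
    if params.n_aniso:
        A = _aniso_columns(scheme, params.orientations, params.lambda_par, params.lambda_perp)
        signal += A @ params.fractions
    mass = params.iso_spectrum * params.grid.weights
    signal += _iso_columns(scheme, params.grid.d_values) @ mass
    return VoxelSignal.from_values(signal, scheme)


# ---------------------------------------------------------------------------
# Candidate orientation grid (subdivided icosahedron hemisphere)
# ---------------------------------------------------------------------------

def _icosphere(subdivisions: int = 2) -> np.ndarray:
    """Vertices of a subdivided icosahedron on the unit sphere."""
    phi = (1 + np.sqrt(5)) / 2
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.array(v, dtype=float) / np.linalg.norm(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts)


def default_candidate_grid(subdivisions: int = 2) -> np.ndarray:
    """Hemisphere of icosphere vertices (antipodes removed): 321 directions
    at 2 subdivisions."""
    v = _icosphere(subdivisions)
    keep = (v[:, 2] > 1e-9) | ((np.abs(v[:, 2]) <= 1e-9) & (v[:, 1] > 1e-9)) | (
        (np.abs(v[:, 2]) <= 1e-9) & (np.abs(v[:, 1]) <= 1e-9) & (v[:, 0] > 0)
    )
    return v[keep]


# ---------------------------------------------------------------------------
# Fit configuration
# ---------------------------------------------------------------------------

@dataclass
class DbsiFitConfig:
    """Knobs of the two-stage spectral fit.

    Both regularization weights multiply the largest singular value of their
    design matrix to give the Tikhonov (ridge) strength, and both default to
    small values: ridge on these highly coherent exponential bases prefers
    *spreading* weight across correlated columns, which manufactures diffuse
    anisotropic weight on isotropic voxels in stage 1 and pushes spectral
    mass across band edges in stage 2. The defaults keep the non-negative
    inversions well-posed without flattening spikes in noiseless data.
    """

    grid: SpectrumGrid = field(default_factory=default_grid)
    max_n_aniso: int = 2
    provisional_lambda_par: float = 1.5
    provisional_lambda_perp: float = 0.3
    fraction_threshold: float = 0.05      # min summed candidate weight per fiber
    cluster_angle_deg: float = 20.0
    reg_weight: float = 2.0e-4
    orientation_reg_weight: float = 0.002  # stage-1 ridge (keeps NNLS well-posed)
    lambda_par_bounds: tuple = (0.5, 3.0)
    lambda_perp_bounds: tuple = (0.0, 1.5)
    optimizer_maxiter: int = 150
    candidate_subdivisions: int = 2
    refine_span: float = 0.06       # tangent half-width of the local search
    refine_steps: int = 5
    refine_iters: int = 3           # 0 disables orientation refinement

    def candidate_grid(self) -> np.ndarray:
        return default_candidate_grid(self.candidate_subdivisions)


# ---------------------------------------------------------------------------
# Stage 1: orientation estimation
# ---------------------------------------------------------------------------

def estimate_orientations(
    signal: VoxelSignal,
    scheme: AcquisitionScheme,
    candidate_grid: np.ndarray | None = None,
    config: DbsiFitConfig | None = None,
) -> list[np.ndarray]:
    """Estimate fiber directions by sparse NNLS over a dense candidate basis.

    A non-negative least-squares problem is solved over anisotropic basis
    tensors (provisional diffusivities) on every candidate direction plus the
    isotropic spectrum columns. Surviving candidate weights are clustered by
    angular proximity (antipodally symmetric); each cluster whose summed
    weight exceeds ``fraction_threshold`` of the total contributes its
    weighted mean direction, up to ``max_n_aniso`` fibers.
    """
    config = config or DbsiFitConfig()
    if candidate_grid is None:
        candidate_grid = config.candidate_grid()
    candidate_grid = np.atleast_2d(np.asarray(candidate_grid, dtype=float))
    if candidate_grid.size == 0:
        raise ValidationError("candidate grid is empty")
    y = signal.normalized()
    n_cand = candidate_grid.shape[0]
    A_aniso = _aniso_columns(
        scheme,
        candidate_grid,
        np.full(n_cand, config.provisional_lambda_par),
        np.full(n_cand, config.provisional_lambda_perp),
    )
    A_iso = _iso_columns(scheme, config.grid.d_values)
    A = np.hstack([A_aniso, A_iso])
    # ridge keeps the dense, highly coherent candidate basis well-posed and
    # discourages spurious low-weight candidates under noise
    alpha = config.orientation_reg_weight * np.linalg.norm(A, 2)
    A_aug = np.vstack([A, alpha * np.eye(A.shape[1])])
    y_aug = np.concatenate([y, np.zeros(A.shape[1])])
    w, _ = nnls(A_aug, y_aug)
    cand_w = w[:n_cand]
    total = w.sum()
    if total <= 0:
        return []

    # greedy angular clustering, strongest candidate first
    cos_thresh = np.cos(np.deg2rad(config.cluster_angle_deg))
    order = np.argsort(cand_w)[::-1]
    unassigned = cand_w > 0
    clusters = []
    for idx in order:
        if not unassigned[idx] or cand_w[idx] <= 0:
            continue
        seed = candidate_grid[idx]
        cos = np.abs(candidate_grid @ seed)
        members = unassigned & (cos >= cos_thresh)
        signs = np.sign(candidate_grid[members] @ seed)
        mean_dir = (signs[:, None] * candidate_grid[members] * cand_w[members][:, None]).sum(axis=0)
        norm = np.linalg.norm(mean_dir)
        if norm > 0:
            clusters.append((cand_w[members].sum(), mean_dir / norm))
        unassigned[members] = False
    clusters.sort(key=lambda c: -c[0])
    keep = [d for wgt, d in clusters if wgt >= config.fraction_threshold * total]
    return keep[: config.max_n_aniso]


# ---------------------------------------------------------------------------
# Stage 2: variable-projection refinement
# ---------------------------------------------------------------------------

def _inner_nnls(y, scheme, orientations, lambda_par, lambda_perp, config):
    """Jointly solve fiber fractions and iso-spectrum masses for fixed
    diffusivities; ridge applies to the spectrum coefficients only."""
    n_fib = len(lambda_par)
    cols = []
    if n_fib:
        cols.append(_aniso_columns(scheme, orientations, lambda_par, lambda_perp))
    cols.append(_iso_columns(scheme, config.grid.d_values))
    A = np.hstack(cols)
    alpha = config.reg_weight * np.linalg.norm(A, 2)
    reg = np.zeros((config.grid.n, A.shape[1]))
    reg[:, n_fib:] = alpha * np.eye(config.grid.n)
    A_aug = np.vstack([A, reg])
    y_aug = np.concatenate([y, np.zeros(config.grid.n)])
    coef, _ = nnls(A_aug, y_aug)
    resid = float(np.linalg.norm(A @ coef - y))
    return coef, resid


def _refine_orientation(y, scheme, direction, config: DbsiFitConfig) -> np.ndarray:
    """Deterministic local tangent-grid polish of one estimated direction.

    The candidate grid resolves orientations to ~4 degrees; the leftover
    angular error leaves a residual that the spectrum solve absorbs by
    shifting band mass, so each cluster direction is refined by a shrinking
    5 x 5 tangent search at the provisional diffusivities.
    """
    best = np.asarray(direction, dtype=float)
    span = config.refine_span
    lp = np.array([config.provisional_lambda_par])
    lq = np.array([config.provisional_lambda_perp])
    for _ in range(config.refine_iters):
        helper = np.array([1.0, 0.0, 0.0]) if abs(best[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(best, helper)
        u /= np.linalg.norm(u)
        v = np.cross(best, u)
        best_r = None
        for a in np.linspace(-span, span, config.refine_steps):
            for b in np.linspace(-span, span, config.refine_steps):
                d = best + a * u + b * v
                d /= np.linalg.norm(d)
                _, r = _inner_nnls(y, scheme, [d], lp, lq, config)
                if best_r is None or r < best_r:
                    best_r, winner = r, d
        best = winner
        span /= 3.0
    return best


def fit_dbsi_voxel(
    signal: VoxelSignal,
    scheme: AcquisitionScheme,
    config: DbsiFitConfig | None = None,
    orientations: list | None = None,
):
    """Fit the spectrum model to one voxel.

    Returns ``(DbsiModelParams, DbsiMetrics)``. Degenerate voxels (b0 <= 0 or
    all-zero signal) are never fit: they come back with zeroed parameters and
    ``metrics.quality == "degenerate"`` so callers can exclude them.
    """
    config = config or DbsiFitConfig()
    grid = config.grid
    if signal.is_degenerate:
        params = DbsiModelParams(
            orientations=np.zeros((0, 3)), lambda_par=[], lambda_perp=[],
            fractions=[], iso_spectrum=np.zeros(grid.n), grid=grid,
        )
        metrics = DbsiMetrics(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, quality="degenerate")
        return params, metrics

    y = signal.normalized()
    if orientations is None:
        orientations = estimate_orientations(signal, scheme, config=config)
    orientations = [np.asarray(o, dtype=float) for o in orientations]
    if config.refine_iters > 0:
        orientations = [_refine_orientation(y, scheme, o, config) for o in orientations]
    n_fib = len(orientations)
    quality = "ok"

    if n_fib == 0:
        coef, resid = _inner_nnls(y, scheme, [], np.array([]), np.array([]), config)
        lpar = np.array([])
        lperp = np.array([])
    else:
        lo_par, hi_par = config.lambda_par_bounds
        lo_perp, hi_perp = config.lambda_perp_bounds

        def objective(theta):
            lp = np.clip(theta[0::2], lo_par, hi_par)
            lq = np.minimum(np.clip(theta[1::2], lo_perp, hi_perp), lp)
            _, r = _inner_nnls(y, scheme, orientations, lp, lq, config)
            return r

        starts = [
            np.tile([config.provisional_lambda_par, config.provisional_lambda_perp], n_fib),
            np.tile([1.0, 0.1], n_fib),
        ]
        bounds = [(lo_par, hi_par), (lo_perp, hi_perp)] * n_fib
        best = None
        converged = False
        for x0 in starts:
            res = minimize(
                objective, x0, method="Nelder-Mead", bounds=bounds,
                options={"maxiter": config.optimizer_maxiter, "xatol": 1e-3, "fatol": 1e-8},
            )
            converged = converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if not converged:
            quality = "max_iter"
        lpar = np.clip(best.x[0::2], lo_par, hi_par)
        lperp = np.minimum(np.clip(best.x[1::2], lo_perp, hi_perp), lpar)
        coef, resid = _inner_nnls(y, scheme, orientations, lpar, lperp, config)

    mass = coef[n_fib:]
    params = DbsiModelParams(
        orientations=np.array(orientations).reshape(n_fib, 3),
        lambda_par=lpar,
        lambda_perp=lperp,
        fractions=coef[:n_fib],
        iso_spectrum=mass / grid.weights,
        grid=grid,
    )
    total = params.total_fraction
    if total <= 0:
        metrics = DbsiMetrics(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, quality="empty_fit")
        return params, metrics
    params = params.normalized()

    r_frac, h_frac, f_frac = spectrum_fractions(params.iso_spectrum, grid)
    fib = float(np.sum(params.fractions))
    if fib > 0:
        wts = params.fractions / fib
        ad = float(np.dot(wts, params.lambda_par))
        rd = float(np.dot(wts, params.lambda_perp))
        fa = float(np.dot(wts, [fiber_fa(p, q) for p, q in zip(params.lambda_par, params.lambda_perp)]))
    else:
        ad = rd = fa = 0.0
    metrics = DbsiMetrics(
        fiber_fraction=fib,
        restricted_fraction=r_frac,
        hindered_fraction=h_frac,
        water_fraction=f_frac,
        fiber_fa=fa,
        fiber_ad=ad,
        fiber_rd=rd,
        quality=quality,
    )
    return params, metrics
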