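"""Phase-field model of chromatin organization under mechano-osmotic load.

Chromatin is a composition field c on a disk-shaped nuclear domain, with
euchromatin and heterochromatin as the two wells of a double-well free
energy.  The model couples four ingredients:

  (i)  chromatin-chromatin interaction energetics driving phase
       separation: bulk free energy f(c) = w (c - c_eu)^2 (c - c_het)^2
       plus a gradient penalty (kappa_g / 2) |grad c|^2;
  (ii) chromatin-lamina interaction: a boundary wetting energy
       -gamma_L * c on the rim favouring heterochromatin at the lamina
       (lamina-associated domains), imposed through the natural boundary
       condition kappa_g dc/dn = gamma_L;
  (iii) conserved diffusive transport, dc/dt = div(M grad mu) with
       chemical potential mu = f'(c) - kappa_g lap(c) (Cahn-Hilliard);
  (iv) nonconserved first-order interconversion of the two forms
       (methylation/acetylation), -Gamma * mu, first-order in the
       thermodynamic driving force (Cahn-Hilliard-Oono).

Mechano-osmotic compression by lipid droplets expels water from the
nucleoplasm; chromatin amount is conserved while nucleoplasm volume
drops by the factor lambda, so the composition concentrates:
instantaneously (c -> c * lambda) or kinetically through a rim water
flux relaxing the mean composition toward lambda * c_bar0.

Units are dimensionless-calibrated: lengths in um, energy density in
units of the well height scale, time in units of um^2/(M x energy).

The default integrator is a linearly stabilized semi-implicit scheme:
the stiff fourth-order term and a stabilization split a*(c^{n+1}-c^n)
are implicit (one cached sparse LU factorization), the well force is
explicit.  It conserves total composition to solver precision when
Gamma = 0 and is energy-stable for a >= max|f''|/2 along the
trajectory; the practical accuracy bound dt <~ 10 / sigma_max (inverse
fastest spinodal growth rate) is far above the explicit-Euler bound
dt <= dx^4 / (M (16 kappa_g + 4 max f'' dx^2)), which the optional
explicit integrator (used as an independent cross-check) must respect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu

__all__ = [
    "PhaseFieldParams",
    "PhaseFieldState",
    "DomainStats",
    "initialize",
    "chemical_potential",
    "free_energy",
    "step",
    "apply_compression",
    "kinetic_compression_step",
    "run_to_steady",
    "domain_stats",
    "compression_sweep",
]


@dataclass(frozen=True)
class PhaseFieldParams:
    """Model and solver parameters (see module docstring for the model).

    The defaults put the uniform state c_bar0 = 0.45 inside the spinodal
    (f'' < 0 on (0.418, 0.582) for the default wells) with a fastest
    unstable wavelength of ~2 um in a 7 um nucleus.
    """

    grid_n: int = 128
    nucleus_radius: float = 7.0          # um
    c_eu: float = 0.3
    c_het: float = 0.7
    well_height: float = 20.0            # w, energy density scale
    gradient_coeff: float = 0.08         # kappa_g, energy * um^2
    mobility: float = 1.0                # M
    reaction_rate: float = 0.0           # Gamma, 1/(energy * time)
    lamina_affinity: float = 0.0         # gamma_L, energy/um
    c_bar0: float = 0.45
    noise_amp: float = 0.02
    compression: float = 1.0             # lambda = V0/V >= 1
    water_permeability: float = 1.0      # k_w * delta_mu_w, kinetic mode rate
    dt: float = 5.0e-3
    n_steps: int = 20000
    seed: int = 0
    scheme: str = "semi-implicit"        # or "explicit"
    stabilization: float | None = None   # a; default max|f''| on [c_eu-.1, c_het+.1]

    def __post_init__(self) -> None:
        if self.c_eu >= self.c_het:
            raise ValueError("c_eu must be below c_het")
        if self.compression < 1.0:
            raise ValueError("compression lambda must be >= 1")
        if self.grid_n < 16:
            raise ValueError("grid too small")
        if self.dt <= 0 or self.n_steps < 0:
            raise ValueError("dt must be positive, n_steps non-negative")
        if self.scheme not in ("semi-implicit", "explicit"):
            raise ValueError("scheme must be 'semi-implicit' or 'explicit'")
        if self.scheme == "explicit" and self.dt > self.explicit_dt_bound():
            raise ValueError(
                f"dt={self.dt:g} violates the explicit stability bound "
                f"{self.explicit_dt_bound():g} (dx^4 scaling)")

    @property
    def dx(self) -> float:
        return 2.1 * self.nucleus_radius / self.grid_n

    def fprime(self, c):
        a, b, w = self.c_eu, self.c_het, self.well_height
        return 2.0 * w * (c - a) * (c - b) * (2.0 * c - a - b)

    def fsecond(self, c):
        a, b, w = self.c_eu, self.c_het, self.well_height
        return 2.0 * w * ((c - a) ** 2 + 4.0 * (c - a) * (c - b) + (c - b) ** 2)

    def fwell(self, c):
        a, b, w = self.c_eu, self.c_het, self.well_height
        return w * (c - a) ** 2 * (c - b) ** 2

    def spinodal_unstable(self, c: float) -> bool:
        """True when a uniform state at composition c is linearly unstable."""
        return bool(self.fsecond(c) < 0)

    def explicit_dt_bound(self) -> float:
        cs = np.linspace(self.c_eu - 0.1, self.c_het + 0.1, 256)
        fpp = float(np.max(np.abs(self.fsecond(cs))))
        dx = self.dx
        return dx**4 / (self.mobility * (16.0 * self.gradient_coeff
                                         + 4.0 * fpp * dx**2))

    def default_stabilization(self) -> float:
        cs = np.linspace(self.c_eu - 0.1, self.c_het + 0.1, 256)
        return float(np.max(np.abs(self.fsecond(cs))))


@dataclass
class PhaseFieldState:
    c: np.ndarray            # 2D composition field (NaN-free inside mask)
    mask: np.ndarray         # disk domain
    t: float
    free_energy: float
    total_mass: float        # composition integral x current volume factor
    volume_scale: float = 1.0
    steps: int = 0
    converged_by: str | None = None


class _Lattice:
    """Masked five-point Laplacian with natural (reflecting) boundaries,
    plus the cached LU factorization for the semi-implicit update."""

    def __init__(self, params: PhaseFieldParams):
        n = params.grid_n
        dx = params.dx
        yy, xx = np.mgrid[0:n, 0:n]
        cx = (n - 1) / 2.0
        rad = params.nucleus_radius / dx
        self.mask = (xx - cx) ** 2 + (yy - cx) ** 2 <= rad**2
        self.dx = dx
        idx = -np.ones((n, n), dtype=int)
        cells = np.nonzero(self.mask)
        idx[cells] = np.arange(len(cells[0]))
        self.n_cells = len(cells[0])
        rows, cols, vals = [], [], []
        deg = np.zeros(self.n_cells)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = np.full((n, n), -1, dtype=int)
            src_r = slice(max(0, -dr), n - max(0, dr))
            src_c = slice(max(0, -dc), n - max(0, dc))
            dst_r = slice(max(0, dr), n + min(0, dr))
            dst_c = slice(max(0, dc), n + min(0, dc))
            nb[dst_r, dst_c] = idx[src_r, src_c]
            ok = self.mask & (nb >= 0)
            i = idx[ok]
            j = nb[ok]
            rows.append(i)
            cols.append(j)
            vals.append(np.full(len(i), 1.0 / dx**2))
            np.add.at(deg, i, 1.0)
        rows = np.concatenate(rows + [np.arange(self.n_cells)])
        cols = np.concatenate(cols + [np.arange(self.n_cells)])
        vals = np.concatenate(vals + [-deg / dx**2])
        self.L = sparse.csr_matrix((vals, (rows, cols)),
                                   shape=(self.n_cells, self.n_cells))
        self.missing = (4.0 - deg)  # rim faces without a neighbour
        self.idx = idx
        self._lu = None
        self._lu_key = None

    def lu(self, params: PhaseFieldParams):
        a = (params.stabilization if params.stabilization is not None
             else params.default_stabilization())
        key = (params.dt, params.mobility, params.gradient_coeff, a)
        if self._lu_key != key:
            dtM = params.dt * params.mobility
            A = (sparse.identity(self.n_cells, format="csr")
                 + dtM * (params.gradient_coeff * (self.L @ self.L)
                          - a * self.L))
            self._lu = splu(A.tocsc())
            self._lu_key = key
        return self._lu, a

    def to_grid(self, v: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill)
        out[self.mask] = v
        return out

    def to_vec(self, grid: np.ndarray) -> np.ndarray:
        return grid[self.mask]


@lru_cache(maxsize=8)
def _lattice(grid_n: int, nucleus_radius: float) -> _Lattice:
    return _Lattice(PhaseFieldParams(grid_n=grid_n, nucleus_radius=nucleus_radius))


def _lamina_mu(lat: _Lattice, params: PhaseFieldParams) -> np.ndarray:
    # natural BC kappa_g dc/dn = gamma_L enters mu as -gamma_L/dx per rim face
    return -params.lamina_affinity * lat.missing / lat.dx


def initialize(params: PhaseFieldParams) -> PhaseFieldState:
    """Near-uniform seeded start: c = c_bar0 + U(-noise_amp, noise_amp)."""
    lat = _lattice(params.grid_n, params.nucleus_radius)
    rng = np.random.default_rng(params.seed)
    c = params.c_bar0 + params.noise_amp * rng.uniform(-1, 1, lat.n_cells)
    state = PhaseFieldState(c=lat.to_grid(c), mask=lat.mask, t=0.0,
                            free_energy=0.0, total_mass=0.0)
    state.free_energy = free_energy(state, params)
    state.total_mass = _mass(state, lat)
    return state


def _mass(state: PhaseFieldState, lat: _Lattice) -> float:
    return float(np.sum(state.c[state.mask]) * lat.dx**2 * state.volume_scale)


def chemical_potential(state: PhaseFieldState,
                       params: PhaseFieldParams) -> np.ndarray:
    """mu = f'(c) - kappa_g lap(c) with the lamina wetting boundary term,
    on the masked disk (NaN outside)."""
    lat = _lattice(params.grid_n, params.nucleus_radius)
    c = lat.to_vec(state.c)
    mu = params.fprime(c) - params.gradient_coeff * (lat.L @ c) + _lamina_mu(lat, params)
    return lat.to_grid(mu)


def free_energy(state: PhaseFieldState, params: PhaseFieldParams) -> float:
    """Discrete free energy: bulk wells + gradient penalty - lamina wetting."""
    lat = _lattice(params.grid_n, params.nucleus_radius)
    c = lat.to_vec(state.c)
    bulk = np.sum(params.fwell(c)) * lat.dx**2
    grad = -0.5 * params.gradient_coeff * float(c @ (lat.L @ c)) * lat.dx**2
    wet = -params.lamina_affinity * lat.dx * float(np.sum(lat.missing * c))
    return float(bulk + grad + wet)


def step(state: PhaseFieldState, params: PhaseFieldParams) -> PhaseFieldState:
    """Advance one time step of dc/dt = div(M grad mu) - Gamma mu."""
    lat = _lattice(params.grid_n, params.nucleus_radius)
    c = lat.to_vec(state.c)
    b_lam = _lamina_mu(lat, params)
    if params.scheme == "explicit":
        mu = params.fprime(c) - params.gradient_coeff * (lat.L @ c) + b_lam
        c_new = c + params.dt * (params.mobility * (lat.L @ mu)
                                 - params.reaction_rate * mu)
    else:
        lu, a = lat.lu(params)
        mu_expl = params.fprime(c) - params.gradient_coeff * (lat.L @ c) + b_lam
        rhs = (c + params.dt * params.mobility
               * (lat.L @ (params.fprime(c) - a * c + b_lam))
               - params.dt * params.reaction_rate * mu_expl)
        c_new = lu.solve(rhs)
    if not np.all(np.isfinite(c_new)):
        raise FloatingPointError(
            "phase-field update produced non-finite values; the time step "
            f"violates the stability bound for scheme={params.scheme!r} "
            f"(explicit bound {params.explicit_dt_bound():g})")
    new = PhaseFieldState(c=lat.to_grid(c_new), mask=state.mask,
                          t=state.t + params.dt, free_energy=0.0,
                          total_mass=0.0, volume_scale=state.volume_scale,
                          steps=state.steps + 1,
                          converged_by=state.converged_by)
    new.free_energy = free_energy(new, params)
    new.total_mass = _mass(new, lat)
    return new


def apply_compression(state: PhaseFieldState,
                      params: PhaseFieldParams) -> PhaseFieldState:
    """Instantaneous mechano-osmotic compression: water leaves, chromatin
    stays, so c -> clip(c * lambda, 0, 1) once and the volume bookkeeping
    shrinks by the same factor (total chromatin conserved)."""
    lam = params.compression
    if lam < 1.0:
        raise ValueError("compression lambda must be >= 1")
    lat = _lattice(params.grid_n, params.nucleus_radius)
    c = np.clip(lat.to_vec(state.c) * lam, 0.0, 1.0)
    new = PhaseFieldState(c=lat.to_grid(c), mask=state.mask, t=state.t,
                          free_energy=0.0, total_mass=0.0,
                          volume_scale=state.volume_scale / lam,
                          steps=state.steps, converged_by=state.converged_by)
    new.free_energy = free_energy(new, params)
    new.total_mass = _mass(new, lat)
    return new


def kinetic_compression_step(state: PhaseFieldState,
                             params: PhaseFieldParams) -> PhaseFieldState:
    """One step of the rim water-efflux mode: the mean composition relaxes
    toward lambda * c_bar0 at rate water_permeability (= k_w * delta_mu_w),
    i.e. d c_bar / dt = k_w dmu_w (lambda c_bar0 - c_bar), while the
    spatial pattern of c is preserved and chromatin amount is conserved
    through the volume bookkeeping."""
    lam = params.compression
    target = lam * params.c_bar0
    lat = _lattice(params.grid_n, params.nucleus_radius)
    c = lat.to_vec(state.c)
    cbar = float(c.mean())
    dcbar = params.water_permeability * (target - cbar) * params.dt
    factor = (cbar + dcbar) / cbar
    c = np.clip(c * factor, 0.0, 1.0)
    new = PhaseFieldState(c=lat.to_grid(c), mask=state.mask,
                          t=state.t + params.dt, free_energy=0.0,
                          total_mass=0.0,
                          volume_scale=state.volume_scale / factor,
                          steps=state.steps, converged_by=state.converged_by)
    new.free_energy = free_energy(new, params)
    new.total_mass = _mass(new, lat)
    return new


def run_to_steady(params: PhaseFieldParams,
                  f_tol: float = 1.0e-6,
                  window: int = 500,
                  compression_mode: str = "instant") -> PhaseFieldState:
    """Initialize, apply compression, and step until the free energy is
    stationary (|delta F| over a ``window``-step interval < f_tol |F|) or
    ``n_steps`` is exhausted; ``converged_by`` records which fired."""
    state = initialize(params)
    if params.compression > 1.0 and compression_mode == "instant":
        state = apply_compression(state, params)
    f_prev = state.free_energy
    kinetic = params.compression > 1.0 and compression_mode == "kinetic"
    for k in range(params.n_steps):
        if kinetic:
            state = kinetic_compression_step(state, params)
        state = step(state, params)
        if (k + 1) % window == 0:
            if (abs(state.free_energy - f_prev)
                    <= f_tol * (abs(state.free_energy) + 1e-9)):
                state.converged_by = "free_energy"
                return state
            f_prev = state.free_energy
    state.converged_by = "n_steps"
    return state


@dataclass(frozen=True)
class DomainStats:
    n_domains: int
    mean_domain_area: float   # um^2
    het_area_fraction: float


def domain_stats(state: PhaseFieldState,
                 params: PhaseFieldParams,
                 threshold: float | None = None,
                 min_px: int = 4) -> DomainStats:
    """Heterochromatin domains: connected components of {c > threshold}
    inside the disk, speckles below ``min_px`` pixels discarded."""
    if threshold is None:
        threshold = 0.5 * (params.c_eu + params.c_het)
    lat = _lattice(params.grid_n, params.nucleus_radius)
    het = (state.c > threshold) & state.mask
    labels, n = ndimage.label(het)
    if n == 0:
        return DomainStats(0, 0.0, 0.0)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    sizes = sizes[sizes >= min_px]
    area_px = lat.dx**2
    n_dom = len(sizes)
    mean_area = float(np.mean(sizes) * area_px) if n_dom else 0.0
    het_frac = float(het.sum() / state.mask.sum())
    return DomainStats(n_dom, mean_area, het_frac)


def compression_sweep(params: PhaseFieldParams,
                      lambdas=(1.0, 1.1, 1.2),
                      n_seeds: int = 5,
                      compression_mode: str = "instant") -> pd.DataFrame:
    """Steady-state heterochromatin statistics across compression levels.

    Runs ``run_to_steady`` for every (lambda, seed), seeds derived as
    params.seed + i.  Returns a tidy frame with one row per run plus the
    per-lambda aggregate columns the figure-level comparison needs.
    """
    lambdas = list(lambdas)
    if lambdas != sorted(lambdas):
        raise ValueError("lambda list must be sorted ascending")
    rows = []
    for lam in lambdas:
        for i in range(n_seeds):
            p = replace(params, compression=lam, seed=params.seed + i)
            try:
                st = run_to_steady(p, compression_mode=compression_mode)
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"solver failure at lambda={lam}, seed={p.seed}: {err}"
                ) from err
            ds = domain_stats(st, p)
            rows.append(dict(lam=lam, seed=p.seed, n_domains=ds.n_domains,
                             mean_domain_area_um2=ds.mean_domain_area,
                             het_area_fraction=ds.het_area_fraction,
                             steps_to_steady=st.steps,
                             converged_by=st.converged_by))
    df = pd.DataFrame(rows)
    agg = (df.groupby("lam", as_index=False)
             .agg(mean_domain_area_um2=("mean_domain_area_um2", "mean"),
                  het_area_fraction=("het_area_fraction", "mean")))
    return df.merge(agg, on="lam", suffixes=("", "_mean"))
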