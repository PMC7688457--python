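"""Quasi-static potential solver on the voxel grid.

Solves the conduction equation ``div(sigma grad V) = 0`` with a 7-point
finite-volume stencil: inter-voxel face conductances use the harmonic mean
of the two voxel conductivities scaled by face area over center distance,
which preserves flux continuity across the large conductivity jumps between
tissue compartments (skull/scalp span two orders of magnitude; mucosa and
internal air several more).  Source electrode faces contribute fixed-flux
terms; ground faces pin their owning voxels to V = 0 by Dirichlet
elimination; all other exterior faces are insulated (natural Neumann).

The resulting system is symmetric positive definite and is solved with
conjugate gradients preconditioned by a smoothed-aggregation multigrid
V-cycle (2x2x2 voxel aggregates, Jacobi-smoothed prolongation, Galerkin
coarse operators, damped-Jacobi smoothing), which keeps iteration counts
nearly grid-independent.

The quasi-static approximation itself is justified by the pulse-spectrum
helpers: a rectangular stimulation pulse of duration T has its spectral
power concentrated below the first zero crossing 1/T, and at the analysis
frequency the reactive ratio ``omega * epsilon / sigma`` of head tissues is
much smaller than one, so the complex term of the full equation
``div((sigma + j omega epsilon) grad V) = 0`` is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from . import units
from .errors import (
    ConvergenceError,
    FloatingDomainError,
    InvalidParameterError,
    SingularSystemError,
    StateError,
)
from .montage import BoundaryConditions

_FACE_OFFSETS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]], int
)


def harmonic_mean_conductivity(sigma_a, sigma_b):
    """Harmonic mean 2*sa*sb/(sa+sb) used for inter-voxel face conductances."""
    sigma_a = np.asarray(sigma_a, float)
    sigma_b = np.asarray(sigma_b, float)
    return 2.0 * sigma_a * sigma_b / (sigma_a + sigma_b)


@dataclass
class LinearSystem:
    """Assembled finite-volume system for one montage on one phantom."""

    A: sparse.csr_matrix
    b: np.ndarray
    unknown_ijk: np.ndarray  # (N, 3) voxel indices of unknowns
    flat_to_unknown: np.ndarray  # grid-sized flat array, -1 where not unknown
    pinned_flat: np.ndarray  # flat indices of ground-pinned voxels
    shape: tuple
    spacing: float
    bc: BoundaryConditions
    sigma: np.ndarray
    excluded_flat: np.ndarray  # unknown-free floating voxels (V undefined)


@dataclass
class PotentialField:
    """Scalar potential on the conductive voxels (volts)."""

    values: np.ndarray  # full grid, NaN outside solved domain
    mask: np.ndarray  # solved voxels
    spacing: float
    iterations: int
    relative_residual: float
    system: LinearSystem | None = None

    @property
    def report(self) -> dict:
        return {
            "iterations": self.iterations,
            "relative_residual": self.relative_residual,
            "unknowns": int(self.mask.sum()),
        }


@dataclass
class EFField:
    """Electric field vectors and magnitude in V/m on the phantom grid."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    magnitude: np.ndarray
    mask: np.ndarray
    spacing: float


@dataclass
class PulseSpec:
    """Rectangular stimulation pulse: duration in ms, amplitude in mA."""

    duration_ms: float
    amplitude_ma: float = 1.0
    #: representative (sigma S/m, epsilon F/m) pairs for the reactive check
    tissue_properties: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.duration_ms > 0:
            raise InvalidParameterError(f"pulse duration must be > 0, got {self.duration_ms}")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _homogenized_face_sigma(sampler, coords, axis, spacing, kf, ks):
    """Effective face conductivity by sub-face homogenization.

    For each face between a voxel center and its +axis neighbor, the
    connecting segment is split into ``kf`` x ``kf`` parallel sub-segments
    across the face; each sub-segment conductance is the harmonic mean of
    ``ks`` conductivity samples along it (series composition normal to the
    face), and sub-segments combine arithmetically (parallel composition
    across the face).
    """
    bax, cax = (a for a in range(3) if a != axis)
    eb = np.zeros(3)
    eb[bax] = spacing
    ec = np.zeros(3)
    ec[cax] = spacing
    ea = np.zeros(3)
    ea[axis] = spacing
    offs = (np.arange(kf) + 0.5) / kf - 0.5
    segs = (np.arange(ks) + 0.5) / ks
    gsum = np.zeros(len(coords))
    for ob in offs:
        for oc in offs:
            base = coords + ob * eb + oc * ec
            acc = np.zeros(len(coords))
            for t in segs:
                acc += 1.0 / sampler(base + t * ea)
            gsum += ks / acc
    return gsum / (kf * kf)


def assemble_system(sigma: np.ndarray, bc: BoundaryConditions, spacing: float,
                    sigma_sampler=None, sampler_mask: np.ndarray | None = None,
                    origin: np.ndarray | None = None,
                    subface_divisions: int = 4, segment_samples: int = 8) -> LinearSystem:
    """Assemble the finite-volume system for ``div(sigma grad V) = 0``.

    ``sigma`` is the conductivity volume in S/m with NaN marking voxels
    outside the computational domain; all in-domain values must be strictly
    positive.  ``spacing`` is the voxel edge in mm.

    When the underlying geometry has an analytic description,
    ``sigma_sampler`` (a callable mapping (M, 3) physical mm points to
    conductivities) enables sub-voxel homogenized face conductances: each
    face is subdivided ``subface_divisions`` x ``subface_divisions`` times
    and the series (harmonic) conductance along ``segment_samples`` points
    of each center-to-center sub-segment is averaged arithmetically across
    the face.  This captures interface positions below the voxel scale and
    is used by the layered-sphere validation.  ``sampler_mask`` restricts
    the treatment to voxels where the analytic description applies (e.g.
    excluding stamped electrode and gel voxels); ``origin`` is the physical
    coordinate of voxel (0,0,0), required with ``sigma_sampler``.
    """
    sigma = np.asarray(sigma, float)
    domain = ~np.isnan(sigma)
    if not domain.any():
        raise InvalidParameterError("conductivity volume has no in-domain voxels")
    if np.any(sigma[domain] <= 0):
        raise InvalidParameterError("conductivity must be strictly positive on the domain")

    ground = bc.ground_faces
    if len(ground) == 0:
        raise SingularSystemError("boundary conditions define no ground face")
    shape = sigma.shape
    h = units.mm_to_m(spacing)

    flat = lambda ijk: np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), shape)
    pinned_flat = np.unique(flat(ground[:, :3]))
    pinned_mask = np.zeros(shape, bool)
    pinned_mask.flat[pinned_flat] = True
    if not domain.flat[pinned_flat].all():
        raise InvalidParameterError("ground faces reference voxels outside the domain")

    unknown_mask = domain & ~pinned_mask
    flat_to_unknown = -np.ones(int(np.prod(shape)), dtype=np.int64)
    unknown_flat = np.flatnonzero(unknown_mask.ravel())
    flat_to_unknown[unknown_flat] = np.arange(len(unknown_flat))
    n_unknown = len(unknown_flat)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_unknown)
    b = np.zeros(n_unknown)

    sig_flat = sigma.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)

    for axis in range(3):
        # pairs (p, q=p+1 along axis) with both voxels in the domain
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, shape[axis] - 1)
        sl_hi[axis] = slice(1, shape[axis])
        both = domain[tuple(sl_lo)] & domain[tuple(sl_hi)]
        p = np.flatnonzero(np.pad(both, [(0, 1) if a == axis else (0, 0) for a in range(3)]).ravel())
        q = p + strides[axis]
        g = harmonic_mean_conductivity(sig_flat[p], sig_flat[q]) * h  # S

        if sigma_sampler is not None:
            if origin is None:
                raise InvalidParameterError("origin is required with sigma_sampler")
            if sampler_mask is None:
                eligible = np.ones(len(p), bool)
            else:
                sm = sampler_mask.ravel()
                eligible = sm[p] & sm[q]
            if eligible.any():
                pi = np.stack(np.unravel_index(p[eligible], shape), axis=1)
                coords = np.asarray(origin, float) + spacing * pi
                sig_face = _homogenized_face_sigma(
                    sigma_sampler, coords, axis, spacing,
                    subface_divisions, segment_samples,
                )
                g[eligible] = sig_face * h

        up = flat_to_unknown[p]
        uq = flat_to_unknown[q]
        both_unknown = (up >= 0) & (uq >= 0)
        rows.append(up[both_unknown]); cols.append(uq[both_unknown]); vals.append(-g[both_unknown])
        rows.append(uq[both_unknown]); cols.append(up[both_unknown]); vals.append(-g[both_unknown])
        np.add.at(diag, up[up >= 0], g[up >= 0])
        np.add.at(diag, uq[uq >= 0], g[uq >= 0])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sparse.coo_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(n_unknown)]),
          np.concatenate([cols, np.arange(n_unknown)]))),
        shape=(n_unknown, n_unknown),
    ).tocsr()

    # source flux terms
    src = bc.source_faces
    if len(src):
        owners = flat(src[:, :3])
        u = flat_to_unknown[owners]
        if np.any(u < 0):
            raise InvalidParameterError("source faces reference pinned or exterior voxels")
        np.add.at(b, u, bc.jn_a_per_m2 * bc.face_area_m2)

    # connectivity: every source component must reach a ground-adjacent voxel
    n_comp, comp = csgraph.connected_components(A, directed=False)
    ground_adjacent = np.zeros(n_unknown, bool)
    # unknowns neighboring a pinned voxel received a diagonal contribution from it
    for axis in range(3):
        for sgn in (-1, 1):
            nb = pinned_flat + sgn * strides[axis]
            ok = (nb >= 0) & (nb < len(flat_to_unknown))
            # guard row wrap-around
            pi = np.stack(np.unravel_index(pinned_flat[ok], shape), axis=1)
            nbi = pi.copy()
            nbi[:, axis] += sgn
            valid = (nbi[:, axis] >= 0) & (nbi[:, axis] < shape[axis])
            nf = nb[ok][valid]
            uu = flat_to_unknown[nf]
            ground_adjacent[uu[uu >= 0]] = True
    grounded_comps = np.unique(comp[ground_adjacent])
    grounded = np.isin(comp, grounded_comps)
    if len(src):
        src_u = flat_to_unknown[flat(src[:, :3])]
        if not grounded[src_u].all():
            raise FloatingDomainError(
                "a source electrode lies on a conductive component with no path to ground"
            )
    excluded = unknown_flat[~grounded]
    if len(excluded):
        keep = np.flatnonzero(grounded)
        A = A[keep][:, keep].tocsr()
        b = b[keep]
        flat_to_unknown = -np.ones_like(flat_to_unknown)
        flat_to_unknown[unknown_flat[grounded]] = np.arange(len(keep))
        unknown_flat = unknown_flat[grounded]

    unknown_ijk = np.stack(np.unravel_index(unknown_flat, shape), axis=1)
    return LinearSystem(
        A=A, b=b, unknown_ijk=unknown_ijk,
        flat_to_unknown=flat_to_unknown, pinned_flat=pinned_flat,
        shape=shape, spacing=spacing, bc=bc, sigma=sigma, excluded_flat=excluded,
    )


# ---------------------------------------------------------------------------
# Multigrid-preconditioned CG
# ---------------------------------------------------------------------------

class _MGPreconditioner:
    """Smoothed-aggregation multigrid V-cycle used as an SPD preconditioner.

    Unknowns are aggregated geometrically by 2x2x2 voxel blocks; the
    piecewise-constant prolongator is smoothed by one damped-Jacobi step,
    and coarse operators are Galerkin products.  Two damped-Jacobi sweeps
    smooth on each level; the coarsest level is solved directly.  Operates
    on the diagonally scaled (unit-diagonal) system.
    """

    def __init__(self, A, ijk, max_coarse=2000, omega=0.7, omega_p=1.0, sweeps=2):
        self.omega = omega
        self.sweeps = sweeps
        self.levels = []
        level_A, level_ijk = A, ijk
        while level_A.shape[0] > max_coarse and len(self.levels) < 12:
            coarse_ijk_all = level_ijk // 2
            coarse_shape = tuple(coarse_ijk_all.max(axis=0) + 1)
            uniq, inv = np.unique(
                np.ravel_multi_index(
                    (coarse_ijk_all[:, 0], coarse_ijk_all[:, 1], coarse_ijk_all[:, 2]),
                    coarse_shape,
                ),
                return_inverse=True,
            )
            nc = len(uniq)
            if nc >= level_A.shape[0]:
                break
            P = sparse.csr_matrix(
                (np.ones(level_A.shape[0]), (np.arange(level_A.shape[0]), inv)),
                shape=(level_A.shape[0], nc),
            )
            invdiag = 1.0 / level_A.diagonal()
            Dinv = sparse.diags(invdiag)
            P = (P - omega_p * (Dinv @ (level_A @ P))).tocsr()
            self.levels.append({"A": level_A, "P": P, "invdiag": invdiag})
            level_A = (P.T @ (level_A @ P)).tocsr()
            level_ijk = np.stack(np.unravel_index(uniq, coarse_shape), axis=1)
        self.coarse_lu = splu(sparse.csc_matrix(level_A))

    def _vcycle(self, lvl, b):
        if lvl == len(self.levels):
            return self.coarse_lu.solve(b)
        L = self.levels[lvl]
        x = self.omega * L["invdiag"] * b
        for _ in range(self.sweeps - 1):
            x = x + self.omega * L["invdiag"] * (b - L["A"] @ x)
        r = b - L["A"] @ x
        x = x + L["P"] @ self._vcycle(lvl + 1, L["P"].T @ r)
        for _ in range(self.sweeps):
            x = x + self.omega * L["invdiag"] * (b - L["A"] @ x)
        return x

    def __call__(self, b):
        return self._vcycle(0, b)


def _pcg(A, b, M, rtol, maxiter):
    """Preconditioned conjugate gradients with recursive residual tracking.

    Returns ``(x, iterations, final_relative_residual, residual_history)``;
    the residual is the PCG-updated residual norm relative to ||b||, the
    standard convergence measure reported by iterative field solvers.
    """
    bnorm = np.linalg.norm(b)
    x = np.zeros_like(b)
    r = b.copy()
    z = M(r) if M is not None else r.copy()
    p = z.copy()
    rz = float(r @ z)
    history = []
    for k in range(maxiter):
        Ap = A @ p
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        rel = float(np.linalg.norm(r) / bnorm)
        history.append(rel)
        if rel <= rtol:
            return x, k + 1, rel, history
        z = M(r) if M is not None else r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, maxiter, history[-1] if history else np.inf, history


def solve_potential(system: LinearSystem, rel_tol: float = 1e-8,
                    max_iter: int | None = None, preconditioner: str = "auto") -> PotentialField:
    """Solve the assembled system to a relative residual <= ``rel_tol``.

    The residual is measured on the symmetrically diagonal-scaled system
    (unit diagonal): with conductivities spanning twelve orders of magnitude
    between electrode metal and internal air, the unscaled residual has a
    float64 cancellation floor, while the scaled residual is the natural
    row-balanced convergence measure.  Deterministic given fixed inputs and
    tolerance.  Raises :class:`ConvergenceError` (carrying the residual
    history) if the iteration cap is exceeded.
    """
    A, b = system.A, system.b
    n = A.shape[0]
    if max_iter is None:
        max_iter = max(200, int(50 * round(n ** (1.0 / 3.0))))

    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        x = np.zeros(n)
        iters, rel = 0, 0.0
    else:
        # symmetric Jacobi scaling: As = D^-1/2 A D^-1/2 has unit diagonal
        dhalf = np.sqrt(A.diagonal())
        inv_dhalf = 1.0 / dhalf
        Dinv = sparse.diags(inv_dhalf)
        As = (Dinv @ A @ Dinv).tocsr()
        bs = inv_dhalf * b
        bs_norm = np.linalg.norm(bs)

        if preconditioner == "jacobi" or (preconditioner == "auto" and n < 20000):
            M = None  # As already has unit diagonal
        elif preconditioner in ("auto", "mg"):
            M = _MGPreconditioner(As, system.unknown_ijk)
        else:
            raise InvalidParameterError(f"unknown preconditioner {preconditioner!r}")

        y, iters, rel, residuals = _pcg(As, bs, M, rel_tol, max_iter)
        if not np.isfinite(rel) or rel > rel_tol:
            raise ConvergenceError(
                f"CG failed to reach {rel_tol:g} in {max_iter} iterations "
                f"(final relative residual {rel:.3e})",
                residuals=residuals,
            )
        x = inv_dhalf * y

    values = np.full(system.shape, np.nan)
    values[system.unknown_ijk[:, 0], system.unknown_ijk[:, 1], system.unknown_ijk[:, 2]] = x
    values.flat[system.pinned_flat] = 0.0
    mask = ~np.isnan(values)
    return PotentialField(
        values=values, mask=mask, spacing=system.spacing,
        iterations=iters, relative_residual=rel, system=system,
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def electric_field(potential: PotentialField, spacing: float | None = None) -> EFField:
    """E = -grad V in V/m: central differences in the interior, one-sided at
    the domain boundary, with the mm -> m conversion applied."""
    if potential is None or not isinstance(potential, PotentialField):
        raise StateError("electric_field requires a solved PotentialField")
    V = potential.values
    mask = potential.mask
    h = units.mm_to_m(spacing if spacing is not None else potential.spacing)
    vecs = np.zeros(V.shape + (3,))

    for axis in range(3):
        fwd = np.full_like(V, np.nan)
        bwd = np.full_like(V, np.nan)
        sl_all = [slice(None)] * 3
        sl_src = [slice(None)] * 3
        sl_all[axis] = slice(0, V.shape[axis] - 1)
        sl_src[axis] = slice(1, V.shape[axis])
        fwd[tuple(sl_all)] = V[tuple(sl_src)]
        bwd[tuple(sl_src)] = V[tuple(sl_all)]
        has_f = ~np.isnan(fwd)
        has_b = ~np.isnan(bwd)
        dV = np.zeros_like(V)
        central = has_f & has_b
        dV[central] = (fwd[central] - bwd[central]) / (2 * h)
        only_f = has_f & ~has_b
        dV[only_f] = (fwd[only_f] - V[only_f]) / h
        only_b = has_b & ~has_f
        dV[only_b] = (V[only_b] - bwd[only_b]) / h
        vecs[..., axis] = np.where(mask, -dV, 0.0)

    vecs[~mask] = 0.0
    mag = np.linalg.norm(vecs, axis=-1)
    return EFField(vectors=vecs, magnitude=mag, mask=mask, spacing=potential.spacing)


def net_electrode_currents(potential: PotentialField) -> dict[str, float]:
    """Per-electrode net currents in mA, recovered from the solved field.

    For every electrode the current is the discrete flux integral of the
    solved potential over the faces between that electrode's conductor
    voxels and the surrounding domain (sources positive: current leaves the
    conductor into the head; grounds negative).  Sources sum to +total
    current and grounds to -total current within the solver tolerance.
    """
    if potential.system is None:
        raise StateError("potential carries no assembled system")
    system = potential.system
    bc = system.bc
    V = potential.values
    h = units.mm_to_m(system.spacing)
    sigma = system.sigma
    shape = np.array(system.shape)
    out = {}

    for ef in bc.electrodes:
        member = np.zeros(system.shape, bool)
        member[ef.voxels[:, 0], ef.voxels[:, 1], ef.voxels[:, 2]] = True
        v_own_all = V[ef.voxels[:, 0], ef.voxels[:, 1], ef.voxels[:, 2]]
        v_own_all = np.where(np.isnan(v_own_all), 0.0, v_own_all)  # pinned grounds
        total = 0.0
        for off in _FACE_OFFSETS:
            nb = ef.voxels + off
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            nbo = nb[ok]
            vn = V[nbo[:, 0], nbo[:, 1], nbo[:, 2]]
            outside = ~member[nbo[:, 0], nbo[:, 1], nbo[:, 2]]
            good = outside & ~np.isnan(vn)
            if not good.any():
                continue
            own = ef.voxels[ok][good]
            v_own = V[own[:, 0], own[:, 1], own[:, 2]]
            v_own = np.where(np.isnan(v_own), 0.0, v_own)
            s_own = sigma[own[:, 0], own[:, 1], own[:, 2]]
            s_nb = sigma[nbo[good, 0], nbo[good, 1], nbo[good, 2]]
            g = harmonic_mean_conductivity(s_own, s_nb) * h
            total += np.sum(g * (v_own - vn[good]))  # outflow from the conductor
        out[ef.name] = units.a_to_ma(total)
    return out


def box_net_current(potential: PotentialField, lo, hi) -> float:
    """Net current (mA) through the closed surface of the voxel box
    ``[lo, hi)`` (discrete conservation check)."""
    system = potential.system
    V = potential.values
    sigma = system.sigma
    h = units.mm_to_m(system.spacing)
    lo = np.asarray(lo, int)
    hi = np.asarray(hi, int)
    inside = np.zeros(system.shape, bool)
    inside[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    total = 0.0
    for axis in range(3):
        for sgn in (-1, 1):
            boundary = inside & ~np.roll(inside, -sgn, axis=axis)
            ijk = np.argwhere(boundary)
            nb = ijk.copy()
            nb[:, axis] += sgn
            ok = (nb[:, axis] >= 0) & (nb[:, axis] < system.shape[axis])
            ijk, nb = ijk[ok], nb[ok]
            v_in = V[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
            v_out = V[nb[:, 0], nb[:, 1], nb[:, 2]]
            good = ~np.isnan(v_in) & ~np.isnan(v_out)
            if not good.any():
                continue
            s_in = sigma[ijk[good, 0], ijk[good, 1], ijk[good, 2]]
            s_out = sigma[nb[good, 0], nb[good, 1], nb[good, 2]]
            g = harmonic_mean_conductivity(s_in, s_out) * h
            total += np.sum(g * (v_in[good] - v_out[good]))  # outflow
    return units.a_to_ma(total)


# ---------------------------------------------------------------------------
# Quasi-static justification helpers
# ---------------------------------------------------------------------------

def pulse_spectrum(pulse: PulseSpec, f_grid_hz) -> np.ndarray:
    """Fourier magnitude spectrum |A T sinc(f T)| of a rectangular pulse.

    ``f_grid_hz`` in Hz; the returned magnitude at f=0 equals the pulse area
    (amplitude x duration, in mA*s)."""
    f = np.asarray(f_grid_hz, float)
    T = pulse.duration_ms * 1e-3
    return np.abs(pulse.amplitude_ma * T * np.sinc(f * T))


def first_zero_crossing_khz(pulse: PulseSpec) -> float:
    """First spectral zero of the rectangular pulse: 1/T, in kHz for T in ms."""
    return 1.0 / pulse.duration_ms


def analysis_frequency_khz(pulse: PulseSpec) -> float:
    """Representative analysis frequency: half the first zero crossing."""
    return 0.5 * first_zero_crossing_khz(pulse)


def reactive_ratio(sigma: float, epsilon: float, f_hz: float) -> float:
    """Dimensionless ratio omega*epsilon/sigma quantifying the reactive term.

    Values << 1 justify dropping the complex permittivity term and solving
    the purely conductive equation."""
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    if f_hz < 0:
        raise InvalidParameterError(f"frequency must be >= 0, got {f_hz}")
    return 2.0 * np.pi * f_hz * epsilon / sigma


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def field_to_nifti(field_values: np.ndarray, phantom, path) -> None:
    """Write a scalar volume on the phantom grid as NIfTI."""
    import nibabel as nib

    affine = np.diag([phantom.spacing] * 3 + [1.0])
    affine[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(np.nan_to_num(field_values).astype(np.float32), affine), str(path))


def field_to_hdf5(path, potential: PotentialField, ef: EFField, metadata: dict) -> None:
    """Write potential + EF volumes with run metadata to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("potential_v", data=potential.values, compression="gzip")
        f.create_dataset("ef_vectors_v_per_m", data=ef.vectors, compression="gzip")
        f.create_dataset("ef_magnitude_v_per_m", data=ef.magnitude, compression="gzip")
        f.create_dataset("mask", data=potential.mask, compression="gzip")
        f.attrs["spacing_mm"] = potential.spacing
        f.attrs["iterations"] = potential.iterations
        f.attrs["relative_residual"] = potential.relative_residual
        for k, v in metadata.items():
            f.attrs[k] = v
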