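"""Spectrum reconstruction: full FT reference, co-MDD, and IRLS-VE.

Three routes from time-domain CPMG series to a stack of real spectra:

``full_ft``
    the reference path for fully sampled data: cosine apodization, two-fold
    zero filling, Fourier transform, zero phase (synthetic signals are
    generated phase-aligned).

``comdd_fit`` / ``comdd_reconstruct``
    co-processing of all CPMG planes at once by multi-dimensional
    decomposition: the plane stack is modelled as a sum of components, each a
    tensor product of one normalized shape vector per spectral dimension with
    a real per-plane amplitude. Shapes are shared across planes -- peak
    positions and lineshapes do not depend on the CPMG frequency -- so only
    the amplitudes carry the dispersion. The model is fitted to the sampled
    coordinates only, by regularized alternating least squares.

``irls_ve_reconstruct``
    per-plane compressed sensing: each (direct-frequency column, plane) is
    extended by the virtual-echo construction, the real VE spectrum is
    estimated by iteratively reweighted least squares promoting an l_p-sparse
    solution, missing time-domain points are synthesized from it, and the
    completed data go through the reference FT path.

The direct dimension is always fully sampled and is transformed first; both
sparse solvers operate on (direct-frequency x indirect-time x plane) data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import GridSpec, TimeDomainSeries
from .systems import CpmgSeriesSpec

__all__ = [
    "SpectrumSeries",
    "DecompositionModel",
    "full_ft",
    "comdd_fit",
    "comdd_reconstruct",
    "virtual_echo",
    "irls_ve_reconstruct",
    "spectral_noise_sigma",
]


# ---------------------------------------------------------------------------
# shared FT machinery
# ---------------------------------------------------------------------------

def _apod(n: int) -> np.ndarray:
    """Cosine window over n acquired points, with the half first point."""
    w = np.cos(0.5 * np.pi * np.arange(n) / n)
    w[0] *= 0.5
    return w

def _process_dim(arr: np.ndarray, axis: int) -> np.ndarray:
    """Apodize, zero-fill x2, FT and shift one time dimension."""
    n = arr.shape[axis]
    shape = [1] * arr.ndim
    shape[axis] = n
    arr = arr * _apod(n).reshape(shape)
    arr = np.fft.fft(arr, n=2 * n, axis=axis)
    return np.fft.fftshift(arr, axes=axis)


def _freq_axis_hz(n: int, sw: float) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftfreq(2 * n, d=1.0 / sw))


@dataclass
class SpectrumSeries:
    """Real spectra, one per CPMG plane, shaped (planes, *indirect_f, direct_f)."""

    values: np.ndarray
    axes_hz: list                # offset axes, ordered like value dims after plane
    obs_mhz: tuple               # per spectral dim, same order as axes_hz
    grid: GridSpec
    spec: CpmgSeriesSpec
    provenance: str

    @property
    def n_planes(self) -> int:
        return self.values.shape[0]

    def axes_ppm(self) -> list:
        return [ax / mhz for ax, mhz in zip(self.axes_hz, self.obs_mhz)]

    def index_of(self, position_ppm) -> tuple:
        """Nearest grid index of a (direct, indirect...) ppm position.

        The position is ordered like site positions (direct first); the
        returned index is ordered like the value dimensions (indirect...,
        direct last).
        """
        axes = self.axes_ppm()
        pos = [position_ppm[d] for d in list(range(1, len(axes))) + [0]]
        return tuple(int(np.argmin(np.abs(ax - p)))
                     for ax, p in zip(axes, pos))


def _axes_for(grid: GridSpec) -> tuple:
    """(axes_hz, obs_mhz) ordered (indirect..., direct)."""
    obs = grid.obs_mhz
    axes = [
        _freq_axis_hz(n, sw)
        for n, sw in zip(grid.n_indirect, grid.sw_indirect_hz)
    ] + [_freq_axis_hz(grid.n_direct, grid.sw_direct_hz)]
    order = list(range(1, grid.ndim)) + [0]
    return axes, tuple(obs[d] for d in order)


def full_ft(data: TimeDomainSeries) -> SpectrumSeries:
    """Reference spectra from fully sampled data (apodize, zero-fill, FT)."""
    if not data.fully_sampled:
        raise ValueError("full_ft requires fully sampled data")
    arr = data.values
    for axis in range(arr.ndim - 1, 0, -1):  # direct last, then indirect dims
        arr = _process_dim(arr, axis)
    axes, obs = _axes_for(data.grid)
    return SpectrumSeries(values=arr.real, axes_hz=axes, obs_mhz=obs,
                          grid=data.grid, spec=data.spec, provenance="full_ft")


def spectral_noise_sigma(grid: GridSpec, noise_sigma: float) -> float:
    """Std of the spectral noise floor implied by time-domain noise.

    With independent complex Gaussian noise of scale ``noise_sigma`` per time
    point and the (unnormalized) processing of :func:`full_ft`, the variance
    of a real spectral point is ``noise_sigma**2 * prod_d sum_t w_d(t)**2``.
    """
    tot = np.sum(_apod(grid.n_direct) ** 2)
    for n in grid.n_indirect:
        tot *= np.sum(_apod(n) ** 2)
    return float(noise_sigma * np.sqrt(tot))


# ---------------------------------------------------------------------------
# co-MDD
# ---------------------------------------------------------------------------

@dataclass
class DecompositionModel:
    """Fitted co-MDD model: shared shapes plus per-plane real amplitudes.

    ``shape_direct`` lives in the frequency domain (the direct dimension is
    transformed before decomposition); indirect shapes are time-domain
    vectors. All shape columns have unit Euclidean norm; scale and the CPMG
    modulation live in ``amplitudes`` (planes x components, real).
    """

    shape_direct: np.ndarray     # (2*n_direct, r) complex
    shapes_indirect: list        # per indirect dim: (n_t, r) complex
    amplitudes: np.ndarray       # (planes, r) real
    lambda_reg: float
    n_iter_run: int
    converged: bool
    rel_residual: float
    grid: GridSpec
    spec: CpmgSeriesSpec

    @property
    def n_components(self) -> int:
        return self.shape_direct.shape[1]


def _direct_ft_tensor(data: TimeDomainSeries) -> np.ndarray:
    """FT the direct dimension only -> complex (planes, *indirect, nf)."""
    return _process_dim(data.values, data.values.ndim - 1)


def comdd_fit(
    data: TimeDomainSeries,
    n_components: int,
    lambda_reg: float = 1e-4,
    n_iter: int = 2000,
    tol: float = 1e-9,
    seed: int | None = None,
    init_positions=None,
    init_linewidth_hz: float = 15.0,
) -> DecompositionModel:
    """Fit the co-MDD model to sparse data by alternating least squares.

    Each ALS sweep updates the direct-dimension shapes, then each indirect
    shape matrix, then the real amplitudes; every sub-problem is a Tikhonov-
    regularized linear LS (penalty ``lambda_reg * ||x||^2`` relative to the
    Gram scale) restricted to the sampled coordinates. Shapes are
    renormalized each sweep with the norm absorbed into the amplitudes.
    Iteration stops at ``n_iter`` or when the relative change of the
    data-domain residual drops below ``tol``.

    ``init_positions`` (optional) is a list of expected peak positions in
    ppm, ordered (direct, indirect...) like site positions: the matching
    leading components are initialized as idealized lineshapes there, which
    keeps alternating least squares out of the degenerate "swamp" regime
    when many components have strongly overlapping shapes. Remaining
    components are initialized randomly (seeded) and absorb noise and
    unlisted signals. Peak lists are available in any quantitative CPMG
    workflow, so this mirrors how multi-dimensional decomposition is used in
    practice.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    mask = data.mask
    if not mask.reshape(mask.shape[0], -1).any(axis=1).all():
        raise ValueError("every plane needs at least one sampled point")
    m = int(mask.sum())
    nf_dof = m * 2  # complex observations per direct-frequency column
    if n_components * (2 + len(data.grid.n_indirect)) > nf_dof:
        warnings.warn("n_components exceeds sampled degrees of freedom; proceeding")

    dirft = _direct_ft_tensor(data)            # (planes, *ind, nf)
    nf = dirft.shape[-1]
    n_ind = data.grid.n_indirect
    planes = data.n_planes
    r = n_components

    # sampled coordinate lists
    samp = np.nonzero(mask)                    # (planes, *ind) order
    p_s = samp[0]
    ind_s = samp[1:]
    d_s = dirft[samp].T                        # (nf, m) complex
    d_norm = np.linalg.norm(d_s)
    if d_norm == 0:
        raise ValueError("data are identically zero")

    rng = np.random.default_rng(seed)

    def _cinit(n, k):
        v = rng.standard_normal((n, k)) + 1j * rng.standard_normal((n, k))
        return v / np.linalg.norm(v, axis=0, keepdims=True)

    h = _cinit(nf, r)                          # direct shapes (freq domain)
    fs = [_cinit(n, r) for n in n_ind]         # indirect shapes (time domain)
    if init_positions:
        obs = data.grid.obs_mhz
        damp = np.pi * init_linewidth_hz
        for i, pos in enumerate(init_positions[:r]):
            td = data.grid.times(0)
            sig = np.exp((2j * np.pi * pos[0] * obs[0] - damp) * td)
            h[:, i] = _process_dim(sig, 0)
            for d in range(len(n_ind)):
                t = data.grid.times(d + 1)
                fs[d][:, i] = np.exp(
                    (2j * np.pi * pos[d + 1] * obs[d + 1] - damp) * t
                )
        h /= np.linalg.norm(h, axis=0, keepdims=True)
        for d in range(len(n_ind)):
            fs[d] /= np.linalg.norm(fs[d], axis=0, keepdims=True)
    a = np.ones((planes, r))                   # real amplitudes

    eye = np.eye(r)

    def _reg(gram):
        """Scale-aware Tikhonov term: lambda_reg relative to the Gram scale."""
        scale = max(float(np.mean(np.abs(np.diagonal(gram)))), 1e-300)
        return lambda_reg * scale * eye

    # per-dimension grouping of sampled points
    groups_ind = [[np.nonzero(ind_s[d] == t)[0] for t in range(n_ind[d])]
                  for d in range(len(n_ind))]
    groups_pl = [np.nonzero(p_s == p)[0] for p in range(planes)]

    def _b_matrix():
        """Khatri-Rao rows of all non-direct factors at sampled coords."""
        b = a[p_s]
        for d in range(len(n_ind)):
            b = b * fs[d][ind_s[d]]
        return b                                # (m, r) complex

    prev_res = np.inf
    it = 0
    converged = False
    for it in range(1, n_iter + 1):
        # --- direct shapes: D_S ~ H @ B^T  (solve H = R A^-1 via A^T H^T = R^T;
        # A = conj(Gb) + reg, so A^T = Gb + reg by hermiticity)
        b = _b_matrix()
        gb = np.conj(b.T) @ b
        h = np.linalg.solve(gb + _reg(gb), (d_s @ np.conj(b)).T).T

        # --- indirect shape matrices
        for d in range(len(n_ind)):
            # rows excluding this dimension's factor
            rrows = a[p_s]
            for d2 in range(len(n_ind)):
                if d2 != d:
                    rrows = rrows * fs[d2][ind_s[d2]]
            gh = np.conj(h.T) @ h              # (r, r)
            proj = np.conj(h.T) @ d_s          # (r, m)
            new = np.zeros_like(fs[d])
            for t, g in enumerate(groups_ind[d]):
                if len(g) == 0:
                    continue  # never-sampled evolution time stays zero
                rt = rrows[g]
                gram = gh * (np.conj(rt.T) @ rt)
                rhs = np.einsum("si,is->i", np.conj(rt), proj[:, g])
                new[t] = np.linalg.solve(gram + _reg(gram), rhs)
            fs[d] = new

        # --- real amplitudes per plane
        gh = np.conj(h.T) @ h
        proj = np.conj(h.T) @ d_s
        q = np.ones((m, r), dtype=complex)
        for d2 in range(len(n_ind)):
            q = q * fs[d2][ind_s[d2]]
        for p, g in enumerate(groups_pl):
            qp = q[g]
            gram = (gh * (np.conj(qp.T) @ qp)).real
            rhs = np.einsum("si,is->i", np.conj(qp), proj[:, g]).real
            a[p] = np.linalg.solve(gram + _reg(gram), rhs)

        # --- renormalize, absorb norms into amplitudes, fix phases
        for mat_idx in range(1 + len(n_ind)):
            mat = h if mat_idx == 0 else fs[mat_idx - 1]
            norms = np.linalg.norm(mat, axis=0)
            norms[norms == 0] = 1.0
            mat /= norms
            a *= norms
            if mat_idx < len(n_ind):  # leave the last factor's phase free
                k = np.argmax(np.abs(mat), axis=0)
                ph = mat[k, np.arange(r)]
                ph = np.where(np.abs(ph) > 0, ph / np.abs(ph), 1.0)
                mat *= np.conj(ph)
                tgt = fs[-1]
                tgt *= ph  # compensate so each component's product is unchanged

        # --- convergence on the sampled-coordinate residual
        model_s = h @ _b_matrix().T
        res = np.linalg.norm(model_s - d_s) / d_norm
        if abs(prev_res - res) < tol:
            converged = True
            break
        prev_res = res

    return DecompositionModel(
        shape_direct=h,
        shapes_indirect=fs,
        amplitudes=a,
        lambda_reg=lambda_reg,
        n_iter_run=it,
        converged=converged,
        rel_residual=float(res),
        grid=data.grid,
        spec=data.spec,
    )


def comdd_reconstruct(model: DecompositionModel,
                      grid: GridSpec | None = None) -> SpectrumSeries:
    """Evaluate the fitted model on the full grid and FT the indirect dims."""
    grid = grid or model.grid
    if model.shape_direct.shape[0] != 2 * grid.n_direct or any(
        f.shape[0] != n for f, n in zip(model.shapes_indirect, grid.n_indirect)
    ):
        raise ValueError("model does not match the requested grid")
    # tensor (planes, *ind_time, nf) from the factor products
    if len(model.shapes_indirect) == 1:
        tens = np.einsum("pi,ti,fi->ptf", model.amplitudes,
                         model.shapes_indirect[0], model.shape_direct)
    else:
        tens = np.einsum("pi,ti,ui,fi->ptuf", model.amplitudes,
                         model.shapes_indirect[0], model.shapes_indirect[1],
                         model.shape_direct)
    for axis in range(tens.ndim - 2, 0, -1):   # indirect dims only
        tens = _process_dim(tens, axis)
    axes, obs = _axes_for(grid)
    return SpectrumSeries(values=tens.real, axes_hz=axes, obs_mhz=obs,
                          grid=grid, spec=model.spec, provenance="comdd")


# ---------------------------------------------------------------------------
# IRLS with virtual echo
# ---------------------------------------------------------------------------

def virtual_echo(vec: np.ndarray) -> np.ndarray:
    """Conjugate-symmetric length-2n extension of a 1D complex FID.

    ``out[t] = vec[t]`` for ``t in [0, n)``, ``out[2n - t] = conj(vec[t])``
    for ``t in (0, n)``, ``out[n] = 0``; the first point's imaginary part is
    dropped so that the DFT of the result is real for an absorptive,
    phase-aligned signal.
    """
    vec = np.asarray(vec, dtype=complex)
    n = len(vec)
    out = np.zeros(2 * n, dtype=complex)
    out[:n] = vec
    out[0] = vec[0].real
    out[n + 1 :] = np.conj(vec[1:][::-1])
    return out


def _ve_design(n_ind: tuple, coords: np.ndarray, ext: int = 4) -> np.ndarray:
    """Real-stacked VE measurement operator for sampled indirect coords.

    Rows map the real VE spectrum x (length prod(ext*n_d)) to the measured
    complex time-domain points via the inverse DFT; returned stacked as
    [Re; Im] -> (2m, L). The model grid is ``ext`` times longer than the
    acquired one so the model can represent a signal that keeps decaying
    beyond the measured window instead of being forced to zero there.
    """
    ls = [ext * n for n in n_ind]
    rows = None
    for d, (n, ldim) in enumerate(zip(n_ind, ls)):
        k = np.arange(ldim)
        block = np.exp(2j * np.pi * np.outer(coords[:, d], k) / ldim) / ldim
        rows = block if rows is None else (rows[:, :, None] * block[:, None, :]).reshape(
            len(coords), -1
        )
    return np.concatenate([rows.real, rows.imag], axis=0)


def irls_ve_reconstruct(
    data: TimeDomainSeries,
    n_iter: int = 30,
    p_norm: float = 0.5,
    lambda_rel: float = 1e-8,
    eps_floor_rel: float = 1e-3,
    ve_extension: int | None = None,
    column_power_rel: float = 1e-4,
) -> SpectrumSeries:
    """Per-plane compressed-sensing reconstruction (IRLS, virtual echo).

    For every (direct-frequency column, plane) the sampled indirect
    time-domain points constrain a real VE spectrum, which is estimated by
    iteratively reweighted least squares with weights
    ``w_i = (x_i^2 + eps^2)^((p-2)/2)`` and ``eps`` halved every iteration
    from the max of the initial minimum-norm solution. Missing time-domain
    points are then synthesized from the solution and the completed series
    goes through the :func:`full_ft` path, so a fully sampled input
    reproduces ``full_ft`` exactly.
    """
    mask = data.mask
    n_ind = tuple(data.grid.n_indirect)
    if ve_extension is None:
        # one indirect dim affords a finer model grid; two keep L tractable
        ve_extension = 4 if len(n_ind) == 1 else 2
    dir_pos = _direct_ft_tensor(data)          # (planes, *ind, nf)
    if data.values_neg is not None:
        # phase-pure column pairs from the two States combinations: the
        # absorptive (Re H) and dispersive (Im H) direct parts each modulate
        # the indirect dimension with a real coefficient, as VE requires
        dir_neg = _process_dim(data.values_neg, data.values_neg.ndim - 1)
        col_sets = (0.5 * (dir_pos + np.conj(dir_neg)),
                    (dir_pos - np.conj(dir_neg)) / 2j)
    else:
        col_sets = (dir_pos,)
    completed = dir_pos.copy()
    exponent = (2.0 - p_norm) / 2.0  # for w^-1 = (x^2 + eps^2)^((2-p)/2)

    for p in range(data.n_planes):
        pm = mask[p]
        if not pm.any():
            raise ValueError(f"plane {p} has no sampled points")
        if pm.all():
            continue
        coords = np.argwhere(pm)
        a_r = _ve_design(n_ind, coords, ve_extension)   # (2m, L)
        m2, big_l = a_r.shape
        y_c = np.concatenate([cs[p][tuple(coords.T)] for cs in col_sets],
                             axis=-1)              # (m, nf * n_sets) complex
        y_r = np.concatenate([y_c.real, y_c.imag], axis=0)  # (2m, ...)

        # iteration 0: unweighted minimum-norm solve, shared across columns
        gram0 = a_r @ a_r.T
        lam = lambda_rel * np.trace(gram0) / m2
        x = a_r.T @ np.linalg.solve(gram0 + lam * np.eye(m2), y_r)  # (L, ncol)

        # iterate only on columns carrying signal; the minimum-norm solution
        # stands for the (peak-height-irrelevant) near-empty columns
        colpow = (np.abs(y_c) ** 2).sum(axis=0)
        act = np.nonzero(colpow >= column_power_rel * max(colpow.max(), 1e-300))[0]
        xa = x[:, act]
        ya = y_r[:, act]
        eps = np.maximum(np.abs(xa).max(axis=0), 1e-300)
        eps_floor = eps * eps_floor_rel
        # chunk the column axis to bound the (L x 2m x chunk) work arrays
        chunk = max(1, int(4e6 // (big_l * m2)))
        for _ in range(n_iter):
            for j0 in range(0, len(act), chunk):
                sl = slice(j0, min(j0 + chunk, len(act)))
                winv = (xa[:, sl] ** 2 + eps[None, sl] ** 2) ** exponent
                wa = winv[:, None, :] * a_r.T[:, :, None]    # (L, 2m, c)
                gram = np.einsum("il,ljn->nij", a_r, wa)     # (c, 2m, 2m)
                gram += lam * np.eye(m2)[None]
                sol = np.linalg.solve(gram, ya.T[sl, :, None])[..., 0]
                xa[:, sl] = np.einsum("lmn,nm->ln", wa, sol)
            eps = np.maximum(eps / 2.0, eps_floor)
        x[:, act] = xa

        # synthesize the unmeasured time-domain points from the VE spectra
        ncol = x.shape[1]
        xs = x.T.reshape((ncol,) + tuple(ve_extension * n for n in n_ind))
        v = np.fft.ifftn(xs, axes=range(1, xs.ndim))
        v = v[(slice(None),) + tuple(slice(0, n) for n in n_ind)]
        v = np.moveaxis(v, 0, -1)                  # (*ind, nf * n_sets)
        if len(col_sets) == 2:
            nf = dir_pos.shape[-1]
            v = v[..., :nf] + 1j * v[..., nf:]     # recombine Re/Im parts
        completed[p] = np.where(pm[..., None], dir_pos[p], v)

    # completed data live in (plane, indirect-time, direct-frequency) space;
    # finish with the same indirect processing as the reference path
    arr = completed
    for axis in range(arr.ndim - 2, 0, -1):
        arr = _process_dim(arr, axis)
    axes, obs = _axes_for(data.grid)
    return SpectrumSeries(values=arr.real, axes_hz=axes, obs_mhz=obs,
                          grid=data.grid, spec=data.spec, provenance="irls_ve")
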