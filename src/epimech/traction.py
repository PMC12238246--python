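"""Traction-force and monolayer-stress reconstruction.

The chain mirrors the bead-based workflow: windowed cross-correlation PIV
turns a (tense, relaxed) bead image pair into a displacement field;
regularized Fourier-transform traction cytometry (FTTC) inverts it through
the Boussinesq half-space solution into a traction field in Pa; and a 2-D
force balance over the cell sheet of height h converts traction into the
average normal intercellular stress (monolayer stress microscopy).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .containers import GelSpec, StressField, VectorField
from .elastic import forward_displacement, greens_tensor_fourier, invert_traction

__all__ = [
    "piv_displacement",
    "fttc",
    "choose_lambda_lcurve",
    "mean_traction",
    "monolayer_stress",
]


# -------------------------------------------------------------------- PIV

def _parabolic_shift(cc: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """3-point parabola refinement of a correlation peak (clamped at edges)."""
    def axis_shift(cm, c0, cp):
        denom = cm - 2.0 * c0 + cp
        return 0.5 * (cm - cp) / denom if denom < 0 else 0.0
    dy = dx = 0.0
    if 0 < iy < cc.shape[0] - 1:
        dy = axis_shift(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
    if 0 < ix < cc.shape[1] - 1:
        dx = axis_shift(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
    return dy, dx


def piv_displacement(img_ref: np.ndarray, img_def: np.ndarray,
                     window_px: int = 32, overlap: float = 0.5,
                     search_px: int = 8,
                     pixel_size_um: float = 1.0,
                     peak_ratio_min: float = 1.1,
                     remove_drift: bool = True) -> VectorField:
    """Windowed normalized-cross-correlation PIV with subpixel refinement.

    ``img_ref`` is the relaxed gel (cells removed), ``img_def`` the tense
    state; the returned vectors (µm) are the displacement of ``img_def``
    relative to ``img_ref``.  Each ``window_px`` template from the reference
    is matched against a search region extended by ``search_px`` on every
    side in the deformed image (so displacements up to ``search_px`` px are
    measurable without the template leaving the search area), and the
    correlation peak is refined with a 3-point parabola.  Windows whose peak
    is less than ``peak_ratio_min`` times the second-highest peak are marked
    invalid and inpainted from their valid neighbors; stage drift is removed
    by subtracting the median vector.
    """
    from skimage.feature import match_template

    a = np.asarray(img_ref, dtype=float)
    b = np.asarray(img_def, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("bead images must be 2-D and the same shape")
    step = max(1, int(round(window_px * (1.0 - overlap))))
    ys = np.arange(search_px, a.shape[0] - window_px - search_px + 1, step)
    xs = np.arange(search_px, a.shape[1] - window_px - search_px + 1, step)
    vx = np.zeros((len(ys), len(xs)))
    vy = np.zeros((len(ys), len(xs)))
    valid = np.zeros((len(ys), len(xs)), dtype=bool)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            tmpl = a[y0:y0 + window_px, x0:x0 + window_px]
            srch = b[y0 - search_px:y0 + window_px + search_px,
                     x0 - search_px:x0 + window_px + search_px]
            if tmpl.std() == 0 or srch.std() == 0:
                continue
            cc = match_template(srch, tmpl)
            iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
            peak = cc[iy, ix]
            masked = cc.copy()
            masked[max(iy - 1, 0):iy + 2, max(ix - 1, 0):ix + 2] = -np.inf
            second = masked.max()
            if np.isfinite(second) and second > 0 \
                    and peak / second < peak_ratio_min:
                continue
            if peak >= 1.0 - 1e-9:
                dy = dx = 0.0   # exact integer match; parabola would only add bias
            else:
                dy, dx = _parabolic_shift(cc, iy, ix)
            vy[i, j] = iy - search_px + dy
            vx[i, j] = ix - search_px + dx
            valid[i, j] = True
    # inpaint invalid vectors from valid 8-neighbors (iterated mean)
    for _ in range(10):
        if valid.all():
            break
        fy, fx = np.where(~valid)
        for i, j in zip(fy, fx):
            sl = (slice(max(i - 1, 0), i + 2), slice(max(j - 1, 0), j + 2))
            if valid[sl].any():
                vx[i, j] = vx[sl][valid[sl]].mean()
                vy[i, j] = vy[sl][valid[sl]].mean()
                valid[i, j] = True
    if remove_drift:
        vx -= np.median(vx)
        vy -= np.median(vy)
    centers_x = (xs + window_px / 2.0) * pixel_size_um
    centers_y = (ys + window_px / 2.0) * pixel_size_um
    return VectorField(grid_x=centers_x, grid_y=centers_y,
                       vx=vx * pixel_size_um, vy=vy * pixel_size_um,
                       spacing=step * pixel_size_um, role="displacement")


# ------------------------------------------------------------------- FTTC

def choose_lambda_lcurve(u: VectorField, gel: GelSpec,
                         n_lambdas: int = 30) -> float:
    """L-curve corner criterion for the Tikhonov parameter.

    Scans λ logarithmically around the median magnitude of the Green tensor
    and returns the λ of maximum curvature of (log residual, log solution
    norm).
    """
    n = u.vx.shape[0]
    G = greens_tensor_fourier(n, u.spacing, gel.E_gel, gel.nu_gel)
    gmag = np.abs(G[..., 0, 0])
    gscale = np.median(gmag[gmag > 0])
    lams = gscale * np.logspace(-4, 2, n_lambdas)
    rho, eta = [], []
    for lam in lams:
        tx, ty = invert_traction(u.vx, u.vy, u.spacing, gel.E_gel,
                                 gel.nu_gel, lam)
        ux, uy = forward_displacement(tx, ty, u.spacing, gel.E_gel, gel.nu_gel)
        rho.append(np.sqrt(np.sum((ux - u.vx) ** 2 + (uy - u.vy) ** 2)) + 1e-300)
        eta.append(np.sqrt(np.sum(tx ** 2 + ty ** 2)) + 1e-300)
    lr, le = np.log(rho), np.log(eta)
    # discrete curvature of the L-curve
    d1r, d1e = np.gradient(lr), np.gradient(le)
    d2r, d2e = np.gradient(d1r), np.gradient(d1e)
    kappa = (d1r * d2e - d2r * d1e) / np.maximum(
        (d1r ** 2 + d1e ** 2) ** 1.5, 1e-300)
    return float(lams[int(np.argmax(kappa))])


def fttc(u: VectorField, gel: GelSpec, lam: float | str = "lcurve"
         ) -> VectorField:
    """Regularized FTTC: displacement field (µm) → traction field (Pa).

    ``lam`` is the Tikhonov parameter in Green-tensor units (µm/Pa);
    ``"lcurve"`` selects it by the L-curve corner, 0 disables
    regularization.  The DC component is zeroed (net-force-free traction).
    """
    if u.vx.shape[0] != u.vx.shape[1]:
        raise ValueError("FTTC needs a square grid")
    dx = np.diff(u.grid_x)
    dy = np.diff(u.grid_y)
    if len(dx) and len(dy) and not np.allclose(dx[0], dy[0]):
        raise ValueError("FTTC needs equal (square) grid spacing")
    if lam == "lcurve":
        lam = choose_lambda_lcurve(u, gel)
    if not isinstance(lam, (int, float)) or lam < 0:
        raise ValueError("lam must be a non-negative number or 'lcurve'")
    tx, ty = invert_traction(u.vx, u.vy, u.spacing, gel.E_gel, gel.nu_gel,
                             float(lam))
    return VectorField(grid_x=u.grid_x, grid_y=u.grid_y, vx=tx, vy=ty,
                       spacing=u.spacing, role="traction")


def mean_traction(T: VectorField, mask: np.ndarray | None = None) -> float:
    """Mean traction magnitude |T| (Pa) over a mask (default: whole field)."""
    mag = T.magnitude
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mag.shape:
            raise ValueError("mask shape must match the field")
        if not mask.any():
            raise ValueError("empty mask")
        mag = mag[mask]
    return float(mag.mean())


# ------------------------------------------------- monolayer stress (FEM)

def _q1_element_matrices(s: float, E: float, nu: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Stiffness (8×8) and mass (4×4) of a square Q1 plane-stress element."""
    C = E / (1.0 - nu ** 2) * np.array([[1.0, nu, 0.0],
                                        [nu, 1.0, 0.0],
                                        [0.0, 0.0, (1.0 - nu) / 2.0]])
    g = 1.0 / np.sqrt(3.0)
    pts = [(-g, -g), (g, -g), (g, g), (-g, g)]
    Ke = np.zeros((8, 8))
    Me = np.zeros((4, 4))
    for xi, eta in pts:
        dN = 0.25 * np.array([[-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
                              [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]])
        N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                             (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
        J = s / 2.0
        dNxy = dN / J
        B = np.zeros((3, 8))
        B[0, 0::2] = dNxy[0]
        B[1, 1::2] = dNxy[1]
        B[2, 0::2] = dNxy[1]
        B[2, 1::2] = dNxy[0]
        Ke += B.T @ C @ B * J * J
        Me += np.outer(N, N) * J * J
    return Ke, Me


def monolayer_stress(T: VectorField, gel: GelSpec, nu_sheet: float = 0.0,
                     balance_tol: float = 1e-6) -> StressField:
    """In-plane intercellular stress from a balanced traction field.

    Solves the 2-D force balance ∂σ_ij/∂x_j = T_i/h (T = traction the cells
    exert on the substrate, h the monolayer height from ``gel``) over the
    image frame with stress-free boundaries, via a displacement-based Q1
    finite-element plane-stress discretization on the traction grid.  The
    recovered stress does not depend on the assumed sheet modulus;
    ``nu_sheet`` defaults to 0 so that unidirectional force balances
    integrate exactly as in the 1-D closed form.

    The input must be net-force-free; an unbalanced field (non-zero DC
    component) makes the balance unsolvable — remove the DC component
    (as FTTC does) first.
    """
    tx, ty = T.vx, T.vy
    ny, nx = tx.shape
    s = T.spacing
    h = gel.monolayer_height
    fx_net, fy_net = T.net_force()
    scale = np.mean(T.magnitude) * s * s * tx.size
    if scale > 0 and np.hypot(fx_net, fy_net) / scale > balance_tol:
        raise ValueError("traction field is not force-balanced; remove its "
                         "DC component (FTTC output is balanced by construction)")

    Ke, Me = _q1_element_matrices(s, 1.0, nu_sheet)

    # element connectivity on the node grid
    ex, ey = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1))
    n0 = (ey * nx + ex).ravel()          # local node order: (0,0) (0,1) (1,1) (1,0)
    conn = np.stack([n0, n0 + 1, n0 + nx + 1, n0 + nx], axis=1)
    ne = conn.shape[0]
    dofs = np.empty((ne, 8), dtype=int)
    dofs[:, 0::2] = 2 * conn
    dofs[:, 1::2] = 2 * conn + 1

    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    data = np.tile(Ke.ravel(), ne)
    ndof = 2 * nx * ny
    K = sparse.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()

    # consistent nodal load from the body force b = −T/h  (so div σ = +T/h)
    bx = -tx.ravel() / h
    by = -ty.ravel() / h
    f = np.zeros(ndof)
    fe_x = (Me @ bx[conn].T).T    # (ne, 4)
    fe_y = (Me @ by[conn].T).T
    np.add.at(f, dofs[:, 0::2], fe_x)
    np.add.at(f, dofs[:, 1::2], fe_y)

    # pin the rigid modes (2 translations + 1 rotation) with Lagrange multipliers
    xx, yy = np.meshgrid(np.arange(nx) * s, np.arange(ny) * s)
    modes = np.zeros((ndof, 3))
    modes[0::2, 0] = 1.0
    modes[1::2, 1] = 1.0
    modes[0::2, 2] = -yy.ravel()
    modes[1::2, 2] = xx.ravel()
    Csp = sparse.csr_matrix(modes)
    A = sparse.bmat([[K, Csp], [Csp.T, None]], format="csc")
    rhs = np.concatenate([f, np.zeros(3)])
    sol = spsolve(A, rhs)
    u = sol[:ndof]

    # stress at element centres (ξ = η = 0)
    Cmat = 1.0 / (1.0 - nu_sheet ** 2) * np.array(
        [[1.0, nu_sheet, 0.0], [nu_sheet, 1.0, 0.0],
         [0.0, 0.0, (1.0 - nu_sheet) / 2.0]])
    J = s / 2.0
    dN = 0.25 * np.array([[-1.0, 1.0, 1.0, -1.0],
                          [-1.0, -1.0, 1.0, 1.0]]) / J
    B = np.zeros((3, 8))
    B[0, 0::2] = dN[0]
    B[1, 1::2] = dN[1]
    B[2, 0::2] = dN[1]
    B[2, 1::2] = dN[0]
    ue = u[dofs]                      # (ne, 8)
    sig = ue @ (Cmat @ B).T           # (ne, 3)
    sxx = sig[:, 0].reshape(ny - 1, nx - 1)
    syy = sig[:, 1].reshape(ny - 1, nx - 1)
    sxy = sig[:, 2].reshape(ny - 1, nx - 1)
    cx = (np.arange(nx - 1) + 0.5) * s + T.grid_x[0]
    cy = (np.arange(ny - 1) + 0.5) * s + T.grid_y[0]
    return StressField(grid_x=cx, grid_y=cy, sxx=sxx, syy=syy, sxy=sxy,
                       spacing=s)
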