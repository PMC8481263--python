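"""Batched Levenberg-Marquardt fitting of Cauchy-Lorentz peak models.

The spectral line model used throughout the package is

    f(E) = c + sum_j  A_j * g_j**2 / ((E - m_j)**2 + g_j**2)

i.e. a constant plus Lorentzian components parameterised by peak height
``A`` (amplitude, unconstrained in sign), centroid ``m`` (MeV) and scale
``g`` (half width at half maximum, MeV).  Parameters are packed as
``theta = [c, A1, m1, g1, A2, m2, g2, ...]``.

The fitter operates on a whole batch of spectra sharing one energy axis,
which is what makes Monte Carlo calibration of the detection test at
2e5 replicates tractable: one damped Gauss-Newton iteration is a handful
of vectorised einsum/solve calls over the active windows.  The step
acceptance rule (only strictly non-increasing SSR steps are taken) is
also what guarantees the nesting SSR_ur <= SSR_r when the unrestricted
fit is warm-started from the restricted solution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lorentz_model", "lorentz_jacobian", "fit_lorentz_batch", "fit_lorentz"]


def n_components(n_params: int) -> int:
    if n_params < 1 or (n_params - 1) % 3:
        raise ValueError(f"invalid Lorentzian parameter count {n_params}")
    return (n_params - 1) // 3


def lorentz_model(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the constant-plus-Lorentzians model.

    Parameters
    ----------
    x : (n,) energy axis shared by the batch.
    theta : (..., p) parameter vectors, p = 1 + 3k.
    """
    x = np.asarray(x, dtype=float)
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    k = n_components(th.shape[-1])
    y = np.broadcast_to(th[..., :1], th.shape[:-1] + x.shape).copy()
    for j in range(k):
        amp = th[..., 1 + 3 * j, None]
        mean = th[..., 2 + 3 * j, None]
        scale = th[..., 3 + 3 * j, None]
        y += amp * scale**2 / ((x - mean) ** 2 + scale**2)
    return y if np.asarray(theta).ndim > 1 else y[0]


def lorentz_jacobian(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d f / d theta, shape (B, n, p)."""
    x = np.asarray(x, dtype=float)
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    batch, p = th.shape
    k = n_components(p)
    jac = np.empty((batch, x.size, p))
    jac[..., 0] = 1.0
    for j in range(k):
        amp = th[:, 1 + 3 * j, None]
        mean = th[:, 2 + 3 * j, None]
        scale = th[:, 3 + 3 * j, None]
        u = x - mean
        denom = u * u + scale * scale
        jac[..., 1 + 3 * j] = scale * scale / denom
        jac[..., 2 + 3 * j] = 2.0 * amp * scale * scale * u / (denom * denom)
        jac[..., 3 + 3 * j] = 2.0 * amp * scale * u * u / (denom * denom)
    return jac


def fit_lorentz_batch(
    x: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    *,
    max_iter: int = 80,
    lam0: float = 1e-3,
    ftol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit every row of ``y`` independently by damped least squares.

    Box constraints are enforced by projection after each trial step.
    Returns ``(theta, ssr, converged)`` with shapes (B, p), (B,), (B,).
    Every accepted step strictly decreases the SSR, so the final SSR
    never exceeds the SSR at ``theta0``.
    """
    x = np.asarray(x, dtype=float)
    theta = np.clip(np.array(theta0, dtype=float, copy=True), lower, upper)
    y = np.asarray(y, dtype=float)
    batch, p = theta.shape

    resid = y - lorentz_model(x, theta)
    ssr = np.einsum("bn,bn->b", resid, resid)
    lam = np.full(batch, lam0)
    stall = np.zeros(batch, dtype=np.int8)
    active = np.arange(batch)
    eye = np.arange(p)

    for _ in range(max_iter):
        if active.size == 0:
            break
        th_a = theta[active]
        r_a = resid[active]
        jac = lorentz_jacobian(x, th_a)
        grad = np.einsum("bnp,bn->bp", jac, r_a)
        hess = np.einsum("bnp,bnq->bpq", jac, jac)
        diag = hess[:, eye, eye]
        # per-parameter relative ridge (the Jacobian columns span many
        # orders of magnitude); zero columns (e.g. the second centroid
        # at zero amplitude) get an absolute floor so the solve stays
        # nonsingular while their step remains zero
        ridge = (lam[active, None] + 1e-12) * diag
        ridge[diag <= 0.0] += 1.0
        haug = hess.copy()
        haug[:, eye, eye] += ridge
        step = np.linalg.solve(haug, grad[..., None])[..., 0]
        th_new = np.clip(th_a + step, lower, upper)
        r_new = y[active] - lorentz_model(x, th_new)
        ssr_new = np.einsum("bn,bn->b", r_new, r_new)

        ok = ssr_new < ssr[active]
        idx_ok = active[ok]
        improve = ssr[idx_ok] - ssr_new[ok]
        theta[idx_ok] = th_new[ok]
        resid[idx_ok] = r_new[ok]
        ssr[idx_ok] = ssr_new[ok]
        lam[idx_ok] = np.maximum(lam[idx_ok] * 0.33, 1e-12)
        idx_bad = active[~ok]
        lam[idx_bad] = np.minimum(lam[idx_bad] * 4.0, 1e10)

        # a window is done after two consecutive negligible outcomes
        # (tiny accepted improvement, or a rejected step at high damping)
        small = np.zeros(active.size, dtype=bool)
        small[ok] = improve <= ftol * (ssr[idx_ok] + 1e-300)
        small[~ok] = lam[idx_bad] >= 1e8
        stall[active] = np.where(small, stall[active] + 1, 0)
        active = active[stall[active] < 2]

    converged = stall >= 2
    return theta, ssr, converged


def fit_lorentz(
    x: np.ndarray,
    y: np.ndarray,
    theta0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    *,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, np.ndarray | None, bool]:
    """Single-spectrum fit; returns (theta, ssr, covariance, converged).

    Covariance is the usual Gauss-Newton estimate ssr/df * (J'J)^-1,
    None when J'J is singular or df <= 0.
    """
    theta, ssr, conv = fit_lorentz_batch(
        x, np.atleast_2d(y), np.atleast_2d(theta0), lower, upper, max_iter=max_iter
    )
    theta, ssr = theta[0], float(ssr[0])
    dof = len(x) - theta.size
    cov = None
    if dof > 0:
        jac = lorentz_jacobian(x, theta[None, :])[0]
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * (ssr / dof)
        except np.linalg.LinAlgError:
            cov = None
    return theta, ssr, cov, bool(conv[0])
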