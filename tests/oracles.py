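"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the kinetic model is
checked against a high-accuracy ODE integration of the underlying rate law,
and the nonlinear least-squares fitter against an exhaustive grid search
with a derivative-free polish.
"""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize


def ode_product(a: float, b: float, times, k_d: float = 0.0) -> np.ndarray:
    """Integrate dP/dt = a*exp(-b*P)*exp(-k_d*t) from P(0)=0 at high accuracy."""
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda t, p: a * np.exp(-b * p[0]) * np.exp(-k_d * t),
        (times[0], times[-1]),
        [0.0],
        t_eval=times,
        rtol=1e-11,
        atol=1e-12,
        method="RK45",
        max_step=1.0,
    )
    return sol.y[0]


def grid_fit(times, product, n_grid: int = 200) -> tuple[float, float]:
    """Brute-force (a, b) estimate: log-spaced grid search + Nelder-Mead polish.

    The grid brackets the data-driven scales (secant slope for a, 1/max(P)
    for b) by two decades either side; the polish minimizes the same sum of
    squares without derivatives.
    """
    times = np.asarray(times, float)
    product = np.asarray(product, float)
    pos = times > 0
    a_scale = np.median(product[pos] / times[pos])
    a_scale = max(a_scale, 1e-6)
    b_scale = 1.0 / max(product.max(), 1e-12)
    a_grid = np.logspace(np.log10(a_scale) - 2, np.log10(a_scale) + 2, n_grid)
    b_grid = np.logspace(np.log10(b_scale) - 2, np.log10(b_scale) + 2, n_grid)
    # vectorized SSE over the full grid: (n_a, n_b, n_t)
    ab = a_grid[:, None, None] * b_grid[None, :, None]
    pred = np.log1p(ab * times[None, None, :]) / b_grid[None, :, None]
    sse = np.sum((pred - product[None, None, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)

    def objective(theta):
        la, lb = theta
        a, b = np.exp(la), np.exp(lb)
        return np.sum((np.log1p(a * b * times) / b - product) ** 2)

    res = minimize(
        objective,
        x0=[np.log(a_grid[i]), np.log(b_grid[j])],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
    )
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))
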