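"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch (hand-derived
equations, fixed-step integration) and must stay independent of the
package's own right-hand sides and solver.
"""

from __future__ import annotations

import numpy as np


def rk4_integrate(f, y0, t_end: float, dt: float, t_out: np.ndarray) -> np.ndarray:
    """Fixed-step classical 4th-order Runge–Kutta on [0, t_end].

    Returns states at the requested output times `t_out` (linear
    interpolation between the fixed steps).
    """
    n_steps = int(round(t_end / dt))
    y = np.asarray(y0, dtype=float).copy()
    ts = [0.0]
    ys = [y.copy()]
    t = 0.0
    for _ in range(n_steps):
        k1 = np.asarray(f(t, y))
        k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1))
        k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2))
        k4 = np.asarray(f(t + dt, y + dt * k3))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        ts.append(t)
        ys.append(y.copy())
    ts = np.asarray(ts)
    ys = np.asarray(ys)
    out = np.empty((len(t_out), ys.shape[1]))
    for j in range(ys.shape[1]):
        out[:, j] = np.interp(t_out, ts, ys[:, j])
    return out


def full_model_rhs_intact(t, y, p):
    """Hand-written RHS of the full (two-repressor, ligand-binding) intact
    network, re-derived independently from the model description.

    State order: OP, G, R, Ap, U, Aout, C_R, C_G, Y.
    `p` is a plain dict of rate constants.
    """
    OP, G, R, Ap, U, Aout, C_R, C_G, Y = y
    R_ = max(R, 0.0)
    G_ = max(G, 0.0)
    promoter = (
        p["k_op"]
        / (1.0 + (R_ / p["k1"]) ** p["nOP"])
        / (1.0 + (G_ / p["k4"]) ** p["nG"])
    )
    lsrR_syn = p["k_r"] / (1.0 + (R_ / p["k2"]) ** p["nR"])
    uptake = (p["k_imp"] * OP + p["k_f"]) * Aout
    seq_R = p["k3"] * R * Ap
    seq_G = p["k5"] * G * Ap
    return np.array(
        [
            promoter - p["k_deg"] * OP,
            promoter - p["k_deg"] * G - seq_G,
            lsrR_syn - p["k_deg"] * R - seq_R,
            uptake - seq_R - seq_G,
            0.0,
            -uptake,
            seq_R - p["k_deg"] * C_R,
            seq_G - p["k_deg"] * C_G,
            promoter - p["k_deg"] * Y,
        ]
    )
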