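"""Independent mass-action ODE oracles.

These integrate the explicit kinetic rate equations of the binding /
transcription-cycle reaction network to stationarity with scipy's stiff
integrator and report the steady-state pools.  They share no code path with
the package's scalar root-find / fixed-point solvers beyond the parameter
values, so agreement is a genuine cross-check.

All quantities are molar.  Reaction scheme per sigma species i:

    E + s_i <-> H_i                     kon_i / koff_i = kon_i * K_i
    A_i + s_i <-> AS_i                  (anti-sigma, optional)
    E + D <-> ED,  H_i + D <-> H_iD     (non-specific, D in excess, optional)
    H_i + P_g <-> C_g                   kon_p / koff_p
    C_g -> X_g (+ 0)                    kinit          (elongation starts)
    X_g -> Y_g + s_i                    v / L_ret      (sigma released)
    Y_g -> E                            v / (L_op - L_ret)
    [holoenzyme release: C_g -> Z_g -> H_i, rates kinit and v / L_op]
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def free_binding_ode(species, core_total, *, ns=None, d_conc=0.0,
                     t_end=1e6, rtol=1e-11, atol=1e-20):
    """Steady state of the bare binding network (+ optional anti-sigma, NS).

    ``species``: list of dicts with keys total, kd, kon and optionally
    anti_total, kd_anti; ``ns``: dict with kd_core and per-species kd_holo
    lists when non-specific binding is included.

    Returns dict: free_core, ns_core, and per species index free_sigma,
    holo (free), ns_holo, anti_complex.
    """
    n = len(species)
    kon = np.array([sp.get("kon", 1e8) for sp in species])
    koff = kon * np.array([sp["kd"] for sp in species])
    anti_tot = np.array([sp.get("anti_total", 0.0) for sp in species])
    kon_a = 1e8
    koff_a = kon_a * np.array([sp.get("kd_anti", 1.0) for sp in species])
    use_ns = ns is not None
    kon_ns = 1e6
    if use_ns:
        koff_ns_core = kon_ns * ns["kd_core"]
        koff_ns_holo = kon_ns * np.asarray(ns["kd_holo"])

    # y = [E, ED, s_0..s_{n-1}, H_0.., HD_0.., A_0.., AS_0..]
    def unpack(y):
        e, ed = y[0], y[1]
        s = y[2:2 + n]
        h = y[2 + n:2 + 2 * n]
        hd = y[2 + 2 * n:2 + 3 * n]
        a = y[2 + 3 * n:2 + 4 * n]
        c = y[2 + 4 * n:2 + 5 * n]
        return e, ed, s, h, hd, a, c

    def rhs(_, y):
        e, ed, s, h, hd, a, c = unpack(y)
        form = kon * e * s - koff * h
        dy = np.zeros_like(y)
        dy[0] = -form.sum()
        dy[2:2 + n] = -form
        dy[2 + n:2 + 2 * n] = form
        if use_ns:
            ecap = kon_ns * d_conc * e - koff_ns_core * ed
            dy[0] -= ecap
            dy[1] = ecap
            hcap = kon_ns * d_conc * h - koff_ns_holo * hd
            dy[2 + n:2 + 2 * n] -= hcap
            dy[2 + 2 * n:2 + 3 * n] = hcap
        seq = kon_a * a * s - koff_a * c
        seq = np.where(anti_tot > 0, seq, 0.0)
        dy[2:2 + n] -= seq
        dy[2 + 3 * n:2 + 4 * n] = -seq
        dy[2 + 4 * n:2 + 5 * n] = seq
        return dy

    y0 = np.zeros(2 + 5 * n)
    y0[0] = core_total
    y0[2:2 + n] = [sp["total"] for sp in species]
    y0[2 + 3 * n:2 + 4 * n] = anti_tot
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=rtol, atol=atol)
    assert sol.success
    y = sol.y[:, -1]
    resid = np.abs(rhs(0.0, y))
    assert np.all(resid * t_end < 1e-6 * max(core_total, 1e-12)), "not stationary"
    e, ed, s, h, hd, a, c = unpack(y)
    return {"free_core": e, "ns_core": ed, "free_sigma": s, "holo": h,
            "ns_holo": hd, "anti_complex": c}


def cycle_ode(species, core_total, promoters, *, t_end=1e6,
              rtol=1e-11, atol=1e-22, koff_p=10.0):
    """Steady state of binding + promoter + elongation kinetics.

    ``promoters``: list of dicts with keys cognate (species index), count
    (molar promoter concentration), km, kmax, L_op, L_ret, v, and
    release_mode.  kon_p is back-computed as (koff_p + kmax) / km so the
    Michaelis constant of the explicit scheme matches the model input.
    """
    n = len(species)
    m = len(promoters)
    kon = np.array([sp.get("kon", 1e8) for sp in species])
    koff = kon * np.array([sp["kd"] for sp in species])
    kinit = np.array([p["kmax"] for p in promoters])
    konp = np.array([(koff_p + p["kmax"]) / p["km"] for p in promoters])
    p_tot = np.array([p["count"] for p in promoters])
    cog = np.array([p["cognate"] for p in promoters], dtype=int)
    k_sig = np.array([p["v"] / p["L_ret"] for p in promoters])
    k_rest = np.array([p["v"] / max(p["L_op"] - p["L_ret"], 1e-9)
                       for p in promoters])
    k_full = np.array([p["v"] / p["L_op"] for p in promoters])
    holo_rel = np.array([p["release_mode"] == "holoenzyme_release"
                         for p in promoters])

    # y = [E, s_i.., H_i.., C_g.., X_g.., Y_g.., Z_g..]
    def unpack(y):
        e = y[0]
        s = y[1:1 + n]
        h = y[1 + n:1 + 2 * n]
        c = y[1 + 2 * n:1 + 2 * n + m]
        x = y[1 + 2 * n + m:1 + 2 * n + 2 * m]
        yy = y[1 + 2 * n + 2 * m:1 + 2 * n + 3 * m]
        z = y[1 + 2 * n + 3 * m:1 + 2 * n + 4 * m]
        return e, s, h, c, x, yy, z

    def rhs(_, y):
        e, s, h, c, x, yy, z = unpack(y)
        dy = np.zeros_like(y)
        form = kon * e * s - koff * h
        dy[0] = -form.sum()
        dy[1:1 + n] = -form
        dy[1 + n:1 + 2 * n] = form
        p_free = p_tot - c - 0.0  # only closed complexes occupy the promoter
        bind = konp * h[cog] * p_free - koff_p * c
        fire = kinit * c
        np.add.at(dy, 1 + n + cog, -bind)
        dy[1 + 2 * n:1 + 2 * n + m] = bind - fire
        # separate release: C -> X (sigma aboard) -> Y + sigma -> E
        sep = ~holo_rel
        dy[1 + 2 * n + m:1 + 2 * n + 2 * m] = np.where(sep, fire - k_sig * x, 0.0)
        dy[1 + 2 * n + 2 * m:1 + 2 * n + 3 * m] = np.where(
            sep, k_sig * x - k_rest * yy, 0.0)
        np.add.at(dy, 1 + cog, np.where(sep, k_sig * x, 0.0))
        dy[0] += (k_rest * yy)[sep].sum() if sep.any() else 0.0
        # holoenzyme release: C -> Z -> H
        dy[1 + 2 * n + 3 * m:1 + 2 * n + 4 * m] = np.where(
            holo_rel, fire - k_full * z, 0.0)
        np.add.at(dy, 1 + n + cog, np.where(holo_rel, k_full * z, 0.0))
        return dy

    y0 = np.zeros(1 + 2 * n + 4 * m)
    y0[0] = core_total
    y0[1:1 + n] = [sp["total"] for sp in species]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=rtol, atol=atol)
    assert sol.success
    y = sol.y[:, -1]
    resid = np.abs(rhs(0.0, y))
    assert np.all(resid * t_end < 1e-4 * max(core_total, 1e-12)), "not stationary"
    e, s, h, c, x, yy, z = unpack(y)
    elong = np.where(holo_rel, z, x + yy)
    retained = np.where(holo_rel, z, x)
    return {"free_core": e, "free_sigma": s, "holo": h,
            "promoter_bound": c, "elongating": elong, "retained_sigma": retained}
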