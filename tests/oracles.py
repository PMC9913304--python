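"""Independent brute-force oracles for the net-survival estimator.

Deliberately written with explicit scalar loops (no shared code with the
package implementation) following the documented numerical convention:
the population-hazard integral uses the midpoint rule on the partition
cut at entry/exit times, grid points and per-subject hazard breakpoints
(up to each subject's exit), refined to a maximum subinterval length.
"""
import math


def expected_cumhaz_oracle(life_table, a0, y0, t):
    """Scalar piecewise integration of the population hazard."""
    h = 0.0
    u = 0.0
    while u < t - 1e-15:
        nxt = min(math.floor(a0 + u) + 1 - a0, math.floor(y0 + u) + 1 - y0, t)
        if nxt <= u + 1e-15:
            nxt = min(u + 1.0, t)
        mid = 0.5 * (u + nxt)
        age = min(int(math.floor(a0 + mid)), life_table.n_ages - 1)
        year = int(math.floor(y0 + mid))
        lam = float(life_table.hazards[year - life_table.year_start, age])
        h += lam * (nxt - u)
        u = nxt
    return h


def _subject_breaks(a0, y0, t_exit):
    """Integer attained-age/year crossings strictly inside (0, t_exit)."""
    out = []
    for x0 in (a0, y0):
        u = math.ceil(x0) - x0
        if u == 0.0:
            u = 1.0
        while u < t_exit:
            out.append(u)
            u += 1.0
    return out


def pohar_perme_oracle(records, life_table, grid, entry=None, step=0.05):
    """Event-time loop implementation of the weighted net-survival
    estimator; returns (S_E, var_S) lists aligned with ``grid``."""
    n = len(records)
    e = [0.0] * n if entry is None else [float(v) for v in entry]
    T = [float(r.follow_up) for r in records]
    died = [r.status == "died" for r in records]
    a0 = [float(r.age_at_dx) for r in records]
    y0 = [float(r.dx_year) for r in records]
    t_max = float(max(grid))

    def w(i, t):
        return math.exp(expected_cumhaz_oracle(life_table, a0[i], y0[i], t))

    # ---- partition for the population-hazard integral -------------------
    pts = {0.0, t_max}
    for arr in (e, T, list(grid)):
        for v in arr:
            if 0.0 < v < t_max:
                pts.add(float(v))
    for i in range(n):
        for u in _subject_breaks(a0[i], y0[i], min(T[i], t_max)):
            if 0.0 < u < t_max:
                pts.add(u)
    base = sorted(pts)
    part = [0.0]
    for u0, u1 in zip(base[:-1], base[1:]):
        k = max(1, int(math.ceil((u1 - u0) / step - 1e-12)))
        for j in range(1, k):
            part.append(u0 + (u1 - u0) * j / k)
        part.append(u1)  # exact endpoint (grid/entry/exit values must round-trip)

    # ---- population-hazard term (midpoint rule) --------------------------
    pop_at = {0.0: 0.0}
    acc = 0.0
    for u0, u1 in zip(part[:-1], part[1:]):
        m = 0.5 * (u0 + u1)
        num = den = 0.0
        for i in range(n):
            if e[i] <= u0 + 1e-12 and T[i] >= u1 - 1e-12:
                wi = w(i, m)
                age = min(int(math.floor(a0[i] + m)), life_table.n_ages - 1)
                year = int(math.floor(y0[i] + m))
                lam = float(life_table.hazards[year - life_table.year_start, age])
                num += wi * lam
                den += wi
        if den > 0:
            acc += num / den * (u1 - u0)
        pop_at[u1] = acc

    # ---- event terms at exact death times --------------------------------
    death_times = sorted({T[i] for i in range(n) if died[i] and T[i] <= t_max})
    ev_cum, var_cum = [], []
    ev = va = 0.0
    for tk in death_times:
        den = 0.0
        for j in range(n):
            if e[j] < tk and T[j] >= tk:
                den += w(j, tk)
        for i in range(n):
            if died[i] and T[i] == tk:
                wi = w(i, tk)
                ev += wi / den
                va += wi * wi / (den * den)
        ev_cum.append(ev)
        var_cum.append(va)

    # ---- assemble on the requested grid ----------------------------------
    S, V = [], []
    for t in grid:
        evt = vat = 0.0
        for k, tk in enumerate(death_times):
            if tk <= t:
                evt, vat = ev_cum[k], var_cum[k]
        # the partition contains every grid point exactly
        popt = pop_at[float(t)]
        lam = evt - popt
        s = math.exp(-lam)
        S.append(s)
        V.append(s * s * vat)
    return S, V


def nelson_aalen_oracle(records, grid):
    """exp(-Nelson-Aalen) by explicit loops (zero life table reduction).

    The cumulative hazard is accumulated with independent loop code; the
    final exponential uses numpy's exp so that bitwise equality of the
    hazards implies bitwise equality of the survival values (math.exp and
    the vectorized exp can differ by one ulp on identical inputs).
    """
    import numpy as _np

    T = [float(r.follow_up) for r in records]
    died = [r.status == "died" for r in records]
    death_times = sorted({t for t, d in zip(T, died) if d})
    na_vals = []
    for t in grid:
        na = 0.0
        for tk in death_times:
            if tk <= t:
                d = sum(1 for i in range(len(T)) if died[i] and T[i] == tk)
                y = sum(1 for i in range(len(T)) if T[i] >= tk)
                na += d / y
        na_vals.append(na)
    return _np.exp(-_np.array(na_vals))
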