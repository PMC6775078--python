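"""Independent brute-force reference for one simulation day.

A deliberately slow, scalar, dictionary-driven re-evaluation of every
contact-scene equation, band transition, activation and retirement rule,
written without reference to the vectorized scheduler so the two can be
compared exactly.
"""

from __future__ import annotations

import numpy as np

S, R, M = 0, 1, 2


def classify(e: float) -> str:
    if e <= 0.33:
        return "negative"
    if e <= 0.66:
        return "immune"
    return "positive"


def reference_step(
    roles,
    emotions,
    d,
    w,
    b,
    days_active,
    contacts,
    *,
    a,
    v,
    f_s,
    f_r,
    lambda_gate=0.0,
    spreader_active_days=3,
    variant="convergent",
    r_sr_override=None,
    u=None,
):
    """One day of the model, evaluated pair by pair in list order.

    ``u`` is the per-agent uniform vector driving spontaneous activations
    (pass the same draws the scheduler will consume).  Returns
    (roles, emotions, days_active) as plain lists.
    """
    n = len(roles)
    roles_t = list(roles)  # roles frozen at day start
    e = [float(x) for x in emotions]
    contacted = [False] * n

    def prob(receiver):
        if r_sr_override is not None:
            return float(r_sr_override)
        return w[receiver] * b[receiver] * a * v

    def clamp(x):
        return min(1.0, max(0.0, x))

    for i, j in contacts:
        ri, rj = roles_t[i], roles_t[j]
        if ri == M and rj == M:
            continue
        if ri == rj:  # S-S or R-R: simultaneous pair update
            p_i, p_j = prob(i), prob(j)
            gi, gj = p_i >= lambda_gate, p_j >= lambda_gate
            ei, ej = e[i], e[j]
            if variant == "as_printed":
                new_i = d[i] * ei + (ei - ej) * p_i
                new_j = d[j] * ej + (ej - ei) * p_j
            else:
                new_i = d[i] * ei + (ej - ei) * p_i
                new_j = d[j] * ej + (ei - ej) * p_j
            if gi:
                e[i] = clamp(new_i)
                contacted[i] = True
            if gj:
                e[j] = clamp(new_j)
                contacted[j] = True
        else:
            # cross-role: the more active member is the source
            if ri == S or (ri == R and rj == M):
                src, recv = i, j
            else:
                src, recv = j, i
            if roles_t[recv] == S:
                continue  # an S never receives from an R
            p = prob(recv)
            if p >= lambda_gate:
                e[recv] = clamp(d[recv] * e[recv] + (e[src] - e[recv]) * p)
                contacted[recv] = True

    for i in range(n):
        if not contacted[i]:
            e[i] = clamp(d[i] * e[i])

    new_roles = list(roles_t)
    new_days = list(days_active)
    for i in range(n):
        if not contacted[i]:
            continue
        band = classify(e[i])
        if roles_t[i] == M and band != "immune":
            new_roles[i] = R
        elif roles_t[i] in (S, R) and band == "immune":
            new_roles[i] = M
            new_days[i] = 0

    if u is None:
        u = np.ones(n)
    for i in range(n):
        if new_roles[i] == M:
            if u[i] < f_s:
                new_roles[i] = S
                new_days[i] = 0
            elif u[i] < f_s + f_r:
                new_roles[i] = R

    for i in range(n):
        if roles_t[i] == S and new_roles[i] == S:
            new_days[i] += 1
            if new_days[i] >= spreader_active_days:
                new_roles[i] = R
    return new_roles, e, new_days
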