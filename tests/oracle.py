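"""Deliberately naive straight-line transcription of the TRI-B formulas.

Used only as an independent cross-check of the engine: plain Python
floats and loops, no shared code with ``vawrisk.electre``.
"""


def naive_partial_concordance(gx, gb, q, p):
    diff = gb - gx
    if diff < q:
        return 1.0
    elif diff >= p:
        return 0.0
    else:
        return (p - diff) / (p - q)


def naive_partial_discordance(gx, gb, p, v):
    diff = gb - gx
    if diff < p:
        return 0.0
    elif diff >= v:
        return 1.0
    else:
        return (diff - p) / (v - p)


def naive_sigma(x, b, qs, ps, vs, ws):
    """Credibility sigma(x, b) for plain lists of evaluations/parameters."""
    cs = []
    for j in range(len(x)):
        cs.append(naive_partial_concordance(x[j], b[j], qs[j], ps[j]))
    num = 0.0
    den = 0.0
    for j in range(len(x)):
        num += ws[j] * cs[j]
        den += ws[j]
    C = num / den
    sigma = C
    for j in range(len(x)):
        D = naive_partial_discordance(x[j], b[j], ps[j], vs[j])
        if D > C:
            sigma = sigma * (1.0 - D) / (1.0 - C)
    return sigma


def naive_pessimistic(x, profiles, qs, ps, vs, ws, lam):
    """profiles: list of n profile vectors b_1..b_n (ascending)."""
    n = len(profiles)
    for h in range(n, 0, -1):
        if naive_sigma(x, profiles[h - 1], qs, ps, vs, ws) >= lam:
            return h + 1
    return 1


def naive_optimistic(x, profiles, qs, ps, vs, ws, lam):
    n = len(profiles)
    for h in range(1, n + 1):
        b = profiles[h - 1]
        b_over_x = naive_sigma(b, x, qs, ps, vs, ws) >= lam
        x_over_b = naive_sigma(x, b, qs, ps, vs, ws) >= lam
        if b_over_x and not x_over_b:
            return h
    return n + 1
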