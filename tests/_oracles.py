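"""Independent brute-force oracles shared by the ternary and acceptance tests."""

import numpy as np

from pharmsel.ternary import TernaryModel


def bisect_oracle(model, l_tot, n_iter=120):
    """Independent nested plain-bisection solve over (free R, free G)."""
    k_l = 10.0**-model.p_k_l
    k_g = 10.0**-model.p_k_g
    a = model.alpha

    def free_l(r, g):
        return l_tot / (1.0 + r / k_l + a * r * g / (k_l * k_g))

    def r_used(r, g):
        l = free_l(r, g)
        return r * (1.0 + l / k_l + g / k_g + a * g * l / (k_l * k_g))

    def solve_r(g):
        lo, hi = 0.0, model.r_tot
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            if r_used(mid, g) < model.r_tot:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def g_used(g):
        r = solve_r(g)
        l = free_l(r, g)
        return g * (1.0 + r / k_g + a * r * l / (k_l * k_g))

    if model.g_tot == 0:
        g = 0.0
    else:
        lo, hi = 0.0, model.g_tot
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            if g_used(mid) < model.g_tot:
                lo = mid
            else:
                hi = mid
        g = 0.5 * (lo + hi)
    r = solve_r(g)
    l = free_l(r, g)
    return {
        "R": r, "G": g, "L": l,
        "LR": r * l / k_l, "RG": r * g / k_g, "LRG": a * r * g * l / (k_l * k_g),
    }


def random_model(rng):
    return TernaryModel(
        p_k_l=rng.uniform(5.0, 10.0),
        alpha=10.0 ** rng.uniform(0.0, 4.0),
        p_k_g=rng.uniform(6.0, 10.0),
        r_tot=10.0 ** rng.uniform(-12.0, -8.0),
        g_tot=0.0 if rng.random() < 0.15 else 10.0 ** rng.uniform(-10.0, -6.0),
    )
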