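"""Numba photon-transport kernel for infinitely wide layered slabs.

Weighted (implicit-capture) MCML-style random walk: hop-drop-spin with
Henyey-Greenstein deflection, Fresnel-governed boundary events, and Russian
roulette.  Only depth matters (infinitely wide layers), so the photon state
is (z, direction, weight, layer).  Photons are processed serially inside a
chunk; chunk seeding lives in :mod:`tissuelight.transport`.
"""

import math

import numpy as np
from numba import njit

__all__ = ["transport_chunk", "fresnel_unpolarized", "hg_cosine"]


@njit(cache=True, inline="always")
def fresnel_unpolarized(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_i``.

    Returns exactly 1.0 beyond the critical angle.
    """
    if n1 == n2:
        return 0.0
    cos_i = min(max(cos_i, 0.0), 1.0)
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t * sin_t))
    if cos_i < 1e-12:  # grazing incidence below TIR: reflectance -> 1
        return 1.0
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def hg_cosine(g, u):
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine."""
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return min(1.0, max(-1.0, c))


@njit(cache=True)
def transport_chunk(
    n_photons,
    mu_a,
    mu_s,
    g,
    n_idx,
    boundaries,  # cumulative depths, len n_layers + 1, boundaries[0] = 0
    n_above,
    n_below,
    w_threshold,
    roulette_m,
    seed,
):
    """Trace ``n_photons`` pencil-beam photons through the layer stack.

    Returns (reflected, transmitted, absorbed) weight sums; the specular
    fraction is removed before launch by the caller (photons start with
    weight ``1 - R_specular``).
    """
    np.random.seed(seed)
    n_layers = mu_a.shape[0]
    r_spec = fresnel_unpolarized(n_above, n_idx[0], 1.0)
    w0 = 1.0 - r_spec
    inv_m = 1.0 / roulette_m

    sum_refl = 0.0
    sum_trans = 0.0
    sum_abs = 0.0

    for _ in range(n_photons):
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w0
        layer = 0
        s_left = 0.0  # dimensionless step remaining
        alive = True
        steps = 0

        while alive:
            # hard cap against pathological trapped trajectories (e.g. total
            # internal reflection inside a clear layer); residual weight is
            # booked as absorbed
            steps += 1
            if steps > 10_000_000:
                sum_abs += w
                break
            mua = mu_a[layer]
            mus = mu_s[layer]
            mut = mua + mus

            if s_left <= 0.0:
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                s_left = -math.log(xi)

            # distance to the boundary along the current direction
            if uz > 1e-12:
                d_b = (boundaries[layer + 1] - z) / uz
            elif uz < -1e-12:
                d_b = (boundaries[layer] - z) / uz
            else:
                d_b = 1e30  # horizontal flight: interacts before any boundary

            if mut <= 0.0:
                # clear (glass-like) layer: ballistic to the boundary
                hit_boundary = True
                step = d_b
            elif s_left > mut * d_b:
                hit_boundary = True
                step = d_b
                s_left -= mut * d_b
            else:
                hit_boundary = False
                step = s_left / mut
                s_left = 0.0

            z += step * uz

            if hit_boundary:
                going_down = uz > 0.0
                if going_down:
                    next_layer = layer + 1
                    n_next = n_below if next_layer == n_layers else n_idx[next_layer]
                else:
                    next_layer = layer - 1
                    n_next = n_above if next_layer < 0 else n_idx[next_layer]
                ci = abs(uz)
                refl = fresnel_unpolarized(n_idx[layer], n_next, ci)
                if np.random.random() < refl:
                    uz = -uz  # internal reflection
                    # clamp back inside the layer
                    z = boundaries[layer + 1] if going_down else boundaries[layer]
                else:
                    # refract (Snell); direction cosines scale by n1/n2
                    ratio = n_idx[layer] / n_next
                    sin_i2 = max(0.0, 1.0 - ci * ci)
                    cos_t = math.sqrt(max(0.0, 1.0 - ratio * ratio * sin_i2))
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if going_down else -cos_t
                    if going_down and next_layer == n_layers:
                        sum_trans += w
                        alive = False
                    elif (not going_down) and next_layer < 0:
                        sum_refl += w
                        alive = False
                    else:
                        layer = next_layer
                        z = boundaries[layer] if going_down else boundaries[layer + 1]
                continue

            # interaction: drop
            dw = w * mua / mut
            sum_abs += dw
            w -= dw

            # spin: HG deflection + uniform azimuth
            cos_t = hg_cosine(g[layer], np.random.random())
            sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            phi = 2.0 * math.pi * np.random.random()
            cos_p = math.cos(phi)
            sin_p = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_t * cos_p
                uy = sin_t * sin_p
                uz = cos_t if uz > 0.0 else -cos_t
            else:
                temp = math.sqrt(1.0 - uz * uz)
                ux_new = sin_t * (ux * uz * cos_p - uy * sin_p) / temp + ux * cos_t
                uy_new = sin_t * (uy * uz * cos_p + ux * sin_p) / temp + uy * cos_t
                uz_new = -sin_t * cos_p * temp + uz * cos_t
                norm = math.sqrt(ux_new * ux_new + uy_new * uy_new + uz_new * uz_new)
                ux = ux_new / norm
                uy = uy_new / norm
                uz = uz_new / norm

            # Russian roulette
            if w < w_threshold:
                if np.random.random() < inv_m:
                    w *= roulette_m
                else:
                    alive = False

    return sum_refl, sum_trans, sum_abs
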