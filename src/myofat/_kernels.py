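"""Numba-accelerated Cauchy-stress kernels for the assembly hot path.

These reproduce :mod:`myofat.materials` exactly (a unit test compares the
two routes on random states); the numpy implementations remain the
reference — this module only exists because the finite-difference tangent
evaluates the constitutive law tens of thousands of times per Newton
iteration.  If numba is unavailable the solver falls back to the numpy
route.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):  # noqa: D103
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def _stress_batch(F, fib, act, fat, is_muscle,
                  K, Gphi, Gbeta, P1, P2, lofl, lstar, smax, fatc,
                  apoK, C1, C2, alpha, beta_apo, ksi, sig):
    n = F.shape[0]
    xs = lstar / lofl
    f_star = P1 * (np.exp(P2 * (xs - 1.0)) - 1.0)
    s_star = P1 * P2 * np.exp(P2 * (xs - 1.0))
    for e in range(n):
        F00 = F[e, 0, 0]; F01 = F[e, 0, 1]; F02 = F[e, 0, 2]
        F10 = F[e, 1, 0]; F11 = F[e, 1, 1]; F12 = F[e, 1, 2]
        F20 = F[e, 2, 0]; F21 = F[e, 2, 1]; F22 = F[e, 2, 2]
        J = (F00 * (F11 * F22 - F12 * F21)
             - F01 * (F10 * F22 - F12 * F20)
             + F02 * (F10 * F21 - F11 * F20))
        if J <= 0.0:
            sig[e, 0, 0] = np.nan
            continue
        s = J ** (-1.0 / 3.0)
        b00 = s * F00; b01 = s * F01; b02 = s * F02
        b10 = s * F10; b11 = s * F11; b12 = s * F12
        b20 = s * F20; b21 = s * F21; b22 = s * F22
        # Bbar = Fbar Fbar^T (symmetric)
        B00 = b00 * b00 + b01 * b01 + b02 * b02
        B01 = b00 * b10 + b01 * b11 + b02 * b12
        B02 = b00 * b20 + b01 * b21 + b02 * b22
        B11 = b10 * b10 + b11 * b11 + b12 * b12
        B12 = b10 * b20 + b11 * b21 + b12 * b22
        B22 = b20 * b20 + b21 * b21 + b22 * b22
        I1 = B00 + B11 + B22
        vol = K * np.log(J) / J

        t00 = 0.0; t01 = 0.0; t02 = 0.0; t11 = 0.0; t12 = 0.0; t22 = 0.0
        if is_muscle[e]:
            x_fat = fat[e] / 100.0
            a0 = fib[e, 0]; a1 = fib[e, 1]; a2 = fib[e, 2]
            m0 = b00 * a0 + b01 * a1 + b02 * a2
            m1 = b10 * a0 + b11 * a1 + b12 * a2
            m2 = b20 * a0 + b21 * a1 + b22 * a2
            I4 = m0 * m0 + m1 * m1 + m2 * m2
            c0 = b00 * m0 + b10 * m1 + b20 * m2  # Fbar^T m
            c1 = b01 * m0 + b11 * m1 + b21 * m2
            c2 = b02 * m0 + b12 * m1 + b22 * m2
            I5 = c0 * c0 + c1 * c1 + c2 * c2

            if x_fat < 1.0:
                lam = np.sqrt(I4)
                xx = lam / lofl
                # active force-length (piecewise quadratic)
                if xx < 0.4 or xx > 1.6:
                    fa = 0.0
                elif xx < 0.6:
                    fa = 9.0 * (xx - 0.4) ** 2
                elif xx <= 1.4:
                    fa = 1.0 - 4.0 * (1.0 - xx) ** 2
                else:
                    fa = 9.0 * (xx - 1.6) ** 2
                # passive (exponential, then linear)
                if xx <= 1.0:
                    fp = 0.0
                elif xx < xs:
                    fp = P1 * (np.exp(P2 * (xx - 1.0)) - 1.0)
                else:
                    fp = f_star + s_star * (xx - xs)
                sigf = smax * (act * fa + fp) * lam / lofl

                # Bbar m
                Bm0 = B00 * m0 + B01 * m1 + B02 * m2
                Bm1 = B01 * m0 + B11 * m1 + B12 * m2
                Bm2 = B02 * m0 + B12 * m1 + B22 * m2
                sqI4 = lam
                y = (I1 * I4 - I5) / (2.0 * sqI4)
                if y < 1.0:
                    y = 1.0
                eps = y - 1.0
                if eps < 1e-8:
                    gy = 1.0 - eps / 3.0
                else:
                    gy = np.arccosh(y) / np.sqrt(y * y - 1.0)
                cb = 2.0 * Gbeta * gy
                cf = sigf / I4
                cp = 2.0 * Gphi
                w4 = cp * (-2.0 * I5 / (I4 ** 3))
                # dy tensor pieces
                ha = I4 / (2.0 * sqI4)
                hb = I1 / (2.0 * sqI4) - y / (2.0 * I4)
                hc = -1.0 / (2.0 * sqI4)
                wmm = cf + w4 + 2.0 * cb * hb
                wmB = cp / (I4 * I4) + 2.0 * cb * hc
                wB = 2.0 * cb * ha
                t00 = wmm * m0 * m0 + wmB * 2.0 * m0 * Bm0 + wB * B00
                t01 = wmm * m0 * m1 + wmB * (m0 * Bm1 + m1 * Bm0) + wB * B01
                t02 = wmm * m0 * m2 + wmB * (m0 * Bm2 + m2 * Bm0) + wB * B02
                t11 = wmm * m1 * m1 + wmB * 2.0 * m1 * Bm1 + wB * B11
                t12 = wmm * m1 * m2 + wmB * (m1 * Bm2 + m2 * Bm1) + wB * B12
                t22 = wmm * m2 * m2 + wmB * 2.0 * m2 * Bm2 + wB * B22
                wmus = 1.0 - x_fat
                t00 *= wmus; t01 *= wmus; t02 *= wmus
                t11 *= wmus; t12 *= wmus; t22 *= wmus
            if x_fat > 0.0:
                cfat = 2.0 * fatc * x_fat
                t00 += cfat * B00
                t01 += cfat * B01
                t02 += cfat * B02
                t11 += cfat * B11
                t12 += cfat * B12
                t22 += cfat * B22
        else:
            # aponeurosis: Mooney-Rivlin matrix + tension-only fibers
            a0 = fib[e, 0]; a1 = fib[e, 1]; a2 = fib[e, 2]
            m0 = b00 * a0 + b01 * a1 + b02 * a2
            m1 = b10 * a0 + b11 * a1 + b12 * a2
            m2 = b20 * a0 + b21 * a1 + b22 * a2
            I4 = m0 * m0 + m1 * m1 + m2 * m2
            t00 = 2.0 * C1 * B00
            t01 = 2.0 * C1 * B01
            t02 = 2.0 * C1 * B02
            t11 = 2.0 * C1 * B11
            t12 = 2.0 * C1 * B12
            t22 = 2.0 * C1 * B22
            if C2 != 0.0:
                BB00 = B00 * B00 + B01 * B01 + B02 * B02
                BB01 = B00 * B01 + B01 * B11 + B02 * B12
                BB02 = B00 * B02 + B01 * B12 + B02 * B22
                BB11 = B01 * B01 + B11 * B11 + B12 * B12
                BB12 = B01 * B02 + B11 * B12 + B12 * B22
                BB22 = B02 * B02 + B12 * B12 + B22 * B22
                t00 += 2.0 * C2 * (I1 * B00 - BB00)
                t01 += 2.0 * C2 * (I1 * B01 - BB01)
                t02 += 2.0 * C2 * (I1 * B02 - BB02)
                t11 += 2.0 * C2 * (I1 * B11 - BB11)
                t12 += 2.0 * C2 * (I1 * B12 - BB12)
                t22 += 2.0 * C2 * (I1 * B22 - BB22)
            eI4 = I4 - 1.0
            if eI4 > 0.0:
                if alpha == 0.0:
                    dW = ksi * eI4 ** (beta_apo - 1.0)
                else:
                    dW = ksi * eI4 ** (beta_apo - 1.0) * np.exp(alpha * eI4 ** beta_apo)
                cfb = 2.0 * dW
                t00 += cfb * m0 * m0
                t01 += cfb * m0 * m1
                t02 += cfb * m0 * m2
                t11 += cfb * m1 * m1
                t12 += cfb * m1 * m2
                t22 += cfb * m2 * m2
            vol = apoK * np.log(J) / J

        tr3 = (t00 + t11 + t22) / 3.0
        sig[e, 0, 0] = (t00 - tr3) / J + vol
        sig[e, 0, 1] = t01 / J
        sig[e, 0, 2] = t02 / J
        sig[e, 1, 0] = t01 / J
        sig[e, 1, 1] = (t11 - tr3) / J + vol
        sig[e, 1, 2] = t12 / J
        sig[e, 2, 0] = t02 / J
        sig[e, 2, 1] = t12 / J
        sig[e, 2, 2] = (t22 - tr3) / J + vol
    return sig


def stress_batch(F, fib, act, fat, is_muscle, mp, ap):
    """Cauchy stresses for a flat batch of states (muscle mixture where
    ``is_muscle``, aponeurosis elsewhere)."""
    sig = np.empty_like(F)
    _stress_batch(
        F, fib, float(act), fat, is_muscle,
        mp.K, mp.G_phi, mp.G_beta, mp.P1, mp.P2, mp.lambda_ofl, mp.lambda_star,
        mp.sigma_max, mp.fat_coeff,
        ap.K, ap.C1, ap.C2, ap.alpha_apo, ap.beta_apo, ap.ksi,
        sig,
    )
    if np.isnan(sig[:, 0, 0]).any():
        raise FloatingPointError("element inversion")
    return sig


@njit(cache=True)
def _element_forces_loop(ue, dNdX, wvol, fib, act, fat, is_muscle,
                         K, Gphi, Gbeta, P1, P2, lofl, lstar, smax, fatc,
                         apoK, C1, C2, alpha, beta_apo, ksi, fe):
    """Internal force vectors for a batch of elements (single fused loop).

    Returns 0 on success, 1 if any integration point has det(F) <= 0."""
    nelem, ngp, npe = dNdX.shape[0], dNdX.shape[1], dNdX.shape[2]
    F = np.empty((1, 3, 3))
    sig = np.empty((1, 3, 3))
    fib1 = np.empty((1, 3))
    fat1 = np.empty(1)
    mus1 = np.empty(1, dtype=np.bool_)
    xs = lstar / lofl
    bad = 0
    for e in range(nelem):
        fib1[0, 0] = fib[e, 0]
        fib1[0, 1] = fib[e, 1]
        fib1[0, 2] = fib[e, 2]
        fat1[0] = fat[e]
        mus1[0] = is_muscle[e]
        for a in range(npe):
            fe[e, a, 0] = 0.0
            fe[e, a, 1] = 0.0
            fe[e, a, 2] = 0.0
        for g in range(ngp):
            for i in range(3):
                for j in range(3):
                    s = 1.0 if i == j else 0.0
                    for a in range(npe):
                        s += ue[e, a, i] * dNdX[e, g, a, j]
                    F[0, i, j] = s
            J = (F[0, 0, 0] * (F[0, 1, 1] * F[0, 2, 2] - F[0, 1, 2] * F[0, 2, 1])
                 - F[0, 0, 1] * (F[0, 1, 0] * F[0, 2, 2] - F[0, 1, 2] * F[0, 2, 0])
                 + F[0, 0, 2] * (F[0, 1, 0] * F[0, 2, 1] - F[0, 1, 1] * F[0, 2, 0]))
            if J <= 0.0:
                bad = 1
                continue
            _stress_batch(F, fib1, act, fat1, mus1,
                          K, Gphi, Gbeta, P1, P2, lofl, lstar, smax, fatc,
                          apoK, C1, C2, alpha, beta_apo, ksi, sig)
            # Finv via adjugate / J
            i00 = (F[0, 1, 1] * F[0, 2, 2] - F[0, 1, 2] * F[0, 2, 1]) / J
            i01 = (F[0, 0, 2] * F[0, 2, 1] - F[0, 0, 1] * F[0, 2, 2]) / J
            i02 = (F[0, 0, 1] * F[0, 1, 2] - F[0, 0, 2] * F[0, 1, 1]) / J
            i10 = (F[0, 1, 2] * F[0, 2, 0] - F[0, 1, 0] * F[0, 2, 2]) / J
            i11 = (F[0, 0, 0] * F[0, 2, 2] - F[0, 0, 2] * F[0, 2, 0]) / J
            i12 = (F[0, 0, 2] * F[0, 1, 0] - F[0, 0, 0] * F[0, 1, 2]) / J
            i20 = (F[0, 1, 0] * F[0, 2, 1] - F[0, 1, 1] * F[0, 2, 0]) / J
            i21 = (F[0, 0, 1] * F[0, 2, 0] - F[0, 0, 0] * F[0, 2, 1]) / J
            i22 = (F[0, 0, 0] * F[0, 1, 1] - F[0, 0, 1] * F[0, 1, 0]) / J
            w = wvol[e, g] * J
            # P = J sig F^-T  (P_ij = J sig_ik Finv_jk)
            P00 = w * (sig[0, 0, 0] * i00 + sig[0, 0, 1] * i01 + sig[0, 0, 2] * i02)
            P01 = w * (sig[0, 0, 0] * i10 + sig[0, 0, 1] * i11 + sig[0, 0, 2] * i12)
            P02 = w * (sig[0, 0, 0] * i20 + sig[0, 0, 1] * i21 + sig[0, 0, 2] * i22)
            P10 = w * (sig[0, 1, 0] * i00 + sig[0, 1, 1] * i01 + sig[0, 1, 2] * i02)
            P11 = w * (sig[0, 1, 0] * i10 + sig[0, 1, 1] * i11 + sig[0, 1, 2] * i12)
            P12 = w * (sig[0, 1, 0] * i20 + sig[0, 1, 1] * i21 + sig[0, 1, 2] * i22)
            P20 = w * (sig[0, 2, 0] * i00 + sig[0, 2, 1] * i01 + sig[0, 2, 2] * i02)
            P21 = w * (sig[0, 2, 0] * i10 + sig[0, 2, 1] * i11 + sig[0, 2, 2] * i12)
            P22 = w * (sig[0, 2, 0] * i20 + sig[0, 2, 1] * i21 + sig[0, 2, 2] * i22)
            for a in range(npe):
                d0 = dNdX[e, g, a, 0]
                d1 = dNdX[e, g, a, 1]
                d2 = dNdX[e, g, a, 2]
                fe[e, a, 0] += P00 * d0 + P01 * d1 + P02 * d2
                fe[e, a, 1] += P10 * d0 + P11 * d1 + P12 * d2
                fe[e, a, 2] += P20 * d0 + P21 * d1 + P22 * d2
    return bad


def element_forces(ue, dNdX, wvol, fib, act, fat, is_muscle, mp, ap):
    """Batched element internal forces through the fused numba loop."""
    fe = np.empty_like(ue)
    bad = _element_forces_loop(
        ue, dNdX, wvol, fib, float(act), fat, is_muscle,
        mp.K, mp.G_phi, mp.G_beta, mp.P1, mp.P2, mp.lambda_ofl, mp.lambda_star,
        mp.sigma_max, mp.fat_coeff,
        ap.K, ap.C1, ap.C2, ap.alpha_apo, ap.beta_apo, ap.ksi,
        fe,
    )
    if bad:
        raise FloatingPointError("element inversion")
    return fe
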