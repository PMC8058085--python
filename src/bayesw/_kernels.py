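"""Compiled inner loop of the Gibbs marker sweep.

One call processes a synchronisation window of markers against a frozen
residual snapshot: it gathers the three carrier partial sums, forms the
adaptive Gauss-Hermite slab marginals and the Dirac-spike term on their
common scale, draws the mixture indicator from pre-supplied uniforms, and
records exclusion messages.  It returns to Python whenever a marker enters a
slab so the effect can be drawn by adaptive rejection sampling there; the
kernel is then resumed at the next position.

No random state lives here: the caller supplies one uniform per marker, which
keeps serial and bulk-synchronous runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["window_sweep", "STATUS_DONE", "STATUS_ARS",
           "STATUS_NUMERIC_ERROR", "STATUS_MESSAGE"]

STATUS_DONE = 0
STATUS_ARS = 1
STATUS_NUMERIC_ERROR = 2
STATUS_MESSAGE = 3

_LOG_SQRT_PI = 0.5723649429247001
_SQRT2 = 1.4142135623730951


@njit(cache=True)
def window_sweep(order, p0, p1,
                 indptr1, idx1, indptr2, idx2, indptrm, idxm,
                 xbar, sd, dx,
                 w, wu, w_mult, wu_mult, stot_w, stot_wu, has_trunc,
                 beta, gamma,
                 group_of, mix_c, mix_len, log_pi, sigma2_g,
                 alpha, tpts, logw_mod, uniforms, u_base,
                 msg_j, msg_db, msg_count, stop_on_msg):
    """Process order[p0:p1]; see module docstring.

    Returns (p_next, j, k, v0, v1, v2, vmiss, msg_count, status); the partial sums
    are on the true (multiplier-folded) scale with the marker's own current
    effect added back, ready for the slab ARS target.
    """
    m_quad = tpts.shape[0]
    expo = np.empty(m_quad)
    lmax_groups = log_pi.shape[1]
    logm = np.empty(lmax_groups)

    for p in range(p0, p1):
        j = order[p]
        s1w = 0.0
        for ii in range(indptr1[j], indptr1[j + 1]):
            s1w += w[idx1[ii]]
        s2w = 0.0
        for ii in range(indptr2[j], indptr2[j + 1]):
            s2w += w[idx2[ii]]
        smw = 0.0
        for ii in range(indptrm[j], indptrm[j + 1]):
            smw += w[idxm[ii]]
        v1 = s1w * w_mult
        v2 = s2w * w_mult
        vm = smw * w_mult
        if has_trunc:
            s1u = 0.0
            for ii in range(indptr1[j], indptr1[j + 1]):
                s1u += wu[idx1[ii]]
            s2u = 0.0
            for ii in range(indptr2[j], indptr2[j + 1]):
                s2u += wu[idx2[ii]]
            smu = 0.0
            for ii in range(indptrm[j], indptrm[j + 1]):
                smu += wu[idxm[ii]]
            v1 -= s1u * wu_mult
            v2 -= s2u * wu_mult
            vm -= smu * wu_mult
        vtot = stot_w * w_mult - stot_wu * wu_mult
        v0 = vtot - v1 - v2 - vm

        xb = xbar[j]
        s = sd[j]
        # add back the marker's own effect so v,u correspond to beta_j = 0
        if beta[j] != 0.0:
            b_old = beta[j]
            arg = -alpha * xb * b_old / s
            cf = np.exp(min(arg, 700.0))
            g1 = np.exp(min(alpha * b_old / s, 700.0))
            v0 = cf * v0
            v1 = cf * g1 * v1
            v2 = cf * g1 * g1 * v2
        vnm = v0 + v1 + v2

        g = group_of[j]
        n_slabs = mix_len[g]
        x2sum = ((1.0 - 2.0 * xb) * v1 + 4.0 * (1.0 - xb) * v2
                 + xb * xb * vnm) / (s * s)
        logm[0] = log_pi[g, 0] + _LOG_SQRT_PI
        for k in range(1, n_slabs + 1):
            ck = mix_c[g, k - 1]
            rad = 1.0 + alpha * alpha * ck * sigma2_g[g] * x2sum
            if rad <= 0.0:
                return p, j, k, v0, v1, v2, vm, msg_count, STATUS_NUMERIC_ERROR
            shat = 1.0 / (_SQRT2 * np.sqrt(rad))
            lam_c = shat * _SQRT2 * np.sqrt(2.0 * ck * sigma2_g[g])
            emax = -1e308
            for r in range(m_quad):
                br = alpha * lam_c * tpts[r]
                brs = br / s
                e0 = np.exp(min(brs * xb, 700.0))
                e1 = np.exp(min(-brs, 700.0))
                e2 = np.exp(min(-2.0 * brs, 700.0))
                qsum = vnm - e0 * (v0 + e1 * v1 + e2 * v2)
                val = (-br * dx[j] + qsum
                       - 2.0 * shat * shat * tpts[r] * tpts[r] + logw_mod[r])
                expo[r] = val
                if val > emax:
                    emax = val
            acc = 0.0
            for r in range(m_quad):
                acc += np.exp(expo[r] - emax)
            logm[k] = (log_pi[g, k] + np.log(_SQRT2 * shat) + emax
                       + np.log(acc))

        lmax = logm[0]
        for k in range(1, n_slabs + 1):
            if logm[k] > lmax:
                lmax = logm[k]
        if not np.isfinite(lmax):
            return p, j, 0, v0, v1, v2, vm, msg_count, STATUS_NUMERIC_ERROR
        tot = 0.0
        for k in range(n_slabs + 1):
            tot += np.exp(logm[k] - lmax)
        uthr = uniforms[p - u_base] * tot
        cum = 0.0
        k_draw = n_slabs
        for k in range(n_slabs + 1):
            cum += np.exp(logm[k] - lmax)
            if uthr <= cum:
                k_draw = k
                break

        if k_draw == 0:
            if beta[j] != 0.0:
                msg_j[msg_count] = j
                msg_db[msg_count] = -beta[j]
                msg_count += 1
                beta[j] = 0.0
                gamma[j] = 0
                if stop_on_msg:
                    # serial schedule: the residual must change before the
                    # next marker is processed
                    return p, j, 0, v0, v1, v2, vm, msg_count, STATUS_MESSAGE
            gamma[j] = 0
        else:
            gamma[j] = k_draw
            return p, j, k_draw, v0, v1, v2, vm, msg_count, STATUS_ARS

    return p1, -1, 0, 0.0, 0.0, 0.0, 0.0, msg_count, STATUS_DONE
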