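"""Numba kernel for cyclic coordinate descent with per-feature penalties.

The kernel operates on an internally standardized design matrix stored in
Fortran order (contiguous columns) and maintains the residual vector in
place.  It only touches the coordinates listed in ``idx`` (ascending, so the
cyclic order is always plain column order); the caller is responsible for
screening and for the KKT certificate on the full coordinate set.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def cd_cycle(X, r, beta, idx, thr, denom, xx, tol, max_sweeps):
    """Cyclic coordinate descent over the columns in ``idx``.

    Solves min_b ||r0 - X b||^2 + sum_j (2*thr_j)|b_j| + (denom_j - xx_j) b_j^2
    coordinate-wise; ``r`` is the current residual and is updated in place,
    as is ``beta``.  Returns (sweeps run, hit tolerance?).
    """
    n = r.size
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for k in range(idx.size):
            j = idx[k]
            dj = denom[j]
            if dj <= 0.0:
                continue
            bj = beta[j]
            rho = bj * xx[j]
            for i in range(n):
                rho += X[i, j] * r[i]
            t = thr[j]
            if rho > t:
                new = (rho - t) / dj
            elif rho < -t:
                new = (rho + t) / dj
            else:
                new = 0.0
            d = new - bj
            if d != 0.0:
                beta[j] = new
                for i in range(n):
                    r[i] -= X[i, j] * d
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return sweep + 1, True
    return max_sweeps, False
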