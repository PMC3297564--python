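"""Hot loops for clash detection.

The clash rule is exact and exhaustive: a configuration clashes when ANY
cross-subunit heavy-atom pair is closer than the clash distance.  The numba
kernel is an early-exit brute force — identical in result to the O(n^2)
all-pairs oracle, just fast on the common deeply-clashed case.  A numpy
fallback keeps the package importable if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _clash_mask_batch(fixed, mobile, rots, trans, d2, out):  # pragma: no cover
    B = rots.shape[0]
    nm = mobile.shape[0]
    nf = fixed.shape[0]
    for b in range(B):
        clash = False
        for i in range(nm):
            mx = mobile[i, 0]
            my = mobile[i, 1]
            mz = mobile[i, 2]
            x = rots[b, 0, 0] * mx + rots[b, 0, 1] * my + rots[b, 0, 2] * mz + trans[b, 0]
            y = rots[b, 1, 0] * mx + rots[b, 1, 1] * my + rots[b, 1, 2] * mz + trans[b, 1]
            z = rots[b, 2, 0] * mx + rots[b, 2, 1] * my + rots[b, 2, 2] * mz + trans[b, 2]
            for j in range(nf):
                dx = fixed[j, 0] - x
                dy = fixed[j, 1] - y
                dz = fixed[j, 2] - z
                if dx * dx + dy * dy + dz * dz < d2:
                    clash = True
                    break
            if clash:
                break
        out[b] = clash
    return out


def _clash_mask_batch_numpy(fixed, mobile, rots, trans, d2, out):
    placed = np.einsum("bij,nj->bni", rots, mobile) + trans[:, None, :]
    diff = placed[:, :, None, :] - fixed[None, None, :, :]
    dist2 = np.einsum("bnfk,bnfk->bnf", diff, diff)
    out[:] = (dist2 < d2).any(axis=(1, 2))
    return out


def clash_mask(
    fixed: np.ndarray,
    mobile: np.ndarray,
    rots: np.ndarray,
    trans: np.ndarray,
    clash_distance: float,
) -> np.ndarray:
    """Boolean clash flag per configuration in a batch.

    ``rots`` is (B, 3, 3), ``trans`` (B, 3); placement of mobile atom x is
    R @ x + t.  Clash iff any cross pair distance < ``clash_distance``.
    """
    out = np.empty(len(rots), dtype=np.bool_)
    fn = _clash_mask_batch if _HAVE_NUMBA else _clash_mask_batch_numpy
    fn(
        np.ascontiguousarray(fixed, dtype=np.float64),
        np.ascontiguousarray(mobile, dtype=np.float64),
        np.ascontiguousarray(rots, dtype=np.float64),
        np.ascontiguousarray(trans, dtype=np.float64),
        float(clash_distance) ** 2,
        out,
    )
    return out


def has_clash(fixed: np.ndarray, mobile_placed: np.ndarray, clash_distance: float) -> bool:
    """Single-configuration clash test on already-placed mobile coordinates."""
    eye = np.eye(3)[None]
    zero = np.zeros((1, 3))
    return bool(clash_mask(fixed, mobile_placed, eye, zero, clash_distance)[0])
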