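"""Numba kernels for sequential Gibbs simulation of ALAAM attribute vectors.

Every model term is either static (its change statistic for node i does not
depend on y) or quadratic (z_t = 0.5 * y' U_t y for a symmetric, zero-diagonal
integer weight matrix U_t, so its change statistic is (U_t y)_i). The kernels
therefore only need, per node, a precomputed static contribution and CSR
neighbor lists with weights for each quadratic term.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def gibbs_sweeps(y, sdot, qtheta, qptr, qidx, qwgt, sweeps):
    """Sequential single-site Gibbs updates, in place.

    y       : int8[n] current attribute vector (mutated)
    sdot    : float64[n], static part of theta' delta_i (S @ theta)
    qtheta  : float64[Q], theta value of each quadratic term
    qptr    : int64[Q, n+1], absolute CSR row pointers into qidx/qwgt
    qidx    : int64[:], neighbor indices (concatenated over terms)
    qwgt    : float64[:], neighbor weights
    sweeps  : number of full passes over the nodes
    """
    n = y.shape[0]
    Q = qtheta.shape[0]
    for _ in range(sweeps):
        for i in range(n):
            v = sdot[i]
            for q in range(Q):
                acc = 0.0
                for k in range(qptr[q, i], qptr[q, i + 1]):
                    acc += qwgt[k] * y[qidx[k]]
                v += qtheta[q] * acc
            p1 = 1.0 / (1.0 + np.exp(-v))
            if np.random.random() < p1:
                y[i] = 1
            else:
                y[i] = 0


@njit(cache=True)
def gibbs_state_counts(y, sdot, qtheta, qptr, qidx, qwgt, sweeps, burn, counts):
    """Run the Gibbs chain and count visited states (n <= ~16).

    After ``burn`` sweeps, the state reached after each subsequent sweep is
    encoded as a bitmask sum_i y_i 2^i and tallied into ``counts``.
    """
    n = y.shape[0]
    Q = qtheta.shape[0]
    for s in range(sweeps):
        for i in range(n):
            v = sdot[i]
            for q in range(Q):
                acc = 0.0
                for k in range(qptr[q, i], qptr[q, i + 1]):
                    acc += qwgt[k] * y[qidx[k]]
                v += qtheta[q] * acc
            p1 = 1.0 / (1.0 + np.exp(-v))
            if np.random.random() < p1:
                y[i] = 1
            else:
                y[i] = 0
        if s >= burn:
            state = 0
            for i in range(n):
                if y[i] == 1:
                    state += 1 << i
            counts[state] += 1
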