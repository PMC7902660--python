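"""Numba kernels for the latent-state MCMC updates.

Layout: tree-years are flattened to one axis ``k`` (trees contiguous,
years ascending within a tree; ``tree_ptr`` is the CSR offset array).
Crop counts attach to tree-years through a CSR (``cc_ptr``); seed-trap
observations are "trap-years" ``j`` coupled to tree-years through source
pairs (``pair_ptr`` CSR from tree-year to trap-year, with precomputed
``area * K(r; u)`` weights).  ``lam`` holds the current Poisson intensity
of every trap-year and is kept incrementally up to date by the kernels.

Maturation is an absorbing state represented per tree by the changepoint
position ``cp`` (index of the first mature year within the tree's block;
``cp == n`` means never mature within the series).  Randomness enters only
through pre-drawn arrays, so runs are reproducible from the caller's seed.
"""

import math

import numpy as np
from numba import njit

_TINY = 1e-300
_NEG_INF = -1e30


@njit(cache=True)
def _prior_w(rho, b0, n, p):
    """Prior mass of changepoint position p under monotone-coupling maturation."""
    if p < n:
        prev = rho[b0 + p - 1] if p > 0 else 0.0
        w = rho[b0 + p] - prev
    else:
        w = 1.0 - rho[b0 + n - 1]
    return w if w > 0.0 else 0.0


@njit(cache=True)
def psi_sweep(log_psi, mature, mu, sig2k,
              cc_ptr, cc_count, cc_frac,
              pair_ptr, pair_tw, pair_ak, lam, tw_count,
              step, zn, un):
    """One Metropolis sweep over mature tree-year log-fecundities."""
    acc = 0
    ntot = 0
    n = log_psi.shape[0]
    for k in range(n):
        if mature[k] == 0:
            continue
        ntot += 1
        lp = log_psi[k]
        lpn = lp + step * zn[k]
        if lpn > 60.0:
            continue
        psi = math.exp(lp)
        psin = math.exp(lpn)
        d = (-(lpn - mu[k]) ** 2 + (lp - mu[k]) ** 2) / (2.0 * sig2k[k])
        for c in range(cc_ptr[k], cc_ptr[k + 1]):
            d += cc_count[c] * (lpn - lp) - cc_frac[c] * (psin - psi)
        for pidx in range(pair_ptr[k], pair_ptr[k + 1]):
            j = pair_tw[pidx]
            ln = lam[j] + pair_ak[pidx] * (psin - psi)
            if ln < _TINY:
                ln = _TINY
            if tw_count[j] > 0:
                lj = lam[j] if lam[j] > _TINY else _TINY
                d += tw_count[j] * (math.log(ln) - math.log(lj))
            d -= ln - lam[j]
        if math.log(un[k]) < d:
            acc += 1
            log_psi[k] = lpn
            for pidx in range(pair_ptr[k], pair_ptr[k + 1]):
                j = pair_tw[pidx]
                lam[j] += pair_ak[pidx] * (psin - psi)
                if lam[j] < 0.0:
                    lam[j] = 0.0
    return acc, ntot


@njit(cache=True)
def cp_sweep(cp, tree_ptr, limit, rho,
             log_psi, mature, mu, sig2k,
             cc_ptr, cc_count, cc_frac,
             pair_ptr, pair_tw, pair_ak, lam, tw_count,
             u_prop, u_acc, zn):
    """One Metropolis-Hastings sweep over per-tree maturation changepoints.

    Proposals come from the (data-constrained) changepoint prior; fecundities
    for newly mature years are proposed from their conditional prior, so the
    acceptance ratio reduces to the observation-likelihood ratio.  Monotone
    (absorbing) maturation holds by construction.
    """
    n_trees = cp.shape[0]
    acc = 0
    ntot = 0
    for i in range(n_trees):
        b0 = tree_ptr[i]
        n = tree_ptr[i + 1] - b0
        L = limit[i]
        if n == 0 or L == 0:
            continue
        maxp = L if L < n else n
        tot = 0.0
        for p in range(maxp + 1):
            tot += _prior_w(rho, b0, n, p)
        if tot <= 0.0:
            continue
        ntot += 1
        r = u_prop[i] * tot
        pnew = maxp
        csum = 0.0
        for p in range(maxp + 1):
            csum += _prior_w(rho, b0, n, p)
            if r <= csum:
                pnew = p
                break
        pold = cp[i]
        if pnew == pold:
            acc += 1
            continue
        lo = pold if pold < pnew else pnew
        hi = pold if pold > pnew else pnew
        adding = pnew < pold  # positions lo..hi-1 become mature
        # tentative fecundities for newly mature years (conditional prior draws)
        tmp = np.empty(hi - lo)
        dll = 0.0
        for off in range(hi - lo):
            k = b0 + lo + off
            if adding:
                lpk = mu[k] + math.sqrt(sig2k[k]) * zn[k]
                tmp[off] = lpk
            else:
                lpk = log_psi[k]
            psik = math.exp(lpk)
            s = 1.0 if adding else -1.0
            # crop counts in the switching range are zero by construction of
            # `limit` (positions with observed seed can never become immature),
            # so only the -fraction*psi rate term changes
            for c in range(cc_ptr[k], cc_ptr[k + 1]):
                dll -= s * cc_frac[c] * psik
            for pidx in range(pair_ptr[k], pair_ptr[k + 1]):
                j = pair_tw[pidx]
                ln = lam[j] + s * pair_ak[pidx] * psik
                if ln < 0.0:
                    ln = 0.0
                if tw_count[j] > 0:
                    a = ln if ln > _TINY else _TINY
                    b = lam[j] if lam[j] > _TINY else _TINY
                    dll += tw_count[j] * (math.log(a) - math.log(b))
                dll -= ln - lam[j]
        if math.log(u_acc[i]) < dll:
            acc += 1
            cp[i] = pnew
            for off in range(hi - lo):
                k = b0 + lo + off
                if adding:
                    log_psi[k] = tmp[off]
                    mature[k] = 1
                else:
                    mature[k] = 0
                psik = math.exp(log_psi[k])
                s = 1.0 if adding else -1.0
                for pidx in range(pair_ptr[k], pair_ptr[k + 1]):
                    j = pair_tw[pidx]
                    lam[j] += s * pair_ak[pidx] * psik
                    if lam[j] < 0.0:
                        lam[j] = 0.0
    return acc, ntot


@njit(cache=True)
def changepoint_logprior(cp, tree_ptr, rho):
    """Sum over trees of log prior mass of the current changepoints."""
    total = 0.0
    for i in range(cp.shape[0]):
        b0 = tree_ptr[i]
        n = tree_ptr[i + 1] - b0
        if n == 0:
            continue
        w = _prior_w(rho, b0, n, cp[i])
        if w < _TINY:
            w = _TINY
        total += math.log(w)
    return total
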