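"""Numba kernels for the coalescent TMRCA sampler.

Layout: a binary coalescent tree over n leaves stored as flat arrays
(leaves 0..n-1 at time 0, internals n..2n-2; the root is always index 2n-2
and only its children ever change). Per-marker likelihood uses Felsenstein
peeling over a bounded repeat-count window with single-step SMM branch
transition probabilities ``P(net change = k | lam) = exp(-lam) * I_k(lam)``
(lam = rate x branch length, I_k the modified Bessel function); the series is
evaluated directly for lam <= 30 and by the Gaussian limit of the compound
random walk beyond. Partial likelihoods carry cumulative per-node log-scales
to avoid underflow, and proposals recompute only the branches and root-ward
path they touch.
"""

import math

import numpy as np
from numba import njit

LAM_GAUSS = 30.0


@njit(cache=True)
def _pk_vector(lam, W, out):
    """out[k] = P(net repeat change = +-k) on a branch with expected
    mutation count lam, for k = 0..W-1."""
    if lam <= 0.0:
        for k in range(W):
            out[k] = 0.0
        out[0] = 1.0
        return
    if lam > LAM_GAUSS:
        norm = 1.0 / math.sqrt(2.0 * math.pi * lam)
        for k in range(W):
            out[k] = norm * math.exp(-0.5 * k * k / lam)
        return
    x = 0.25 * lam * lam
    for k in range(W):
        logt = -lam + k * math.log(0.5 * lam) - math.lgamma(k + 1.0)
        term = math.exp(logt)
        s = term
        j = 0
        while True:
            term *= x / ((j + 1.0) * (j + 1.0 + k))
            s += term
            j += 1
            if term < s * 1e-15 and j > lam:
                break
        out[k] = s


@njit(cache=True)
def _refresh_branch(v, m, parent, times, mu, W, trans_pk):
    lam = mu[m] * (times[parent[v]] - times[v])
    _pk_vector(lam, W[m], trans_pk[v, m])


@njit(cache=True)
def _refresh_node(v, m, child1, child2, W, trans_pk, partial, logscale):
    """Recompute the scaled partial likelihood of internal node v, marker m."""
    w = W[m]
    c1 = child1[v]
    c2 = child2[v]
    best = 0.0
    for s in range(w):
        a = 0.0
        b = 0.0
        for t in range(w):
            d = s - t if s >= t else t - s
            a += trans_pk[c1, m, d] * partial[c1, m, t]
            b += trans_pk[c2, m, d] * partial[c2, m, t]
        val = a * b
        partial[v, m, s] = val
        if val > best:
            best = val
    if best <= 0.0:
        logscale[v, m] = -np.inf
        return
    for s in range(w):
        partial[v, m, s] /= best
    logscale[v, m] = math.log(best) + logscale[c1, m] + logscale[c2, m]


@njit(cache=True)
def _total_loglik(root, W, partial, logscale):
    M = len(W)
    out = 0.0
    for m in range(M):
        s = 0.0
        for t in range(W[m]):
            s += partial[root, m, t]
        if s <= 0.0 or logscale[root, m] == -np.inf:
            return -np.inf
        out += math.log(s / W[m]) + logscale[root, m]
    return out


@njit(cache=True)
def _sort_order_by_time(order, times):
    for i in range(1, len(order)):
        key = order[i]
        j = i - 1
        while j >= 0 and times[order[j]] > times[key]:
            order[j + 1] = order[j]
            j -= 1
        order[j + 1] = key


@njit(cache=True)
def _full_refresh(n, parent, child1, child2, times, mu, W, trans_pk, partial, logscale, order):
    M = len(W)
    total = 2 * n - 1
    for v in range(total):
        if parent[v] != -1:
            for m in range(M):
                _refresh_branch(v, m, parent, times, mu, W, trans_pk)
    for i in range(len(order)):
        for m in range(M):
            _refresh_node(order[i], m, child1, child2, W, trans_pk, partial, logscale)


@njit(cache=True)
def _Nt(t, N, alpha, T0):
    if t >= T0 or alpha <= 0.0:
        return N
    return N * math.exp(alpha * (T0 - t))


@njit(cache=True)
def _Lambda(t, N, alpha, T0):
    # integral of 1/N(s) ds from 0 (present) to t (generations back)
    if alpha <= 0.0:
        return t / N
    if t <= T0:
        return (math.exp(-alpha * (T0 - t)) - math.exp(-alpha * T0)) / (alpha * N)
    head = (1.0 - math.exp(-alpha * T0)) / (alpha * N)
    return head + (t - T0) / N


@njit(cache=True)
def _coal_logprior(n, times, N, model, alpha, beta, sorted_buf):
    """Log density of the coalescence times (in generations) of n leaves.

    model 0: constant size N (pairwise rate 1/N). model 2: size N beyond
    scaled time beta (i.e. t > beta*N generations), exponential growth at
    per-generation rate alpha from that onset to the present.
    """
    for i in range(n - 1):
        sorted_buf[i] = times[n + i]
    sorted_buf.sort()
    logp = 0.0
    prev = 0.0
    lineages = n
    if model == 0:
        for i in range(n - 1):
            t = sorted_buf[i]
            pair = lineages * (lineages - 1) * 0.5
            logp += -pair * (t - prev) / N - math.log(N)
            prev = t
            lineages -= 1
        return logp
    T0 = beta * N
    for i in range(n - 1):
        t = sorted_buf[i]
        pair = lineages * (lineages - 1) * 0.5
        logp += -pair * (_Lambda(t, N, alpha, T0) - _Lambda(prev, N, alpha, T0))
        logp += -math.log(_Nt(t, N, alpha, T0))
        prev = t
        lineages -= 1
    return logp


@njit(cache=True)
def _collect_path(v, parent, mark):
    while v != -1:
        mark[v] = True
        v = parent[v]


@njit(cache=True)
def _dirty_list(mark, n, total, idx_buf):
    cnt = 0
    for j in range(n, total):
        if mark[j]:
            idx_buf[cnt] = j
            cnt += 1
    return cnt


@njit(cache=True)
def _refresh_dirty(idx_buf, cnt, times, child1, child2, W, trans_pk, partial, logscale):
    # children before parents: sort the dirty nodes by time
    for i in range(1, cnt):
        key = idx_buf[i]
        j = i - 1
        while j >= 0 and times[idx_buf[j]] > times[key]:
            idx_buf[j + 1] = idx_buf[j]
            j -= 1
        idx_buf[j + 1] = key
    M = len(W)
    for i in range(cnt):
        for m in range(M):
            _refresh_node(idx_buf[i], m, child1, child2, W, trans_pk, partial, logscale)


@njit(cache=True)
def _is_in_subtree(a, b, parent):
    """True if a lies in the subtree rooted at b (or equals b)."""
    while a != -1:
        if a == b:
            return True
        a = parent[a]
    return False


@njit(cache=True)
def run_chain(
    n,
    parent,
    child1,
    child2,
    times,
    W,
    trans_pk,
    partial,
    logscale,
    mu,
    mu_prior_mean,
    mu_prior_shape,
    N0,
    n_prior_mean,
    n_prior_shape,
    model,
    alpha0,
    alpha_rate,
    beta0,
    beta_rate,
    iterations,
    tree_moves,
    param_moves,
    seed,
    likelihood_on,
    fix_n,
    fix_mu,
    out_tmrca,
    out_N,
    out_alpha,
    out_beta,
    acc,
):
    """Metropolis-Hastings over (tree times + topology, N, mutation rates,
    growth parameters). One iteration = *tree_moves* attempted tree changes
    plus *param_moves* attempted parameter changes; the state after each
    iteration is recorded. acc counts accepted moves by kind
    (time, root, scale, swap, demography, mutation-rate)."""
    np.random.seed(seed)
    M = len(W)
    total = 2 * n - 1
    root = total - 1
    mark = np.zeros(total, dtype=np.bool_)
    idx_buf = np.zeros(total, dtype=np.int64)
    sorted_buf = np.zeros(n - 1, dtype=np.float64)
    bak_partial = np.zeros_like(partial)
    bak_logscale = np.zeros_like(logscale)
    bak_trans = np.zeros_like(trans_pk)

    order = np.arange(n, total).astype(np.int64)
    _sort_order_by_time(order, times)
    _full_refresh(n, parent, child1, child2, times, mu, W, trans_pk, partial, logscale, order)
    loglik = _total_loglik(root, W, partial, logscale) if likelihood_on else 0.0
    logcoal = _coal_logprior(n, times, N0, model, alpha0, beta0, sorted_buf)
    N = N0
    alpha = alpha0
    beta = beta0

    for it in range(iterations):
        for _ in range(tree_moves):
            u = np.random.random()
            ndirty = 0
            if u < 0.45 and n >= 3:
                # internal non-root node time, uniform within its bracket
                v = n + np.random.randint(n - 2)
                lower = max(times[child1[v]], times[child2[v]])
                upper = times[parent[v]]
                tnew = lower + np.random.random() * (upper - lower)
                told = times[v]
                times[v] = tnew
                new_logcoal = _coal_logprior(n, times, N, model, alpha, beta, sorted_buf)
                if likelihood_on:
                    c1 = child1[v]
                    c2 = child2[v]
                    for m in range(M):
                        bak_trans[v, m, :] = trans_pk[v, m, :]
                        bak_trans[c1, m, :] = trans_pk[c1, m, :]
                        bak_trans[c2, m, :] = trans_pk[c2, m, :]
                        _refresh_branch(v, m, parent, times, mu, W, trans_pk)
                        _refresh_branch(c1, m, parent, times, mu, W, trans_pk)
                        _refresh_branch(c2, m, parent, times, mu, W, trans_pk)
                    for j in range(total):
                        mark[j] = False
                    _collect_path(v, parent, mark)
                    ndirty = _dirty_list(mark, n, total, idx_buf)
                    for jj in range(ndirty):
                        for m in range(M):
                            bak_partial[idx_buf[jj], m, :] = partial[idx_buf[jj], m, :]
                            bak_logscale[idx_buf[jj], m] = logscale[idx_buf[jj], m]
                    _refresh_dirty(idx_buf, ndirty, times, child1, child2, W, trans_pk, partial, logscale)
                    new_loglik = _total_loglik(root, W, partial, logscale)
                else:
                    new_loglik = 0.0
                if math.log(np.random.random() + 1e-300) < (new_loglik - loglik) + (new_logcoal - logcoal):
                    loglik = new_loglik
                    logcoal = new_logcoal
                    acc[0] += 1
                else:
                    times[v] = told
                    if likelihood_on:
                        c1 = child1[v]
                        c2 = child2[v]
                        for m in range(M):
                            trans_pk[v, m, :] = bak_trans[v, m, :]
                            trans_pk[c1, m, :] = bak_trans[c1, m, :]
                            trans_pk[c2, m, :] = bak_trans[c2, m, :]
                        for jj in range(ndirty):
                            for m in range(M):
                                partial[idx_buf[jj], m, :] = bak_partial[idx_buf[jj], m, :]
                                logscale[idx_buf[jj], m] = bak_logscale[idx_buf[jj], m]
            elif u < 0.65:
                # root time: multiplicative walk on the span above the
                # deeper child (Hastings term log(fac))
                v = root
                lower = max(times[child1[v]], times[child2[v]])
                span = times[v] - lower
                if span <= 0.0:
                    continue
                fac = math.exp(0.6 * (np.random.random() - 0.5))
                told = times[v]
                times[v] = lower + span * fac
                new_logcoal = _coal_logprior(n, times, N, model, alpha, beta, sorted_buf)
                if likelihood_on:
                    c1 = child1[v]
                    c2 = child2[v]
                    for m in range(M):
                        bak_trans[c1, m, :] = trans_pk[c1, m, :]
                        bak_trans[c2, m, :] = trans_pk[c2, m, :]
                        _refresh_branch(c1, m, parent, times, mu, W, trans_pk)
                        _refresh_branch(c2, m, parent, times, mu, W, trans_pk)
                        bak_partial[v, m, :] = partial[v, m, :]
                        bak_logscale[v, m] = logscale[v, m]
                        _refresh_node(v, m, child1, child2, W, trans_pk, partial, logscale)
                    new_loglik = _total_loglik(root, W, partial, logscale)
                else:
                    new_loglik = 0.0
                logr = (new_loglik - loglik) + (new_logcoal - logcoal) + math.log(fac)
                if math.log(np.random.random() + 1e-300) < logr:
                    loglik = new_loglik
                    logcoal = new_logcoal
                    acc[1] += 1
                else:
                    times[v] = told
                    if likelihood_on:
                        c1 = child1[v]
                        c2 = child2[v]
                        for m in range(M):
                            trans_pk[c1, m, :] = bak_trans[c1, m, :]
                            trans_pk[c2, m, :] = bak_trans[c2, m, :]
                            partial[v, m, :] = bak_partial[v, m, :]
                            logscale[v, m] = bak_logscale[v, m]
            elif u < 0.75:
                # scale every internal time; Jacobian fac^(n-1)
                fac = math.exp(0.4 * (np.random.random() - 0.5))
                for v in range(n, total):
                    times[v] *= fac
                new_logcoal = _coal_logprior(n, times, N, model, alpha, beta, sorted_buf)
                if likelihood_on:
                    bak_partial[:, :, :] = partial
                    bak_logscale[:, :] = logscale
                    bak_trans[:, :, :] = trans_pk
                    _sort_order_by_time(order, times)
                    _full_refresh(n, parent, child1, child2, times, mu, W, trans_pk, partial, logscale, order)
                    new_loglik = _total_loglik(root, W, partial, logscale)
                else:
                    new_loglik = 0.0
                logr = (new_loglik - loglik) + (new_logcoal - logcoal) + (n - 1) * math.log(fac)
                if math.log(np.random.random() + 1e-300) < logr:
                    loglik = new_loglik
                    logcoal = new_logcoal
                    acc[2] += 1
                else:
                    for v in range(n, total):
                        times[v] /= fac
                    if likelihood_on:
                        partial[:, :, :] = bak_partial
                        logscale[:, :] = bak_logscale
                        trans_pk[:, :, :] = bak_trans
            else:
                # subtree swap: exchange the parents of two compatible nodes
                a = np.random.randint(total - 1)
                b = np.random.randint(total - 1)
                if a == b:
                    continue
                pa = parent[a]
                pb = parent[b]
                if pa == pb:
                    continue
                if _is_in_subtree(pa, b, parent) or _is_in_subtree(pb, a, parent):
                    continue
                if times[pb] <= times[a] or times[pa] <= times[b]:
                    continue
                if child1[pa] == a:
                    child1[pa] = b
                else:
                    child2[pa] = b
                if child1[pb] == b:
                    child1[pb] = a
                else:
                    child2[pb] = a
                parent[a] = pb
                parent[b] = pa
                if likelihood_on:
                    for j in range(total):
                        mark[j] = False
                    _collect_path(pa, parent, mark)
                    _collect_path(pb, parent, mark)
                    ndirty = _dirty_list(mark, n, total, idx_buf)
                    for jj in range(ndirty):
                        for m in range(M):
                            bak_partial[idx_buf[jj], m, :] = partial[idx_buf[jj], m, :]
                            bak_logscale[idx_buf[jj], m] = logscale[idx_buf[jj], m]
                    for m in range(M):
                        bak_trans[a, m, :] = trans_pk[a, m, :]
                        bak_trans[b, m, :] = trans_pk[b, m, :]
                        _refresh_branch(a, m, parent, times, mu, W, trans_pk)
                        _refresh_branch(b, m, parent, times, mu, W, trans_pk)
                    _refresh_dirty(idx_buf, ndirty, times, child1, child2, W, trans_pk, partial, logscale)
                    new_loglik = _total_loglik(root, W, partial, logscale)
                else:
                    new_loglik = 0.0
                if math.log(np.random.random() + 1e-300) < (new_loglik - loglik):
                    loglik = new_loglik
                    acc[3] += 1
                else:
                    if child1[pa] == b:
                        child1[pa] = a
                    else:
                        child2[pa] = a
                    if child1[pb] == a:
                        child1[pb] = b
                    else:
                        child2[pb] = b
                    parent[a] = pa
                    parent[b] = pb
                    if likelihood_on:
                        for m in range(M):
                            trans_pk[a, m, :] = bak_trans[a, m, :]
                            trans_pk[b, m, :] = bak_trans[b, m, :]
                        for jj in range(ndirty):
                            for m in range(M):
                                partial[idx_buf[jj], m, :] = bak_partial[idx_buf[jj], m, :]
                                logscale[idx_buf[jj], m] = bak_logscale[idx_buf[jj], m]

        for _ in range(param_moves):
            choice = np.random.random()
            if choice < 0.5 and not fix_n:
                fac = math.exp(0.5 * (np.random.random() - 0.5))
                Nnew = N * fac
                new_logcoal = _coal_logprior(n, times, Nnew, model, alpha, beta, sorted_buf)
                scale = n_prior_mean / n_prior_shape
                dprior = (n_prior_shape - 1.0) * (math.log(Nnew) - math.log(N)) - (Nnew - N) / scale
                if math.log(np.random.random() + 1e-300) < (new_logcoal - logcoal) + dprior + math.log(fac):
                    N = Nnew
                    logcoal = new_logcoal
                    acc[4] += 1
            elif choice < 0.7 and model == 2:
                if np.random.random() < 0.5:
                    fac = math.exp(0.5 * (np.random.random() - 0.5))
                    anew = alpha * fac
                    new_logcoal = _coal_logprior(n, times, N, model, anew, beta, sorted_buf)
                    dprior = -alpha_rate * (anew - alpha)
                    if math.log(np.random.random() + 1e-300) < (new_logcoal - logcoal) + dprior + math.log(fac):
                        alpha = anew
                        logcoal = new_logcoal
                        acc[4] += 1
                else:
                    fac = math.exp(0.5 * (np.random.random() - 0.5))
                    bnew = beta * fac
                    new_logcoal = _coal_logprior(n, times, N, model, alpha, bnew, sorted_buf)
                    dprior = (math.log(bnew) - math.log(beta)) - beta_rate * (bnew - beta)
                    if math.log(np.random.random() + 1e-300) < (new_logcoal - logcoal) + dprior + math.log(fac):
                        beta = bnew
                        logcoal = new_logcoal
                        acc[4] += 1
            elif not fix_mu and likelihood_on:
                m = np.random.randint(M)
                fac = math.exp(0.4 * (np.random.random() - 0.5))
                mnew = mu[m] * fac
                scale = mu_prior_mean[m] / mu_prior_shape
                dprior = (mu_prior_shape - 1.0) * (math.log(mnew) - math.log(mu[m])) - (mnew - mu[m]) / scale
                mold = mu[m]
                mu[m] = mnew
                for v in range(total - 1):
                    bak_trans[v, m, :] = trans_pk[v, m, :]
                    _refresh_branch(v, m, parent, times, mu, W, trans_pk)
                _sort_order_by_time(order, times)
                for i in range(n - 1):
                    v = order[i]
                    bak_partial[v, m, :] = partial[v, m, :]
                    bak_logscale[v, m] = logscale[v, m]
                    _refresh_node(v, m, child1, child2, W, trans_pk, partial, logscale)
                new_loglik = _total_loglik(root, W, partial, logscale)
                if math.log(np.random.random() + 1e-300) < (new_loglik - loglik) + dprior + math.log(fac):
                    loglik = new_loglik
                    acc[5] += 1
                else:
                    mu[m] = mold
                    for v in range(total - 1):
                        trans_pk[v, m, :] = bak_trans[v, m, :]
                    for i in range(n - 1):
                        v = order[i]
                        partial[v, m, :] = bak_partial[v, m, :]
                        logscale[v, m] = bak_logscale[v, m]

        out_tmrca[it] = times[root]
        out_N[it] = N
        out_alpha[it] = alpha
        out_beta[it] = beta
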