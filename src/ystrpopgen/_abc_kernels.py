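"""Numba kernel: structured-coalescent simulation of a haplogroup locus.

Backward-in-time continuous-time structured coalescent over up to three
populations: per-population pairwise coalescence at rate 1/N_p, per-lineage
backward migration (a lineage in population i has its parent in j with rate
m_ij per generation, the forward rate of migration into i from j), and
population merges at fixed divergence times. Each lineage carries the counts
of its descendant samples per extant population, so a single mutation placed
uniformly on the genealogy (reservoir sampling of a branch segment) yields
the derived-allele counts per population directly. The haplogroup locus is
binary with a tiny mutation rate; the probability of two or more hits on one
genealogy is ~1e-7 and only the first sampled hit is applied.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_batch(
    n_pops,
    sample_sizes,  # (K,) int64, lineages sampled per extant pop
    pop_sizes0,  # (K,) float64
    merge_times,  # (E,) float64 ascending
    merge_target,  # (E,) int64
    merge_source,  # (E,) int64
    merge_newsize,  # (E,) float64
    mig,  # (n_sims, K, K) float64, mig[s, i, j] = rate into i from j
    mu,  # haplogroup mutation rate per generation
    seed,
    derived_out,  # (n_sims, K) int64: derived-allele counts (0 if no mutation)
):
    np.random.seed(seed)
    K = n_pops
    n_sims = mig.shape[0]
    maxlin = 0
    for p in range(K):
        maxlin += sample_sizes[p]
    E = len(merge_times)

    lin_pop = np.zeros(maxlin, dtype=np.int64)
    lin_d = np.zeros((maxlin, K), dtype=np.int64)
    members = np.zeros((K, maxlin), dtype=np.int64)  # slot ids per pop
    pos = np.zeros(maxlin, dtype=np.int64)  # position of slot in its pop list
    cnt = np.zeros(K, dtype=np.int64)
    sizes = np.zeros(K, dtype=np.float64)
    alive = np.zeros(K, dtype=np.bool_)
    cand_d = np.zeros(K, dtype=np.int64)

    for s in range(n_sims):
        # --- init ---
        slot = 0
        for p in range(K):
            cnt[p] = 0
            sizes[p] = pop_sizes0[p]
            alive[p] = True
        for p in range(K):
            for _ in range(sample_sizes[p]):
                lin_pop[slot] = p
                for q in range(K):
                    lin_d[slot, q] = 0
                lin_d[slot, p] = 1
                members[p, cnt[p]] = slot
                pos[slot] = cnt[p]
                cnt[p] += 1
                slot += 1
        total = maxlin
        t = 0.0
        epoch = 0
        branch_len = 0.0
        wtot = 0.0
        has_cand = False
        for q in range(K):
            cand_d[q] = 0

        while total > 1:
            # event rates in the current state
            rate = 0.0
            for p in range(K):
                if not alive[p]:
                    continue
                kp = cnt[p]
                if kp >= 2:
                    rate += kp * (kp - 1.0) * 0.5 / sizes[p]
                if kp >= 1:
                    mrow = 0.0
                    for q in range(K):
                        if q != p and alive[q]:
                            mrow += mig[s, p, q]
                    rate += kp * mrow
            if rate <= 0.0:
                dt = np.inf
            else:
                dt = -np.log(np.random.random() + 1e-300) / rate
            # epoch boundary crossing?
            if epoch < E and t + dt >= merge_times[epoch]:
                seg = merge_times[epoch] - t
                w = total * seg
                branch_len += w
                wtot += w
                if wtot > 0.0 and np.random.random() < w / wtot:
                    # uniform lineage during this segment
                    r = np.random.randint(total)
                    # r-th active lineage across pops
                    for p in range(K):
                        if r < cnt[p]:
                            sl = members[p, r]
                            for q in range(K):
                                cand_d[q] = lin_d[sl, q]
                            has_cand = True
                            break
                        r -= cnt[p]
                t = merge_times[epoch]
                tgt = merge_target[epoch]
                src = merge_source[epoch]
                # move all source lineages into the target
                for i in range(cnt[src]):
                    sl = members[src, i]
                    lin_pop[sl] = tgt
                    members[tgt, cnt[tgt]] = sl
                    pos[sl] = cnt[tgt]
                    cnt[tgt] += 1
                cnt[src] = 0
                alive[src] = False
                sizes[tgt] = merge_newsize[epoch]
                epoch += 1
                continue

            w = total * dt
            branch_len += w
            wtot += w
            if wtot > 0.0 and np.random.random() < w / wtot:
                r = np.random.randint(total)
                for p in range(K):
                    if r < cnt[p]:
                        sl = members[p, r]
                        for q in range(K):
                            cand_d[q] = lin_d[sl, q]
                        has_cand = True
                        break
                    r -= cnt[p]
            t += dt

            # which event?
            u = np.random.random() * rate
            done = False
            for p in range(K):
                if not alive[p]:
                    continue
                kp = cnt[p]
                if kp >= 2:
                    cr = kp * (kp - 1.0) * 0.5 / sizes[p]
                    if u < cr:
                        # coalesce two random lineages of p
                        i = np.random.randint(kp)
                        j = np.random.randint(kp - 1)
                        if j >= i:
                            j += 1
                        a = members[p, i]
                        b = members[p, j]
                        for q in range(K):
                            lin_d[a, q] += lin_d[b, q]
                        # remove b (swap with last member)
                        last = members[p, cnt[p] - 1]
                        members[p, pos[b]] = last
                        pos[last] = pos[b]
                        cnt[p] -= 1
                        total -= 1
                        done = True
                        break
                    u -= cr
                if kp >= 1:
                    for q in range(K):
                        if q != p and alive[q]:
                            mr = kp * mig[s, p, q]
                            if u < mr:
                                # one lineage of p has its parent in q
                                i = np.random.randint(kp)
                                a = members[p, i]
                                last = members[p, cnt[p] - 1]
                                members[p, pos[a]] = last
                                pos[last] = pos[a]
                                cnt[p] -= 1
                                lin_pop[a] = q
                                members[q, cnt[q]] = a
                                pos[a] = cnt[q]
                                cnt[q] += 1
                                done = True
                                break
                            u -= mr
                if done:
                    break

        # mutations on the genealogy
        n_mut = np.random.poisson(mu * branch_len)
        for q in range(K):
            derived_out[s, q] = cand_d[q] if (n_mut >= 1 and has_cand) else 0
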