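"""Numba inner loops for the haplotype-length scans, H12 windows and the
forward simulator.  Pure-array interfaces; all orchestration stays in the
owning modules.

The EHH-family scans share one primitive: iterative group splitting.  The
carriers of a core allele start in one identity group; extending outward one
SNP at a time, each group splits by the allele carried there, and the pair
homozygosity at offset k is sum_g C(c_g,2) / C(n,2) over group sizes c_g.
"""

import numpy as np
from numba import njit

NO_STOP, STOP_TRUNC, STOP_EDGE, STOP_GAP, STOP_CAP = 0, 1, 2, 3, 4


@njit(cache=True)
def _split_step(A, col, rows, labels, nlab, tmp, cnt):
    """Split identity groups by the allele at ``col``.

    Returns (new nlab, number of still-identical pairs)."""
    k = rows.size
    for t in range(2 * nlab):
        tmp[t] = -1
    new = 0
    for i in range(k):
        key = labels[i] * 2 + A[rows[i], col]
        if tmp[key] < 0:
            tmp[key] = new
            new += 1
        labels[i] = tmp[key]
    for t in range(new):
        cnt[t] = 0
    for i in range(k):
        cnt[labels[i]] += 1
    pairs = 0
    for t in range(new):
        pairs += cnt[t] * (cnt[t] - 1) // 2
    return new, pairs


@njit(cache=True)
def _ehh_fill(A, rows, core, step, lo, hi, trunc, pos_bp, max_gap_bp, cap,
              out_idx, out_hom, labels, tmp, cnt):
    """Walk outward from ``core`` in direction ``step`` recording
    (SNP index, pair homozygosity) until truncation/gap/edge/cap.

    The first point with hom < trunc IS recorded (the integrator handles the
    crossing).  Returns (n_points, stop_reason)."""
    k = rows.size
    npairs = k * (k - 1) // 2
    if npairs == 0:
        return 0, STOP_TRUNC
    for i in range(k):
        labels[i] = 0
    nlab = 1
    n = 0
    j = core
    while True:
        jn = j + step
        if jn < lo or jn >= hi:
            return n, STOP_EDGE
        if abs(pos_bp[jn] - pos_bp[j]) > max_gap_bp:
            return n, STOP_GAP
        j = jn
        nlab, pairs = _split_step(A, j, rows, labels, nlab, tmp, cnt)
        hom = pairs / npairs
        out_idx[n] = j
        out_hom[n] = hom
        n += 1
        if hom < trunc or pairs == 0:
            return n, STOP_TRUNC
        if n >= cap:
            return n, STOP_CAP
    return n, NO_STOP


@njit(cache=True)
def _trapz_cm(out_idx, out_hom, n, pos_cm, core, trunc):
    """Trapezoidal area under the homozygosity decay over |cM| distance,
    integrating down to the truncation value (linear interpolation at the
    crossing)."""
    area = 0.0
    prev_d = 0.0
    prev_h = 1.0
    for t in range(n):
        d = abs(pos_cm[out_idx[t]] - pos_cm[core])
        h = out_hom[t]
        if h < trunc:
            if prev_h > trunc and prev_h > h:
                frac = (prev_h - trunc) / (prev_h - h)
                area += 0.5 * (prev_h + trunc) * (d - prev_d) * frac
            return area
        area += 0.5 * (prev_h + h) * (d - prev_d)
        prev_d = d
        prev_h = h
    return area


@njit(cache=True)
def _sum_hom(out_hom, n):
    s = 0.0
    for t in range(n):
        s += out_hom[t]
    return s


@njit(cache=True)
def ihs_unstandardized(A, pos_bp, pos_cm, known, starts, stops, maf_min,
                       trunc, max_gap_bp, cap):
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) per core SNP.

    Cores need a known ancestral state, derived frequency inside
    [maf_min, 1 - maf_min] and >= 2 carriers of each allele.  Returns
    (values, derived_freq); NaN where undefined."""
    n, m = A.shape
    out = np.full(m, np.nan)
    freq = np.full(m, np.nan)
    idx_buf = np.empty(cap + 1, np.int64)
    hom_buf = np.empty(cap + 1, np.float64)
    labels = np.empty(n, np.int64)
    tmp = np.empty(2 * n + 2, np.int64)
    cnt = np.empty(n, np.int64)
    rows_a = np.empty(n, np.int64)
    rows_d = np.empty(n, np.int64)
    for b in range(starts.size):
        lo, hi = starts[b], stops[b]
        for j in range(lo, hi):
            if not known[j]:
                continue
            na = 0
            nd = 0
            for i in range(n):
                if A[i, j] == 0:
                    rows_a[na] = i
                    na += 1
                else:
                    rows_d[nd] = i
                    nd += 1
            p = nd / n
            if p < maf_min or p > 1.0 - maf_min or na < 2 or nd < 2:
                continue
            ihh = np.empty(2, np.float64)
            ok = True
            for c in range(2):
                rows = rows_a[:na] if c == 0 else rows_d[:nd]
                total = 0.0
                for step in (-1, 1):
                    np_, _r = _ehh_fill(A, rows, j, step, lo, hi, trunc,
                                        pos_bp, max_gap_bp, cap,
                                        idx_buf, hom_buf, labels, tmp, cnt)
                    total += _trapz_cm(idx_buf, hom_buf, np_, pos_cm, j, trunc)
                ihh[c] = total
                if total <= 0.0:
                    ok = False
            if ok:
                out[j] = np.log(ihh[0] / ihh[1])
                freq[j] = p
    return out, freq


@njit(cache=True)
def nsl_unstandardized(A, known, starts, stops, maf_min, cap):
    """Unstandardized nSL = ln(SL_ancestral / SL_derived) per core SNP.

    ``A`` must contain only sites segregating in the population, so offsets
    count segregating sites.  SL per allele class is the mean pairwise
    identity run length (core included), capped at ``cap`` sites per
    direction."""
    n, m = A.shape
    out = np.full(m, np.nan)
    freq = np.full(m, np.nan)
    idx_buf = np.empty(cap + 1, np.int64)
    hom_buf = np.empty(cap + 1, np.float64)
    labels = np.empty(n, np.int64)
    tmp = np.empty(2 * n + 2, np.int64)
    cnt = np.empty(n, np.int64)
    rows_a = np.empty(n, np.int64)
    rows_d = np.empty(n, np.int64)
    fake_bp = np.zeros(1, np.int64)  # gaps not defined in segregating-site space
    for b in range(starts.size):
        lo, hi = starts[b], stops[b]
        for j in range(lo, hi):
            if not known[j]:
                continue
            na = 0
            nd = 0
            for i in range(n):
                if A[i, j] == 0:
                    rows_a[na] = i
                    na += 1
                else:
                    rows_d[nd] = i
                    nd += 1
            p = nd / n
            if p < maf_min or p > 1.0 - maf_min or na < 2 or nd < 2:
                continue
            sl = np.empty(2, np.float64)
            for c in range(2):
                rows = rows_a[:na] if c == 0 else rows_d[:nd]
                total = 1.0  # the core site itself
                for step in (-1, 1):
                    np_, _r = _sl_fill(A, rows, j, step, lo, hi, cap,
                                       idx_buf, hom_buf, labels, tmp, cnt)
                    total += _sum_hom(hom_buf, np_)
                sl[c] = total
            out[j] = np.log(sl[0] / sl[1])
            freq[j] = p
    return out, freq


@njit(cache=True)
def _sl_fill(A, rows, core, step, lo, hi, cap, out_idx, out_hom, labels, tmp, cnt):
    """Like _ehh_fill with no truncation and no gap rule (unit distances)."""
    k = rows.size
    npairs = k * (k - 1) // 2
    if npairs == 0:
        return 0, STOP_TRUNC
    for i in range(k):
        labels[i] = 0
    nlab = 1
    n = 0
    j = core
    while True:
        jn = j + step
        if jn < lo or jn >= hi:
            return n, STOP_EDGE
        j = jn
        nlab, pairs = _split_step(A, j, rows, labels, nlab, tmp, cnt)
        out_idx[n] = j
        out_hom[n] = pairs / npairs
        n += 1
        if pairs == 0:
            return n, STOP_TRUNC
        if n >= cap:
            return n, STOP_CAP
    return n, NO_STOP


@njit(cache=True)
def xpehh_unstandardized(A, rows_a, rows_b, pos_bp, pos_cm, starts, stops,
                         trunc, max_gap_bp, cap):
    """Unstandardized XP-EHH = ln(IHH_A / IHH_B) per core SNP.

    EHH in each population runs over ALL its haplotypes at the core (no
    allele split); the joint extension stops when the pooled two-population
    EHH falls below ``trunc`` (both curves interpolated to the pooled
    crossing), at a gap, the cap, or the chromosome edge."""
    n = A.shape[0]
    m = A.shape[1]
    out = np.full(m, np.nan)
    na, nb = rows_a.size, rows_b.size
    rows_p = np.empty(na + nb, np.int64)
    rows_p[:na] = rows_a
    rows_p[na:] = rows_b
    lab_a = np.empty(na, np.int64)
    lab_b = np.empty(nb, np.int64)
    lab_p = np.empty(na + nb, np.int64)
    tmp = np.empty(2 * (na + nb) + 2, np.int64)
    cnt = np.empty(na + nb, np.int64)
    pairs_a = na * (na - 1) // 2
    pairs_b = nb * (nb - 1) // 2
    pairs_p = (na + nb) * (na + nb - 1) // 2
    for blk in range(starts.size):
        lo, hi = starts[blk], stops[blk]
        for core in range(lo, hi):
            ia = 0.0
            ib = 0.0
            for step in (-1, 1):
                for i in range(na):
                    lab_a[i] = 0
                for i in range(nb):
                    lab_b[i] = 0
                for i in range(na + nb):
                    lab_p[i] = 0
                nl_a = 1
                nl_b = 1
                nl_p = 1
                prev_d = 0.0
                prev_a = 1.0
                prev_b = 1.0
                prev_p = 1.0
                j = core
                steps = 0
                while True:
                    jn = j + step
                    if jn < lo or jn >= hi:
                        break
                    if abs(pos_bp[jn] - pos_bp[j]) > max_gap_bp:
                        break
                    j = jn
                    nl_a, pa = _split_step(A, j, rows_a, lab_a, nl_a, tmp, cnt)
                    nl_b, pb = _split_step(A, j, rows_b, lab_b, nl_b, tmp, cnt)
                    nl_p, pp = _split_step(A, j, rows_p, lab_p, nl_p, tmp, cnt)
                    ha = pa / pairs_a
                    hb = pb / pairs_b
                    hp = pp / pairs_p
                    d = abs(pos_cm[j] - pos_cm[core])
                    if hp < trunc:
                        if prev_p > trunc and prev_p > hp:
                            frac = (prev_p - trunc) / (prev_p - hp)
                            dx = (d - prev_d) * frac
                            ha_x = prev_a + (ha - prev_a) * frac
                            hb_x = prev_b + (hb - prev_b) * frac
                            ia += 0.5 * (prev_a + ha_x) * dx
                            ib += 0.5 * (prev_b + hb_x) * dx
                        break
                    ia += 0.5 * (prev_a + ha) * (d - prev_d)
                    ib += 0.5 * (prev_b + hb) * (d - prev_d)
                    prev_d = d
                    prev_a = ha
                    prev_b = hb
                    prev_p = hp
                    steps += 1
                    if steps >= cap or pp == 0:
                        break
            if ia > 0.0 and ib > 0.0:
                out[core] = np.log(ia / ib)
    return out


@njit(cache=True)
def h12_windows(A, w):
    """Garud's H12 per sliding window: haplotypes are exact strings over the
    window; the top two haplotype frequencies are pooled."""
    n, m = A.shape
    nw = m - w + 1
    out = np.empty(nw)
    labels = np.empty(n, np.int64)
    tmp = np.empty(2 * n + 2, np.int64)
    cnt = np.empty(n, np.int64)
    rows = np.arange(n)
    for s in range(nw):
        for i in range(n):
            labels[i] = 0
        nlab = 1
        for j in range(s, s + w):
            nlab, _ = _split_step(A, j, rows, labels, nlab, tmp, cnt)
        for t in range(nlab):
            cnt[t] = 0
        for i in range(n):
            cnt[labels[i]] += 1
        freqs = np.sort(cnt[:nlab])[::-1].astype(np.float64) / n
        top2 = freqs[0]
        if nlab > 1:
            top2 += freqs[1]
        h = top2 * top2
        for t in range(2, nlab):
            h += freqs[t] * freqs[t]
        out[s] = h
    return out


@njit(cache=True)
def wf_generation(H, children, pa, pb, start_hap, bkpts, bk_off, counts):
    """One Wright-Fisher generation: each child haplotype is a recombinant
    of its parent diploid's two haplotypes (rows ``pa``/``pb``), switching
    source at each breakpoint SNP index; derived-allele column counts of the
    children are accumulated into ``counts`` (caller zeroes it)."""
    n2, m = H.shape
    for i in range(n2):
        if start_hap[i] == 0:
            s0, s1 = pa[i], pb[i]
        else:
            s0, s1 = pb[i], pa[i]
        k0, k1 = bk_off[i], bk_off[i + 1]
        if k1 == k0:
            for j in range(m):
                v = H[s0, j]
                children[i, j] = v
                counts[j] += v
        else:
            pos = 0
            cur = 0
            for t in range(k0, k1):
                b = bkpts[t]
                src = s0 if cur == 0 else s1
                for j in range(pos, b):
                    v = H[src, j]
                    children[i, j] = v
                    counts[j] += v
                pos = b
                cur = 1 - cur
            src = s0 if cur == 0 else s1
            for j in range(pos, m):
                v = H[src, j]
                children[i, j] = v
                counts[j] += v
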