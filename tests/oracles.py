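"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit loops over template pairs,
ordinal patterns, quantized words, hypergeometric tables and EDF grids.
"""

import math

import numpy as np


def _cheb(a, b):
    return max(abs(float(x) - float(y)) for x, y in zip(a, b))


def apen_oracle(x, m, r):
    x = [float(v) for v in x]
    n = len(x)

    def phi(mm):
        templ = [x[i:i + mm] for i in range(n - mm + 1)]
        logs = []
        for a in templ:
            c = sum(1 for b in templ if _cheb(a, b) <= r)
            logs.append(math.log(c / len(templ)))
        return sum(logs) / len(logs)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    x = [float(v) for v in x]
    n = len(x)
    tm = [x[i:i + m] for i in range(n - m)]
    tm1 = [x[i:i + m + 1] for i in range(n - m)]
    b = sum(1 for i in range(len(tm)) for j in range(i + 1, len(tm))
            if _cheb(tm[i], tm[j]) <= r)
    a = sum(1 for i in range(len(tm1)) for j in range(i + 1, len(tm1))
            if _cheb(tm1[i], tm1[j]) <= r)
    if a == 0 or b == 0:
        return float("inf")
    return -math.log(a / b)


def permen_oracle(x, m):
    x = [float(v) for v in x]
    n = len(x)
    counts = {}
    for i in range(n - m + 1):
        w = x[i:i + m]
        # ties broken by order of occurrence
        pattern = tuple(sorted(range(m), key=lambda k: (w[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(m))


def disten_oracle(x, m, n_bins):
    x = [float(v) for v in x]
    n = len(x)
    emb = [x[i:i + m] for i in range(n - m + 1)]
    d = [_cheb(emb[i], emb[j]) for i in range(len(emb))
         for j in range(i + 1, len(emb))]
    dmax = max(d)
    if dmax == 0:
        return 0.0
    hist, _ = np.histogram(d, bins=n_bins, range=(0.0, dmax))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)) / np.log2(n_bins))


def incren_oracle(x, m, R):
    x = [float(v) for v in x]
    v = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    sd = float(np.std(v))
    symbols = []
    for vi in v:
        s = (vi > 0) - (vi < 0)
        q = 0 if sd == 0 else min(int(math.floor(R * abs(vi) / sd)), R)
        symbols.append((s, q))
    words = {}
    for i in range(len(symbols) - m + 1):
        w = tuple(symbols[i:i + m])
        words[w] = words.get(w, 0) + 1
    total = sum(words.values())
    h = -sum((c / total) * math.log2(c / total) for c in words.values())
    return h / (m * math.log2(2.0 * (R + 1)))


def lz76_oracle(bits):
    """LZ76 phrase count by exhaustive substring search over the prefix."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = 0
    i = 0
    while i < n:
        l = 1
        while i + l <= n and s[i:i + l] in s[:i + l - 1]:
            l += 1
        c += 1
        i += l
    return c


def fisher_oracle(table):
    """Two-tailed Fisher p by full enumeration of tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2

    def prob(aa):
        return (math.comb(r1, aa) * math.comb(r2, c1 - aa)
                / math.comb(ntot, c1))

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(aa) for aa in range(lo, hi + 1)
               if prob(aa) <= p_obs * (1 + 1e-9))


def ks_d_oracle(a, b):
    """Supremum EDF distance by scanning every observed value."""
    a = sorted(float(v) for v in a)
    b = sorted(float(v) for v in b)
    grid = sorted(set(a) | set(b))
    d = 0.0
    for g in grid:
        fa = sum(1 for v in a if v <= g) / len(a)
        fb = sum(1 for v in b if v <= g) / len(b)
        d = max(d, abs(fa - fb))
    return d


def icc_oracle(pairs):
    """ICC(1,1) from explicitly written one-way ANOVA sums of squares."""
    x = np.asarray(pairs, dtype=float)
    n, k = x.shape
    grand = x.mean()
    means = x.mean(axis=1)
    ssb = k * sum((mi - grand) ** 2 for mi in means)
    ssw = sum((x[i, j] - means[i]) ** 2 for i in range(n) for j in range(k))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)
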