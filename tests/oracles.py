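"""Independent brute-force / closed-form oracles shared across test modules.

These stay deliberately naive (python loops, direct enumeration) and never
call the implementation paths they are used to check.
"""

from math import comb

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_scan(seq, consensus, max_mismatch, both_strands=True):
    """All windows, both strands, python-string Hamming distance.

    'N' in the consensus is a wildcard; 'N' in the sequence mismatches any
    constrained position. Returns {(offset, strand, mismatches)}.
    """
    out = set()
    m = len(consensus)
    targets = [("+", consensus)]
    if both_strands:
        targets.append(("-", rc(consensus)))
    for strand, cons in targets:
        for off in range(len(seq) - m + 1):
            win = seq[off:off + m]
            mm = sum(1 for a, b in zip(win, cons)
                     if b != "N" and (a != b or a == "N"))
            if mm <= max_mismatch:
                out.add((off, strand, mm))
    return out


def hypergeom_tail_enumeration(N, K, n, k):
    """P(X >= k) by direct combinatorial summation."""
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / comb(N, n)


def poisson_tail_direct(k, lam, n_terms=2000):
    """P(X >= k) by log-space summation of pmf terms."""
    from scipy.special import gammaln, logsumexp
    i = np.arange(k, k + n_terms + 1)
    logpmf = -lam + i * np.log(lam) - gammaln(i + 1)
    return float(np.exp(logsumexp(logpmf)))
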