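"""Independent oracles used by unit and acceptance tests.

These are deliberately written as naive nested-if / brute-force routines,
independent of the package implementation they check.
"""

import numpy as np


def sic_score_oracle(plt, inr, sofa):
    """Nested-if transcription of the published SIC table (defaults)."""
    if plt < 100:
        p = 2
    elif plt < 150:
        p = 1
    else:
        p = 0
    if inr > 1.4:
        i = 2
    elif inr > 1.2:
        i = 1
    else:
        i = 0
    if sofa >= 2:
        s = 2
    elif sofa >= 1:
        s = 1
    else:
        s = 0
    total = p + i + s
    return (p, i, s), total, total >= 4


def isth_dic_score_oracle(plt, marker, pt_s, fib, pt_ref=12.0):
    """Nested-if transcription of the ISTH overt-DIC table (defaults)."""
    if plt < 50:
        p = 2
    elif plt < 100:
        p = 1
    else:
        p = 0
    if marker > 5.0:
        d = 3
    elif marker >= 1.0:
        d = 2
    else:
        d = 0
    prolong = pt_s - pt_ref
    if prolong > 6.0:
        t = 2
    elif prolong >= 3.0:
        t = 1
    else:
        t = 0
    f = 1 if fib < 1.0 else 0
    total = p + d + t + f
    return (p, d, t, f), total, total >= 5


def backward_scan_intervals(s, m):
    """Naive per-variable backward scan: time since the most recent
    observation strictly before t, accumulated through gaps (time since the
    series start when the variable was never observed)."""
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    T, D = m.shape
    out = np.zeros((T, D))
    for t in range(1, T):
        for d in range(D):
            prior = [k for k in range(t) if m[k, d] == 1]
            out[t, d] = s[t] - s[prior[-1]] if prior else s[t] - s[0]
    return out


def auroc_pair_counting(scores, labels):
    """All-pairs concordance with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
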