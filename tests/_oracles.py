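"""Independent brute-force reference implementations used as test oracles."""

from fractions import Fraction
from math import log2, sqrt

GAP = "-"


def brute_force_column_scores(row_ids, rows, q, threshold):
    """Per-column (d_kl, g_w, conserved) by direct summation.

    Re-derives everything from the raw rows: the initiator-Met mask (each
    row's first non-gap symbol, if 'M', is treated as a gap), exact-fraction
    column frequencies, and the base-2 divergence computed term by term as
    p*(log2(count) - log2(n_nongap) - log2(q)).
    """
    n_rows = len(rows)
    n_cols = len(rows[0])
    masked = set()
    for i, row in enumerate(rows):
        for col, s in enumerate(row, start=1):
            if s != GAP:
                if s == "M":
                    masked.add((i, col))
                break
    out = []
    for col in range(1, n_cols + 1):
        counts = {}
        for i, row in enumerate(rows):
            s = row[col - 1]
            if s == GAP or (i, col) in masked:
                continue
            counts[s] = counts.get(s, 0) + 1
        n_nongap = sum(counts.values())
        if n_nongap == 0:
            out.append((0.0, 0.0, False))
            continue
        d_kl = 0.0
        for a, c in counts.items():
            p = Fraction(c, n_nongap)
            d_kl += float(p) * (log2(c) - log2(n_nongap) - log2(q[a]))
        g_w = float(Fraction(n_nongap, n_rows)) * d_kl
        out.append((d_kl, g_w, g_w > threshold))
    return out


def welch_by_hand(a, b):
    """Welch t, Satterthwaite df and two-sided p from first principles."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p
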