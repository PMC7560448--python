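"""Naive, loop-based reference implementation of the CTA score.

Kept deliberately independent of the package's vectorized code paths:
pure Python lists, ``statistics.median``/``mean``, and explicit loops
written directly from the score's definition. Used only to cross-check
the vectorized implementation on small random instances.
"""

from statistics import mean, median


def oracle_cta(expr_rows, cluster_of_cell, marker_rows):
    """Normalized CTA scores for one cell type.

    Parameters
    ----------
    expr_rows
        list of per-gene lists of expression over cells.
    cluster_of_cell
        list giving each cell's cluster index 0..K-1.
    marker_rows
        indices into ``expr_rows`` of the cell type's markers.

    Returns (raw, normalized) lists of length K.
    """
    k = max(cluster_of_cell) + 1
    n = len(marker_rows)

    # step 1: cluster medians, row-normalized
    p = []
    for i in marker_rows:
        meds = []
        for c in range(k):
            vals = [expr_rows[i][j] for j, cc in enumerate(cluster_of_cell) if cc == c]
            meds.append(median(vals))
        s = sum(meds)
        p.append([m / s for m in meds] if s > 0 else [1.0 / k] * k)

    # step 2: inverted Gini weight per marker
    w = []
    for row in p:
        acc = 0.0
        for v in row:
            acc += v * v
        w.append(1.0 + acc)

    # step 3: weighted cluster-mean score
    raw = []
    for c in range(k):
        s = 0.0
        for idx, i in enumerate(marker_rows):
            vals = [expr_rows[i][j] for j, cc in enumerate(cluster_of_cell) if cc == c]
            s += mean(vals) * w[idx]
        raw.append(s / n**3)

    # step 4: probabilities
    total = sum(raw)
    normalized = [r / total for r in raw] if total > 0 else [1.0 / k] * k
    return raw, normalized
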