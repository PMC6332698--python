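"""Independent brute-force oracles for window scoring.

Every function here recomputes a pipeline quantity by direct summation
loops, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


def oracle_window_average(values, window):
    out = []
    for i in range(len(values) - window + 1):
        total = 0.0
        for j in range(window):
            total += values[i + j]
        out.append(total / window)
    return out


def oracle_foldindex(sequence, window, kd_scale):
    lo = min(kd_scale.values())
    hi = max(kd_scale.values())
    out = []
    for i in range(len(sequence) - window + 1):
        h = 0.0
        q = 0.0
        for j in range(window):
            aa = sequence[i + j]
            h += (kd_scale[aa] - lo) / (hi - lo)
            q += CHARGE.get(aa, 0.0)
        out.append(2.785 * (h / window) - abs(q / window) - 1.151)
    return out


def oracle_composition(sequence, scale, kd_scale, window):
    """(score, argmax 1-based window center, floored) by direct enumeration
    of every (outer, inner) window pair with symmetric edge shrink."""
    first = oracle_window_average([scale[aa] for aa in sequence], window)
    n = len(first)
    half = (window - 1) // 2
    second = []
    for i in range(n):
        h = min(half, i, n - 1 - i)
        total = 0.0
        for j in range(i - h, i + h + 1):
            total += first[j]
        second.append(total / (2 * h + 1))
    fold = oracle_foldindex(sequence, window, kd_scale)
    best_score = None
    best_pos = None
    for i in range(n):
        if fold[i] < 0 and (best_score is None or second[i] > best_score):
            best_score = second[i]
            best_pos = i + (window + 1) // 2
    if best_score is None:
        return min(scale.values()), None, True
    return best_score, best_pos, False


def oracle_amyloid(sequence, matrix_rows, min_anchor, max_anchor, core_length=21):
    """(normalized score, 1-based core start) enumerating all windows and
    all hexapeptides by direct summation.  ``matrix_rows`` is a list of 6
    dicts residue -> value."""
    best_raw = None
    best_start = None
    for s in range(len(sequence) - core_length + 1):
        total = 0.0
        n_hex = core_length - 6 + 1
        for k in range(n_hex):
            for j in range(6):
                total += matrix_rows[j][sequence[s + k + j]]
        raw = total / n_hex
        if best_raw is None or raw > best_raw:
            best_raw = raw
            best_start = s + 1
    score = 100.0 * (best_raw - min_anchor) / (max_anchor - min_anchor)
    return score, best_start


def oracle_spearman(x, y):
    """Spearman rho via explicit average ranks and Pearson on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def oracle_confusion(pairs):
    """(sensitivity, specificity, precision, accuracy, mcc) from
    (predicted_positive, observed_positive) booleans; None marks an
    undefined ratio."""
    tp = sum(1 for p, o in pairs if p and o)
    tn = sum(1 for p, o in pairs if not p and not o)
    fp = sum(1 for p, o in pairs if p and not o)
    fn = sum(1 for p, o in pairs if not p and o)

    def div(a, b):
        return a / b if b else None

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else None
    return (
        div(tp, tp + fn),
        div(tn, tn + fp),
        div(tp, tp + fp),
        div(tp + tn, tp + tn + fp + fn),
        mcc,
    )
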