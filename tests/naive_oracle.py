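"""Independent brute-force evaluation of the summary-measure formulas.

Deliberately naive: plain Python loops, explicit normal equations for the
rank regression, no numpy vectorisation and no imports from the package
under test.  Used as the oracle in equivalence tests.
"""

import math


def naive_mean(p, y):
    total = 0.0
    for pj, yj in zip(p, y):
        total += pj * yj
    return total


def naive_ranks(p):
    x, cum = [], 0.0
    for pj in p:
        cum += pj
        x.append(cum - 0.5 * pj)
    return x


def naive_wls_line(x, y, w):
    s0 = s1 = s2 = t0 = t1 = 0.0
    for xj, yj, wj in zip(x, y, w):
        s0 += wj
        s1 += wj * xj
        s2 += wj * xj * xj
        t0 += wj * yj
        t1 += wj * xj * yj
    slope = (s0 * t1 - s1 * t0) / (s0 * s2 - s1 * s1)
    intercept = (t0 - slope * s1) / s0
    return intercept, intercept + slope  # v0, v1


def naive_measure(measure_id, p, y, kind, favourable=True, reference_index=None):
    """Evaluate one measure by direct transcription of its printed formula.

    ``reference_index`` identifies the reference subgroup of a binary
    dimension; ordered slices must already be sorted most disadvantaged
    first.  Returns None where the measure is undefined.
    """
    n = len(p)
    mu = naive_mean(p, y)

    if kind == "ordered":
        hi, lo = y[-1], y[0]
    elif kind == "binary":
        hi = y[reference_index]
        lo = y[1 - reference_index]
    else:
        hi, lo = max(y), min(y)

    if measure_id == "D":
        return hi - lo
    if measure_id == "R":
        return hi / lo if lo != 0 else None

    if measure_id == "BGV":
        return sum(pj * (yj - mu) ** 2 for pj, yj in zip(p, y))
    if measure_id == "MDM":
        return sum(pj * abs(yj - mu) for pj, yj in zip(p, y))
    if measure_id == "MDB":
        ref = max(y) if favourable else min(y)
        return sum(pj * abs(yj - ref) for pj, yj in zip(p, y))
    if measure_id == "IDIS":
        if mu == 0:
            return None
        return (1.0 / n) * sum(abs(yj - mu) for yj in y) / mu * 100.0

    if measure_id == "MLD":
        if mu <= 0 or any(yj <= 0 for yj in y):
            return None
        return sum(pj * (-math.log(yj / mu)) for pj, yj in zip(p, y)) * 1000.0
    if measure_id == "TI":
        if mu <= 0 or any(yj <= 0 for yj in y):
            return None
        return sum(pj * (yj / mu) * math.log(yj / mu) for pj, yj in zip(p, y)) * 1000.0

    if measure_id in ("ACI", "RCI"):
        x = naive_ranks(p)
        aci = sum(pj * (2.0 * xj - 1.0) * yj for pj, xj, yj in zip(p, x, y))
        if measure_id == "ACI":
            return aci
        return aci / mu * 100.0 if mu != 0 else None

    if measure_id in ("SII", "RII", "KMI"):
        x = naive_ranks(p)
        v0, v1 = naive_wls_line(x, y, p)
        sii = (v1 - v0) if favourable else (v0 - v1)
        if measure_id == "SII":
            return sii
        if measure_id == "RII":
            return sii / mu if mu != 0 else None
        num, den = (v1, v0) if favourable else (v0, v1)
        return num / den if den != 0 else None

    if measure_id in ("PAR", "PAF"):
        if kind == "ordered":
            ref = y[-1]
        elif kind == "binary":
            ref = y[reference_index]
        else:
            ref = max(y) if favourable else min(y)
        par = ref - mu
        if measure_id == "PAR":
            return par
        return par / mu * 100.0 if mu != 0 else None

    raise KeyError(measure_id)
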