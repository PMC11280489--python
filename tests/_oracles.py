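"""Independent brute-force oracle implementations of the eco-acoustic indices.

Deliberately naive (explicit Python loops, O(n^2) where a closed form is
shortcut in the package) so they share no code path with the vectorized
implementations they check.
"""

import math


def relative_db(amp):
    peak = max(max(row) for row in amp)
    if peak == 0:
        return [[-200.0 for _ in row] for row in amp]
    out = []
    for row in amp:
        out.append([
            max(20.0 * math.log10(v / peak), -200.0) if v > 0 else -200.0
            for v in row
        ])
    return out


def oracle_aci(freqs, amp, fmin, fmax):
    total = 0.0
    for k, f in enumerate(freqs):
        if not (fmin <= f <= fmax):
            continue
        num = 0.0
        den = 0.0
        for t in range(len(amp[k]) - 1):
            num += abs(amp[k][t + 1] - amp[k][t])
        for t in range(len(amp[k])):
            den += amp[k][t]
        if den > 0:
            total += num / den
    return total


def oracle_occupancy(freqs, amp, fmin, fmax, band_width, threshold_db, fr):
    width = max(band_width, fr)
    n_bands = int((fmax - fmin) // width)
    db = relative_db(amp)
    occ = []
    for b in range(n_bands):
        lo = fmin + b * width
        hi = lo + width
        cells = []
        for k, f in enumerate(freqs):
            if lo <= f < hi:
                cells.extend(db[k])
        if cells:
            occ.append(sum(1 for c in cells if c > threshold_db) / len(cells))
        else:
            occ.append(0.0)
    return occ


def oracle_adi(freqs, amp, fmin, fmax, band_width, threshold_db, fr):
    occ = oracle_occupancy(freqs, amp, fmin, fmax, band_width, threshold_db, fr)
    total = sum(occ)
    if total == 0:
        return 0.0
    h = 0.0
    for p in occ:
        q = p / total
        if q > 0:
            h -= q * math.log(q)
    return h


def oracle_gini(values):
    """Gini as half the relative mean absolute difference (O(n^2) pairwise)."""
    n = len(values)
    mean = sum(values) / n
    if mean == 0:
        return 0.0
    acc = 0.0
    for a in values:
        for b in values:
            acc += abs(a - b)
    return acc / (2.0 * n * n * mean)


def oracle_aei(freqs, amp, fmin, fmax, band_width, threshold_db, fr):
    occ = oracle_occupancy(freqs, amp, fmin, fmax, band_width, threshold_db, fr)
    if sum(occ) == 0:
        return 0.0
    return oracle_gini(occ)


def oracle_bi(freqs, amp, fmin, fmax):
    db = relative_db(amp)
    rows = [k for k, f in enumerate(freqs) if fmin <= f <= fmax]
    mean_db = [sum(db[k]) / len(db[k]) for k in rows]
    base = min(mean_db)
    shifted = [v - base for v in mean_db]
    area = 0.0
    for i in range(len(rows) - 1):
        df_khz = (freqs[rows[i + 1]] - freqs[rows[i]]) / 1000.0
        area += 0.5 * (shifted[i] + shifted[i + 1]) * df_khz
    return area


def oracle_ndsi(freqs, amp, anthro, bio):
    a = b = 0.0
    for k, f in enumerate(freqs):
        for t in range(len(amp[k])):
            p = amp[k][t] ** 2
            if anthro[0] <= f < anthro[1]:
                a += p
            if bio[0] <= f < bio[1]:
                b += p
    if a + b == 0:
        return 0.0
    return (b - a) / (b + a)


def oracle_dsc(freqs, amp, fmin, fmax):
    rows = [k for k, f in enumerate(freqs) if fmin <= f <= fmax]
    centroids = []
    for t in range(len(amp[0])):
        mass = sum(amp[k][t] for k in rows)
        if mass > 0:
            centroids.append(sum(freqs[k] * amp[k][t] for k in rows) / mass)
    return sum(centroids) / len(centroids)


def oracle_normalized_entropy(values):
    total = sum(values)
    h = 0.0
    for v in values:
        q = v / total
        if q > 0:
            h -= q * math.log(q)
    return h / math.log(len(values))


def oracle_zcr(samples, sample_rate):
    crossings = 0
    for i in range(1, len(samples)):
        prev_pos = samples[i - 1] >= 0
        cur_pos = samples[i] >= 0
        if prev_pos != cur_pos:
            crossings += 1
    return crossings / (len(samples) / sample_rate)
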