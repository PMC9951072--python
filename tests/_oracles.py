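"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (linear scans, explicit
double loops, textbook formulas) and deliberately shares no code path with
the package internals it checks.
"""

from __future__ import annotations

import math


def band_level_linear_scan(indicator, value: float) -> int:
    """Severity level by scanning every band's [lo, hi) interval."""
    hits = [b.level for b in indicator.level_bands if b.lo <= value < b.hi]
    assert len(hits) == 1, f"{indicator.indicator_id}: {value} hit {hits}"
    return hits[0]


def brute_force_dimension_scores(record, window, catalog) -> dict[str, float]:
    """Re-score one resident by enumerating every observation.

    Mirrors the scoring rules independently: per-indicator most abnormal
    in-window value (locomotion as events/day, underweight as minimum BMI),
    single counting within equivalence sets with catalog-order tie-break,
    weight base**(level-1) - 1 summed per dimension.
    """
    base = catalog.weight_base
    days = (window.end_date - window.start_date).days
    in_window = [
        o for o in record.observations
        if window.start_date <= o.date < window.end_date
    ]

    levels: dict[str, int] = {}
    for ind in catalog.indicators:
        if ind.sex_specific is not None and ind.sex_specific != record.sex:
            continue
        if ind.aggregation == "daily_frequency_then_band":
            count = sum(
                o.value for o in in_window if o.indicator_id == ind.indicator_id
            )
            levels[ind.indicator_id] = band_level_linear_scan(ind, count / days)
        elif ind.indicator_id == "bmi_underweight":
            bmis = [
                v for d, v in record.bmi_series()
                if window.start_date <= d < window.end_date
            ]
            obs_vals = [
                o.value for o in in_window if o.indicator_id == ind.indicator_id
            ]
            bmis += obs_vals
            levels[ind.indicator_id] = (
                band_level_linear_scan(ind, min(bmis)) if bmis else 1
            )
        else:
            best = 1
            for o in in_window:
                if o.indicator_id == ind.indicator_id:
                    best = max(best, band_level_linear_scan(ind, o.value))
            levels[ind.indicator_id] = best

    # equivalence sets: keep only the most abnormal member (catalog order ties)
    suppressed: set[str] = set()
    for es in catalog.equivalence_sets:
        members = [m for m in es.member_indicator_ids if m in levels]
        if not members:
            continue
        best_level = max(levels[m] for m in members)
        keep = None
        for ind in catalog.indicators:  # catalog order
            if ind.indicator_id in members and levels[ind.indicator_id] == best_level:
                keep = ind.indicator_id
                break
        for m in members:
            if m != keep:
                suppressed.add(m)

    dims = {d: 0.0 for d in ("laboratory", "weights_vitals_pain",
                             "locomotion", "underweight")}
    for ind in catalog.indicators:
        iid = ind.indicator_id
        if iid not in levels or iid in suppressed:
            continue
        dims[ind.dimension_id] += base ** (levels[iid] - 1) - 1.0
    return dims


def all_pairs_concordance(outcome, scores) -> float:
    """C statistic by exhaustive pair enumeration, ties counted one half."""
    cases = [s for y, s in zip(outcome, scores) if y == 1]
    controls = [s for y, s in zip(outcome, scores) if y == 0]
    assert cases and controls
    num = 0.0
    for c in cases:
        for k in controls:
            num += 1.0 if c > k else (0.5 if c == k else 0.0)
    return num / (len(cases) * len(controls))


def textbook_pooled_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float]:
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, float(n1 + n2 - 2)


def textbook_welch_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float]:
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df


def textbook_chi_square(table) -> tuple[float, int]:
    """Pearson chi-square via the explicit O/E double loop."""
    r, c = len(table), len(table[0])
    row = [sum(table[i]) for i in range(r)]
    col = [sum(table[i][j] for i in range(r)) for j in range(c)]
    total = sum(row)
    chi2 = 0.0
    for i in range(r):
        for j in range(c):
            e = row[i] * col[j] / total
            chi2 += (table[i][j] - e) ** 2 / e
    return chi2, (r - 1) * (c - 1)


def pearson_by_hand(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
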