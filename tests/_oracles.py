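"""Independent brute-force oracles used only by the tests.

The metric oracle is a direct transliteration of the textbook formulas,
deliberately written without reference to the package implementation (which
clears denominators to integer arithmetic); agreement to 1e-12 on random
tables is therefore a genuine cross-check.
"""


def oracle_metrics(h, fa, m, cn):
    """All nine verification metrics; None where a denominator is zero."""
    n = h + fa + m + cn

    def div(a, b):
        return None if b == 0 else a / b

    h_random = (h + fa) * (h + m) / n
    pd_ = div(h, h + m)
    pfd = div(fa, cn + fa)
    ets_den = h + fa + m - h_random
    return {
        "accuracy": div(h + cn, n),
        "bias": div(h + fa, h + m),
        "pd": pd_,
        "pfd": pfd,
        "far": div(fa, h + fa),
        "ets": None if ets_den == 0 else (h - h_random) / ets_den,
        "ts": div(h, h + fa + m),
        "orss": div(h * cn - m * fa, h * cn + m * fa),
        "pss": None if (pd_ is None or pfd is None) else pd_ - pfd,
        "h_random": h_random,
    }


def oracle_monthly_climatology(sst, baseline):
    """Two-stage monthly means by explicit loops over years and months."""
    y0, y1 = baseline
    means = []
    for month in range(1, 13):
        per_year = []
        for year in range(y0, y1 + 1):
            days = sst[(sst.index.year == year) & (sst.index.month == month)]
            if len(days):
                per_year.append(days.mean())
        means.append(sum(per_year) / len(per_year))
    return means
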