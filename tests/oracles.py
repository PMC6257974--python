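"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written as plain spreadsheet-style arithmetic with
explicit loops over dictionaries — deliberately sharing no code with the
package implementation it checks.
"""

import math


def weibull_F(t, alpha, beta):
    return 1.0 - math.exp(-((t / alpha) ** beta))


def ols_slope(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    sse = sum((yi - (intercept + slope * xi)) ** 2 for xi, yi in zip(x, y))
    se = math.sqrt(sse / (n - 2) / sxx) if n > 2 else 0.0
    return slope, intercept, se


def cascade_oracle(ground_truth, params, out_years, window=10):
    """Brute-force patient counts for a toy configuration.

    ``ground_truth``: list of dicts with keys base_rate, apc, base_pop,
    pop_growth (one per stratum; rates follow exact geometric compounding
    from the year 2000).  ``params``: plain dict in the bundled YAML layout.
    Returns {(year, histology, lot): count} for second/third LOT.
    """
    def rate(st, year):
        return st["base_rate"] * (1.0 + st["apc"] / 100.0) ** (year - 2000)

    def pop(st, year):
        return st["base_pop"] * (1.0 + st["pop_growth"] / 100.0) ** (year - 2000)

    def incidence(year):
        return sum(rate(st, year) / 1e5 * pop(st, year) for st in ground_truth)

    sd = params["stage_dist"]
    known = sd["I"] + sd["II"] + sd["III"] + sd["IV"]
    redist = {s: sd[s] * 100.0 / known for s in ("I", "II", "III", "IV")}
    p3b = params["pct_IIIb_of_III"] / 100.0

    def early(year):
        nsclc = incidence(year) * params["pct_nsclc"] / 100.0
        return {
            "I": nsclc * redist["I"] / 100.0,
            "II": nsclc * redist["II"] / 100.0,
            "IIIA": nsclc * redist["III"] / 100.0 * (1.0 - p3b),
        }

    def advanced_at_dx(year):
        nsclc = incidence(year) * params["pct_nsclc"] / 100.0
        return nsclc * (redist["IV"] / 100.0 + redist["III"] / 100.0 * p3b)

    alphas = {s: 5.0 / (-math.log(1.0 - params["recurrence_5yr"][s] / 100.0))
              for s in ("I", "II", "IIIA")}

    out = {}
    hs = {"squamous": params["pct_squamous"], "nonsquamous": params["pct_nonsquamous"]}
    for year in out_years:
        progressed = 0.0
        for d in range(1, window + 1):
            cohort = early(year - d)
            for s, count in cohort.items():
                q = weibull_F(d, alphas[s], 1.0) - weibull_F(d - 1, alphas[s], 1.0)
                progressed += count * q
        advanced = advanced_at_dx(year) + progressed
        eligible = advanced * params["pct_eligible"] / 100.0
        for h, share in hs.items():
            for lot in ("second", "third"):
                out[(year, h, lot)] = (eligible * share / 100.0
                                       * params["lot_rates"][h][lot] / 100.0)
    return out
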