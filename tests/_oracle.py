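"""Independent brute-force oracle for the 2x2 screening statistics.

A literal transcription of the defining formulas, computed with exact
rational arithmetic (fractions.Fraction) up to the final log/exp, and kept
deliberately separate from the package implementation. Used only to
cross-check faersig.stats on random tables.
"""

from __future__ import annotations

import math
from fractions import Fraction


def oracle_stats(a: int, b: int, c: int, d: int,
                 g11=1, al=2, al1=1, be=2, be1=1, yates: bool = False) -> dict:
    corrected = min(a, b, c, d) == 0
    if corrected:
        A, B, C, D = (Fraction(2 * x + 1, 2) for x in (a, b, c, d))
    else:
        A, B, C, D = (Fraction(x) for x in (a, b, c, d))
    N = A + B + C + D

    ror = (A / C) / (B / D)
    se_ror = math.sqrt(float(1 / A + 1 / B + 1 / C + 1 / D))
    ror_ci = (math.exp(math.log(float(ror)) - 1.96 * se_ror),
              math.exp(math.log(float(ror)) + 1.96 * se_ror))

    prr = (A / (A + B)) / (C / (C + D))
    se_prr = math.sqrt(float(1 / A - 1 / (A + B) + 1 / C - 1 / (C + D)))
    prr_ci = (math.exp(math.log(float(prr)) - 1.96 * se_prr),
              math.exp(math.log(float(prr)) + 1.96 * se_prr))

    # chi-squared always on the raw integer cells
    ra, rb, rc, rd = (Fraction(x) for x in (a, b, c, d))
    rn = ra + rb + rc + rd
    denom = (ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)
    if denom == 0:
        chi2 = 0.0
    else:
        diff = abs(ra * rd - rb * rc)
        if yates:
            diff = max(Fraction(0), diff - rn / 2)
        chi2 = float(rn * diff * diff / denom)

    # BCPNN on the raw cells; Dirichlet priors keep everything finite
    if ra + rb == 0 or ra + rc == 0:
        ic_raw = math.nan
    elif ra == 0:
        ic_raw = -math.inf
    else:
        ic_raw = math.log2(float(ra * rn / ((ra + rb) * (ra + rc))))
    gamma = Fraction(g11) * (rn + al) * (rn + be) / ((ra + rb + al1) * (ra + rc + be1))
    ic_expect = math.log2(float(
        (ra + g11) * (rn + al) * (rn + be)
        / ((rn + gamma) * (ra + rb + al1) * (ra + rc + be1))
    ))
    ic_var = (1 / math.log(2) ** 2) * float(
        (rn - ra + gamma - g11) / ((ra + g11) * (1 + rn + gamma))
        + (rn - (ra + rb) + al - al1) / ((ra + rb + al1) * (1 + rn + al))
        + (rn - (ra + rc) + be - be1) / ((ra + rc + be1) * (1 + rn + be))
    )
    ic025 = ic_expect - 2 * math.sqrt(ic_var)

    ebgm = A * N / ((A + C) * (A + B))
    ebgm_ci = (math.exp(math.log(float(ebgm)) - 1.96 * se_ror),
               math.exp(math.log(float(ebgm)) + 1.96 * se_ror))

    return {
        "ror": float(ror), "ror_low": ror_ci[0], "ror_high": ror_ci[1],
        "prr": float(prr), "prr_low": prr_ci[0], "prr_high": prr_ci[1],
        "chi2": chi2,
        "ic_raw": ic_raw, "ic_expect": ic_expect, "ic_var": ic_var, "ic025": ic025,
        "ebgm": float(ebgm), "ebgm_low": ebgm_ci[0], "ebgm_high": ebgm_ci[1],
        "corrected": corrected,
    }
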