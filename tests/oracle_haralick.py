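"""Independent brute-force reference for the 13 Haralick statistics.

Written directly from the textbook double-sum definitions with explicit
Python loops and 1-based gray levels; deliberately shares no code with the
package implementation.
"""

import math


def brute_force_haralick(p_rows):
    """p_rows: list of lists, normalized co-occurrence probabilities."""
    n = len(p_rows)
    levels = [i + 1 for i in range(n)]

    def log0(v):
        return math.log(v) if v > 0 else 0.0

    # marginals: p_x(j) sums over rows, p_y(i) over columns
    p_x = [sum(p_rows[i][j] for i in range(n)) for j in range(n)]
    p_y = [sum(p_rows[i][j] for j in range(n)) for i in range(n)]
    p_sum = {k: 0.0 for k in range(2, 2 * n + 1)}
    p_diff = {k: 0.0 for k in range(0, n)}
    for i in range(n):
        for j in range(n):
            p_sum[levels[i] + levels[j]] += p_rows[i][j]
            p_diff[abs(levels[i] - levels[j])] += p_rows[i][j]

    out = {}
    out["asm"] = sum(p_rows[i][j] ** 2 for i in range(n) for j in range(n))
    out["contrast"] = sum((levels[i] - levels[j]) ** 2 * p_rows[i][j]
                          for i in range(n) for j in range(n))

    mu_x = sum(levels[j] * p_x[j] for j in range(n))
    mu_y = sum(levels[i] * p_y[i] for i in range(n))
    sd_x = math.sqrt(sum((levels[j] - mu_x) ** 2 * p_x[j] for j in range(n)))
    sd_y = math.sqrt(sum((levels[i] - mu_y) ** 2 * p_y[i] for i in range(n)))
    cross = sum(levels[i] * levels[j] * p_rows[i][j] for i in range(n) for j in range(n))
    out["correlation"] = ((cross - mu_x * mu_y) / (sd_x * sd_y)
                          if sd_x > 0 and sd_y > 0 else 0.0)

    mu = sum(levels[i] * p_rows[i][j] for i in range(n) for j in range(n))
    out["variance"] = sum((levels[i] - mu) ** 2 * p_rows[i][j]
                          for i in range(n) for j in range(n))
    out["idm"] = sum(p_rows[i][j] / (1 + (levels[i] - levels[j]) ** 2)
                     for i in range(n) for j in range(n))
    out["sum_average"] = sum(k * p_sum[k] for k in p_sum)
    out["sum_variance"] = sum((k - out["sum_average"]) ** 2 * p_sum[k] for k in p_sum)
    out["sum_entropy"] = -sum(p_sum[k] * log0(p_sum[k]) for k in p_sum)
    out["entropy"] = -sum(p_rows[i][j] * log0(p_rows[i][j])
                          for i in range(n) for j in range(n))
    mu_d = sum(k * p_diff[k] for k in p_diff)
    out["difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in p_diff)
    out["difference_entropy"] = -sum(p_diff[k] * log0(p_diff[k]) for k in p_diff)

    hxy = out["entropy"]
    hx = -sum(p_x[j] * log0(p_x[j]) for j in range(n))
    hy = -sum(p_y[i] * log0(p_y[i]) for i in range(n))
    hxy1 = -sum(p_rows[i][j] * log0(p_x[j] * p_y[i])
                for i in range(n) for j in range(n))
    hxy2 = -sum(p_x[j] * p_y[i] * log0(p_x[j] * p_y[i])
                for i in range(n) for j in range(n))
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = math.sqrt(abs(1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out
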