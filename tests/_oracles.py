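"""Independent brute-force oracles, deliberately written with plain
loops and the statistics module so they share no code path with the
package implementations they check."""
import itertools
import math
import statistics


def cv_oracle(values):
    return 100.0 * statistics.stdev(values) / statistics.mean(values)


def multilevel_cv_oracle(rows):
    """Spreadsheet-style four-level CVs for a single-parameter long
    table given as (individual, locality, group, value) tuples."""
    by_ind, ind_loc, ind_grp = {}, {}, {}
    for ind, loc, grp, value in rows:
        by_ind.setdefault(ind, []).append(value)
        ind_loc[ind] = loc
        ind_grp[ind] = grp
    cv_i = {ind: cv_oracle(vals) for ind, vals in by_ind.items()}
    means = {ind: statistics.mean(vals) for ind, vals in by_ind.items()}
    by_loc, by_grp = {}, {}
    for ind, mean in means.items():
        by_loc.setdefault(ind_loc[ind], []).append(mean)
        by_grp.setdefault(ind_grp[ind], []).append(mean)
    cv_p = {loc: cv_oracle(v) for loc, v in by_loc.items() if len(v) >= 2}
    cv_g = {grp: cv_oracle(v) for grp, v in by_grp.items() if len(v) >= 2}
    cv_o = cv_oracle(list(means.values()))
    return cv_i, cv_p, cv_g, cv_o


def anova_oracle(values, labels):
    """One-way ANOVA sums of squares by enumeration."""
    grand = statistics.mean(values)
    groups = {}
    for v, lab in zip(values, labels):
        groups.setdefault(lab, []).append(v)
    ss_between = sum(len(g) * (statistics.mean(g) - grand) ** 2
                     for g in groups.values())
    ss_total = sum((v - grand) ** 2 for v in values)
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    ss_within = ss_total - ss_between
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between, ss_within, ss_between / ss_total


def pearson_oracle(x, y):
    mx, my = statistics.mean(x), statistics.mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den


def mantel_exhaustive_oracle(a, b):
    """(r_observed, one-tailed-upper p) by enumerating all n!
    relabelings of matrix b.  Matrices are lists of lists."""
    n = len(a)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    x = [a[i][j] for i, j in pairs]
    r_obs = pearson_oracle(x, [b[i][j] for i, j in pairs])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        y = [b[perm[i]][perm[j]] for i, j in pairs]
        if pearson_oracle(x, y) >= r_obs - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


def ranksum_exact_oracle(a, b):
    """Two-sided exact rank-sum p by enumerating all C(n+m, n)
    assignments of the pooled ranks."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    observed = sum(ranks[v] for v in a)
    n = len(a)
    mean_stat = n * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        stat = sum(combo)
        if abs(stat - mean_stat) >= abs(observed - mean_stat) - 1e-12:
            count += 1
        total += 1
    return count / total


def best_window_oracle(scores, k):
    """Index of the k-length window with maximal sum, by full scan."""
    best_i, best_sum = 0, -math.inf
    for i in range(len(scores) - k + 1):
        s = sum(scores[i:i + k])
        if s > best_sum:
            best_i, best_sum = i, s
    return best_i


def dft_power_oracle(frame):
    """Direct O(n^2) DFT power spectrum (one-sided)."""
    n = len(frame)
    out = []
    for k in range(n // 2 + 1):
        re = sum(frame[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = -sum(frame[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        out.append(re * re + im * im)
    return out
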