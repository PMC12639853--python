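"""Independent brute-force oracles used only by the test suite.

The ANOVA oracle implements the textbook weighted-means sums of squares
with explicit Python loops over marginal means — deliberately naive and
structurally unrelated to the contrast-projection implementation it
checks.
"""

import numpy as np


def oneway_anova_oracle(groups):
    """Classical one-way between-subjects ANOVA from group lists."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


def within_anova_oracle(Y):
    """Fully within-subjects two-factor ANOVA, Y shape (n, a, b).

    Returns {effect: (F, df_num, df_den)} for A, B, A*B using the
    standard subject-interaction error terms.
    """
    n, a, b = Y.shape
    grand = Y.mean()
    Ys = Y.mean(axis=(1, 2))
    Yi = Y.mean(axis=(0, 2))
    Yj = Y.mean(axis=(0, 1))
    Yij = Y.mean(axis=0)
    Ysi = Y.mean(axis=2)
    Ysj = Y.mean(axis=1)

    ss_a = n * b * sum((Yi[i] - grand) ** 2 for i in range(a))
    ss_as = b * sum((Ysi[s, i] - Ys[s] - Yi[i] + grand) ** 2
                    for s in range(n) for i in range(a))
    ss_b = n * a * sum((Yj[j] - grand) ** 2 for j in range(b))
    ss_bs = a * sum((Ysj[s, j] - Ys[s] - Yj[j] + grand) ** 2
                    for s in range(n) for j in range(b))
    ss_ab = n * sum((Yij[i, j] - Yi[i] - Yj[j] + grand) ** 2
                    for i in range(a) for j in range(b))
    ss_abs = sum((Y[s, i, j] - Ysi[s, i] - Ysj[s, j] + Ys[s]
                  - Yij[i, j] + Yi[i] + Yj[j] - grand) ** 2
                 for s in range(n) for i in range(a) for j in range(b))
    out = {}
    out["A"] = ((ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1))),
                a - 1, (a - 1) * (n - 1))
    out["B"] = ((ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1))),
                b - 1, (b - 1) * (n - 1))
    out["A*B"] = ((ss_ab / ((a - 1) * (b - 1)))
                  / (ss_abs / ((a - 1) * (b - 1) * (n - 1))),
                  (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1))
    return out


def mixed_anova_oracle(Y, group_sizes):
    """Mixed design oracle: Y shape (N, a, b) ordered by group, one within
    pair of factors (use b == 1 for a single within factor); groups of
    sizes `group_sizes`. Weighted-means solution with equal subject weight.

    Returns {effect: (F, df_num, df_den)}.
    """
    N, a, b = Y.shape
    G = len(group_sizes)
    idx = np.repeat(np.arange(G), group_sizes)
    grand = Y.mean()
    Ys = Y.mean(axis=(1, 2))
    Yg = np.array([Ys[idx == g].mean() for g in range(G)])
    Yi = Y.mean(axis=(0, 2))
    Ygi = np.array([Y[idx == g].mean(axis=(0, 2)) for g in range(G)])
    Ysi = Y.mean(axis=2)
    Yj = Y.mean(axis=(0, 1))
    Ygj = np.array([Y[idx == g].mean(axis=(0, 1)) for g in range(G)])
    Ysj = Y.mean(axis=1)
    Yij = Y.mean(axis=0)
    Ygij = np.array([Y[idx == g].mean(axis=0) for g in range(G)])

    n_g = np.asarray(group_sizes)
    ss_grp = a * b * sum(n_g[g] * (Yg[g] - grand) ** 2 for g in range(G))
    ss_sg = a * b * sum((Ys[s] - Yg[idx[s]]) ** 2 for s in range(N))
    ss_a = b * N * sum((Yi[i] - grand) ** 2 for i in range(a))
    ss_ag = b * sum(n_g[g] * (Ygi[g, i] - Yg[g] - Yi[i] + grand) ** 2
                    for g in range(G) for i in range(a))
    ss_asg = b * sum((Ysi[s, i] - Ys[s] - Ygi[idx[s], i] + Yg[idx[s]]) ** 2
                     for s in range(N) for i in range(a))
    ss_b = a * N * sum((Yj[j] - grand) ** 2 for j in range(b))
    ss_bg = a * sum(n_g[g] * (Ygj[g, j] - Yg[g] - Yj[j] + grand) ** 2
                    for g in range(G) for j in range(b))
    ss_bsg = a * sum((Ysj[s, j] - Ys[s] - Ygj[idx[s], j] + Yg[idx[s]]) ** 2
                     for s in range(N) for j in range(b))
    ss_ab = N * sum((Yij[i, j] - Yi[i] - Yj[j] + grand) ** 2
                    for i in range(a) for j in range(b))
    ss_abg = sum(n_g[g] * (Ygij[g, i, j] - Ygi[g, i] - Ygj[g, j] + Yg[g]
                           - Yij[i, j] + Yi[i] + Yj[j] - grand) ** 2
                 for g in range(G) for i in range(a) for j in range(b))
    ss_absg = sum((Y[s, i, j] - Ysi[s, i] - Ysj[s, j] + Ys[s]
                   - Ygij[idx[s], i, j] + Ygi[idx[s], i] + Ygj[idx[s], j]
                   - Yg[idx[s]]) ** 2
                  for s in range(N) for i in range(a) for j in range(b))

    out = {}

    def F(ss_eff, df_eff, ss_err, df_err):
        return ((ss_eff / df_eff) / (ss_err / df_err), df_eff, df_err)

    out["group"] = F(ss_grp, G - 1, ss_sg, N - G)
    out["A"] = F(ss_a, a - 1, ss_asg, (a - 1) * (N - G))
    out["A*group"] = F(ss_ag, (a - 1) * (G - 1), ss_asg, (a - 1) * (N - G))
    if b > 1:
        out["B"] = F(ss_b, b - 1, ss_bsg, (b - 1) * (N - G))
        out["B*group"] = F(ss_bg, (b - 1) * (G - 1), ss_bsg, (b - 1) * (N - G))
        out["A*B"] = F(ss_ab, (a - 1) * (b - 1), ss_absg,
                       (a - 1) * (b - 1) * (N - G))
        out["A*B*group"] = F(ss_abg, (a - 1) * (b - 1) * (G - 1), ss_absg,
                             (a - 1) * (b - 1) * (N - G))
    return out
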