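"""Independent brute-force oracle for the mixed repeated-measures ANOVA.

Everything here is computed from first principles with explicit loops,
cell means and the Box/centering-matrix form of the sphericity epsilon --
deliberately a different route from the packaged implementation (which
works through orthonormal contrast scores), so the two can check each
other.  Only one between-subjects factor and one within factor are
supported; that is all the oracle needs.
"""

import numpy as np


def bruteforce_mixed_anova(y: np.ndarray, groups: np.ndarray) -> dict:
    """y : (n_subjects, k_levels); groups : group label per subject.

    Returns F, dfs, Greenhouse-Geisser epsilon, and generalized
    eta-squared (group treated as observed) for the group, within and
    interaction effects, plus the total SS for bookkeeping.
    """
    n, k = y.shape
    labels = list(dict.fromkeys(groups))
    g_idx = {g: np.flatnonzero(groups == g) for g in labels}
    n_g = {g: len(ix) for g, ix in g_idx.items()}
    G = len(labels)

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = {g: y[ix].mean() for g, ix in g_idx.items()}
    level_means = y.mean(axis=0)
    cell_means = {g: y[ix].mean(axis=0) for g, ix in g_idx.items()}

    ss_group = k * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in labels)
    ss_subj = k * sum((subj_means[i] - group_means[g]) ** 2
                      for g in labels for i in g_idx[g])
    ss_within = n * ((level_means - grand) ** 2).sum()
    ss_inter = sum(n_g[g] * (cell_means[g][c] - group_means[g]
                             - level_means[c] + grand) ** 2
                   for g in labels for c in range(k))
    ss_err = sum((y[i, c] - subj_means[i] - cell_means[g][c]
                  + group_means[g]) ** 2
                 for g in labels for i in g_idx[g] for c in range(k))
    ss_total = ((y - grand) ** 2).sum()

    df_group, df_subj = G - 1, n - G
    df_within, df_inter, df_err = k - 1, (k - 1) * (G - 1), (k - 1) * (n - G)

    # pooled within-group covariance, double-centered (Box form)
    S = np.zeros((k, k))
    for g, ix in g_idx.items():
        resid = y[ix] - y[ix].mean(axis=0)
        S += resid.T @ resid
    S /= df_subj
    P = np.eye(k) - np.ones((k, k)) / k
    Sc = P @ S @ P
    eps = float(np.trace(Sc) ** 2 / ((k - 1) * np.trace(Sc @ Sc)))
    eps = min(1.0, max(1.0 / (k - 1), eps))

    F_group = (ss_group / df_group) / (ss_subj / df_subj)
    F_within = (ss_within / df_within) / (ss_err / df_err)
    F_inter = (ss_inter / df_inter) / (ss_err / df_err)

    errors = ss_subj + ss_err
    return {
        "group": {"F": F_group, "df": (df_group, df_subj), "eps": 1.0,
                  "eta2_g": ss_group / (ss_group + errors)},
        "within": {"F": F_within, "df": (df_within, df_err), "eps": eps,
                   "eta2_g": ss_within / (ss_within + errors + ss_group)},
        "interaction": {"F": F_inter, "df": (df_inter, df_err), "eps": eps,
                        "eta2_g": ss_inter / (ss_inter + errors + ss_group)},
        "ss_total": ss_total,
        "ss_parts": ss_group + ss_subj + ss_within + ss_inter + ss_err,
    }
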