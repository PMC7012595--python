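"""Independent oracles shared across test modules.

Everything here is deliberately brute-force and kept independent of the
implementation paths it checks.
"""

import numpy as np


def efron_loglik(beta, entry, exit_age, event, x):
    """Hand-coded Efron partial log-likelihood, one covariate, left truncation."""
    beta = float(beta)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(exit_age[event == 1]):
        D = (exit_age == t) & (event == 1)
        R = (entry < t) & (exit_age >= t)
        d = int(D.sum())
        sR, sD = theta[R].sum(), theta[D].sum()
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD)
    return ll


def rmcorr_ancova(x, y, subjects):
    """rmcorr via the ANCOVA sums-of-squares decomposition.

    Fit y ~ subject dummies + common slope * x by least squares;
    r^2 = SS_model(x) / (SS_model(x) + SS_error), signed by the slope.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subs, inv = np.unique(subjects, return_inverse=True)
    k = len(subs)
    D = np.zeros((len(x), k))
    D[np.arange(len(x)), inv] = 1.0
    X_full = np.column_stack([D, x])
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    resid_full = y - X_full @ beta
    sse = float(resid_full @ resid_full)
    beta0, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid_red = y - D @ beta0
    ss_model = float(resid_red @ resid_red) - sse
    r2 = ss_model / (ss_model + sse)
    return float(np.sign(beta[-1]) * np.sqrt(r2))


def ward_lance_williams(d2):
    """Agglomerative Ward on a squared-distance matrix via Lance-Williams.

    Returns the merge list [(i, j, height)] with scipy-style cluster ids
    (originals 0..n-1, merges numbered onward); heights on the scipy scale
    (Euclidean), i.e. sqrt of the Ward-updated squared distance.
    """
    d2 = np.array(d2, dtype=float)
    n = d2.shape[0]
    active = {i: (i, 1) for i in range(n)}       # key -> (cluster id, size)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d2[i, j]
    merges = []
    next_id = n
    keys = sorted(active)
    while len(keys) > 1:
        best = min(
            ((a, b) for ai, a in enumerate(keys) for b in keys[ai + 1:]),
            key=lambda ab: (dist[ab], ab),
        )
        i, j = best
        dij = dist[(i, j)]
        id_i, n_i = active[i]
        id_j, n_j = active[j]
        merges.append((id_i, id_j, np.sqrt(dij)))
        for k in keys:
            if k in (i, j):
                continue
            n_k = active[k][1]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            upd = ((n_i + n_k) * dik + (n_j + n_k) * djk - n_k * dij) / \
                (n_i + n_j + n_k)
            dist[tuple(sorted((i, k)))] = upd     # reuse slot i for the merge
        active[i] = (next_id, n_i + n_j)
        next_id += 1
        del active[j]
        keys = sorted(active)
    return merges


def balanced_sample_cohort(rng, n_pairs=100, n_visits=4, beta=(2.0, 0.3, 1.5),
                           s_pair=2.0, s_ind=3.0, s_eps=1.0):
    """Small nested two-level dataset: y = b0 + b1*age + b2*sex + u_p + u_i + e."""
    n_ind = 2 * n_pairs
    pair = np.repeat(np.arange(n_pairs), 2 * n_visits)
    ind = np.repeat(np.arange(n_ind), n_visits)
    age = rng.uniform(50, 90, n_ind * n_visits)
    sex = np.repeat(rng.integers(0, 2, n_ind), n_visits).astype(float)
    y = (beta[0] + beta[1] * age + beta[2] * sex
         + np.repeat(rng.normal(0, s_pair, n_pairs), 2 * n_visits)
         + np.repeat(rng.normal(0, s_ind, n_ind), n_visits)
         + rng.normal(0, s_eps, n_ind * n_visits))
    X = np.column_stack([np.ones_like(y), age, sex])
    return y, X, pair, ind
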