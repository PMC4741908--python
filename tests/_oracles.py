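"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (log-factorial enumeration, explicit
pairwise loops, grid-free scipy optimization) that share no code with the
package, so agreement is evidence and not tautology.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln


def hwe_enumeration_pvalues(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact p-value for every heterozygote count at (n diploids, n_rare).

    Probabilities follow P(h) = n! / (r_hom! h! c_hom!) * 2^h * n_rare!
    (2n-n_rare)! / (2n)! evaluated via log-gamma, the direct closed form of
    the conditional distribution of heterozygote counts given allele
    counts.  Returns (heterozygote counts, two-sided exact p-values).
    """
    if n_rare == 0:
        return np.array([0]), np.array([1.0])
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    r_hom = (n_rare - hets) // 2
    c_hom = n - hets - r_hom
    logp = (
        gammaln(n + 1)
        - gammaln(r_hom + 1)
        - gammaln(hets + 1)
        - gammaln(c_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    pvals = np.array(
        [min(probs[probs <= probs[i] * (1 + 1e-12)].sum(), 1.0) for i in range(hets.size)]
    )
    return hets, pvals


def auc_pairwise(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC by explicit enumeration of all case-control pairs."""
    wins = 0.0
    for x in cases:
        for y in controls:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def delong_brute_force(scores_a, scores_b, labels):
    """Placement-value variances/covariance by explicit loops."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(bool)
    xa, ya = scores_a[labels], scores_a[~labels]
    xb, yb = scores_b[labels], scores_b[~labels]
    m, n = len(xa), len(ya)

    def psi(u, v):
        return 1.0 if u > v else (0.5 if u == v else 0.0)

    def placements(x, y):
        v10 = [sum(psi(xi, yj) for yj in y) / n for xi in x]
        v01 = [sum(psi(xi, yj) for xi in x) / m for yj in y]
        return np.array(v10), np.array(v01)

    v10a, v01a = placements(xa, ya)
    v10b, v01b = placements(xb, yb)
    auc_a, auc_b = v10a.mean(), v10b.mean()

    def cov(u, v, mu_u, mu_v):
        return sum((ui - mu_u) * (vi - mu_v) for ui, vi in zip(u, v)) / (len(u) - 1)

    var_a = cov(v10a, v10a, auc_a, auc_a) / m + cov(v01a, v01a, auc_a, auc_a) / n
    var_b = cov(v10b, v10b, auc_b, auc_b) / m + cov(v01b, v01b, auc_b, auc_b) / n
    cov_ab = cov(v10a, v10b, auc_a, auc_b) / m + cov(v01a, v01b, auc_a, auc_b) / n
    return auc_a, auc_b, var_a, var_b, cov_ab


def logistic_mle_dosage(dosages: np.ndarray, labels: np.ndarray) -> float:
    """Dosage coefficient of status ~ intercept + dosage by direct
    likelihood maximization (Nelder-Mead refined by BFGS)."""

    def nll(beta):
        eta = beta[0] + beta[1] * dosages
        return np.sum(np.logaddexp(0.0, eta) - labels * eta)

    res = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    res = minimize(nll, x0=res.x, method="BFGS", options={"gtol": 1e-12})
    return float(res.x[1])


def wilcoxon_exact_pvalue(cases: np.ndarray, controls: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments
    (no ties assumed; feasible for combined n around 20)."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([cases, controls])
    ranks = rankdata(pooled)
    n1 = len(cases)
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(observed - mu) - 1e-9:
            count += 1
    return count / total
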