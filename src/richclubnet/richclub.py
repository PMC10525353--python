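"""Weighted rich-club coefficient, rewired null ensemble and existence test.

The weighted rich-club coefficient Φw(κ) asks whether the sub-network of
hub nodes (binary degree > κ) concentrates the strongest connections: it is
the total weight inside that subgraph divided by the sum of the equally many
strongest edge weights anywhere in the network, so Φw(κ) ∈ [0, 1] and equals
1 when the hub core monopolises the top weights.

Because high-degree nodes interconnect by chance, Φw is normalized against
an ensemble of random networks that preserve each node's degree exactly and
the multiset of edge weights exactly (Maslov–Sneppen double edge swaps on
the binary topology followed by a random reassignment of the original
weights).  Φnorm(κ) = Φw(κ) / ⟨Φw,rand(κ)⟩ > 1 over a range of κ indicates
rich-club organization; an AUC permutation test against the null ensemble
makes that criterion inferential.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from numba import njit
from scipy import stats

from .io import WeightedConnectome, make_connectome

__all__ = [
    "RichClubCurve",
    "RichClubTestResult",
    "weighted_rich_club_curve",
    "rewire_preserving_degree_and_weights",
    "normalized_rich_club",
    "rich_club_existence_test",
    "average_connectome",
    "curve_auc",
]


@dataclasses.dataclass(frozen=True)
class RichClubCurve:
    """Φ(κ) and, when a null ensemble was used, its normalization.

    Arrays are indexed by ``kappa_grid``; undefined entries (no edges in the
    >κ subgraph, or no defined null value) are NaN — never silently zero.
    """

    kappa_grid: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray | None = None
    phi_rand_sd: np.ndarray | None = None
    phi_norm: np.ndarray | None = None
    auc_norm: float | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.phi)


@dataclasses.dataclass(frozen=True)
class RichClubTestResult:
    observed_auc: float
    null_auc_values: np.ndarray
    p_value: float
    p_ttest: float
    n_permutations: int
    decision: bool
    alpha: float
    curve: RichClubCurve


def _phi_values(weights: np.ndarray) -> np.ndarray:
    """Φw(κ) for κ = 1..κmax (NaN where the >κ subgraph has no edges)."""
    deg = (weights > 0).sum(axis=1)
    iu, ju = np.nonzero(np.triu(weights, 1))
    if iu.size == 0:
        raise ValueError("no edges: rich-club coefficient undefined")
    ew = weights[iu, ju]
    order = np.argsort(ew)[::-1]
    cum_top = np.concatenate([[0.0], np.cumsum(ew[order])])
    kmax = int(deg.max())
    phi = np.full(kmax, np.nan)
    for k in range(1, kmax + 1):
        in_club = deg > k
        mask = in_club[iu] & in_club[ju]
        e_k = int(mask.sum())
        if e_k == 0:
            break  # subgraphs only shrink with κ: defined range is a prefix
        phi[k - 1] = ew[mask].sum() / cum_top[e_k]
    return phi


def weighted_rich_club_curve(c: WeightedConnectome) -> RichClubCurve:
    """Observed Φw(κ) over κ = 1..κmax (no normalization)."""
    phi = _phi_values(c.weights)
    kappa = np.arange(1, phi.size + 1)
    return RichClubCurve(kappa_grid=kappa, phi=phi)


@njit(cache=False)
def _swap_loop(eu, ev, adj, target_swaps, max_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    m = eu.size
    accepted = 0
    attempts = 0
    while accepted < target_swaps and attempts < max_attempts:
        attempts += 1
        a = np.random.randint(0, m)
        b = np.random.randint(0, m)
        if a == b:
            continue
        u, v = eu[a], ev[a]
        x, y = eu[b], ev[b]
        if np.random.randint(0, 2) == 1:
            x, y = y, x
        # propose replacing (u,v),(x,y) with (u,x),(v,y)
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = adj[v, u] = False
        adj[x, y] = adj[y, x] = False
        adj[u, x] = adj[x, u] = True
        adj[v, y] = adj[y, v] = True
        eu[a], ev[a] = u, x
        eu[b], ev[b] = v, y
        accepted += 1
    return accepted


def rewire_preserving_degree_and_weights(
    c: WeightedConnectome,
    seed: int,
    swap_factor: int = 10,
) -> WeightedConnectome:
    """Degree- and weight-multiset-preserving randomization of a connectome.

    Maslov–Sneppen double edge swaps are applied to the binary topology
    (``swap_factor`` × |E| accepted swaps are targeted; swaps that would
    create self-loops or multi-edges are rejected), then the original edge
    weights are reassigned to the rewired edge list in a random permutation.
    The degree sequence and the multiset of edge weights are preserved
    exactly.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    iu, ju, ew = c.edge_list()
    m = iu.size
    if m < 2:
        warnings.warn("fewer than 2 edges: returning weight-shuffled original")
        accepted = 1  # nothing to swap but permutation below still applies
        eu, ev = iu.copy(), ju.copy()
    else:
        eu, ev = iu.astype(np.int64).copy(), ju.astype(np.int64).copy()
        adj = c.weights > 0
        target = swap_factor * m
        max_attempts = max(1000, 40 * target)
        accepted = _swap_loop(
            eu, ev, adj.copy(), target, max_attempts,
            int(rng.integers(0, 2**31 - 1)),
        )
        if accepted == 0:
            warnings.warn(
                "no valid double edge swap found (graph too small or dense); "
                "returning weight-shuffled original topology"
            )
            eu, ev = iu.copy(), ju.copy()
    w_new = np.zeros_like(c.weights)
    perm = rng.permutation(m)
    w_new[eu, ev] = ew[perm]
    w_new[ev, eu] = ew[perm]
    return make_connectome(w_new, node_ids=c.node_ids,
                           subject_id=f"{c.subject_id}__rewired")


def _null_phi_matrix(
    c: WeightedConnectome, n: int, seed: int, swap_factor: int
) -> np.ndarray:
    """Φ curves of ``n`` freshly rewired nulls, padded with NaN to equal κmax."""
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    curves = []
    kmax = 0
    for s in seeds:
        null = rewire_preserving_degree_and_weights(c, int(s), swap_factor)
        phi = _phi_values(null.weights)
        kmax = max(kmax, phi.size)
        curves.append(phi)
    out = np.full((n, kmax), np.nan)
    for i, phi in enumerate(curves):
        out[i, : phi.size] = phi
    return out


def curve_auc(kappa: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal AUC over the κ where ``values`` is defined (finite)."""
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("degenerate curve: fewer than 2 defined κ values")
    return float(np.trapezoid(values[ok], kappa[ok]))


def normalized_rich_club(
    c: WeightedConnectome,
    m: int = 1000,
    seed: int = 0,
    swap_factor: int = 10,
) -> RichClubCurve:
    """Φnorm(κ) = Φ(κ) / mean Φrand(κ) over an ``m``-member null ensemble."""
    if m < 2:
        raise ValueError("need m >= 2 null networks")
    phi = _phi_values(c.weights)
    nulls = _null_phi_matrix(c, m, seed, swap_factor)
    kmax = max(phi.size, nulls.shape[1])
    phi = np.pad(phi, (0, kmax - phi.size), constant_values=np.nan)
    nulls = np.pad(nulls, ((0, 0), (0, kmax - nulls.shape[1])),
                   constant_values=np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        rand_mean = np.nanmean(nulls, axis=0)
        rand_sd = np.nanstd(nulls, axis=0, ddof=1)
    phi_norm = np.full(kmax, np.nan)
    ok = np.isfinite(phi) & np.isfinite(rand_mean) & (rand_mean > 0)
    phi_norm[ok] = phi[ok] / rand_mean[ok]
    kappa = np.arange(1, kmax + 1)
    auc = curve_auc(kappa, phi_norm) if np.isfinite(phi_norm).sum() >= 2 else None
    return RichClubCurve(
        kappa_grid=kappa, phi=phi, phi_rand_mean=rand_mean,
        phi_rand_sd=rand_sd, phi_norm=phi_norm, auc_norm=auc,
    )


def _has_contiguous_exceedance(phi_norm: np.ndarray, min_len: int = 2) -> bool:
    """True if Φnorm > 1 over at least ``min_len`` consecutive defined κ."""
    above = np.isfinite(phi_norm) & (phi_norm > 1.0)
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= min_len:
            return True
    return False


def rich_club_existence_test(
    c: WeightedConnectome,
    m: int = 1000,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    swap_factor: int = 10,
) -> RichClubTestResult:
    """Permutation test for rich-club organization.

    The observed statistic is the trapezoidal AUC of Φ(κ); the null
    distribution is the AUCs of Φrand curves from freshly rewired networks.
    Two-tailed p with the +1 correction: p = 2·min(P(null ≥ obs),
    P(null ≤ obs)), each (b+1)/(n+1), capped at 1.  A one-sample two-tailed
    t-test of the null AUC sample against the observed AUC is reported
    alongside.  The decision requires p < alpha AND Φnorm(κ) > 1 over a
    contiguous κ range (≥ 2 consecutive κ); Φnorm uses the first ``m``
    ensemble members.
    """
    n_total = max(m, n_perm)
    phi = _phi_values(c.weights)
    if np.isfinite(phi).sum() < 2:
        raise ValueError("degenerate curve: fewer than 2 defined κ values")
    nulls = _null_phi_matrix(c, n_total, seed, swap_factor)
    kmax = max(phi.size, nulls.shape[1])
    phi = np.pad(phi, (0, kmax - phi.size), constant_values=np.nan)
    nulls = np.pad(nulls, ((0, 0), (0, kmax - nulls.shape[1])),
                   constant_values=np.nan)
    kappa = np.arange(1, kmax + 1)
    observed_auc = curve_auc(kappa, phi)
    null_aucs = np.array(
        [curve_auc(kappa, nulls[i]) for i in range(n_perm)]
    )
    n = null_aucs.size
    p_hi = (np.sum(null_aucs >= observed_auc) + 1) / (n + 1)
    p_lo = (np.sum(null_aucs <= observed_auc) + 1) / (n + 1)
    p_value = min(1.0, 2.0 * min(p_hi, p_lo))
    if np.ptp(null_aucs) == 0 and null_aucs[0] == observed_auc:
        p_ttest = 1.0
    else:
        p_ttest = float(stats.ttest_1samp(null_aucs, observed_auc).pvalue)

    ens = nulls[:m]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rand_mean = np.nanmean(ens, axis=0)
        rand_sd = np.nanstd(ens, axis=0, ddof=1)
    phi_norm = np.full(kmax, np.nan)
    ok = np.isfinite(phi) & np.isfinite(rand_mean) & (rand_mean > 0)
    phi_norm[ok] = phi[ok] / rand_mean[ok]
    curve = RichClubCurve(
        kappa_grid=kappa, phi=phi, phi_rand_mean=rand_mean,
        phi_rand_sd=rand_sd, phi_norm=phi_norm,
        auc_norm=curve_auc(kappa, phi_norm)
        if np.isfinite(phi_norm).sum() >= 2 else None,
    )
    decision = bool(p_value < alpha and _has_contiguous_exceedance(phi_norm))
    return RichClubTestResult(
        observed_auc=observed_auc, null_auc_values=null_aucs,
        p_value=float(p_value), p_ttest=p_ttest, n_permutations=n,
        decision=decision, alpha=alpha, curve=curve,
    )


def average_connectome(connectomes: list[WeightedConnectome],
                       subject_id: str = "group_mean") -> WeightedConnectome:
    """Element-wise mean connectome (the group-averaged matrix on which the
    cohort-level existence test is run by default)."""
    if not connectomes:
        raise ValueError("no connectomes to average")
    w = np.mean([c.weights for c in connectomes], axis=0)
    return make_connectome(w, node_ids=connectomes[0].node_ids,
                           subject_id=subject_id)
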