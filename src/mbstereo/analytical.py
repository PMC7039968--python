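"""Expected PRED stereotypy in a binary PN/KC threshold network.

The simplified network has binary PN odor patterns (each PN active with
probability ``pn_active_prob``), a binary random PN-KC connection matrix
drawn independently per individual (entry probability ``conn_prob``) and
binary KCs that fire when the number of their active connected PNs reaches
the integer threshold ``kc_threshold``.  The population response to an
odor is the count of active KCs, and stereotypy is the expected PRED of
these counts over two random odors and two random individuals.

Two routes are provided.  :func:`expected_pred_enumeration` computes the
expectation exactly on small instances:

1. the two odors' PN patterns reduce to the triple (w1, w2, m) of active
   counts and overlap, with a trinomial law over PNs;
2. given the triple, each KC's joint activation for the two odors follows
   from independent binomial counts of connected-active PNs on the overlap
   and the two exclusive sets;
3. an n_kcs-fold convolution (dynamic program) yields the exact joint pmf
   of the two response counts for one individual, identical and
   independent across individuals;
4. the PRED ratio is averaged exactly over the two individuals' response
   pairs.

:func:`expected_pred_monte_carlo` estimates the same quantity by direct
simulation at realistic sizes, with a standard error.  The ``shuffled``
mode draws odor 2's pattern as a random permutation of odor 1's, the
condition under which stereotypy vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "BinaryModelParams",
    "default_threshold",
    "expected_active_fraction",
    "expected_pred_enumeration",
    "expected_pred_monte_carlo",
]

_MAX_ENUM_PNS = 12
_MAX_ENUM_KCS = 64


@dataclass(frozen=True)
class BinaryModelParams:
    """Binary-network sizes and probabilities; defaults mirror the fly-like
    rate network (50 PNs at 0.5 response probability, 2000 KCs at
    connection probability 0.14, threshold set for sparse KC activity)."""

    n_pns: int = 50
    pn_active_prob: float = 0.5
    n_kcs: int = 2000
    conn_prob: float = 0.14
    kc_threshold: int | None = None  # None -> default_threshold(...)

    def __post_init__(self):
        if not 0.0 <= self.pn_active_prob <= 1.0:
            raise ValueError("pn_active_prob must be in [0, 1]")
        if not 0.0 <= self.conn_prob <= 1.0:
            raise ValueError("conn_prob must be in [0, 1]")
        if self.n_pns < 1 or self.n_kcs < 1:
            raise ValueError("n_pns and n_kcs must be positive")
        if self.kc_threshold is not None and self.kc_threshold < 0:
            raise ValueError("kc_threshold must be non-negative")

    def resolve(self) -> "BinaryModelParams":
        """Fill in the default threshold if unset."""
        if self.kc_threshold is not None:
            return self
        return replace(self, kc_threshold=default_threshold(
            self.n_pns, self.pn_active_prob, self.conn_prob))


def _activation_prob(theta: int, w: np.ndarray, p: float) -> np.ndarray:
    """P(KC active | w active PNs) = P(Binomial(w, p) >= theta)."""
    w = np.asarray(w)
    if theta <= 0:
        return np.ones(w.shape)
    return stats.binom.sf(theta - 1, w, p)


def expected_active_fraction(n_pns: int, pn_active_prob: float,
                             conn_prob: float, theta: int) -> float:
    """Expected fraction of active KCs, averaging over odor patterns."""
    w = np.arange(n_pns + 1)
    pw = stats.binom.pmf(w, n_pns, pn_active_prob)
    return float(np.sum(pw * _activation_prob(theta, w, conn_prob)))


def default_threshold(n_pns: int, pn_active_prob: float, conn_prob: float,
                      target_fraction: float = 0.12) -> int:
    """Smallest integer threshold keeping expected KC activity sparse
    (at most ``target_fraction`` of KCs active on average)."""
    for theta in range(n_pns + 2):
        if expected_active_fraction(n_pns, pn_active_prob, conn_prob,
                                    theta) <= target_fraction:
            return theta
    return n_pns + 1


def _overlap_distribution(n_pns: int, p: float, shuffled: bool):
    """Joint pmf over (w1, w2, m): active counts of the two odor patterns
    and the size of their overlap.

    Independent odors: per PN the four joint states are a trinomial-style
    multinomial.  Shuffled odors: w2 = w1 and m is hypergeometric (pattern
    2 is a random permutation of pattern 1).
    """
    out = {}
    if shuffled:
        for w in range(n_pns + 1):
            pw = stats.binom.pmf(w, n_pns, p)
            if pw == 0:
                continue
            m_vals = np.arange(max(0, 2 * w - n_pns), w + 1)
            pm = stats.hypergeom.pmf(m_vals, n_pns, w, w)
            for m, q in zip(m_vals, pm):
                if q > 0:
                    out[(w, w, int(m))] = out.get((w, w, int(m)), 0.0) + pw * q
        return out
    # counts of PNs active in (both, only odor 1, only odor 2)
    from math import comb
    pb, p1, p0 = p * p, p * (1 - p), (1 - p) * (1 - p)
    for nb in range(n_pns + 1):
        for n1 in range(n_pns - nb + 1):
            for n2 in range(n_pns - nb - n1 + 1):
                nn = n_pns - nb - n1 - n2
                prob = (comb(n_pns, nb) * comb(n_pns - nb, n1)
                        * comb(n_pns - nb - n1, n2)
                        * pb ** nb * p1 ** n1 * p1 ** n2 * p0 ** nn)
                if prob > 0:
                    key = (nb + n1, nb + n2, nb)
                    out[key] = out.get(key, 0.0) + prob
    return out


def _joint_kc_probs(w1: int, w2: int, m: int, p: float, theta: int):
    """2x2 joint activation probabilities of one KC for the two odors.

    The KC's connected-active counts decompose into independent binomials
    on the overlap (m PNs) and the two exclusive sets; the KC fires for
    odor i when its total reaches theta.
    """
    cb = np.arange(m + 1)
    c1 = np.arange(w1 - m + 1)
    c2 = np.arange(w2 - m + 1)
    pb = stats.binom.pmf(cb, m, p)
    p1 = stats.binom.pmf(c1, w1 - m, p)
    p2 = stats.binom.pmf(c2, w2 - m, p)
    fire1 = (cb[:, None] + c1[None, :]) >= theta  # (cb, c1)
    fire2 = (cb[:, None] + c2[None, :]) >= theta  # (cb, c2)
    # sum over cb of P(cb) * P(fire1 pattern) * P(fire2 pattern)
    q1_given_b = p1 @ fire1.T          # P(fire odor1 | cb)
    q2_given_b = p2 @ fire2.T
    q11 = float(np.sum(pb * q1_given_b * q2_given_b))
    q10 = float(np.sum(pb * q1_given_b * (1 - q2_given_b)))
    q01 = float(np.sum(pb * (1 - q1_given_b) * q2_given_b))
    q00 = max(0.0, 1.0 - q11 - q10 - q01)
    return q11, q10, q01, q00


def _count_pair_pmf(n_kcs: int, q11: float, q10: float, q01: float,
                    q00: float) -> np.ndarray:
    """Joint pmf of (N1, N2): total active-KC counts for the two odors.

    n_kcs-fold convolution of the per-KC 2x2 contribution, as a dynamic
    program over the (n_kcs + 1)^2 count grid.
    """
    pmf = np.zeros((n_kcs + 1, n_kcs + 1))
    pmf[0, 0] = 1.0
    for _ in range(n_kcs):
        nxt = q00 * pmf
        nxt[1:, :] += q10 * pmf[:-1, :]
        nxt[:, 1:] += q01 * pmf[:, :-1]
        nxt[1:, 1:] += q11 * pmf[:-1, :-1]
        pmf = nxt
    return pmf


def _pred_tensor(n: int) -> np.ndarray:
    """PRED(a1, a2, b1, b2) on the integer count grid [0, n]^4."""
    g = np.arange(n + 1, dtype=float)
    a1 = g[:, None, None, None]
    a2 = g[None, :, None, None]
    b1 = g[None, None, :, None]
    b2 = g[None, None, None, :]
    d1 = (a1 - b1) ** 2 + (a2 - b2) ** 2
    d2 = (a1 - b2) ** 2 + (a2 - b1) ** 2
    denom = d1 + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (d2 - d1) / np.where(denom == 0, 1.0, denom),
                     0.0)
    return t


def expected_pred_enumeration(params: BinaryModelParams,
                              shuffled: bool = False) -> float:
    """Exact E[PRED] of the total active-KC count on a small instance.

    Requires n_pns <= 12 and n_kcs <= 64 so the enumeration over odor
    patterns and response counts stays exact and affordable; larger
    instances are directed to :func:`expected_pred_monte_carlo`.
    """
    params = params.resolve()
    if params.n_pns > _MAX_ENUM_PNS or params.n_kcs > _MAX_ENUM_KCS:
        raise ValueError(
            f"instance too large for exact enumeration "
            f"(n_pns <= {_MAX_ENUM_PNS}, n_kcs <= {_MAX_ENUM_KCS}); "
            f"use expected_pred_monte_carlo")
    tensor = _pred_tensor(params.n_kcs)
    overlap = _overlap_distribution(params.n_pns, params.pn_active_prob,
                                    shuffled)
    total = 0.0
    for (w1, w2, m), pw in overlap.items():
        q11, q10, q01, q00 = _joint_kc_probs(w1, w2, m, params.conn_prob,
                                             params.kc_threshold)
        pmf = _count_pair_pmf(params.n_kcs, q11, q10, q01, q00)
        # two individuals: independent, identically distributed given odors
        total += pw * float(np.einsum("ij,kl,ijkl->", pmf, pmf, tensor))
    return total


def expected_pred_monte_carlo(params: BinaryModelParams, n_samples: int = 2000,
                              seed: int | None = None,
                              shuffled: bool = False,
                              batch_size: int = 100):
    """Monte-Carlo E[PRED] of the total active-KC count.

    Each sample draws a fresh pair of odor patterns (shared by both
    individuals) and a fresh pair of connection matrices, computes the
    2 x 2 table of active-KC counts and its PRED.  Returns
    ``(estimate, standard_error)``.
    """
    params = params.resolve()
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    theta = params.kc_threshold
    preds = np.empty(n_samples)
    done = 0
    while done < n_samples:
        b = min(batch_size, n_samples - done)
        z1 = rng.random((b, params.n_pns)) < params.pn_active_prob
        if shuffled:
            z2 = np.stack([row[rng.permutation(params.n_pns)] for row in z1])
        else:
            z2 = rng.random((b, params.n_pns)) < params.pn_active_prob
        z = np.stack([z1, z2], axis=1).astype(np.float32)  # (b, 2, n_pns)
        counts = np.empty((b, 2, 2))  # (sample, individual, odor)
        for ind in range(2):
            conn = (rng.random((b, params.n_pns, params.n_kcs))
                    < params.conn_prob).astype(np.float32)
            inputs = np.einsum("bop,bpk->bok", z, conn)
            counts[:, ind, :] = (inputs >= theta).sum(axis=2)
        a, c = counts[:, 0, :], counts[:, 1, :]
        d1 = (a[:, 0] - c[:, 0]) ** 2 + (a[:, 1] - c[:, 1]) ** 2
        d2 = (a[:, 0] - c[:, 1]) ** 2 + (a[:, 1] - c[:, 0]) ** 2
        denom = d1 + d2
        preds[done:done + b] = np.where(
            denom > 0, (d2 - d1) / np.where(denom == 0, 1.0, denom), 0.0)
        done += b
    est = float(preds.mean())
    se = float(preds.std(ddof=1) / np.sqrt(n_samples))
    return est, se
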