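"""Gaussian-mixture meta-QTL detection with known per-QTL variances.

Projected QTL positions on one chromosome are modelled as draws from a
mixture of K point loci:

    x_i ~ sum_k pi_k * Normal(mu_k, s_i^2)

where s_i is each QTL's own positional standard deviation (derived from its
95% CI), so the mixture is heteroscedastic with *known* variances — only
the K locus positions mu_k and the K−1 free mixing weights are estimated
(p = 2K − 1 free parameters).  Models for K = 1..K_max are fitted by EM and
the number of meta-QTLs is chosen by a vote over five information criteria
(AIC, AICc, AIC3, BIC, AWE): the winning K attains the minimum on at least
three of the five, with a plurality fallback and smaller-K tie-break.

Each selected component becomes a meta-QTL whose position is the
responsibility- and precision-weighted mean of its members and whose 95% CI
is position ± 1.96 / sqrt(sum_i r_ik / s_i^2) — the inverse-variance
pooling that makes meta-QTL intervals much narrower than any member's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .consensus_map import ConsensusMap
from .qtl_projection import ProjectedQTL

log = logging.getLogger(__name__)

_LOG2PI = math.log(2 * math.pi)
#: EM weight floor guarding log(0); a component ending below 1/(2n) is empty.
WEIGHT_FLOOR = 1e-8
DEFAULT_SEED = 17


@dataclass
class MixtureModel:
    K: int
    mu: np.ndarray  # (K,) consensus positions, sorted ascending
    pi: np.ndarray  # (K,) mixing weights, sum 1
    loglik: float
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    assignment: np.ndarray  # (n,) argmax component per QTL

    @property
    def classification_loglik(self) -> float:
        """Log-likelihood with responsibilities hardened to the assignment."""
        n = self.responsibilities.shape[0]
        hard = np.zeros_like(self.responsibilities)
        hard[np.arange(n), self.assignment] = 1.0
        return float(np.sum(hard * self._log_joint))

    # set by em_fit: log(pi_k) + log phi(x_i; mu_k, s_i^2)
    _log_joint: np.ndarray = None  # type: ignore[assignment]


@dataclass(frozen=True)
class CriteriaRow:
    K: int
    n: int
    p: int
    loglik: float
    aic: float
    aicc: float  # nan when inadmissible (n <= p + 1)
    aic3: float
    bic: float
    awe: float


@dataclass
class MQTL:
    chromosome: str
    position: float  # cM, inverse-variance weighted
    ci_lo: float
    ci_hi: float
    members: list[str]  # QTL ids
    traits: frozenset[str]
    n_populations: int
    flanking_markers: tuple[str | None, str | None]

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo


def _validate(positions, sds) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(positions, dtype=float)
    s = np.asarray(sds, dtype=float)
    if x.shape != s.shape or x.ndim != 1:
        raise ValueError("positions and sds must be 1-D and the same length")
    if np.any(s <= 0):
        raise ValueError("all sds must be positive")
    return x, s


def _log_density_matrix(x: np.ndarray, s: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log phi(x_i; mu_k, s_i^2)."""
    z = (x[:, None] - mu[None, :]) / s[:, None]
    return -0.5 * (z**2) - np.log(s)[:, None] - 0.5 * _LOG2PI


def _row_logsumexp(lj: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp; cheaper than the scipy wrapper in the EM loop."""
    m = lj.max(axis=1)
    return m + np.log(np.exp(lj - m[:, None]).sum(axis=1))


def loglik(positions, sds, mu, pi) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_k phi(x_i; mu_k, s_i^2)."""
    x, s = _validate(positions, sds)
    mu = np.asarray(mu, dtype=float)
    pi = np.asarray(pi, dtype=float)
    lj = _log_density_matrix(x, s, mu) + np.log(pi)[None, :]
    return float(np.sum(_row_logsumexp(lj)))


def _em_once(
    x: np.ndarray, s: np.ndarray, mu0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    K = len(mu0)
    n = len(x)
    mu = mu0.copy()
    pi = np.full(K, 1.0 / K)
    prec = 1.0 / s**2
    prev_ll = -np.inf
    for _ in range(max_iter):
        lj = _log_density_matrix(x, s, mu) + np.log(np.maximum(pi, WEIGHT_FLOOR))[None, :]
        norm = _row_logsumexp(lj)
        ll = float(np.sum(norm))
        if ll < prev_ll - 1e-9:
            raise AssertionError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        r = np.exp(lj - norm[:, None])
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
        # M-step: precision-weighted means, mean responsibilities
        denom = r.T @ prec  # (K,)
        numer = r.T @ (x * prec)
        mask = denom > 0
        mu[mask] = numer[mask] / denom[mask]
        pi = np.maximum(r.mean(axis=0), WEIGHT_FLOOR)
        pi = pi / pi.sum()
    lj = _log_density_matrix(x, s, mu) + np.log(np.maximum(pi, WEIGHT_FLOOR))[None, :]
    norm = _row_logsumexp(lj)
    r = np.exp(lj - norm[:, None])
    return mu, pi, float(np.sum(norm)), r, lj


def em_fit(
    positions,
    sds,
    K: int,
    *,
    seed: int = DEFAULT_SEED,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 10,
) -> MixtureModel:
    """Fit a K-component known-variance Gaussian mixture by restarted EM.

    Initialisation: evenly spaced quantiles of the positions, plus jittered
    restarts; the best (highest log-likelihood, non-degenerate) fit wins.
    Deterministic given the seed.
    """
    x, s = _validate(positions, sds)
    n = len(x)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(np.unique(x)):
        raise ValueError(f"K={K} exceeds the number of distinct positions")

    rng = np.random.default_rng(seed)
    q = np.quantile(x, (np.arange(K) + 0.5) / K)
    spread = max(x.max() - x.min(), 1e-6)

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None
    best_degenerate: tuple | None = None
    for restart in range(max(n_restarts, 1)):
        mu0 = q if restart == 0 else q + rng.normal(0, 0.1 * spread, size=K)
        mu, pi, ll, r, lj = _em_once(x, s, np.sort(mu0), tol, max_iter)
        degenerate = bool(np.any(pi < 1.0 / (2 * n)))
        cand = (ll, mu, pi, r, lj)
        if degenerate:
            if best_degenerate is None or ll > best_degenerate[0]:
                best_degenerate = cand
        elif best is None or ll > best[0]:
            best = cand
    if best is None:
        if best_degenerate is None:
            raise RuntimeError(f"degenerate K: no usable fit at K={K}")
        log.warning("em_fit: all restarts left an empty component at K=%d", K)
        best = best_degenerate

    ll, mu, pi, r, lj = best
    order = np.argsort(mu)
    mu, pi, r, lj = mu[order], pi[order], r[:, order], lj[:, order]
    model = MixtureModel(
        K=K, mu=mu, pi=pi, loglik=ll,
        responsibilities=r, assignment=np.argmax(r, axis=1),
    )
    model._log_joint = lj
    return model


def criteria(model: MixtureModel, n: int) -> CriteriaRow:
    """One information-criteria row for a fitted model.

    p = 2K − 1 free parameters (K means, K−1 weights; variances are known).
    AWE uses the classification log-likelihood with hardened assignments
    (Banfield–Raftery form): −2*Lc + 2p(3/2 + ln n).
    """
    K = model.K
    p = 2 * K - 1
    L = model.loglik
    aic = -2 * L + 2 * p
    aicc = aic + 2 * p * (p + 1) / (n - p - 1) if n > p + 1 else float("nan")
    aic3 = -2 * L + 3 * p
    bic = -2 * L + p * math.log(n)
    lc = model.classification_loglik
    awe = -2 * lc + 2 * p * (1.5 + math.log(n))
    return CriteriaRow(K=K, n=n, p=p, loglik=L, aic=aic, aicc=aicc, aic3=aic3, bic=bic, awe=awe)


def select_K(table: list[CriteriaRow]) -> int:
    """Vote over the five criteria: the K minimal on >= 3 of them wins;
    otherwise the K winning the most criteria; ties go to the smaller K."""
    if not table:
        raise ValueError("empty criteria table")
    wins = {row.K: 0 for row in table}
    for attr in ("aic", "aicc", "aic3", "bic", "awe"):
        vals = [(getattr(row, attr), row.K) for row in table
                if not math.isnan(getattr(row, attr))]
        if not vals:
            continue
        best_val = min(v for v, _ in vals)
        # a tie on one criterion credits the smallest K attaining it
        best_k = min(k for v, k in vals if v == best_val)
        wins[best_k] += 1
    for k in sorted(wins):
        if wins[k] >= 3:
            return k
    top = max(wins.values())
    return min(k for k, w in wins.items() if w == top)


def summarize(
    model: MixtureModel,
    projected: list[ProjectedQTL],
    consensus: ConsensusMap | None = None,
    *,
    chromosome: str | None = None,
) -> list[MQTL]:
    """Turn fitted components into meta-QTLs.

    position_k = sum_i r_ik x_i / s_i^2  /  sum_i r_ik / s_i^2
    var_k      = 1 / sum_i r_ik / s_i^2
    CI         = position ± 1.96 sqrt(var)
    Flanking markers are the nearest consensus markers outside the CI.
    """
    x = np.array([q.peak_c for q in projected])
    s = np.array([q.sd for q in projected])
    r = model.responsibilities
    prec = 1.0 / s**2
    lg = chromosome or projected[0].source.linkage_group
    out: list[MQTL] = []
    for k in range(model.K):
        members_idx = np.flatnonzero(model.assignment == k)
        if members_idx.size == 0:
            continue
        wk = r[:, k] * prec
        pos = float(np.sum(wk * x) / np.sum(wk))
        sd_k = float(1.0 / math.sqrt(np.sum(wk)))
        ci_lo, ci_hi = pos - 1.96 * sd_k, pos + 1.96 * sd_k
        members = [projected[i] for i in members_idx]
        left = right = None
        if consensus is not None and lg in consensus.linkage_groups:
            group = consensus.group(lg)
            lefts = [m for m in group if m.position < ci_lo]
            rights = [m for m in group if m.position > ci_hi]
            left = lefts[-1].marker_name if lefts else None
            right = rights[0].marker_name if rights else None
        out.append(MQTL(
            chromosome=lg,
            position=pos, ci_lo=ci_lo, ci_hi=ci_hi,
            members=[m.source.qtl_id for m in members],
            traits=frozenset(m.source.trait for m in members),
            n_populations=len({m.source.population_id for m in members}),
            flanking_markers=(left, right),
        ))
    out.sort(key=lambda m: m.position)
    return out


def run_chromosome(
    projected: list[ProjectedQTL],
    *,
    K_max: int | None = None,
    consensus: ConsensusMap | None = None,
    chromosome: str | None = None,
    seed: int = DEFAULT_SEED,
    n_restarts: int = 10,
) -> tuple[list[MQTL], list[CriteriaRow]]:
    """Fit K = 1..K_max on one chromosome, select K, and summarise.

    The mixture approach is meant for chromosomes carrying more than 10
    QTLs; below that a warning is logged and the fit proceeds anyway.
    Input order does not matter: QTLs are processed sorted by position.
    """
    if len(projected) < 2:
        raise ValueError("need at least 2 QTLs on a chromosome")
    if len(projected) <= 10:
        log.warning("only %d QTLs on chromosome %s: mixture selection is "
                    "designed for > 10", len(projected), chromosome or "?")
    projected = sorted(projected, key=lambda q: (q.peak_c, q.source.qtl_id))
    x = [q.peak_c for q in projected]
    s = [q.sd for q in projected]
    n = len(x)
    n_distinct = len(set(x))
    kmax = min(K_max or 20, n - 1, n_distinct)
    kmax = max(kmax, 1)
    table: list[CriteriaRow] = []
    models: dict[int, MixtureModel] = {}
    for K in range(1, kmax + 1):
        try:
            m = em_fit(x, s, K, seed=seed + K, n_restarts=n_restarts)
        except (ValueError, RuntimeError) as exc:
            log.info("K=%d not fitted: %s", K, exc)
            continue
        models[K] = m
        table.append(criteria(m, n))
    k_best = select_K(table)
    mqtls = summarize(models[k_best], projected, consensus, chromosome=chromosome)
    return mqtls, table
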