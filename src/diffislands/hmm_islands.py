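"""Constrained 3-state Gaussian HMM island calling.

Per-SNP normal scores z are modelled by a hidden Markov chain with states
L (low differentiation), I (intermediate) and H (high), Gaussian
emissions per state, and a transition matrix in which direct L<->H jumps
are structurally forbidden. Parameters are estimated per chromosome by
Baum-Welch with random restarts; islands are called in two steps: the
Viterbi path delimits candidate runs of the extreme states, and only runs
containing at least one SNP significant under a genome-wide LIS-based
false discovery rate are retained.

The Local Index of Significance (LIS) of a SNP for state s is
1 − γ(s), the posterior probability that the SNP does *not* occupy s;
sorting LIS ascending and taking the largest prefix whose running mean
stays below α controls the genome-wide FDR at α.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

log = logging.getLogger("diffislands")

STATE_L, STATE_I, STATE_H = 0, 1, 2
STATE_NAMES = np.array(["L", "I", "H"])

SIGMA_FLOOR = 1e-4


@dataclass
class HMMParams:
    """Parameters of the 3-state Gaussian chain, states ordered μ_L<μ_I<μ_H."""

    means: np.ndarray          # (3,)
    sds: np.ndarray            # (3,)
    transmat: np.ndarray       # (3,3), rows sum to 1; [L,H] = [H,L] = 0 if constrained
    startprob: np.ndarray      # (3,)
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False

    def validate(self, constrained: bool = True) -> None:
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise ValueError("state means must be strictly increasing after relabelling")
        if (self.sds <= 0).any():
            raise ValueError("state sds must be positive")
        if np.abs(self.transmat.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if abs(self.startprob.sum() - 1) > 1e-12:
            raise ValueError("startprob must sum to 1")
        if constrained and (self.transmat[0, 2] != 0.0 or self.transmat[2, 0] != 0.0):
            raise ValueError("structural zeros A[L,H], A[H,L] violated")


@dataclass
class Decoding:
    """Per-SNP decoding of one chromosome under fitted parameters."""

    viterbi_state: np.ndarray   # (n,) int8 in {0,1,2}
    gamma: np.ndarray           # (n,3) posterior state probabilities
    lis_h: np.ndarray           # 1 - gamma[:, H]
    lis_l: np.ndarray           # 1 - gamma[:, L]


@dataclass
class Island:
    """A called genomic island (contiguous run of extreme-state SNPs)."""

    chrom: str
    start: int                 # 1-based position of first member SNP
    end: int                   # 1-based position of last member SNP
    type: str                  # "HDI" | "LDI"
    n_snps: int
    n_fdr_snps: int
    mean_fst: float
    mean_het: float
    mean_z: float
    snp_ids: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _emissions(z, mu, sigma):                       # pragma: no cover - numba
    n = z.shape[0]
    B = np.empty((n, 3))
    for s in range(3):
        inv = 1.0 / (sigma[s] * np.sqrt(2.0 * np.pi))
        for t in range(n):
            d = (z[t] - mu[s]) / sigma[s]
            B[t, s] = inv * np.exp(-0.5 * d * d)
    return B


@njit(cache=True)
def _forward_backward(B, A, pi):                    # pragma: no cover - numba
    """Scaled forward-backward: returns (loglik, gamma, xi_sum, c)."""
    n = B.shape[0]
    alpha = np.empty((n, 3))
    beta = np.empty((n, 3))
    c = np.empty(n)
    for s in range(3):
        alpha[0, s] = pi[s] * B[0, s]
    c[0] = alpha[0, 0] + alpha[0, 1] + alpha[0, 2]
    for s in range(3):
        alpha[0, s] /= c[0]
    for t in range(1, n):
        tot = 0.0
        for j in range(3):
            v = 0.0
            for i in range(3):
                v += alpha[t - 1, i] * A[i, j]
            v *= B[t, j]
            alpha[t, j] = v
            tot += v
        c[t] = tot
        for j in range(3):
            alpha[t, j] /= tot
    loglik = 0.0
    for t in range(n):
        loglik += np.log(c[t])
    for s in range(3):
        beta[n - 1, s] = 1.0
    xi = np.zeros((3, 3))
    for t in range(n - 2, -1, -1):
        for i in range(3):
            v = 0.0
            for j in range(3):
                v += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = v / c[t + 1]
        for i in range(3):
            for j in range(3):
                xi[i, j] += alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
    gamma = alpha * beta
    # rows of gamma already sum to 1 under this scaling; renormalize
    # defensively, falling back on the filtered (alpha) distribution if a
    # row degenerates numerically (e.g. a state starved to zero mass)
    for t in range(n):
        tot = gamma[t, 0] + gamma[t, 1] + gamma[t, 2]
        if tot > 0.0 and np.isfinite(tot):
            for s in range(3):
                gamma[t, s] /= tot
        else:
            for s in range(3):
                gamma[t, s] = alpha[t, s]
    return loglik, gamma, xi, c


@njit(cache=True)
def _viterbi_kernel(logB, logA, logpi):             # pragma: no cover - numba
    n = logB.shape[0]
    delta = np.empty((n, 3))
    psi = np.zeros((n, 3), dtype=np.int8)
    for s in range(3):
        delta[0, s] = logpi[s] + logB[0, s]
    for t in range(1, n):
        for j in range(3):
            best = delta[t - 1, 0] + logA[0, j]
            arg = 0
            for i in range(1, 3):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:        # strict: ties keep the lower state index
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            psi[t, j] = arg
    path = np.empty(n, dtype=np.int8)
    best = delta[n - 1, 0]
    arg = 0
    for s in range(1, 3):
        if delta[n - 1, s] > best:
            best = delta[n - 1, s]
            arg = s
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# Baum-Welch with restarts
# ---------------------------------------------------------------------------

def _em_fit(z, mu, sigma, A, pi, tol, max_iter, sigma_floor=SIGMA_FLOOR,
            trans_pseudocount=0.0):
    """Run (MAP-)EM from one start; returns params or None if degenerate.

    ``trans_pseudocount`` adds a Dirichlet prior count to every allowed
    transition (structural zeros receive none). EM then monotonically
    maximizes the penalized objective log-likelihood + prior term; with a
    zero pseudocount that objective is the plain log-likelihood. The
    monotonicity of the maximized objective is asserted on every
    iteration.
    """
    allowed = A > 0
    kappa = trans_pseudocount

    def prior_term(A_):
        if kappa == 0.0:
            return 0.0
        return kappa * np.log(A_[allowed]).sum()

    prev_obj = -np.inf
    ll = -np.inf
    n_iter = 0
    converged = False
    clamped = False
    for n_iter in range(1, max_iter + 1):
        B = _emissions(z, mu, sigma)
        if not np.isfinite(B).all() or (B.sum(axis=1) <= 0).any():
            return None
        ll, gamma, xi, _ = _forward_backward(B, A, pi)
        if not np.isfinite(ll):
            return None
        obj = ll + prior_term(A)
        if not clamped and obj < prev_obj - 1e-8:
            raise AssertionError(f"EM objective decreased: {prev_obj} -> {obj}")
        if abs(obj - prev_obj) < tol and n_iter > 1:
            converged = True
            prev_obj = obj
            break
        prev_obj = obj
        # M step
        xi = xi + kappa * allowed
        denom = xi.sum(axis=1, keepdims=True)
        A = np.where(denom > 0, xi / np.where(denom > 0, denom, 1.0), A)
        A[np.isclose(denom[:, 0], 0)] = np.eye(3)[np.isclose(denom[:, 0], 0)]
        pi = gamma[0] / gamma[0].sum()
        w = gamma.sum(axis=0)
        mu = (gamma * z[:, None]).sum(axis=0) / w
        var = (gamma * (z[:, None] - mu) ** 2).sum(axis=0) / w
        sigma = np.sqrt(var)
        if (sigma < SIGMA_FLOOR).any():
            return None                       # true collapse: discard restart
        # clamp at the regularization floor (e.g. ties from saturated
        # quantiles); the projection step suspends the monotonicity check
        # for one iteration
        clamped = bool((sigma < sigma_floor).any())
        sigma = np.maximum(sigma, sigma_floor)
    occupancy = gamma.sum(axis=0) / len(z)
    return mu, sigma, A, pi, ll, n_iter, converged, occupancy


def _relabel(mu, sigma, A, pi):
    order = np.argsort(mu)
    return mu[order], sigma[order], A[np.ix_(order, order)], pi[order], order


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (uniform fallback
    if the chain is not irreducible)."""
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    if v.sum() == 0 or not np.isfinite(v).all():
        return np.full(len(A), 1.0 / len(A))
    v = np.abs(v)
    return v / v.sum()


def baum_welch(z: np.ndarray, n_restarts: int = 1000, seed: int = 0,
               tol: float = 1e-6, max_iter: int = 500,
               constrained: bool = True,
               sigma_min_frac: float = 0.3,
               init_dist: str = "stationary",
               trans_pseudocount: float = 1.0) -> HMMParams:
    """Estimate constrained 3-state Gaussian HMM parameters for one chromosome.

    EM is launched ``n_restarts`` times from randomized starting values
    and the highest-likelihood fit is kept; states are then relabelled so
    that μ_L < μ_I < μ_H (transition matrix and initial distribution
    permuted consistently). Structural zeros A[L,H] = A[H,L] = 0 survive
    EM exactly because the update is multiplicative in A.

    ``sigma_min_frac`` floors every state's σ at that fraction of the
    chromosome-wide spread of z: restarts whose σ falls below the floor
    are discarded as degenerate. Gaussian-mixture likelihoods are
    unbounded as a component collapses onto near-coincident points, and a
    collapsed "spike" state yields spuriously confident posteriors (LIS
    underflow) on featureless data; since the emissions are z-scores, no
    genuine differentiation state is narrower than a modest fraction of
    the data spread.

    ``init_dist``: "stationary" (default) replaces the fitted initial
    distribution with the stationary distribution of the transition
    matrix after EM. With a single sequence per chromosome the free-π
    maximum-likelihood solution is a point mass on whichever state best
    fits the first SNP, which makes that SNP's posterior exactly
    degenerate (LIS = 0) and would auto-select it at any FDR level;
    ``init_dist="em"`` keeps the raw EM estimate.

    ``trans_pseudocount`` regularizes transition rows with a flat
    Dirichlet prior count per allowed transition (structural zeros stay
    exact). On data without genuine spatial structure the likelihood is
    almost flat in A, and unregularized EM can drift to near-absorbing
    self-transitions whose dynamic reinforcement manufactures
    machine-precision-confident posteriors; one prior count is negligible
    for genuinely persistent states.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < 50:
        raise ValueError("baum_welch requires >= 50 observations")
    rng = np.random.default_rng(seed)
    sd = z.std()
    sigma_floor = max(SIGMA_FLOOR, sigma_min_frac * sd)
    best = None
    for batch in range(3):          # retry with fresh starts if none admissible
        for _ in range(n_restarts):
            qs = np.quantile(z, [0.15, 0.5, 0.85])
            mu = qs + rng.normal(0, 0.5 * sd, 3)
            sigma = sd * rng.uniform(max(0.35, sigma_min_frac + 0.05), 1.2, 3)
            A = rng.dirichlet(np.full(3, 5.0), size=3)
            if constrained:
                A[0, 2] = A[2, 0] = 0.0
                A /= A.sum(axis=1, keepdims=True)
            # encourage persistence: mix with identity
            A = 0.5 * A + 0.5 * np.eye(3)
            pi = rng.dirichlet(np.ones(3))
            fit = _em_fit(z, mu, sigma, A, pi, tol, max_iter, sigma_floor=sigma_floor,
                          trans_pseudocount=trans_pseudocount)
            if fit is None:
                continue
            mu_f, occ_f = fit[0], fit[7]
            order = np.argsort(mu_f)
            if constrained and order[1] != 1:
                # the L<->H prohibition is tied to the state labels: the
                # structural zeros only forbid transitions between the two
                # *extreme* states if the middle-mean state carries the
                # middle label, so other arrangements are inadmissible
                continue
            if occ_f[order[1]] < max(occ_f[order[0]], occ_f[order[2]]):
                # identifiability of "intermediate": the method presumes a
                # mostly-neutral genome, i.e. the middle state is the
                # majority state; fits that park the data bulk in an
                # extreme state invert that reading and make whole-bulk
                # runs spuriously significant
                continue
            if best is None or fit[4] > best[4]:
                best = fit
        if best is not None:
            break
    if best is None:
        raise RuntimeError("all Baum-Welch restarts degenerated")
    mu, sigma, A, pi, ll, n_iter, converged, _ = best
    mu, sigma, A, pi, _ = _relabel(mu, sigma, A, pi)
    if constrained:
        A[0, 2] = A[2, 0] = 0.0        # exact structural zeros after relabelling
        A /= A.sum(axis=1, keepdims=True)
    if init_dist == "stationary":
        pi = stationary_distribution(A)
        ll, _, _, _ = _forward_backward(_emissions(z, mu, sigma), A, pi)
    params = HMMParams(means=mu, sds=sigma, transmat=A, startprob=pi,
                       loglik=float(ll), n_iter=n_iter, converged=converged)
    params.validate(constrained=constrained)
    return params


#: free parameters of the constrained 3-state model: 3 means + 3 sds +
#: 4 free transition entries (constrained rows L and H have 1 each, row I
#: has 2; the initial distribution is tied to the transition matrix)
N_FREE_CONSTRAINED = 10


def bic_advantage(z: np.ndarray, params: HMMParams,
                  n_free: int = N_FREE_CONSTRAINED) -> float:
    """BIC advantage of the fitted 3-state chain over a single Gaussian.

    Positive means the 3-state model is supported. A hidden-state
    segmentation is only meaningful where the observations actually carry
    multi-state structure; on a featureless chromosome the
    maximum-likelihood 3-state fit degenerates into an arbitrary mixture
    decomposition of the bulk whose extreme components claim ordinary
    tail observations with near-certainty, so decoding such a fit
    manufactures false discoveries. The single-Gaussian reference has 2
    free parameters.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    sd = z.std()
    ll1 = float(np.sum(stats_norm_logpdf(z, z.mean(), sd)))
    bic1 = -2.0 * ll1 + 2.0 * np.log(n)
    bic3 = -2.0 * params.loglik + n_free * np.log(n)
    return float(bic1 - bic3)


def stats_norm_logpdf(x, loc, scale):
    return -0.5 * ((x - loc) / scale) ** 2 - np.log(scale * np.sqrt(2 * np.pi))


def viterbi(z: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most probable state path; ties broken toward the lower state index."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transmat)
        logpi = np.log(params.startprob)
    logB = -0.5 * ((z[:, None] - params.means) / params.sds) ** 2 \
        - np.log(params.sds * np.sqrt(2 * np.pi))
    return _viterbi_kernel(logB, logA, logpi)


def posterior_lis(z: np.ndarray, params: HMMParams) -> Decoding:
    """Posterior decoding: state probabilities γ and per-state LIS."""
    z = np.asarray(z, dtype=float)
    B = _emissions(z, params.means, params.sds)
    ll, gamma, _, _ = _forward_backward(B, params.transmat, params.startprob)
    if not np.isfinite(ll):
        raise FloatingPointError("forward-backward underflow")
    return Decoding(
        viterbi_state=viterbi(z, params),
        gamma=gamma,
        lis_h=1.0 - gamma[:, STATE_H],
        lis_l=1.0 - gamma[:, STATE_L],
    )


def fdr_select(lis: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """Step-up LIS selection controlling the genome-wide FDR at alpha.

    Sort LIS ascending and keep the largest k whose running mean stays
    ≤ alpha; returns a boolean mask over the input (k may be 0). Pool LIS
    genome-wide across chromosomes before calling.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lis = np.asarray(lis, dtype=float)
    order = np.argsort(lis, kind="stable")
    running = np.cumsum(lis[order]) / np.arange(1, len(lis) + 1)
    ok = np.flatnonzero(running <= alpha)
    mask = np.zeros(len(lis), dtype=bool)
    if len(ok):
        mask[order[: ok[-1] + 1]] = True
    return mask


def call_islands(table: pd.DataFrame) -> list[Island]:
    """Two-step island calling from a decoded per-SNP table.

    ``table`` needs columns snp_id, chrom, pos, fst, h_bp, z, viterbi,
    fdr_h, fdr_l (as produced by :func:`decode_genome`). Maximal runs of
    consecutive H (L) Viterbi SNPs become candidate regions; a candidate
    is emitted as HDI (LDI) iff it contains at least one FDR-SNP of the
    matching state.
    """
    islands: list[Island] = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        v = sub["viterbi"].to_numpy()
        for state, typ, fdr_col in ((STATE_H, "HDI", "fdr_h"), (STATE_L, "LDI", "fdr_l")):
            m = v == state
            if not m.any():
                continue
            # run boundaries of the boolean mask
            d = np.diff(m.astype(int))
            starts = np.flatnonzero(d == 1) + 1
            ends = np.flatnonzero(d == -1) + 1
            if m[0]:
                starts = np.r_[0, starts]
            if m[-1]:
                ends = np.r_[ends, len(m)]
            for s, e in zip(starts, ends):
                run = sub.iloc[s:e]
                n_fdr = int(run[fdr_col].sum())
                if n_fdr == 0:
                    continue
                islands.append(Island(
                    chrom=str(chrom),
                    start=int(run["pos"].iloc[0]),
                    end=int(run["pos"].iloc[-1]),
                    type=typ,
                    n_snps=len(run),
                    n_fdr_snps=n_fdr,
                    mean_fst=float(run["fst"].mean()),
                    mean_het=float(run["h_bp"].mean()),
                    mean_z=float(run["z"].mean()),
                    snp_ids=list(run["snp_id"]),
                ))
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


def decode_genome(stats: pd.DataFrame, n_restarts: int = 1000, seed: int = 0,
                  alpha: float = 0.001, constrained: bool = True,
                  tol: float = 1e-6, max_iter: int = 500,
                  model_check: bool = True):
    """Fit the HMM per chromosome, decode, pool LIS genome-wide, call islands.

    ``stats`` is the per-SNP scan table (columns snp_id, chrom, pos, fst,
    h_bp, z). With ``model_check`` (default), a chromosome whose best
    3-state fit does not beat a single Gaussian by BIC is treated as
    all-intermediate: no SNP on it can reach the FDR stage (see
    :func:`bic_advantage`). Returns (table with decoding columns,
    per-chromosome HMMParams dict, list of Islands).
    """
    stats = stats.copy()
    params: dict[str, HMMParams] = {}
    vit = np.empty(len(stats), dtype=np.int8)
    lis_h = np.empty(len(stats))
    lis_l = np.empty(len(stats))
    for k, (chrom, sub) in enumerate(stats.groupby("chrom", sort=False)):
        idx = sub.index.to_numpy()
        z = sub["z"].to_numpy()
        p = baum_welch(z, n_restarts=n_restarts, seed=seed + 7919 * k,
                       tol=tol, max_iter=max_iter, constrained=constrained)
        params[str(chrom)] = p
        if model_check and bic_advantage(z, p) <= 0.0:
            log.info("chromosome %s: 3-state model unsupported by BIC; "
                     "treated as all-intermediate", chrom)
            vit[idx] = STATE_I
            lis_h[idx] = 1.0
            lis_l[idx] = 1.0
            continue
        dec = posterior_lis(z, p)
        vit[idx] = dec.viterbi_state
        lis_h[idx] = dec.lis_h
        lis_l[idx] = dec.lis_l
    stats["viterbi"] = vit
    stats["lis_h"] = lis_h
    stats["lis_l"] = lis_l
    stats["fdr_h"] = fdr_select(lis_h, alpha)
    stats["fdr_l"] = fdr_select(lis_l, alpha)
    islands = call_islands(stats)
    return stats, params, islands


def summarize_islands(islands: list[Island], recmap=None) -> pd.DataFrame:
    """Per-island summary table plus length-weighted mean recombination rate.

    The island's mean rate is the overlap-length-weighted mean of the
    recombination-map windows it intersects; islands outside map coverage
    get NaN (logged).
    """
    rows = []
    for isl in islands:
        rate = np.nan
        n_windows = 0
        if recmap is not None:
            m = recmap.chrom == isl.chrom
            s = np.maximum(recmap.start[m], isl.start - 1)
            e = np.minimum(recmap.end[m], isl.end)
            w = np.maximum(e - s, 0).astype(float)
            n_windows = int((w > 0).sum())
            if w.sum() > 0:
                rate = float((recmap.rate[m] * w).sum() / w.sum())
            else:
                log.warning("island %s:%d-%d outside recombination-map coverage",
                            isl.chrom, isl.start, isl.end)
        rows.append({
            "chrom": isl.chrom, "start": isl.start, "end": isl.end,
            "type": isl.type, "length_bp": isl.length_bp,
            "n_snps": isl.n_snps, "n_fdr_snps": isl.n_fdr_snps,
            "mean_fst": isl.mean_fst, "mean_het": isl.mean_het,
            "mean_z": isl.mean_z, "mean_rec_rate": rate,
            "n_rec_windows": n_windows,
        })
    return pd.DataFrame(rows)


def summarize_by_type(summary: pd.DataFrame) -> pd.DataFrame:
    """Aggregate mean/min/max of the island summary columns per island type."""
    cols = ["length_bp", "n_snps", "n_fdr_snps", "mean_fst", "mean_het",
            "mean_z", "mean_rec_rate"]
    return summary.groupby("type")[cols].agg(["mean", "min", "max", "count"])
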