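"""Continuous-time Markov chain of vagitype dynamics from panel data.

Vagitype trajectories are observed only at visit times (interval-censored
panel data), so the likelihood of a subject's consecutive visit pair
(state r at t, state s at t + dt) is the (r, s) entry of the transition
matrix P(dt) = exp(Q dt).  Intensities follow a log-linear covariate model

    q_rs(z) = q0_rs * exp(beta_rs * z)

with z the pregnancy outcome (1 = PTB, 0 = TB).  To keep the MLE
well-behaved, the modeled transitions are restricted to those observed at
least four times between consecutive visits; the remaining intensities are
fixed at zero (the unrestricted fit typically fails to converge).

The five default states are L. crispatus, L. iners, BVAB1, G. vaginalis and
"Other"; unassigned samples and all non-focal vagitypes map to "Other".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

DEFAULT_STATES = (
    "Lactobacillus_crispatus_cluster",
    "Lactobacillus_iners",
    "Lachnospiraceae_BVAB1",
    "Gardnerella_vaginalis",
    "Other",
)

MIN_TRANSITIONS = 4
TRIMESTER_DAYS = 91  # 13 weeks
STATIONARY_T = 100_000.0  # days


def _validate_generator(Q: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("intensity matrix must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -tol):
        raise ValueError("off-diagonal intensities must be non-negative")
    if np.any(np.abs(Q.sum(axis=1)) > tol):
        raise ValueError("generator rows must sum to 0")
    return Q


@dataclass
class CtmcModel:
    """Fitted CTMC with a log-linear outcome effect on each free intensity."""

    states: list[str]
    Q0: np.ndarray  # baseline (z = 0) intensity matrix, per day
    beta: np.ndarray  # covariate effect per transition (0 where disallowed)
    allowed_mask: np.ndarray  # boolean, off-diagonal transitions modeled
    loglik: float = np.nan
    standard_errors: dict = field(default_factory=dict)
    converged: bool = True

    def Q(self, z: float = 0.0) -> np.ndarray:
        """Intensity matrix at covariate value z (rows re-balanced to sum 0)."""
        off = self.Q0 * np.exp(self.beta * z)
        np.fill_diagonal(off, 0.0)
        Q = off.copy()
        np.fill_diagonal(Q, -off.sum(axis=1))
        return Q


def build_state_sequences(
    assignments: pd.DataFrame,
    records: pd.DataFrame,
    states=DEFAULT_STATES,
) -> dict[str, list[tuple[str, int]]]:
    """Per-subject chronological (state, gestational day) series.

    Vagitypes outside the focal state set (including UNASSIGNED) map to
    "Other".  Duplicate days within a subject collapse to the
    lexicographically earlier sample (logged).  Single-visit subjects are
    retained (they inform the initial distribution but contribute no
    transition intervals).
    """
    focal = set(states) - {"Other"}
    vag = dict(zip(assignments["sample_id"], assignments["vagitype"]))
    merged = records[["sample_id", "subject_id", "gestational_age"]].copy()
    merged["state"] = [
        vag[s] if vag.get(s) in focal else "Other" for s in merged["sample_id"]
    ]
    sequences: dict[str, list[tuple[str, int]]] = {}
    for subject, grp in merged.groupby("subject_id", sort=False):
        grp = grp.sort_values(["gestational_age", "sample_id"])
        dup = grp["gestational_age"].duplicated()
        if dup.any():
            logger.warning("subject %s: %d duplicate visit day(s) collapsed",
                           subject, int(dup.sum()))
            grp = grp[~dup]
        sequences[subject] = list(zip(grp["state"], grp["gestational_age"].astype(int)))
    return sequences


def count_transitions(sequences: dict, states=DEFAULT_STATES,
                      covariate: dict | None = None) -> np.ndarray:
    """Between-visit state-change counts (r != s).

    Pooled over all subjects by default; with ``covariate`` given, returns
    the element-wise minimum of the per-group count matrices, so a
    min-count restriction then demands the threshold within every group.
    """
    idx = {s: i for i, s in enumerate(states)}
    groups: dict[float, np.ndarray] = {}
    for subject, seq in sequences.items():
        z = 0.0 if covariate is None else float(covariate[subject])
        counts = groups.setdefault(z, np.zeros((len(states), len(states)), dtype=int))
        for (s1, _), (s2, _) in zip(seq, seq[1:]):
            if s1 != s2:
                counts[idx[s1], idx[s2]] += 1
    return np.minimum.reduce(list(groups.values()))


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Q t) for a valid generator, via scaling-and-squaring Padé.

    Rows are checked to sum to 1 within 1e-10 and entries are clipped to
    [0, 1] after that tolerance check.
    """
    Q = _validate_generator(Q)
    if t < 0:
        raise ValueError("t must be non-negative")
    P = expm(Q * t)
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-10):
        raise FloatingPointError("transition matrix rows failed to sum to 1")
    return np.clip(P, 0.0, 1.0)


def _pack_intervals(sequences, covariate, states):
    """Collapse the panel to counts per (z, dt, r, s) for fast likelihoods."""
    idx = {s: i for i, s in enumerate(states)}
    counts: dict[tuple[float, float], np.ndarray] = {}
    n = len(states)
    for subject, seq in sequences.items():
        z = 0.0 if covariate is None else float(covariate[subject])
        for (s1, t1), (s2, t2) in zip(seq, seq[1:]):
            dt = float(t2 - t1)
            if dt <= 0:
                continue
            key = (z, dt)
            if key not in counts:
                counts[key] = np.zeros((n, n))
            counts[key][idx[s1], idx[s2]] += 1
    return counts


def _build_Q(theta, allowed_idx, n, z, with_covariate):
    k = len(allowed_idx)
    q0 = np.exp(theta[:k])
    beta = theta[k:] if with_covariate else np.zeros(k)
    Q = np.zeros((n, n))
    for (r, s), q, b in zip(allowed_idx, q0, beta):
        Q[r, s] = q * np.exp(b * z)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_ctmc(
    sequences: dict,
    covariate: dict | None = None,
    states=DEFAULT_STATES,
    allowed_mask: np.ndarray | None = None,
    min_transitions: int = MIN_TRANSITIONS,
    pool_counts: bool = True,
    n_starts: int = 3,
    seed: int = 0,
) -> CtmcModel:
    """Maximum-likelihood CTMC fit to interval-censored vagitype panels.

    ``covariate`` maps subject -> z (1 = PTB, 0 = TB); None fits a
    covariate-free chain.  ``allowed_mask`` defaults to the transitions with
    at least ``min_transitions`` observed between-visit changes, pooled over
    both outcome groups (``pool_counts=False`` demands the threshold inside
    every group instead).  Optimization is quasi-Newton on log-intensities
    (positivity by construction) with ``n_starts`` seeded starts; standard
    errors come from the observed information (central-difference Hessian).
    """
    states = list(states)
    n = len(states)
    if allowed_mask is None:
        counts = count_transitions(
            sequences, states,
            covariate=None if pool_counts else covariate)
        allowed_mask = counts >= min_transitions
        np.fill_diagonal(allowed_mask, False)
    allowed_mask = np.asarray(allowed_mask, dtype=bool)
    allowed_idx = [(r, s) for r in range(n) for s in range(n)
                   if allowed_mask[r, s] and r != s]
    if not allowed_idx:
        raise ValueError("no transition passes the minimum-count restriction")
    k = len(allowed_idx)
    with_cov = covariate is not None
    n_par = 2 * k if with_cov else k

    packed = _pack_intervals(sequences, covariate, states)
    if not packed:
        raise ValueError("no transition intervals in the data")

    def negloglik(theta):
        total = 0.0
        for (z, dt), cmat in packed.items():
            Q = _build_Q(theta, allowed_idx, n, z, with_cov)
            P = expm(Q * dt)
            with np.errstate(divide="ignore", invalid="ignore"):
                logP = np.log(np.maximum(P, 1e-300))
            total -= float((cmat * logP).sum())
        if not np.isfinite(total):
            raise FloatingPointError(f"non-finite likelihood at theta={theta}")
        return total

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        theta0 = np.concatenate([
            np.log(np.full(k, 0.01)) + (rng.normal(0, 0.5, k) if start else 0.0),
            np.zeros(k) if with_cov else np.zeros(0),
        ])
        res = minimize(negloglik, theta0, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        logger.warning("CTMC fit did not fully converge: %s", best.message)

    theta = best.x
    q0 = np.exp(theta[:k])
    beta = theta[k:] if with_cov else np.zeros(k)
    Q0 = np.zeros((n, n))
    B = np.zeros((n, n))
    for (r, s), q, b in zip(allowed_idx, q0, beta):
        Q0[r, s] = q
        B[r, s] = b
    np.fill_diagonal(Q0, -Q0.sum(axis=1))

    se = _observed_information_se(negloglik, theta)
    se_dict = {}
    for j, (r, s) in enumerate(allowed_idx):
        se_dict[("log_q0", states[r], states[s])] = se[j]
        if with_cov:
            se_dict[("beta", states[r], states[s])] = se[k + j]

    return CtmcModel(
        states=states, Q0=Q0, beta=B, allowed_mask=allowed_mask,
        loglik=-best.fun, standard_errors=se_dict, converged=bool(best.success),
    )


def _observed_information_se(negloglik, theta, h: float = 1e-4) -> np.ndarray:
    """Standard errors from a central-difference Hessian of -loglik."""
    k = len(theta)
    H = np.zeros((k, k))
    f0 = negloglik(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (negloglik(theta + ei) - 2 * f0 + negloglik(theta - ei)) / h**2
            else:
                fpp = negloglik(theta + ei + ej)
                fpm = negloglik(theta + ei - ej)
                fmp = negloglik(theta - ei + ej)
                fmm = negloglik(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        logger.warning("observed information matrix is singular; SEs unavailable")
        se = np.full(k, np.nan)
    return se


def stationary_distribution(
    model_or_Q,
    z: float = 0.0,
    t_large: float = STATIONARY_T,
) -> np.ndarray:
    """Long-run state distribution, any row of P(t_large).

    When the chain is irreducible the result is cross-checked against the
    null-space solution of pi Q = 0 within 1e-6; reducible chains return the
    P(t_large) row with a warning (the limit then depends on the start).
    """
    Q = model_or_Q.Q(z) if isinstance(model_or_Q, CtmcModel) else np.asarray(model_or_Q, float)
    Q = _validate_generator(Q)
    P = transition_probability(Q, t_large)
    pi = P[0]
    # null-space solution for the irreducible case
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi_null, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.all(pi_null > -1e-9) and np.max(np.abs(pi_null @ Q)) < 1e-8:
        if np.max(np.abs(P - P[0][None, :])) < 1e-6:
            if np.max(np.abs(pi - pi_null)) > 1e-6:
                logger.warning("P(t_large) row and null-space solution disagree")
        else:
            logger.warning("chain appears reducible; stationary row depends on start")
    return pi


def dynamic_balance(
    model_or_Q,
    z: float = 0.0,
    t: float = TRIMESTER_DAYS,
    states=None,
) -> pd.DataFrame:
    """Forward-minus-reverse one-trimester transition probabilities.

    For each ordered state pair (i, j) reports ``P_ij(t) - P_ji(t)``; a
    secondary column gives the detailed-balance flux at stationarity,
    ``pi_i P_ij(t) - pi_j P_ji(t)`` (zero for any reversible chain).
    """
    if isinstance(model_or_Q, CtmcModel):
        Q = model_or_Q.Q(z)
        states = states or model_or_Q.states
    else:
        Q = np.asarray(model_or_Q, dtype=float)
        states = states or [f"state_{i}" for i in range(Q.shape[0])]
    P = transition_probability(Q, t)
    pi = stationary_distribution(Q, t_large=STATIONARY_T)
    rows = []
    for i, j in itertools.combinations(range(len(states)), 2):
        rows.append(dict(
            from_state=states[i], to_state=states[j],
            forward=P[i, j], reverse=P[j, i],
            forward_minus_reverse=P[i, j] - P[j, i],
            detailed_balance_flux=pi[i] * P[i, j] - pi[j] * P[j, i],
        ))
    return pd.DataFrame(rows)
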