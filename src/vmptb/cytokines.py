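"""Cytokine panel handling and sparse canonical correlation with taxa.

The mucosal immunoproteome enters as per-swab cytokine concentrations
(pg/ml) with limit-of-detection flags.  Cytokines with at least 30%
out-of-range readings are dropped; remaining out-of-range values are imputed
at the nearer detection limit.  The link between log cytokines and log taxon
abundances is estimated by sparse canonical correlation analysis (sCCA): an
l1-penalized matrix decomposition that alternates soft-thresholded power
iterations on the cross-covariance, suited to more variables than
observations.  Results are summarized on a correlation circle whose
coordinates are the correlations of each variable with its own block's
canonical variates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the nine-cytokine panel retained in the reference analysis
CYTOKINE_NAMES = (
    "IL-1b", "eotaxin", "IL-8", "TNF-a", "IL-17A",
    "MIP-1b", "IL-6", "IP-10", "RANTES",
)

IN_RANGE, BELOW_LOD, ABOVE_LOD = "in_range", "below_lod", "above_lod"

MAX_OOR_FRACTION = 0.30

#: trimester boundaries in gestational days (T1 < 98, T2 98-195, T3 > 195)
TRIMESTER_BOUNDS = (98, 196)


@dataclass
class CytokinePanel:
    """Per-sample cytokine concentrations with LOD censoring flags."""

    sample_ids: list[str]
    cytokine_names: list[str]
    values: np.ndarray  # pg/ml, after per-swab normalization
    oor_flags: np.ndarray  # strings: in_range / below_lod / above_lod
    lod_bounds: dict  # cytokine -> (lod_lo, lod_hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.cytokine_names)

    def oor_fraction(self) -> pd.Series:
        return pd.Series(
            (self.oor_flags != IN_RANGE).mean(axis=0), index=self.cytokine_names
        )


@dataclass
class SccaResult:
    """Sparse canonical vectors, correlations and circle coordinates."""

    taxa_weights: pd.DataFrame  # taxa x components
    cytokine_weights: pd.DataFrame  # cytokines x components
    canonical_correlations: np.ndarray
    circle_coords: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_cytokines(panel: CytokinePanel, max_oor: float = MAX_OOR_FRACTION) -> CytokinePanel:
    """Drop high-censoring cytokines and impute the rest at their LOD bound.

    A cytokine with an out-of-range fraction of ``max_oor`` or more is
    dropped; below-LOD readings of the survivors are set to the lower
    detection limit and above-LOD readings to the upper limit.
    """
    frac = panel.oor_fraction()
    keep = [c for c in panel.cytokine_names if frac[c] < max_oor]
    dropped = sorted(set(panel.cytokine_names) - set(keep))
    if dropped:
        logger.info("select_cytokines: dropped %s (>= %.0f%% out of range)",
                    dropped, 100 * max_oor)
    cols = [panel.cytokine_names.index(c) for c in keep]
    values = panel.values[:, cols].copy()
    flags = panel.oor_flags[:, cols].copy()
    for j, c in enumerate(keep):
        lo, hi = panel.lod_bounds[c]
        values[flags[:, j] == BELOW_LOD, j] = lo
        values[flags[:, j] == ABOVE_LOD, j] = hi
    return CytokinePanel(
        sample_ids=list(panel.sample_ids), cytokine_names=keep,
        values=values, oor_flags=flags,
        lod_bounds={c: panel.lod_bounds[c] for c in keep},
    )


def trimester_of(gestational_age: int) -> int:
    """Trimester (1-3) of a gestational age in days."""
    t1_end, t2_end = TRIMESTER_BOUNDS
    if gestational_age < t1_end:
        return 1
    if gestational_age < t2_end:
        return 2
    return 3


def trimester_earliest(records: pd.DataFrame) -> pd.DataFrame:
    """Earliest sample per subject per trimester (at most 3 rows a subject).

    Ties on gestational age break to the lexicographically smallest
    sample_id, the package-wide tie rule.
    """
    frame = records.copy()
    frame["trimester"] = frame["gestational_age"].map(trimester_of)
    picks = []
    for (_, _), grp in frame.groupby(["subject_id", "trimester"], sort=False):
        day = grp["gestational_age"].min()
        at_min = grp[grp["gestational_age"] == day].sort_values("sample_id")
        picks.append(at_min.index[0])
    return frame.loc[picks].reset_index(drop=True)


def _soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _l1_constrained_unit(a: np.ndarray, c: float) -> np.ndarray:
    """argmax u'a subject to ||u||_2 <= 1, ||u||_1 <= c (soft-threshold + bisection)."""
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    u = a / norm
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(100):
        delta = (lo + hi) / 2
        su = _soft_threshold(a, delta)
        nrm = np.linalg.norm(su)
        if nrm == 0:
            hi = delta
            continue
        if np.abs(su / nrm).sum() > c:
            lo = delta
        else:
            hi = delta
    su = _soft_threshold(a, hi)
    return su / np.linalg.norm(su)


def sparse_cca(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    penalties: tuple[float, float] = (2.0, 2.0),
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> SccaResult:
    """l1-penalized CCA of two blocks by penalized matrix decomposition.

    Columns of both blocks are standardized internally (zero-variance
    columns dropped with a warning).  Per component the algorithm maximizes
    ``u' X'Y v`` subject to ``||u||_2 <= 1, ||u||_1 <= cx`` (and likewise
    for v) by alternating soft-thresholded power iterations; the objective
    is asserted non-decreasing at every iteration.  Later components are
    extracted from the deflated cross-covariance.  Canonical correlations
    are the Pearson correlations of the block variates.  Sign convention:
    the largest-magnitude taxa (Y-block) weight of each component is
    positive.

    X is the cytokine block, Y the taxa block, both log-transformed
    upstream; rows are matched samples (at least 3 required).
    """
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must share samples")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    cx, cy = penalties

    def standardize(df):
        sd = df.std(axis=0, ddof=1)
        dead = sd[sd == 0].index
        if len(dead):
            logger.warning("dropping zero-variance columns: %s", list(dead))
            df = df.drop(columns=dead)
            sd = sd.drop(dead)
        return (df - df.mean(axis=0)) / sd

    Xs = standardize(X)
    Ys = standardize(Y)
    K = Xs.to_numpy().T @ Ys.to_numpy() / (Xs.shape[0] - 1)

    us, vs, cors = [], [], []
    Kd = K.copy()
    rng_free_v0 = np.ones(Kd.shape[1]) / np.sqrt(Kd.shape[1])
    for comp in range(n_components):
        v = rng_free_v0.copy()
        u = np.zeros(Kd.shape[0])
        prev_obj = -np.inf
        for _ in range(max_iter):
            u_new = _l1_constrained_unit(Kd @ v, cx)
            v_new = _l1_constrained_unit(Kd.T @ u_new, cy)
            obj = float(u_new @ Kd @ v_new)
            assert obj >= prev_obj - 1e-9, "sCCA objective decreased"
            delta = max(np.max(np.abs(u_new - u)), np.max(np.abs(v_new - v)))
            u, v, prev_obj = u_new, v_new, obj
            if delta < tol:
                break
        # sign convention: largest-|weight| taxa coefficient positive
        if len(v) and v[np.argmax(np.abs(v))] < 0:
            u, v = -u, -v
        d = float(u @ Kd @ v)
        Kd = Kd - d * np.outer(u, v)
        xi = Xs.to_numpy() @ u
        eta = Ys.to_numpy() @ v
        if xi.std() == 0 or eta.std() == 0:
            cors.append(0.0)
        else:
            cors.append(float(np.corrcoef(xi, eta)[0, 1]))
        us.append(u)
        vs.append(v)

    comp_names = [f"comp{i + 1}" for i in range(n_components)]
    result = SccaResult(
        taxa_weights=pd.DataFrame(np.column_stack(vs), index=Ys.columns,
                                  columns=comp_names),
        cytokine_weights=pd.DataFrame(np.column_stack(us), index=Xs.columns,
                                      columns=comp_names),
        canonical_correlations=np.asarray(cors),
    )
    result.circle_coords = correlation_circle(result, Xs, Ys)
    return result


def correlation_circle(
    result: SccaResult,
    X: pd.DataFrame,
    Y: pd.DataFrame,
    flip_component1: bool = False,
) -> pd.DataFrame:
    """Correlation-circle coordinates for every variable of both blocks.

    A variable's coordinate k is its Pearson correlation with its own
    block's component-k canonical variate.  Because deflation does not force
    later variates to be uncorrelated with earlier ones, the variates are
    Gram-Schmidt orthogonalized within each block first, which guarantees
    every point lies in the unit disk.  ``flip_component1`` negates the
    first coordinate (for display conventions that reverse an axis).
    """
    rows = []
    for block, frame, weights in (
        ("cytokine", X[result.cytokine_weights.index], result.cytokine_weights),
        ("taxa", Y[result.taxa_weights.index], result.taxa_weights),
    ):
        variates = frame.to_numpy() @ weights.to_numpy()  # n x n_components
        variates = variates - variates.mean(axis=0)
        for k in range(1, variates.shape[1]):
            for j in range(k):
                prev = variates[:, j]
                denom = prev @ prev
                if denom > 0:
                    variates[:, k] -= (variates[:, k] @ prev) / denom * prev
        data = frame.to_numpy()
        for j, var in enumerate(frame.columns):
            coords = []
            for k in range(variates.shape[1]):
                vk = variates[:, k]
                if data[:, j].std() == 0 or vk.std() == 0:
                    coords.append(0.0)
                else:
                    coords.append(float(np.corrcoef(data[:, j], vk)[0, 1]))
            rows.append({"variable": var, "block": block,
                         "comp1": coords[0],
                         "comp2": coords[1] if len(coords) > 1 else 0.0})
    out = pd.DataFrame(rows)
    if flip_component1:
        out["comp1"] = -out["comp1"]
    return out
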