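"""Cross-sectional univariate screening of taxa and categorical contrasts.

One earliest sample per subject enters the screen; abundances below 1e-5 are
rounded to zero before ranking, each retained taxon gets a two-sided
Mann-Whitney U test of PTB vs TB abundance, and p-values are adjusted by the
Benjamini-Hochberg step-up at FDR 5%.  Medians and 75th percentiles per
group accompany each test.  Vagitype-by-outcome count contrasts use Fisher's
exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ZERO_FLOOR = 0.00001
EXACT_MAX_N = 12  # exact Mann-Whitney enumeration up to this combined size


@dataclass
class DifferentialResult:
    """Screen outcome for one taxon."""

    taxon: str
    u_statistic: float
    p_value: float
    q_value: float
    median_ptb: float
    median_tb: float
    p75_ptb: float
    p75_tb: float
    direction: int  # sign of median_ptb - median_tb
    significant: bool


def mann_whitney(x, y, zero_floor: float = ZERO_FLOOR) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with small-value rounding.

    Values below ``zero_floor`` are set to 0 before ranking.  The p-value is
    exact (full enumeration) when the combined sample size is at most 12 and
    there are no ties, otherwise the normal approximation with tie-corrected
    variance and continuity correction is used.  Returns ``(U_x, p)`` where
    ``U_x`` is the U statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if zero_floor > 0:
        x = np.where(x < zero_floor, 0.0, x)
        y = np.where(y < zero_floor, 0.0, y)

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    logger.debug("mann_whitney: n=(%d,%d) ties=%s method=%s", x.size, y.size, has_ties, method)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    In sorted order, ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1,
    mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p-value sums hypergeometric probabilities of all tables,
    with the observed margins, at most as probable as the observed table.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def differential_screen(
    table,
    cohort,
    alpha_fdr: float = 0.05,
    zero_floor: float = ZERO_FLOOR,
) -> pd.DataFrame:
    """Mann-Whitney screen of every taxon between the PTB and TB groups.

    Parameters
    ----------
    table : AbundanceTable or DataFrame (samples x taxa)
        Restricted to one (earliest) sample per subject and to taxa that
        already passed the low-abundance filter.
    cohort : CohortTable, or a mapping/Series sample_id -> "PTB"/"TB"
    alpha_fdr : flag taxa with BH q below this false-discovery rate

    Returns one row per input taxon (count is preserved regardless of
    significance) with U, p, q, per-group medians and 75th percentiles
    computed on the floored values, direction, and the significance flag.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    if hasattr(cohort, "records"):  # CohortTable: map via subject outcome
        rec = cohort.records
        sub_outcome = {}
        for case in cohort.cases:
            sub_outcome[case] = "PTB"
        for ctrl in cohort.controls:
            sub_outcome[ctrl] = "TB"
        samp_subject = dict(zip(rec["sample_id"], rec["subject_id"])) if "sample_id" in rec else {}
        labels = pd.Series(
            {s: sub_outcome[samp_subject.get(s, s)] for s in frame.index}
        )
    else:
        labels = pd.Series(cohort).reindex(frame.index)
    is_ptb = labels == "PTB"
    if is_ptb.sum() == 0 or (~is_ptb).sum() == 0:
        raise ValueError("both PTB and TB groups must be present")

    rows = []
    pvals = []
    for taxon in frame.columns:
        x = frame.loc[is_ptb.values, taxon].to_numpy(dtype=float)
        y = frame.loc[~is_ptb.values, taxon].to_numpy(dtype=float)
        u, p = mann_whitney(x, y, zero_floor=zero_floor)
        xf = np.where(x < zero_floor, 0.0, x)
        yf = np.where(y < zero_floor, 0.0, y)
        rows.append(
            dict(
                taxon=taxon,
                u_statistic=u,
                p_value=p,
                median_ptb=float(np.median(xf)),
                median_tb=float(np.median(yf)),
                p75_ptb=float(np.percentile(xf, 75)),  # linear interpolation
                p75_tb=float(np.percentile(yf, 75)),
            )
        )
        pvals.append(p)

    q = bh_adjust(pvals)
    out = pd.DataFrame(rows)
    out["q_value"] = q
    out["direction"] = np.sign(out["median_ptb"] - out["median_tb"]).astype(int)
    out["significant"] = out["q_value"] < alpha_fdr
    return out


def correlation_network(
    table,
    focal_taxa,
    threshold: float = 0.3,
    presence_floor: float = 0.001,
) -> pd.DataFrame:
    """Plain correlation network around a set of focal taxa.

    Pearson correlations of soft-threshold-log abundances between each focal
    taxon and every other taxon present (abundance >= ``presence_floor``) in
    at least 10% of samples; edges with |r| below ``threshold`` are dropped.
    A deliberately simple stand-in for model-based co-occurrence estimation.
    """
    from .profiles import soft_threshold_log

    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    present = [t for t in frame.columns
               if (frame[t] >= presence_floor).mean() >= 0.10]
    logged = pd.DataFrame(soft_threshold_log(frame[present].to_numpy()),
                          columns=present, index=frame.index)
    edges = []
    for focal in focal_taxa:
        if focal not in logged:
            continue
        for other in present:
            if other == focal:
                continue
            r = float(np.corrcoef(logged[focal], logged[other])[0, 1])
            if abs(r) >= threshold:
                edges.append(dict(source=focal, target=other, correlation=r))
    return pd.DataFrame(edges, columns=["source", "target", "correlation"])


def lcrispatus_vagitype_contrast(assignments: pd.DataFrame, outcomes: pd.Series,
                                 taxon: str = "Lactobacillus_crispatus_cluster") -> dict:
    """Fisher exact contrast of L. crispatus vagitype counts, PTB vs TB.

    Unassigned samples are excluded from the contrast.  ``assignments`` is
    the frame from :func:`vmptb.profiles.assign_vagitypes`; ``outcomes`` maps
    sample_id -> "PTB"/"TB".
    """
    from .profiles import UNASSIGNED

    assigned = assignments[assignments["vagitype"] != UNASSIGNED]
    lab = outcomes.reindex(assigned["sample_id"]).to_numpy()
    is_lc = (assigned["vagitype"] == taxon).to_numpy()
    a = int(np.sum(is_lc & (lab == "PTB")))
    b = int(np.sum(~is_lc & (lab == "PTB")))
    c = int(np.sum(is_lc & (lab == "TB")))
    d = int(np.sum(~is_lc & (lab == "TB")))
    return {
        "table": [[a, b], [c, d]],
        "p_value": fisher_exact_2x2(a, b, c, d),
    }
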