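"""Compositional transforms, abundance filtering, vagitype assignment, diversity.

A *vagitype* (community state type) labels a vaginal sample by its single
most abundant taxon; samples whose top taxon holds less than 30% of reads
stay unassigned.  The predominant-taxon rule is deliberately free of any
dataset-dependent clustering step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

#: soft-threshold applied to proportions before the log10 transform
SOFT_THRESHOLD = 0.001

#: minimum top-taxon proportion for a sample to receive a vagitype
VAGITYPE_MIN_PROPORTION = 0.30


@dataclass(frozen=True)
class VagitypeAssignment:
    """Vagitype call for one sample."""

    sample_id: str
    vagitype: str  # taxon label, or UNASSIGNED
    max_proportion: float

    def __post_init__(self) -> None:
        if self.vagitype != UNASSIGNED and self.max_proportion < VAGITYPE_MIN_PROPORTION:
            raise ValueError(
                f"assigned vagitype with max proportion {self.max_proportion} < "
                f"{VAGITYPE_MIN_PROPORTION}"
            )


def soft_threshold_log(abundance, threshold: float = SOFT_THRESHOLD):
    """Soft-thresholded log10 transform of a relative abundance.

    Computes ``log10((max(a - t, 0) + t) / t)`` with t = 0.001 by default.
    Abundances at or below the threshold map to 0; an abundance of 1 maps to
    3.  The transform is continuous and monotone non-decreasing, and shifts
    log-abundance from [-3, 0] to the non-negative range [0, 3] without
    changing the relative order of samples.

    Accepts scalars or arrays; returns the same shape.
    """
    a = np.asarray(abundance, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("abundance must lie in [0, 1]")
    out = np.log10((np.maximum(a - threshold, 0.0) + threshold) / threshold)
    if np.isscalar(abundance) or np.ndim(abundance) == 0:
        return float(out)
    return out


def filter_low_abundance(table) -> list[str]:
    """Return the taxa that pass the two-criterion low-abundance filter.

    A taxon is retained iff at least 5% of samples show abundance >= 1%, or
    at least 15% of samples show abundance >= 0.1%.  Both outer fractions are
    inclusive and computed over all samples in the table.

    Parameters
    ----------
    table : AbundanceTable or pandas.DataFrame of proportions (samples x taxa)
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    if frame.shape[0] == 0:
        raise ValueError("cannot filter an empty table")
    frac_1pct = (frame.values >= 0.01).mean(axis=0)
    frac_01pct = (frame.values >= 0.001).mean(axis=0)
    keep = (frac_1pct >= 0.05) | (frac_01pct >= 0.15)
    return [t for t, k in zip(frame.columns, keep) if k]


def assign_vagitype(abundances: pd.Series, sample_id: str | None = None) -> VagitypeAssignment:
    """Assign a vagitype to one sample by the predominant-taxon rule.

    The vagitype is the taxon with the largest proportion, provided that
    proportion is at least 0.30; otherwise the sample is UNASSIGNED.  Exact
    ties break to the lexicographically first taxon label (logged).
    """
    a = abundances.astype(float)
    max_prop = float(a.max())
    top = sorted(a.index[a.values == max_prop])
    if len(top) > 1:
        logger.warning(
            "vagitype tie at %.4f among %s for sample %s; taking %s",
            max_prop, top, sample_id, top[0],
        )
    label = top[0] if max_prop >= VAGITYPE_MIN_PROPORTION else UNASSIGNED
    return VagitypeAssignment(
        sample_id=sample_id if sample_id is not None else str(a.name),
        vagitype=label,
        max_proportion=max_prop,
    )


def assign_vagitypes(table) -> pd.DataFrame:
    """Vagitype calls for every sample of an abundance table.

    Returns a DataFrame with columns ``sample_id``, ``vagitype``,
    ``max_proportion``.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    rows = [assign_vagitype(frame.loc[s], sample_id=str(s)) for s in frame.index]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "vagitype": [r.vagitype for r in rows],
            "max_proportion": [r.max_proportion for r in rows],
        }
    )


def shannon_diversity(abundances) -> float:
    """Shannon diversity (natural log) of one composition, in nats."""
    p = np.asarray(abundances, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
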