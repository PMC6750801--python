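"""Core data types, TSV readers/writers and cohort-selection utilities.

The central object is the :class:`AbundanceTable`, a samples-by-taxa matrix
of relative abundances (each row a composition summing to 1) with the
per-sample classified read depth retained alongside.  Sample metadata travel
as :class:`SampleRecord` rows; a matched case-control design is a
:class:`CohortTable`.

Gestational age is stored in integer days everywhere; weeks appear only at
I/O boundaries (``weeks = days // 7``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: row sums this far from 1 are silently renormalized; beyond, rejected
PROPORTION_TOLERANCE = 1e-6

#: minimum classified reads for a sample to enter any analysis
MIN_READS_DEFAULT = 1000

#: canonical names for the field's common taxon abbreviations
TAXON_ABBREVIATIONS = {
    "Samn": "Sneathia_amnii",
    "BVAB1": "Lachnospiraceae_BVAB1",
    "BVAB2": "Clostridiales_BVAB2",
    "TM7": "TM7_H1",
    "Pcl2": "Prevotella_cluster2",
    "Lcricl": "Lactobacillus_crispatus_cluster",
    "Liners": "Lactobacillus_iners",
    "Gvag": "Gardnerella_vaginalis",
    "Avag": "Atopobium_vaginae",
    "Mtype1": "Megasphaera_type1",
    "Dcl51": "Dialister_cluster51",
    "Pamn": "Prevotella_amnii",
    "Dmic": "Dialister_micraerophilus",
    "P142": "Parvimonas_OTU142",
    "CO27": "Coriobacteriaceae_OTU27",
}


class FormatError(ValueError):
    """Raised when an input table violates the documented format."""


def canonical_taxon(label: str) -> str:
    """Map a field abbreviation (Samn, BVAB1, Pcl2, ...) to its canonical name.

    Unknown labels pass through unchanged: taxon labels are free strings.
    """
    return TAXON_ABBREVIATIONS.get(label, label)


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances with per-sample read depth.

    Invariants: abundances in [0, 1]; each row sums to 1 (within 1e-9 after
    normalization from counts); sample and taxon identifiers are unique.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_taxa), proportions
    read_depth: np.ndarray  # shape (n_samples,), counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.read_depth = np.asarray(self.read_depth)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon identifiers")
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise FormatError("value matrix shape does not match identifiers")
        if self.read_depth.shape != (len(self.sample_ids),):
            raise FormatError("read_depth length does not match samples")
        if self.values.size:
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise FormatError("abundances must lie in [0, 1]")
            sums = self.values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise FormatError("rows must sum to 1 within 1e-9")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        """Proportions as a DataFrame indexed by sample, columns by taxon."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        """Subset (and reorder) to the given sample identifiers."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceTable(
            sample_ids=list(sample_ids),
            taxon_ids=list(self.taxon_ids),
            values=self.values[idx],
            read_depth=self.read_depth[idx],
        )

    def select_taxa(self, taxon_ids) -> "AbundanceTable":
        """Subset to the given taxa, keeping raw (unrenormalized) proportions.

        Rows no longer sum to 1, so the result is returned as a plain
        DataFrame rather than an AbundanceTable.
        """
        return self.to_frame()[list(taxon_ids)]


# clinical flags carried by every sample record (YES/NO -> 1/0)
CLINICAL_FLAGS = (
    "short_cervix",
    "cerclage",
    "progesterone",
    "history_miscarriage_stillbirth",
    "history_ptb",
    "antibiotics_6mo",
)

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "gestational_age",
    "outcome",
    "bmi",
    "vaginal_ph",
    "ethnicity_indicator",
    "ancestry",
    "age",
    "income_bracket",
    "gravidity",
    "parity",
    "delivery_gestational_age",
    "vaginal_delivery",
    "pprom",
) + CLINICAL_FLAGS


@dataclass
class SampleRecord:
    """Longitudinal metadata for one vaginal sample.

    ``gestational_age`` is days since conception estimate (0-315);
    ``outcome`` is "PTB" or "TB"; ``ethnicity_indicator`` is 0 for African
    ancestry and 1 for all other ancestries.
    """

    sample_id: str
    subject_id: str
    gestational_age: int
    outcome: str
    bmi: float = np.nan
    vaginal_ph: float = np.nan
    ethnicity_indicator: int = 0
    ancestry: str = "African"
    age: float = np.nan
    income_bracket: float = np.nan  # ordinal; NaN = missing
    gravidity: float = np.nan
    parity: float = np.nan
    delivery_gestational_age: float = np.nan
    vaginal_delivery: int = 0
    pprom: int = 0
    short_cervix: int = 0
    cerclage: int = 0
    progesterone: int = 0
    history_miscarriage_stillbirth: int = 0
    history_ptb: int = 0
    antibiotics_6mo: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gestational_age <= 315:
            raise ValueError(f"gestational_age {self.gestational_age} outside [0, 315] days")
        if self.outcome not in ("PTB", "TB"):
            raise ValueError(f"outcome must be PTB or TB, got {self.outcome!r}")
        if self.ethnicity_indicator not in (0, 1):
            raise ValueError("ethnicity_indicator must be 0 or 1")


def records_to_frame(records) -> pd.DataFrame:
    """SampleRecord collection -> metadata DataFrame (one row per sample)."""
    if isinstance(records, pd.DataFrame):
        return records
    cols = [f.name for f in dc_fields(SampleRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    """Metadata DataFrame -> list of SampleRecord (validates each row)."""
    cols = {f.name for f in dc_fields(SampleRecord)}
    out = []
    for _, row in frame.iterrows():
        kwargs = {k: v for k, v in row.items() if k in cols}
        kwargs["gestational_age"] = int(kwargs["gestational_age"])
        kwargs["ethnicity_indicator"] = int(kwargs["ethnicity_indicator"])
        out.append(SampleRecord(**kwargs))
    return out


@dataclass
class CohortTable:
    """A matched case-control design.

    ``cases`` and ``controls`` are disjoint subject-identifier lists;
    ``match_map`` sends each case to its matched controls, and every control
    appears in at most one case's list.
    """

    records: pd.DataFrame  # per-sample metadata for the design's subjects
    cases: list[str]
    controls: list[str]
    match_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.cases) & set(self.controls):
            raise ValueError("cases and controls overlap")
        used: set[str] = set()
        for case, ctrls in self.match_map.items():
            for c in ctrls:
                if c in used:
                    raise ValueError(f"control {c} matched to more than one case")
                used.add(c)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.cases) + list(self.controls)

    def outcome_of(self, subject_id: str) -> str:
        return "PTB" if subject_id in set(self.cases) else "TB"


# ---------------------------------------------------------------------------
# readers / writers

def read_abundance_table(path, layout: str = "counts") -> AbundanceTable:
    """Read a tab-delimited abundance table (samples x taxa).

    The header row holds taxon labels and the first column sample IDs.  With
    ``layout="counts"`` the cells are non-negative integers, normalized
    row-wise to proportions with the row total kept as the read depth.  With
    ``layout="proportions"`` rows must already sum to 1 (within 1e-6, then
    renormalized); an optional ``read_depth`` column supplies depths,
    otherwise depth is recorded as 0 (unknown).
    """
    if layout not in ("counts", "proportions"):
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError("empty abundance table")
    if df.index.duplicated().any():
        raise FormatError("duplicate sample identifiers")
    if df.columns.duplicated().any():
        raise FormatError("duplicate taxon identifiers")

    depth = None
    if "read_depth" in df.columns:
        depth = df.pop("read_depth").to_numpy()
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise FormatError("abundance values must be finite and non-negative")

    if layout == "counts":
        if np.any(values != np.round(values)):
            raise FormatError("counts layout requires integer values")
        depth = values.sum(axis=1)
        if np.any(depth == 0):
            bad = [s for s, d in zip(df.index, depth) if d == 0]
            raise FormatError(f"zero-depth samples: {bad}")
        values = values / depth[:, None]
    else:
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > PROPORTION_TOLERANCE):
            bad = [s for s, t in zip(df.index, sums) if abs(t - 1.0) > PROPORTION_TOLERANCE]
            raise FormatError(f"rows are not compositions (sum != 1): {bad}")
        # renormalize only rows that need it, so read/write round-trips are
        # textually stable
        off = np.abs(sums - 1.0) > 1e-9
        values[off] = values[off] / sums[off, None]
        if depth is None:
            depth = np.zeros(len(df), dtype=int)

    return AbundanceTable(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        values=values,
        read_depth=np.asarray(depth),
    )


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write proportions plus a read_depth column as TSV (round-trippable)."""
    df = table.to_frame()
    df.insert(0, "read_depth", table.read_depth)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV; empty fields decode as missing (NaN)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = {"sample_id", "subject_id", "gestational_age", "outcome"} - set(df.columns)
    if missing:
        raise FormatError(f"metadata lacks required columns: {sorted(missing)}")
    return df


def write_metadata(records, path) -> None:
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample selection

def filter_min_reads(table: AbundanceTable, min_reads: int = MIN_READS_DEFAULT) -> AbundanceTable:
    """Drop samples with fewer than ``min_reads`` classified reads.

    The boundary is inclusive: a sample with exactly ``min_reads`` reads is
    retained.  Survivor order is preserved; an empty table is allowed (with a
    warning) when nothing passes.
    """
    keep = [s for s, d in zip(table.sample_ids, table.read_depth) if d >= min_reads]
    if not keep:
        logger.warning("filter_min_reads: no sample reaches %d reads", min_reads)
    return table.select_samples(keep)


def earliest_sample_in_window(records, window: tuple[int, int] = (42, 167)) -> pd.DataFrame:
    """Earliest sample per subject inside an inclusive gestational-age window.

    Subjects with no sample in the window are excluded.  Ties on gestational
    age within a subject break to the lexicographically smallest sample_id
    (logged).
    """
    frame = records_to_frame(records)
    lo, hi = window
    inside = frame[(frame["gestational_age"] >= lo) & (frame["gestational_age"] <= hi)]
    picks = []
    for subject, grp in inside.groupby("subject_id", sort=False):
        day = grp["gestational_age"].min()
        at_min = grp[grp["gestational_age"] == day].sort_values("sample_id")
        if len(at_min) > 1:
            logger.warning(
                "subject %s has %d samples at day %d; taking %s",
                subject, len(at_min), day, at_min.iloc[0]["sample_id"],
            )
        picks.append(at_min.index[0])
    return frame.loc[picks].reset_index(drop=True)


class PoolExhaustedError(RuntimeError):
    """Raised when the control pool cannot supply the requested matches."""


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 2,
    seed: int | None = 0,
    max_age_tolerance: int = 10,
) -> CohortTable:
    """Match controls to cases on ethnicity, age and income, in widening passes.

    ``cases`` and ``pool`` are one-row-per-subject frames with columns
    ``subject_id``, ``ethnicity_indicator``, ``age``, ``income_bracket``.
    Pass 0 requires exact ethnicity, age within +/-2 years and the same
    income bracket; each later pass widens the age tolerance by 2 years up to
    ``max_age_tolerance``, then drops the income requirement, then drops the
    age requirement (ethnicity is always required).  Controls are consumed
    without replacement; within a pass the closest-age eligible control wins,
    with a seeded shuffle breaking exact ties.  Matching sees only the three
    matching keys, never microbiome or outcome-adjacent fields.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    case_ids = list(cases["subject_id"])
    if set(case_ids) & set(pool["subject_id"]):
        raise ValueError("pool overlaps cases")

    rng = np.random.default_rng(seed)
    pool = pool.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    pool = pool.reset_index(drop=True)
    available = pool.copy()

    # (age_tolerance or None, require_income) in loosening order
    passes = [(tol, True) for tol in range(2, max_age_tolerance + 1, 2)]
    passes.append((max_age_tolerance, False))
    passes.append((None, False))

    need = {c: ratio for c in case_ids}
    match_map: dict[str, list[str]] = {c: [] for c in case_ids}

    for age_tol, want_income in passes:
        for _, case in cases.iterrows():
            cid = case["subject_id"]
            while need[cid] > 0 and len(available):
                elig = available[available["ethnicity_indicator"] == case["ethnicity_indicator"]]
                if want_income:
                    if pd.isna(case["income_bracket"]):
                        elig = elig[elig["income_bracket"].isna()]
                    else:
                        elig = elig[elig["income_bracket"] == case["income_bracket"]]
                if age_tol is not None:
                    elig = elig[(elig["age"] - case["age"]).abs() <= age_tol]
                if not len(elig):
                    break
                best = elig.loc[(elig["age"] - case["age"]).abs().idxmin()]
                match_map[cid].append(best["subject_id"])
                available = available.drop(best.name)
                need[cid] -= 1
        if all(n == 0 for n in need.values()):
            break

    unmatched = [c for c, n in need.items() if n > 0]
    if unmatched:
        raise PoolExhaustedError(f"control pool exhausted; unmatched cases: {unmatched}")

    controls = [c for ctrls in match_map.values() for c in ctrls]
    design = pd.concat([cases, pool[pool["subject_id"].isin(controls)]], ignore_index=True)
    return CohortTable(records=design, cases=case_ids, controls=controls, match_map=match_map)
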