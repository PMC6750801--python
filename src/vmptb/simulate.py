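"""Synthetic longitudinal PTB/TB cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every downstream stage can be exercised and checked for
parameter recovery:

* each subject carries a latent vagitype trajectory simulated from a
  continuous-time Markov chain whose intensity matrix and initial
  distribution differ by pregnancy outcome;
* each visit's taxonomic composition is Dirichlet-multinomial, concentrated
  on the current vagitype's dominant taxon, with PTB-enriched signature taxa
  (BVAB1, S. amnii, Prevotella cluster 2, TM7-H1) and TB-enriched
  L. crispatus acting multiplicatively on the Dirichlet template;
* read depths are overdispersed around 50,000 with occasional low-depth
  failures exercising the 1,000-read QC floor;
* proinflammatory cytokines load positively on the log abundances of
  dysbiotic taxa, with limit-of-detection censoring;
* clinical covariates (age, ancestry, income, BMI, pH, obstetric history)
  support 2:1 case matching and the clinical comparator model;
* deliveries fall in 23w0d-36w6d (PTB) or >= 39w (TB) and truncate each
  subject's visit schedule.

All randomness flows from a single integer seed; the returned
:class:`SyntheticCohort` keeps the generating configuration and the latent
vagitype paths for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytokines import ABOVE_LOD, BELOW_LOD, CYTOKINE_NAMES, IN_RANGE, CytokinePanel
from .io import AbundanceTable, CohortTable, match_controls
from .profiles import soft_threshold_log

# ---------------------------------------------------------------------------
# default study conditions

#: taxon panel: the taxa that survive the low-abundance filter in vaginal
#: 16S surveys of this design, plus Megasphaera type 1
DEFAULT_TAXA = (
    "Lactobacillus_crispatus_cluster",
    "Lactobacillus_iners",
    "Lactobacillus_jensenii",
    "Lactobacillus_gasseri_cluster",
    "Lactobacillus_delbrueckii",
    "Gardnerella_vaginalis",
    "Lachnospiraceae_BVAB1",
    "Sneathia_amnii",
    "Sneathia_sanguinegens",
    "Prevotella_cluster2",
    "Prevotella_amnii",
    "Prevotella_bivia",
    "TM7_H1",
    "Atopobium_vaginae",
    "Megasphaera_type1",
    "Clostridiales_BVAB2",
    "Dialister_cluster51",
    "Dialister_micraerophilus",
    "Parvimonas_OTU142",
    "Coriobacteriaceae_OTU27",
    "Mycoplasma_hominis",
    "Ureaplasma_cluster23",
    "Aerococcus_christensenii",
    "Anaerococcus_tetradius",
    "Peptoniphilus_lacrimalis",
    "Streptococcus_cluster29",
    "Finegoldia_magna",
)

VAGITYPE_STATES = (
    "Lactobacillus_crispatus_cluster",
    "Lactobacillus_iners",
    "Lachnospiraceae_BVAB1",
    "Gardnerella_vaginalis",
    "Other",
)

#: dominant-taxon mass fraction and total concentration of each template
_TEMPLATE_SPECS = {
    "Lactobacillus_crispatus_cluster": ("Lactobacillus_crispatus_cluster", 0.80),
    "Lactobacillus_iners": ("Lactobacillus_iners", 0.75),
    "Lachnospiraceae_BVAB1": ("Lachnospiraceae_BVAB1", 0.55),
    "Gardnerella_vaginalis": ("Gardnerella_vaginalis", 0.60),
    "Other": ("Atopobium_vaginae", 0.28),
}
_TEMPLATE_CONCENTRATION = 40.0

#: extra template mass given to dysbiosis-associated companions of the
#: anaerobic states (the rest is spread evenly over the panel)
_DYSBIOTIC_COMPANIONS = (
    "Sneathia_amnii", "Prevotella_cluster2", "TM7_H1", "Megasphaera_type1",
    "Sneathia_sanguinegens", "Prevotella_amnii", "Clostridiales_BVAB2",
    "Atopobium_vaginae", "Gardnerella_vaginalis", "Dialister_cluster51",
)

LACTOBACILLI = tuple(t for t in DEFAULT_TAXA if t.startswith("Lactobacillus"))


def default_dirichlet_templates(taxa=DEFAULT_TAXA) -> dict[str, np.ndarray]:
    """Per-vagitype Dirichlet concentration vectors over the taxon panel."""
    taxa = list(taxa)
    templates = {}
    for state, (dominant, mass) in _TEMPLATE_SPECS.items():
        alpha = np.full(len(taxa), 0.02)
        if state in ("Lachnospiraceae_BVAB1", "Gardnerella_vaginalis", "Other"):
            for t in _DYSBIOTIC_COMPANIONS:
                if t != dominant:
                    alpha[taxa.index(t)] = (1.0 - mass) / len(_DYSBIOTIC_COMPANIONS) * 3.0
        alpha[taxa.index(dominant)] = mass
        alpha = alpha / alpha.sum() * _TEMPLATE_CONCENTRATION
        templates[state] = alpha
    return templates


def _default_Q(tb: bool) -> np.ndarray:
    """Per-day vagitype transition intensities (states in VAGITYPE_STATES order).

    Sojourn times are weeks to a few months; the term-pregnancy chain drifts
    toward L. crispatus, the preterm chain toward BVAB1/dysbiosis.
    """
    # order: Lcrispatus, Liners, BVAB1, Gvaginalis, Other
    if tb:
        Q = np.array([
            [0.0, 0.004, 0.0002, 0.001, 0.002],
            [0.006, 0.0, 0.0005, 0.002, 0.003],
            [0.004, 0.004, 0.0, 0.003, 0.004],
            [0.005, 0.004, 0.0008, 0.0, 0.004],
            [0.005, 0.004, 0.0008, 0.003, 0.0],
        ])
    else:
        Q = np.array([
            [0.0, 0.005, 0.0015, 0.002, 0.003],
            [0.003, 0.0, 0.003, 0.003, 0.004],
            [0.0015, 0.002, 0.0, 0.002, 0.003],
            [0.002, 0.003, 0.004, 0.0, 0.004],
            [0.002, 0.003, 0.004, 0.004, 0.0],
        ])
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort generator."""

    n_cases: int = 45
    n_controls_pool: int = 300
    match_ratio: int = 2
    visit_start: int = 60
    visit_interval: int = 28
    taxa: tuple = DEFAULT_TAXA
    vagitype_states: tuple = VAGITYPE_STATES
    dirichlet_templates: dict = field(default_factory=default_dirichlet_templates)
    Q_ptb: np.ndarray = field(default_factory=lambda: _default_Q(tb=False))
    Q_tb: np.ndarray = field(default_factory=lambda: _default_Q(tb=True))
    initial_dist_ptb: np.ndarray = field(
        default_factory=lambda: np.array([0.26, 0.24, 0.14, 0.16, 0.20]))
    initial_dist_tb: np.ndarray = field(
        default_factory=lambda: np.array([0.40, 0.26, 0.04, 0.14, 0.16]))
    #: log-fold change of Dirichlet template mass in PTB relative to TB
    ptb_effect: dict = field(default_factory=lambda: {
        "Lachnospiraceae_BVAB1": 0.85,
        "Sneathia_amnii": 0.85,
        "Prevotella_cluster2": 0.75,
        "TM7_H1": 0.75,
        "Lactobacillus_crispatus_cluster": -0.6,
    })
    read_depth_mean: float = 50_000.0
    read_depth_dispersion: float = 8.0  # negative-binomial size parameter
    low_depth_prob: float = 0.02  # failed samples exercising the QC floor
    #: cytokine model: log10 baseline, loadings on dysbiotic log-taxa, noise
    cytokine_names: tuple = CYTOKINE_NAMES
    cytokine_baseline: dict = field(default_factory=lambda: {
        "IL-1b": 1.5, "eotaxin": 0.8, "IL-8": 2.0, "TNF-a": 0.7,
        "IL-17A": 0.5, "MIP-1b": 1.2, "IL-6": 1.0, "IP-10": 1.8, "RANTES": 1.0,
    })
    #: cytokine -> {taxon: loading on soft-threshold-log10 abundance}
    cytokine_loadings: dict = field(default_factory=lambda: {
        c: {
            "Lachnospiraceae_BVAB1": 0.30, "Sneathia_amnii": 0.30,
            "Prevotella_cluster2": 0.20, "TM7_H1": 0.20,
            "Gardnerella_vaginalis": 0.15, "Atopobium_vaginae": 0.15,
        }
        for c in ("IL-1b", "IL-6", "MIP-1b", "eotaxin")
    })
    cytokine_noise_sd: float = 0.30  # log10 scale
    #: cytokine -> (LOD_lo, LOD_hi) in pg/ml
    cytokine_lod: dict = field(default_factory=lambda: {
        c: (10 ** (b - 1.2), 10 ** (b + 2.2))
        for c, b in {
            "IL-1b": 1.5, "eotaxin": 0.8, "IL-8": 2.0, "TNF-a": 0.7,
            "IL-17A": 0.5, "MIP-1b": 1.2, "IL-6": 1.0, "IP-10": 1.8,
            "RANTES": 1.0,
        }.items()
    })
    ptb_delivery_range: tuple = (161, 258)  # 23w0d - 36w6d
    tb_delivery_range: tuple = (273, 294)  # >= 39w
    seed: int = 0

    def __post_init__(self) -> None:
        for Q in (self.Q_ptb, self.Q_tb):
            Q = np.asarray(Q, float)
            off = Q - np.diag(np.diag(Q))
            if np.any(off < 0) or np.any(np.abs(Q.sum(axis=1)) > 1e-10):
                raise ValueError("Q rows must sum to 0 with non-negative off-diagonals")
        for alpha in self.dirichlet_templates.values():
            if np.any(np.asarray(alpha) <= 0):
                raise ValueError("Dirichlet concentrations must be strictly positive")
        lo, hi = self.ptb_delivery_range
        if not (161 <= lo and hi <= 258):
            raise ValueError("PTB delivery support must lie within [161, 258] days")
        if self.tb_delivery_range[0] < 273:
            raise ValueError("TB delivery support must start at >= 273 days")


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth that produced it."""

    table: AbundanceTable
    records: pd.DataFrame
    cytokines: CytokinePanel
    cohort: CohortTable
    truth: dict  # config, latent vagitype paths, per-subject delivery days


# ---------------------------------------------------------------------------
# component generators

def simulate_vagitype_path(Q, initial_dist, t_grid, seed=None, rng=None):
    """Exact CTMC sample reported at the visit times ``t_grid``.

    Simulates exponential holding times and the embedded jump chain from the
    first visit time onward; returns one state index per visit.
    """
    Q = np.asarray(Q, dtype=float)
    off = Q - np.diag(np.diag(Q))
    if np.any(off < 0) or np.any(np.abs(Q.sum(axis=1)) > 1e-10):
        raise ValueError("invalid generator matrix")
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = Q.shape[0]
    state = int(rng.choice(n, p=np.asarray(initial_dist) / np.sum(initial_dist)))
    if len(t_grid) == 0:
        return np.zeros(0, dtype=int)
    out = [state]
    t = t_grid[0]
    for target in t_grid[1:]:
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break  # absorbing state
            dwell = rng.exponential(1.0 / rate)
            if t + dwell > target:
                break
            t += dwell
            probs = Q[state].copy()
            probs[state] = 0.0
            probs = probs / probs.sum()
            state = int(rng.choice(n, p=probs))
        t = target
        out.append(state)
    return np.asarray(out, dtype=int)


def outcome_alpha(template: np.ndarray, taxa, ptb_effect: dict, outcome: str) -> np.ndarray:
    """Dirichlet template with the PTB/TB effect applied, total mass preserved."""
    alpha = np.asarray(template, dtype=float).copy()
    if outcome == "PTB":
        for taxon, logfold in ptb_effect.items():
            alpha[list(taxa).index(taxon)] *= np.exp(logfold)
        alpha = alpha / alpha.sum() * np.sum(template)
    return alpha


def simulate_composition(state, config: SyntheticConfig, outcome: str,
                         depth: int, seed=None, rng=None) -> np.ndarray:
    """One sample's taxon counts: Multinomial(depth, p), p ~ Dirichlet(alpha)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if state not in config.dirichlet_templates:
        raise ValueError(f"unknown vagitype state {state!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    alpha = outcome_alpha(config.dirichlet_templates[state], config.taxa,
                          config.ptb_effect, outcome)
    p = rng.dirichlet(alpha)
    return rng.multinomial(int(depth), p)


def simulate_cytokines(taxa_log_abundance: np.ndarray, config: SyntheticConfig,
                       seed=None, rng=None):
    """Cytokine concentrations for a batch of samples, with LOD censoring.

    ``taxa_log_abundance`` is (n_samples, n_taxa) of soft-threshold-log10
    abundances.  log10 concentration = baseline + loadings . log-taxa +
    Gaussian noise; values outside the detection window are censored at the
    bound and flagged.
    Returns ``(values, flags)`` arrays of shape (n_samples, n_cytokines).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(taxa_log_abundance, dtype=float))
    n = X.shape[0]
    names = list(config.cytokine_names)
    taxa = list(config.taxa)
    values = np.empty((n, len(names)))
    flags = np.full((n, len(names)), IN_RANGE, dtype=object)
    for j, c in enumerate(names):
        load = np.zeros(len(taxa))
        for taxon, w in config.cytokine_loadings.get(c, {}).items():
            load[taxa.index(taxon)] = w
        log10_conc = (config.cytokine_baseline[c] + X @ load
                      + rng.normal(0.0, config.cytokine_noise_sd, n))
        conc = 10 ** log10_conc
        lo, hi = config.cytokine_lod[c]
        below, above = conc < lo, conc > hi
        conc = np.clip(conc, lo, hi)
        values[:, j] = conc
        flags[below, j] = BELOW_LOD
        flags[above, j] = ABOVE_LOD
    return values, flags


def _draw_depth(config: SyntheticConfig, rng) -> int:
    if rng.random() < config.low_depth_prob:
        return int(rng.integers(100, 2000))
    r = config.read_depth_dispersion
    p = r / (r + config.read_depth_mean)
    return int(max(rng.negative_binomial(r, p), 1))


def _draw_subject(rng, outcome: str, subject_id: str, config: SyntheticConfig) -> dict:
    """Clinical covariates for one subject (visit-independent fields)."""
    ancestry = rng.choice(
        ["African", "European", "Hispanic", "NativeAmerican"],
        p=[0.78, 0.14, 0.06, 0.02])
    income = rng.choice([0.0, 1.0, 2.0, np.nan], p=[0.70, 0.17, 0.05, 0.08])
    gravidity = 1 + rng.poisson(1.5)
    parity = rng.binomial(gravidity - 1, 0.6) if gravidity > 1 else 0
    ptb = outcome == "PTB"
    lo, hi = config.ptb_delivery_range if ptb else config.tb_delivery_range
    return dict(
        subject_id=subject_id,
        outcome=outcome,
        age=float(np.clip(np.round(rng.normal(26.0, 5.5)), 18, 42)),
        ancestry=ancestry,
        ethnicity_indicator=0 if ancestry == "African" else 1,
        income_bracket=income,
        bmi=float(np.clip(rng.normal(28.0, 6.0), 16, 50)),
        gravidity=float(gravidity),
        parity=float(parity),
        history_ptb=int(rng.random() < (0.31 if ptb else 0.10)),
        history_miscarriage_stillbirth=int(rng.random() < (0.25 if ptb else 0.18)),
        short_cervix=int(rng.random() < (0.15 if ptb else 0.03)),
        cerclage=int(rng.random() < (0.07 if ptb else 0.01)),
        progesterone=int(rng.random() < (0.20 if ptb else 0.05)),
        antibiotics_6mo=int(rng.random() < (0.30 if ptb else 0.25)),
        pprom=int(rng.random() < 0.578) if ptb else 0,
        vaginal_delivery=int(rng.random() < (0.844 if ptb else 0.822)),
        delivery_gestational_age=float(rng.integers(lo, hi + 1)),
    )


def simulate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full 2:1 matched longitudinal cohort with ground truth."""
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    taxa = list(config.taxa)
    states = list(config.vagitype_states)

    # subjects: cases plus an oversized TB control pool for matching
    subject_rows = []
    for i in range(config.n_cases):
        subject_rows.append(_draw_subject(rng, "PTB", f"P{i:03d}", config))
    for i in range(config.n_controls_pool):
        subject_rows.append(_draw_subject(rng, "TB", f"T{i:03d}", config))
    subjects = pd.DataFrame(subject_rows)

    cases = subjects[subjects["outcome"] == "PTB"]
    pool = subjects[subjects["outcome"] == "TB"]
    cohort = match_controls(cases, pool, ratio=config.match_ratio,
                            seed=int(rng.integers(2**31)))
    design = subjects[subjects["subject_id"].isin(cohort.subject_ids)]

    records_rows = []
    count_rows = []
    sample_ids = []
    depths = []
    latent_paths: dict[str, list[tuple[int, str]]] = {}
    for _, subj in design.iterrows():
        outcome = subj["outcome"]
        delivery = subj["delivery_gestational_age"]
        visits = [d for d in range(config.visit_start, 316, config.visit_interval)
                  if d < delivery]
        if not visits:
            continue
        Q = config.Q_ptb if outcome == "PTB" else config.Q_tb
        init = config.initial_dist_ptb if outcome == "PTB" else config.initial_dist_tb
        path = simulate_vagitype_path(Q, init, visits, rng=rng)
        latent_paths[subj["subject_id"]] = [
            (day, states[s]) for day, s in zip(visits, path)
        ]
        for day, s in zip(visits, path):
            depth = _draw_depth(config, rng)
            counts = simulate_composition(states[s], config, outcome, depth, rng=rng)
            sid = f"{subj['subject_id']}_d{day:03d}"
            sample_ids.append(sid)
            depths.append(depth)
            count_rows.append(counts)
            props = counts / counts.sum()
            lacto = sum(props[taxa.index(t)] for t in LACTOBACILLI)
            row = dict(subj)
            row.update(
                sample_id=sid,
                gestational_age=int(day),
                vaginal_ph=float(np.clip(3.9 + 2.0 * (1 - lacto)
                                         + rng.normal(0, 0.25), 3.5, 7.5)),
            )
            records_rows.append(row)

    counts = np.asarray(count_rows, dtype=float)
    table = AbundanceTable(
        sample_ids=sample_ids,
        taxon_ids=taxa,
        values=counts / counts.sum(axis=1, keepdims=True),
        read_depth=np.asarray(depths),
    )
    records = pd.DataFrame(records_rows)

    log_taxa = soft_threshold_log(table.values)
    cyt_values, cyt_flags = simulate_cytokines(log_taxa, config, rng=rng)
    cytokines = CytokinePanel(
        sample_ids=sample_ids,
        cytokine_names=list(config.cytokine_names),
        values=cyt_values,
        oor_flags=cyt_flags,
        lod_bounds=dict(config.cytokine_lod),
    )

    cohort.records = records
    return SyntheticCohort(
        table=table,
        records=records,
        cytokines=cytokines,
        cohort=cohort,
        truth={
            "config": config,
            "latent_paths": latent_paths,
            "delivery": dict(zip(design["subject_id"],
                                 design["delivery_gestational_age"])),
        },
    )
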