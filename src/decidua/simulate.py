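"""Synthetic cohorts, count matrices and barcode read distributions.

Every downstream stage of the package is testable without external data
because this module plants known ground truth:

* ``generate_cohort`` emulates a case/control study of recurrent pregnancy
  loss (RPL): per subject an LH-timed biopsy day, RT-qPCR delta-Ct values for
  the two stromal markers (*SCARA5*, *DIO2*) and CD56+/stromal cell counts
  from three images.  Subjects carry a latent decidual-pathway class
  (normal / decid_failure / excess_senescence / unk_deficiency) realized in
  *percentile space* and inverted through the generative day-specific
  quantile functions, so the screening rules are recoverable by construction.
* ``generate_timecourse_matrix`` emulates a decidualization time course with
  two diverging stromal fates: negative-binomial counts with dropout, one
  gene module elevated in decidual cells (DC) and one in senescent decidual
  cells (snDC).
* ``generate_barcode_reads`` emulates a droplet experiment's barcode read
  distribution: a population of real cells above an ambient-RNA background,
  for exercising knee-point cell calling.

All generators are deterministic given their config's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .centiles import SUPPORTED_DAYS, UNK_KEY, CentileCurve, CentileCurveSet
from .screening import DefectRuleSet, classify_defect_arrays

__all__ = [
    "CohortSimConfig",
    "ScSimConfig",
    "BarcodeSimConfig",
    "generate_cohort",
    "generate_timecourse_matrix",
    "generate_barcode_reads",
    "generate_profile_patterns",
    "generative_curves",
    "generate_reference_table",
    "generate_unk_reference",
    "expected_state_means",
    "DEFAULT_DAY_EFFECTS",
]

LATENT_CLASSES = ("decid_failure", "excess_senescence", "unk_deficiency")

# Per-day (mean, sd) of delta-Ct for each marker across LH+6..11.  SCARA5
# (decidual marker) is induced across the window (dCt falls); DIO2
# (senescence-associated, progesterone-repressed) rises toward menstruation.
# Scales are typical for qPCR of moderately expressed transcripts vs L19.
DEFAULT_DAY_EFFECTS: dict[str, dict[int, tuple[float, float]]] = {
    "SCARA5": {6: (7.0, 1.2), 7: (6.2, 1.2), 8: (5.4, 1.2),
               9: (4.8, 1.2), 10: (4.4, 1.2), 11: (4.2, 1.2)},
    "DIO2": {6: (9.0, 1.5), 7: (8.6, 1.5), 8: (8.0, 1.5),
             9: (7.2, 1.5), 10: (6.4, 1.5), 11: (5.8, 1.5)},
}

# Defect prevalences emulating the published cohort: aberrant incidence
# ~14% in controls and ~44% in RPL, dominated by excessive senescence and
# uNK deficiency in the RPL arm.
DEFAULT_PREVALENCES = {
    "control": {"decid_failure": 0.05, "excess_senescence": 0.04,
                "unk_deficiency": 0.05},
    "RPL": {"decid_failure": 0.07, "excess_senescence": 0.22,
            "unk_deficiency": 0.15},
}


def _validate_prevalence(p: dict) -> None:
    for group, classes in p.items():
        unknown = set(classes) - set(LATENT_CLASSES)
        if unknown:
            raise ValueError(f"group {group!r}: unknown classes {sorted(unknown)}")
        vals = np.array(list(classes.values()), float)
        if np.any(vals < 0) or np.any(vals > 1) or vals.sum() > 1 + 1e-12:
            raise ValueError(
                f"group {group!r}: prevalences must lie in [0,1] and sum <= 1")


@dataclass
class CohortSimConfig:
    """Configuration of the synthetic RPL/control cohort (defaults = study design)."""

    n_control: int = 90
    n_rpl: int = 89
    prevalence_by_group: dict = field(
        default_factory=lambda: {g: dict(c) for g, c in DEFAULT_PREVALENCES.items()})
    lh_day_range: tuple[int, int] = (6, 11)
    day_effects: dict = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_DAY_EFFECTS.items()})
    unk_reference: tuple[float, float] = (10.0, 2.0)  # (loc, scale) of uNK %
    n_images: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_rpl < 0:
            raise ValueError("cohort sizes must be non-negative")
        lo, hi = self.lh_day_range
        if hi < lo:
            raise ValueError("lh_day_range is empty")
        if not set(range(lo, hi + 1)) <= set(SUPPORTED_DAYS):
            raise ValueError(f"lh_day_range must lie within {SUPPORTED_DAYS}")
        _validate_prevalence(self.prevalence_by_group)
        if self.unk_reference[1] <= 0:
            raise ValueError("uNK reference scale must be positive")

    @property
    def days(self) -> list[int]:
        return list(range(self.lh_day_range[0], self.lh_day_range[1] + 1))


def _gene_quantile(day_effects, gene: str, day: int, u_pct: np.ndarray) -> np.ndarray:
    """Invert an expression percentile to dCt through the day's Normal model.

    Higher expression percentile means lower dCt.  Clipped at 0 (the dCt
    reference-table convention); the defaults keep 0 several sd away.
    """
    mean, sd = day_effects[gene][day]
    return np.clip(mean - sd * stats.norm.ppf(np.asarray(u_pct) / 100.0), 0.0, None)


def _unk_quantile(unk_reference, u_pct: np.ndarray) -> np.ndarray:
    loc, scale = unk_reference
    return np.clip(loc + scale * stats.norm.ppf(np.asarray(u_pct) / 100.0), 0.0, None)


def _draw_class_percentiles(rng: np.random.Generator, cls: str,
                            rules: DefectRuleSet) -> tuple[float, float, float]:
    """Class-conditional (scara5, dio2, unk) percentiles.

    Defect classes draw uniformly from the open interior of their rule
    region; "normal" draws uniformly on [0,100]^3 conditioned (by rejection)
    on matching no rule.
    """
    lo, hi = rules.low_threshold, rules.high_threshold
    if cls == "decid_failure":
        return (rng.uniform(0, lo), rng.uniform(0, lo), rng.uniform(lo, 100))
    if cls == "excess_senescence":
        return (rng.uniform(0, lo), rng.uniform(hi, 100), rng.uniform(lo, 100))
    if cls == "unk_deficiency":
        return (rng.uniform(lo, hi), rng.uniform(lo, hi), rng.uniform(0, lo))
    while True:  # normal: no rule may fire
        s, d, u = rng.uniform(0, 100, size=3)
        if classify_defect_arrays([s], [d], [u], rules)[0] == "none":
            return (s, d, u)


def generate_cohort(config: CohortSimConfig,
                    rules: DefectRuleSet = DefectRuleSet()
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort table plus a ground-truth class sidecar.

    Returns ``(cohort, truth)``: ``cohort`` has one row per subject with
    columns ``subject_id, group, lh_day, dct_scara5, dct_dio2,
    cd56_1, stromal_1, ..., cd56_{n_images}, stromal_{n_images}``;
    ``truth`` maps ``subject_id`` to the latent ``truth_class``.
    """
    rng = np.random.default_rng(config.seed)
    rows, truth_rows = [], []
    sid = 0
    for group, n in (("control", config.n_control), ("RPL", config.n_rpl)):
        prev = config.prevalence_by_group.get(group, {})
        # plant prevalences exactly (largest-remainder apportionment) so a
        # cohort's class composition is the configured one, not a draw from it
        classes = list(prev)
        ideal = np.array([prev[c] * n for c in classes])
        counts = np.floor(ideal).astype(int)
        short = int(round(ideal.sum())) - counts.sum()
        for i in np.argsort(-(ideal - counts))[:short]:
            counts[i] += 1
        labels = np.repeat(classes + ["normal"],
                           list(counts) + [n - counts.sum()])
        rng.shuffle(labels)
        for cls in labels:
            sid += 1
            subject_id = f"S{sid:04d}"
            day = int(rng.integers(config.lh_day_range[0],
                                   config.lh_day_range[1] + 1))
            s_pct, d_pct, u_pct = _draw_class_percentiles(rng, cls, rules)
            dct_s = float(_gene_quantile(config.day_effects, "SCARA5", day, s_pct))
            dct_d = float(_gene_quantile(config.day_effects, "DIO2", day, d_pct))
            target_unk = float(_unk_quantile(config.unk_reference, u_pct))
            row = {"subject_id": subject_id, "group": group, "lh_day": day,
                   "dct_scara5": round(dct_s, 6), "dct_dio2": round(dct_d, 6)}
            # Images: stromal field size varies; CD56 count is the rounded
            # expected count so the averaged percentage tracks the latent one.
            for i in range(1, config.n_images + 1):
                stromal = int(rng.integers(150, 251))
                row[f"cd56_{i}"] = int(round(target_unk * stromal / 100.0))
                row[f"stromal_{i}"] = stromal
            rows.append(row)
            truth_rows.append({"subject_id": subject_id, "truth_class": cls})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generative_curves(config: CohortSimConfig, n_grid: int = 4001) -> CentileCurveSet:
    """The generator's own quantile functions as a CentileCurveSet.

    A dense grid of exact Normal quantiles per (gene, day) — scoring a
    simulated subject against these curves returns its latent percentile up
    to interpolation error, which makes planted classes recoverable exactly.
    """
    u = 100.0 * (np.arange(1, n_grid + 1) - 0.5) / n_grid
    curves: dict[tuple[str, int], CentileCurve] = {}
    for gene in config.day_effects:
        for day in config.days:
            dct = _gene_quantile(config.day_effects, gene, day, u)
            curves[(gene, day)] = CentileCurve(-dct, n_grid)
    for day in config.days:
        curves[(UNK_KEY, day)] = CentileCurve(
            _unk_quantile(config.unk_reference, u), n_grid)
    return CentileCurveSet(curves, {"source": "generative", "n_grid": n_grid})


def generate_reference_table(config: CohortSimConfig, n_total: int = 250,
                             seed: int | None = None) -> pd.DataFrame:
    """Long-format dCt reference table (subject_id, lh_day, gene, dct).

    Subjects are spread evenly across the configured days and drawn from the
    generative day model — the synthetic analogue of a percentile-reference
    biopsy bank.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    days = config.days
    day_of = [days[i % len(days)] for i in range(n_total)]
    rows = []
    for i, day in enumerate(day_of):
        for gene in config.day_effects:
            mean, sd = config.day_effects[gene][day]
            rows.append({"subject_id": f"R{i + 1:04d}", "lh_day": day,
                         "gene": gene,
                         "dct": float(np.clip(rng.normal(mean, sd), 0.0, None))})
    return pd.DataFrame(rows)


def generate_unk_reference(config: CohortSimConfig, n_per_day: int = 80,
                           seed: int | None = None) -> pd.DataFrame:
    """uNK percentage reference table (lh_day, unk_pct) from the generative model."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loc, scale = config.unk_reference
    rows = []
    for day in config.days:
        for v in np.clip(rng.normal(loc, scale, size=n_per_day), 0.0, None):
            rows.append({"lh_day": day, "unk_pct": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-cell time-course matrices
# ---------------------------------------------------------------------------

def _default_module_assignment(genes: list[str]) -> dict[str, str]:
    out = {}
    for i, g in enumerate(genes):
        out[g] = ("dc_module" if i < 30 else
                  "sndc_module" if i < 60 else "background")
    return out


@dataclass
class ScSimConfig:
    """Configuration of the branch-structured count-matrix simulator.

    Default branch proportions (0.78 DC / 0.13 snDC / 0.09 trunk) match the
    day-6 composition of the decidual time course.
    """

    n_cells: int = 1000
    n_genes: int = 200
    genes: list[str] | None = None
    module_assignment: dict[str, str] | None = None
    branch_proportions: tuple[float, float, float] = (0.78, 0.13, 0.09)
    module_fold: float = 8.0          # elevation of a module in its own state
    nb_dispersion: float = 2.0        # NB size parameter; larger = less dispersed
    dropout_rate: float = 0.3
    library_size: float = 2000.0      # mean counts per cell before dropout
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.branch_proportions, float)
        if np.any(props < 0) or np.any(props > 1) or abs(props.sum() - 1) > 1e-9:
            raise ValueError("branch proportions must lie in [0,1] and sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0,1]")
        if self.genes is None:
            self.genes = [f"GENE{i + 1:04d}" for i in range(self.n_genes)]
        elif len(self.genes) != self.n_genes:
            raise ValueError("len(genes) must equal n_genes")
        if self.module_assignment is None:
            self.module_assignment = _default_module_assignment(self.genes)
        else:
            unknown = set(self.module_assignment) - set(self.genes)
            if unknown:
                raise ValueError(
                    f"module_assignment references unknown genes: {sorted(unknown)[:5]}")
            bad = set(self.module_assignment.values()) - {
                "dc_module", "sndc_module", "background"}
            if bad:
                raise ValueError(f"unknown module labels: {sorted(bad)}")


STATES = ("DC", "snDC", "trunk")


def expected_state_means(config: ScSimConfig) -> pd.DataFrame:
    """Per-gene expected counts in each cell state (genes x states).

    Baseline relative weights are log-normal (drawn from the config seed);
    module genes are elevated ``module_fold``-fold in their own state.  Each
    state's weights are normalized so expected library size is constant.
    """
    rng = np.random.default_rng(config.seed)
    base = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)
    modules = np.array([config.module_assignment.get(g, "background")
                        for g in config.genes])
    weights = {}
    for state in STATES:
        w = base.copy()
        if state == "DC":
            w[modules == "dc_module"] *= config.module_fold
        elif state == "snDC":
            w[modules == "sndc_module"] *= config.module_fold
        weights[state] = config.library_size * w / w.sum()
    return pd.DataFrame(weights, index=config.genes)


def generate_timecourse_matrix(config: ScSimConfig
                               ) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x cells count matrix with two planted gene modules.

    Counts are negative binomial around the state-specific means of
    :func:`expected_state_means`, then zeroed independently with probability
    ``dropout_rate``.  Returns ``(counts, states)`` where ``states`` is the
    ground-truth cell-state label per barcode.
    """
    means = expected_state_means(config)
    # continue the seed stream past the base-weight draw used by the means
    rng = np.random.default_rng(config.seed)
    rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)

    n_by_state = np.floor(
        np.asarray(config.branch_proportions) * config.n_cells).astype(int)
    n_by_state[0] += config.n_cells - n_by_state.sum()
    states = np.repeat(STATES, n_by_state)

    barcodes = [f"CELL{i + 1:05d}" for i in range(config.n_cells)]
    counts = np.empty((config.n_genes, config.n_cells), dtype=np.int64)
    size = config.nb_dispersion
    for j, state in enumerate(states):
        mu = means[state].to_numpy()
        p = size / (size + mu)
        counts[:, j] = rng.negative_binomial(size, p)
    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts = counts * keep
    df = pd.DataFrame(counts, index=pd.Index(config.genes, name="GENE"),
                      columns=barcodes)
    return df, pd.Series(states, index=barcodes, name="state")


def generate_profile_patterns(n_patterns: int = 7, n_conditions: int = 9,
                              genes_per_pattern: int = 10,
                              noise_sd: float = 0.15,
                              amplitude_range: tuple[float, float] = (0.5, 2.0),
                              offset_range: tuple[float, float] = (-1.0, 1.0),
                              seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene profiles built from planted co-regulation patterns.

    Patterns are mutually uncorrelated by construction (orthogonalized
    centered random profiles) — "distinct" in exactly the sense the Pearson
    clustering metric sees.  Each gene is a positive-affine rescaling of its
    pattern plus Gaussian noise, so correlation-based clustering should
    recover the pattern labels.

    Returns ``(profiles, truth)``: genes x conditions DataFrame and the
    planted pattern index per gene.
    """
    if n_patterns > n_conditions - 1:
        raise ValueError(
            "n_patterns must be <= n_conditions - 1 for uncorrelated patterns")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_patterns, n_conditions))
    raw -= raw.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(raw.T)
    patterns = q.T[:n_patterns]
    prof = np.repeat(patterns, genes_per_pattern, axis=0)
    amp = rng.uniform(*amplitude_range, size=(prof.shape[0], 1))
    off = rng.uniform(*offset_range, size=(prof.shape[0], 1))
    prof = amp * prof + off + rng.normal(
        0.0, noise_sd * np.sqrt(1.0 / n_conditions), size=prof.shape)
    truth = np.repeat(np.arange(n_patterns), genes_per_pattern)
    profiles = pd.DataFrame(
        prof, index=[f"g{i + 1:03d}" for i in range(prof.shape[0])],
        columns=[f"C{j}" for j in range(n_conditions)])
    return profiles, truth


# ---------------------------------------------------------------------------
# barcode read distributions
# ---------------------------------------------------------------------------

@dataclass
class BarcodeSimConfig:
    """Configuration of the barcode-rank simulator (real cells + ambient RNA)."""

    n_real: int = 100
    n_ambient: int = 900
    real_read_mean: float = 1000.0
    ambient_read_mean: float = 10.0
    real_read_sigma: float = 0.25     # log-scale spread of real barcodes
    ambient_read_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_real < 0 or self.n_ambient < 0:
            raise ValueError("barcode counts must be non-negative")
        if not self.real_read_mean > self.ambient_read_mean > 0:
            raise ValueError(
                "read means must satisfy real_read_mean > ambient_read_mean > 0")


def generate_barcode_reads(config: BarcodeSimConfig
                           ) -> tuple[pd.Series, set[str]]:
    """Simulate per-barcode read counts.

    Real barcodes are log-normal around ``real_read_mean`` and ambient
    barcodes log-normal around ``ambient_read_mean`` (means on the natural
    scale).  Returns ``(reads, real_barcodes)`` with reads indexed by
    barcode id; the ground-truth real set is returned separately.
    """
    rng = np.random.default_rng(config.seed)

    def _draw(n, mean, sigma):
        mu = np.log(mean) - sigma ** 2 / 2.0
        return np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(int)

    real = _draw(config.n_real, config.real_read_mean, config.real_read_sigma)
    amb = _draw(config.n_ambient, config.ambient_read_mean,
                config.ambient_read_sigma)
    ids = [f"BC{i + 1:05d}" for i in range(config.n_real + config.n_ambient)]
    reads = pd.Series(np.concatenate([real, amb]), index=ids, name="reads")
    return reads, set(ids[:config.n_real])
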