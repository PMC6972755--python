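"""Classification of decidual-pathway defects and cohort-level statistics.

A subject is summarized by three day-normalized percentiles: *SCARA5*
(decidual-cell marker), *DIO2* (senescent-decidual-cell marker) and uNK-cell
abundance.  Rule-based thresholds at the 30th and 70th percentiles define
three mutually exclusive defects:

* ``decid_failure``      — SCARA5 <=30th and DIO2 <=30th percentile
* ``excess_senescence``  — SCARA5 <=30th and DIO2 >=70th percentile
* ``unk_deficiency``     — uNK <=30th with both markers strictly between the
  30th and 70th percentiles

Everything else is ``none``; "aberrant" means any defect.  Cohorts are also
binned on the sum of the SCARA5 and uNK percentiles (DIO2 participates in
classification but not in the bin sum), and group differences are tested
with Fisher's exact test (2x2) or the chi-square test (larger tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "DefectRuleSet",
    "BinningScheme",
    "DefectClassifier",
    "classify_defect",
    "classify_defect_arrays",
    "bin_percentile_sum",
    "cohort_contingency",
    "screen_cohort",
    "DEFECT_LABELS",
]

DEFECT_LABELS = ("decid_failure", "excess_senescence", "unk_deficiency")
NO_DEFECT = "none"


@dataclass(frozen=True)
class DefectRuleSet:
    """Percentile thresholds of the defect rules (defaults 30th / 70th)."""

    low_threshold: float = 30.0
    high_threshold: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold < 100):
            raise ValueError(
                "thresholds must satisfy 0 < low < high < 100, got "
                f"low={self.low_threshold}, high={self.high_threshold}")


@dataclass(frozen=True)
class BinningScheme:
    """Bins on the SCARA5 + uNK percentile sum scale [0, 200].

    Bins are half-open ``[lo, hi)`` except the top bin, which is closed at
    200.  Default: four equal-width bins with edges 50/100/150.
    """

    edges: tuple = (50.0, 100.0, 150.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        if e.size < 1 or np.any(np.diff(e) <= 0) or e[0] <= 0 or e[-1] >= 200:
            raise ValueError(
                f"edges must be strictly increasing within (0, 200): {self.edges}")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1


def _check_percentiles(*arrays) -> None:
    for a in arrays:
        a = np.asarray(a, float)
        if np.any(~np.isfinite(a)) or np.any(a < 0) or np.any(a > 100):
            raise ValueError("percentiles must lie in [0, 100]")


def classify_defect_arrays(scara5_pct, dio2_pct, unk_pct,
                           rules: DefectRuleSet = DefectRuleSet()) -> np.ndarray:
    """Vectorized defect classification; returns an array of labels."""
    s = np.asarray(scara5_pct, float)
    d = np.asarray(dio2_pct, float)
    u = np.asarray(unk_pct, float)
    _check_percentiles(s, d, u)
    lo, hi = rules.low_threshold, rules.high_threshold

    labels = np.full(np.broadcast(s, d, u).shape, NO_DEFECT, dtype=object)
    failure = (s <= lo) & (d <= lo)
    senescence = (s <= lo) & (d >= hi)
    # marker conditions strictly interior, per the printed rule ">30th-<70th"
    unk_def = (u <= lo) & (s > lo) & (s < hi) & (d > lo) & (d < hi)
    labels[failure] = "decid_failure"
    labels[senescence] = "excess_senescence"
    labels[unk_def] = "unk_deficiency"
    return labels


def classify_defect(subject, rules: DefectRuleSet = DefectRuleSet()) -> dict:
    """Classify one subject (mapping/Series with ``*_pct`` fields).

    Returns ``{"label": ..., "aberrant": bool}``.
    """
    label = classify_defect_arrays(
        [subject["scara5_pct"]], [subject["dio2_pct"]], [subject["unk_pct"]],
        rules)[0]
    return {"label": label, "aberrant": label != NO_DEFECT}


def bin_percentile_sum(subject, scheme: BinningScheme = BinningScheme()) -> int:
    """Bin index (1-based) of a subject's SCARA5 + uNK percentile sum."""
    s, u = float(subject["scara5_pct"]), float(subject["unk_pct"])
    _check_percentiles([s], [u])
    return int(np.searchsorted(scheme.edges, s + u, side="right")) + 1


class DefectClassifier(BaseEstimator):
    """scikit-learn style wrapper around the defect rules.

    ``predict`` maps a DataFrame with columns ``scara5_pct``, ``dio2_pct``,
    ``unk_pct`` to defect labels.  There is nothing to fit; ``fit`` only
    validates thresholds and records them as ``rules_``.
    """

    def __init__(self, low_threshold: float = 30.0, high_threshold: float = 70.0):
        self.low_threshold = low_threshold
        self.high_threshold = high_threshold

    def fit(self, X=None, y=None) -> "DefectClassifier":
        self.rules_ = DefectRuleSet(self.low_threshold, self.high_threshold)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "rules_"):
            self.fit()
        return classify_defect_arrays(
            X["scara5_pct"], X["dio2_pct"], X["unk_pct"], self.rules_)


def cohort_contingency(categories, groups) -> dict:
    """Category x group contingency table with the appropriate test.

    2x2 tables get a two-sided Fisher exact test (hypergeometric tail
    summation, scipy convention: all tables with probability <= the observed
    table's) plus the sample odds ratio; larger tables get a chi-square test
    without continuity correction (Yates correction only exists for 2x2).

    Returns a dict with ``table`` (DataFrame), ``test``, ``p_value`` and,
    for 2x2, ``odds_ratio``.
    """
    cats = pd.Series(list(categories), name="category")
    grps = pd.Series(list(groups), name="group")
    if len(cats) != len(grps):
        raise ValueError("categories and groups differ in length")
    table = pd.crosstab(cats, grps)
    if table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
        raise ValueError("both groups must be present and non-empty")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 categories")

    counts = table.to_numpy()
    if counts.shape == (2, 2):
        odds, p = stats.fisher_exact(counts, alternative="two-sided")
        return {"table": table, "test": "fisher_exact_two_sided",
                "p_value": float(p), "odds_ratio": float(odds)}
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return {"table": table, "test": "chi2", "p_value": float(p),
            "statistic": float(chi2), "dof": int(dof)}


def _two_by_two(a, b, c, d) -> np.ndarray:
    return np.array([[a, b], [c, d]], dtype=int)


def screen_cohort(samples: pd.DataFrame,
                  rules: DefectRuleSet = DefectRuleSet(),
                  scheme: BinningScheme = BinningScheme()) -> tuple[pd.DataFrame, dict]:
    """Classify every subject and summarize the cohort.

    ``samples`` columns: ``subject_id``, ``group`` (control / RPL),
    ``scara5_pct``, ``dio2_pct``, ``unk_pct``.

    Returns ``(per_subject, summary)`` where ``per_subject`` adds ``defect``,
    ``aberrant`` and ``bin`` columns, and ``summary`` holds per-group defect
    frequencies, aberrant incidence, per-bin group composition and the
    contingency tests (Fisher exact for aberrant-vs-group and for the
    extreme-bins 2x2; chi-square for each defect and the full bin table).
    """
    if samples.empty:
        raise ValueError("empty cohort")
    if samples["subject_id"].duplicated().any():
        dup = samples.loc[samples["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject id(s): {sorted(set(dup))}")

    per = samples.copy()
    per["defect"] = classify_defect_arrays(
        per["scara5_pct"], per["dio2_pct"], per["unk_pct"], rules)
    per["aberrant"] = per["defect"] != NO_DEFECT
    per["bin"] = [bin_percentile_sum(row, scheme)
                  for _, row in per.iterrows()]

    groups = sorted(per["group"].unique())
    n_by_group = per.groupby("group").size()

    defect_counts = pd.crosstab(per["defect"], per["group"]).reindex(
        list(DEFECT_LABELS) + [NO_DEFECT], fill_value=0)[groups]
    defect_freq = defect_counts / n_by_group

    aberrant_by_group = per.groupby("group")["aberrant"].agg(["sum", "size"])
    incidence = {g: float(r["sum"] / r["size"])
                 for g, r in aberrant_by_group.iterrows()}

    bin_counts = pd.crosstab(per["bin"], per["group"]).reindex(
        range(1, scheme.n_bins + 1), fill_value=0)[groups]
    bin_pct = 100.0 * bin_counts.div(bin_counts.sum(axis=1), axis=0).fillna(0.0)

    summary: dict = {
        "n_by_group": n_by_group.to_dict(),
        "defect_counts": defect_counts,
        "defect_frequencies": defect_freq,
        "aberrant_incidence": incidence,
        "bin_counts": bin_counts,
        "bin_group_percent": bin_pct,
    }

    if len(groups) == 2:
        g0, g1 = groups
        ab = per["aberrant"]
        if 0 < ab.sum() < len(ab):
            summary["aberrant_test"] = cohort_contingency(
                np.where(ab, "aberrant", "not_aberrant"), per["group"])
        per_defect = {}
        for lab in DEFECT_LABELS:
            if not per["defect"].eq(lab).any():
                continue
            tab = _two_by_two(
                (per["defect"].eq(lab) & per["group"].eq(g0)).sum(),
                (per["defect"].eq(lab) & per["group"].eq(g1)).sum(),
                (~per["defect"].eq(lab) & per["group"].eq(g0)).sum(),
                (~per["defect"].eq(lab) & per["group"].eq(g1)).sum())
            chi2, p, dof, _ = stats.chi2_contingency(tab, correction=True)
            per_defect[lab] = {"table": tab, "test": "chi2_yates",
                               "p_value": float(p), "statistic": float(chi2)}
        summary["per_defect_tests"] = per_defect

        if (bin_counts.to_numpy().sum(axis=1)[[0, -1]] > 0).all():
            lo_bin = bin_counts.iloc[0]
            hi_bin = bin_counts.iloc[-1]
            tab = _two_by_two(lo_bin[g0], lo_bin[g1], hi_bin[g0], hi_bin[g1])
            odds, p = stats.fisher_exact(tab, alternative="two-sided")
            summary["extreme_bins_test"] = {
                "table": tab, "test": "fisher_exact_two_sided",
                "p_value": float(p), "odds_ratio": float(odds)}
        if (bin_counts.to_numpy().sum(axis=1) > 0).all():
            chi2, p, dof, _ = stats.chi2_contingency(
                bin_counts.to_numpy(), correction=False)
            summary["bin_test"] = {"test": "chi2", "p_value": float(p),
                                   "statistic": float(chi2), "dof": int(dof)}
    return per, summary
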