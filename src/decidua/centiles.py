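"""Day-normalized percentile reference curves for decidual markers and uNK cells.

Endometrial biopsies are timed relative to the pre-ovulatory LH surge
(LH+6..LH+11).  Because marker transcript levels (RT-qPCR delta-Ct) and
uNK-cell abundance both change across the luteal phase, a raw value is only
interpretable relative to other biopsies taken on the *same* cycle day.  This
module builds, per (gene, day), an empirical quantile curve from a reference
cohort and maps new measurements onto a 0-100 percentile scale.

Conventions
-----------
* delta-Ct is ``Ct(target) - Ct(reference gene)``: *lower* dCt means *higher*
  expression.  Percentiles are percentiles of expression, so dCt is negated
  into a "score" before ranking.
* Percentiles use Hazen plotting positions ``(i - 0.5) / n`` with midrank
  handling of ties and linear interpolation; queries outside the reference
  range clamp to 0 / 100.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CentileCurve",
    "CentileCurveSet",
    "CentileReference",
    "build_curves",
    "build_unk_curves",
    "percentile_of",
    "unk_percentage",
    "unk_percentile",
]

SUPPORTED_DAYS = tuple(range(6, 12))
UNK_KEY = "uNK"


def _midrank_positions(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct sorted scores and their midrank Hazen plotting positions (percent).

    Tied observations share the mean of their individual positions, so the
    empirical CDF is single-valued at every distinct score.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    n = s.size
    pos = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    distinct, start = np.unique(s, return_index=True)
    # mean position within each tie group
    bounds = np.append(start, n)
    mid = np.array([pos[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    return distinct, mid


@dataclass
class CentileCurve:
    """Empirical quantile curve for one (gene, day) cell of the reference."""

    scores: np.ndarray          # sorted raw scores (higher = more expression)
    n: int                      # number of reference observations
    pooled_days: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        self._xp, self._fp = _midrank_positions(self.scores)

    def percentile(self, score: float) -> float:
        """Percentile in [0, 100] of ``score``; clamps outside the range."""
        if score < self._xp[0]:
            return 0.0
        if score > self._xp[-1]:
            return 100.0
        return float(np.interp(score, self._xp, self._fp))


class CentileCurveSet:
    """Per-(gene, day) quantile curves with build metadata.

    Keys are gene identifiers (the uNK reference uses the reserved key
    ``"uNK"``); days are integers within the supported LH+6..11 window.
    """

    interpolation = "hazen-midrank-linear"

    def __init__(self, curves: dict[tuple[str, int], CentileCurve],
                 metadata: dict | None = None):
        self.curves = curves
        self.metadata = dict(metadata or {})
        self.metadata.setdefault("interpolation", self.interpolation)
        self.metadata.setdefault(
            "build_date", datetime.date.today().isoformat())

    def _curve(self, gene: str, lh_day: int) -> CentileCurve:
        try:
            return self.curves[(gene, int(lh_day))]
        except KeyError:
            raise KeyError(
                f"no reference curve for gene {gene!r} on LH+{lh_day}; "
                f"available: {sorted(set(g for g, _ in self.curves))} "
                f"days {sorted(set(d for _, d in self.curves))}") from None

    def percentile_of_score(self, gene: str, lh_day: int, score: float) -> float:
        return self._curve(gene, lh_day).percentile(score)

    def percentile_of(self, gene: str, lh_day: int, dct: float) -> float:
        """Expression percentile of a dCt value (lower dCt = higher percentile)."""
        return self.percentile_of_score(gene, lh_day, -float(dct))

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {"metadata": self.metadata, "curves": {}}
        for (gene, day), c in self.curves.items():
            payload["curves"].setdefault(gene, {})[str(day)] = {
                "scores": c.scores.tolist(),
                "n": c.n,
                "pooled_days": c.pooled_days,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CentileCurveSet":
        with open(path) as fh:
            payload = json.load(fh)
        curves = {}
        for gene, by_day in payload["curves"].items():
            for day, d in by_day.items():
                curves[(gene, int(day))] = CentileCurve(
                    np.asarray(d["scores"]), d["n"], list(d["pooled_days"]))
        return cls(curves, payload["metadata"])


def _pool_days(by_day: dict[int, np.ndarray], day: int,
               min_per_day: int) -> tuple[np.ndarray, list[int]]:
    """Pool ``day`` with nearest neighbouring days until ``min_per_day`` reached.

    Distance ties are broken toward the earlier day.  Raises if the whole
    reference cannot reach the minimum.
    """
    pooled = [day]
    scores = [by_day.get(day, np.empty(0))]
    candidates = sorted(
        (d for d in by_day if d != day),
        key=lambda d: (abs(d - day), d))
    total = scores[0].size
    for d in candidates:
        if total >= min_per_day:
            break
        pooled.append(d)
        scores.append(by_day[d])
        total += by_day[d].size
    if total < min_per_day:
        raise ValueError(
            f"day LH+{day}: only {total} reference observations available "
            f"even after pooling all days; min_per_day={min_per_day}")
    return np.concatenate(scores), sorted(pooled)


class CentileReference(BaseEstimator):
    """Builds day-specific expression percentile curves from a dCt reference table.

    Parameters
    ----------
    min_per_day : int, default 20
        Minimum reference observations per (gene, day); sparser days are
        pooled with their nearest neighbouring day (ties toward the earlier
        day) and the pooling recorded in the curve metadata.
    days : tuple of int
        Supported LH+ days.

    Attributes
    ----------
    curves_ : CentileCurveSet
        Fitted per-(gene, day) quantile curves.
    genes_ : list of str
    """

    def __init__(self, min_per_day: int = 20, days: tuple = SUPPORTED_DAYS):
        self.min_per_day = min_per_day
        self.days = days

    def fit(self, ref: pd.DataFrame, y=None) -> "CentileReference":
        """Fit from a long-format reference table.

        ``ref`` columns: ``subject_id``, ``lh_day``, ``gene``, ``dct``.
        Each (subject, gene) may appear once; dCt must be non-negative.
        """
        required = {"subject_id", "lh_day", "gene", "dct"}
        missing = required - set(ref.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        dup = ref.duplicated(subset=["subject_id", "gene"])
        if dup.any():
            bad = ref.loc[dup, ["subject_id", "gene"]].iloc[0]
            raise ValueError(
                f"duplicated (subject, gene) row: {tuple(bad)}")
        if (ref["dct"] < 0).any():
            raise ValueError("negative dCt in reference table")
        if not ref["lh_day"].isin(self.days).all():
            bad_days = sorted(set(ref["lh_day"]) - set(self.days))
            raise ValueError(f"lh_day outside supported range: {bad_days}")

        curves: dict[tuple[str, int], CentileCurve] = {}
        pooling: dict[str, dict[str, list[int]]] = {}
        for gene, sub in ref.groupby("gene"):
            by_day = {int(d): -g["dct"].to_numpy(float)
                      for d, g in sub.groupby("lh_day")}
            for day in self.days:
                scores, pooled = _pool_days(by_day, day, self.min_per_day)
                curves[(str(gene), day)] = CentileCurve(
                    scores, scores.size,
                    pooled_days=[d for d in pooled if d != day])
                if len(pooled) > 1:
                    pooling.setdefault(str(gene), {})[str(day)] = pooled
        self.curves_ = CentileCurveSet(
            curves, {"min_per_day": self.min_per_day, "pooling": pooling,
                     "source": "empirical-dct"})
        self.genes_ = sorted({g for g, _ in curves})
        return self

    def transform(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Map a long-format sample table (same columns as fit) to percentiles."""
        out = samples.copy()
        out["percentile"] = [
            self.curves_.percentile_of(str(g), int(d), float(v))
            for g, d, v in zip(samples["gene"], samples["lh_day"], samples["dct"])
        ]
        return out


def build_curves(ref: pd.DataFrame, min_per_day: int = 20) -> CentileCurveSet:
    """Build expression percentile curves from a long-format dCt reference table."""
    return CentileReference(min_per_day=min_per_day).fit(ref).curves_


def build_unk_curves(ref: pd.DataFrame, min_per_day: int = 20) -> CentileCurveSet:
    """Build uNK percentile curves from a table with ``lh_day`` and ``unk_pct``.

    Higher uNK percentage maps to a higher percentile (no negation).
    """
    curves: dict[tuple[str, int], CentileCurve] = {}
    by_day = {int(d): g["unk_pct"].to_numpy(float)
              for d, g in ref.groupby("lh_day")}
    pooling: dict[str, list[int]] = {}
    for day in SUPPORTED_DAYS:
        scores, pooled = _pool_days(by_day, day, min_per_day)
        curves[(UNK_KEY, day)] = CentileCurve(
            scores, scores.size, pooled_days=[d for d in pooled if d != day])
        if len(pooled) > 1:
            pooling[str(day)] = pooled
    return CentileCurveSet(
        curves, {"min_per_day": min_per_day, "pooling": {UNK_KEY: pooling},
                 "source": "empirical-unk"})


def percentile_of(curves: CentileCurveSet, gene: str, lh_day: int,
                  dct: float) -> float:
    """Expression percentile of one dCt measurement on one cycle day."""
    return curves.percentile_of(gene, lh_day, dct)


def unk_percentage(image_pairs) -> float:
    """uNK abundance: CD56+ cells per 100 stromal cells, averaged over images.

    ``image_pairs`` is an iterable of ``(cd56_count, stromal_count)``.
    """
    pairs = list(image_pairs)
    if not pairs:
        raise ValueError("no images supplied")
    vals = []
    for i, (cd56, stromal) in enumerate(pairs, 1):
        if stromal < 1:
            raise ValueError(f"image {i}: stromal count must be >= 1")
        if cd56 < 0:
            raise ValueError(f"image {i}: negative CD56 count")
        vals.append(100.0 * cd56 / stromal)
    return float(np.mean(vals))


def unk_percentile(curves: CentileCurveSet, lh_day: int, unk_pct: float) -> float:
    """Day-normalized percentile of a uNK percentage (higher uNK = higher)."""
    return curves.percentile_of_score(UNK_KEY, lh_day, float(unk_pct))


def score_cohort(cohort: pd.DataFrame, curves: CentileCurveSet,
                 n_images: int = 3) -> pd.DataFrame:
    """Map a cohort table to day-normalized subject percentiles.

    ``cohort`` is the wide per-subject table (``subject_id``, ``group``,
    ``lh_day``, ``dct_scara5``, ``dct_dio2`` and ``cd56_i``/``stromal_i``
    image pairs); ``curves`` must hold SCARA5, DIO2 and uNK reference
    curves.  Returns the screening input table with ``scara5_pct``,
    ``dio2_pct`` and ``unk_pct`` columns.
    """
    rows = []
    for _, r in cohort.iterrows():
        unk = unk_percentage([(r[f"cd56_{i}"], r[f"stromal_{i}"])
                              for i in range(1, n_images + 1)])
        rows.append({
            "subject_id": r["subject_id"], "group": r["group"],
            "scara5_pct": curves.percentile_of("SCARA5", int(r["lh_day"]),
                                               float(r["dct_scara5"])),
            "dio2_pct": curves.percentile_of("DIO2", int(r["lh_day"]),
                                             float(r["dct_dio2"])),
            "unk_pct": unk_percentile(curves, int(r["lh_day"]), unk),
        })
    return pd.DataFrame(rows)
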