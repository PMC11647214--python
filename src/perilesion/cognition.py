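"""Normative Z-scoring, domain composites and VCD classification.

Raw neuropsychological test scores are converted to Z-scores against
normative (age band, sex, education level) cells; education uses the Dutch
seven-category system.  Tests where a *lower* raw score is better are
sign-flipped so that negative Z always means worse performance.  Domain
composites are unweighted means of the available test Z-scores in a
domain.  Vascular cognitive disorder (VCD) status follows the VASCOG-style
composite rule with the specificity-adjusted cut-off: mild VCD is a
composite between -1.5 and -2.0 in one or more domains, major VCD a
composite below -2.0 (major takes precedence).  A composite of exactly
-1.5 or exactly -2.0 counts as mild; major requires strictly < -2.0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DOMAINS", "NormTable", "raw_to_z", "domain_composite", "classify_vcd",
    "normal_band_fraction", "score_cohort",
]

#: the seven cognitive domains assessed
DOMAINS = (
    "episodic_memory",
    "processing_speed",
    "visuoconstruction",
    "executive_functioning",
    "visual_neglect",
    "language",
    "attention_working_memory",
)

MILD_LOWER = -2.0
MILD_UPPER = -1.5

EDUCATION_LEVELS = tuple(range(1, 8))   # Dutch 7-category system


class NormTable:
    """Normative (mean, SD) per test and demographic cell.

    Backed by a table with columns ``test, age_min, age_max, sex,
    education, mean, sd, higher_is_better``; ``sex`` and ``education`` may
    be ``*`` to match anything (norms are stratified by age, sex and/or
    education depending on the test).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"test", "age_min", "age_max", "sex", "education",
                    "mean", "sd", "higher_is_better"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"norm table missing columns: {sorted(missing)}")
        if (table["sd"] <= 0).any():
            raise ValueError("every norm cell must have SD > 0")
        edu = table.loc[table["education"].astype(str) != "*", "education"]
        if len(edu) and not edu.astype(int).isin(EDUCATION_LEVELS).all():
            raise ValueError("education levels must be in 1..7")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "NormTable":
        return cls(pd.read_csv(path, sep="\t"))

    def lookup(self, test: str, age: float, sex: str, education: int):
        """Return (mean, sd, higher_is_better) for one demographic cell."""
        t = self.table
        rows = t[(t["test"] == test)
                 & (t["age_min"] <= age) & (age <= t["age_max"])
                 & (t["sex"].astype(str).isin(["*", str(sex)]))
                 & (t["education"].astype(str).isin(["*", str(education)]))]
        if rows.empty:
            raise KeyError(
                f"no norm cell for test={test!r}, age={age}, sex={sex!r}, "
                f"education={education}")
        r = rows.iloc[0]
        return float(r["mean"]), float(r["sd"]), bool(r["higher_is_better"])


def raw_to_z(raw: float, mean: float, sd: float,
             higher_is_better: bool = True) -> float:
    """Normative Z-score of a raw test score; sign-flipped for inverted tests."""
    if sd <= 0:
        raise ValueError("norm SD must be positive")
    z = (raw - mean) / sd
    return float(z if higher_is_better else -z)


def domain_composite(test_zs) -> float:
    """Unweighted mean of the available (non-missing) test Z-scores."""
    vals = np.asarray([z for z in test_zs if z is not None and np.isfinite(z)],
                      dtype=float)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def classify_vcd(domain_composites) -> str:
    """VCD status from domain composites: ``none`` | ``mild`` | ``major``.

    major if any composite < -2.0; else mild if any composite lies in
    [-2.0, -1.5]; else none.  All-missing input is unclassifiable.
    """
    if isinstance(domain_composites, dict):
        vals = list(domain_composites.values())
    else:
        vals = list(domain_composites)
    vals = np.asarray([v for v in vals if v is not None], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("unclassifiable: every domain composite is missing")
    if np.any(vals < MILD_LOWER):
        return "major"
    if np.any((MILD_LOWER <= vals) & (vals <= MILD_UPPER)):
        return "mild"
    return "none"


def normal_band_fraction(lower: float, upper: float) -> float:
    """Percent of a standard normal population with Z in (lower, upper).

    The band (-2, -1) covers 13.6% of the normal population — the fraction
    implied by the conventional mild-VCD cut-off — and (-2, -1.5) covers
    4.4%, the fraction under the specificity-adjusted cut-off used here.
    """
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    return float(100.0 * (norm.cdf(upper) - norm.cdf(lower)))


def score_cohort(raw_scores: pd.DataFrame, norms: NormTable,
                 domain_map: dict) -> pd.DataFrame:
    """Score a cohort: raw tests -> test Zs -> domain composites -> status.

    ``raw_scores`` needs columns ``subject, age, sex, education`` plus one
    column per test; ``domain_map`` maps each domain name to the list of
    its tests (the test-to-domain assignment is configurable, not fixed).
    Returns one row per subject with the domain composites and
    ``vcd_status``.
    """
    unknown = set(domain_map) - set(DOMAINS)
    if unknown:
        raise KeyError(f"unknown cognitive domain(s): {sorted(unknown)}")
    rows = []
    for _, subj in raw_scores.iterrows():
        rec = {"subject": subj["subject"]}
        composites = {}
        for domain, tests in domain_map.items():
            zs = []
            for test in tests:
                raw = subj.get(test)
                if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                    continue
                mean, sd, hib = norms.lookup(test, subj["age"], subj["sex"],
                                             int(subj["education"]))
                zs.append(raw_to_z(raw, mean, sd, hib))
            composites[domain] = domain_composite(zs)
            rec[domain] = composites[domain]
        rec["vcd_status"] = classify_vcd(composites)
        rows.append(rec)
    return pd.DataFrame(rows)
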