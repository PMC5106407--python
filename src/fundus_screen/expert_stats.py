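"""Analytics over expert retinopathy gradings.

Three ophthalmologists graded the 600-image Hospital Melaka fundus set on a
10-stage scale (disease-free through advanced diabetic eye disease, with
each severity split by maculopathy status).  This module codes the scale,
re-categorises it into coarser schemes, and reproduces the descriptive and
inferential statistics commonly reported for such a ground truth: pooled
mean/SD of the coded labels, boxplot five-number summaries per expert, the
expert-by-stage crosstab with a Pearson chi-square independence test, and
one-way ANOVA across experts with Bonferroni-adjusted pairwise comparisons.

Stages are coded 1-10 in scale order; SDs are sample SDs (n-1); quartiles
follow the Tukey median-of-halves (hinge) rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import warn

STAGE_NAMES: tuple[str, ...] = (
    "No DR",
    "Mild DR without maculopathy",
    "Mild DR with maculopathy",
    "Moderate DR without maculopathy",
    "Moderate DR with maculopathy",
    "Severe DR without maculopathy",
    "Severe DR with maculopathy",
    "PDR without maculopathy",
    "PDR with maculopathy",
    "ADED",
)

STAGE_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(STAGE_NAMES)}

#: Consensus stage counts for the 600-image Hospital Melaka reference set.
CONSENSUS_COUNTS: dict[str, int] = {
    "No DR": 276,
    "Mild DR without maculopathy": 72,
    "Mild DR with maculopathy": 27,
    "Moderate DR without maculopathy": 85,
    "Moderate DR with maculopathy": 83,
    "Severe DR without maculopathy": 23,
    "Severe DR with maculopathy": 11,
    "PDR without maculopathy": 6,
    "PDR with maculopathy": 10,
    "ADED": 7,
}

#: Per-expert stage counts (600 images each) for the same reference set.
EXPERT_COUNTS: dict[str, dict[str, int]] = {
    "expert1": dict(zip(STAGE_NAMES, (326, 55, 21, 79, 90, 5, 3, 6, 8, 7))),
    "expert2": dict(zip(STAGE_NAMES, (267, 58, 12, 90, 127, 6, 6, 9, 20, 5))),
    "expert3": dict(zip(STAGE_NAMES, (314, 14, 31, 43, 143, 0, 19, 2, 25, 9))),
}

CATEGORISATION_SCHEMES = ("I", "II", "III")


@dataclass(frozen=True)
class GradingTable:
    """Long-format grading records: one row per (image, expert) pair."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"image_id", "expert_id", "stage"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"grading table needs columns {sorted(required)}")
        bad = set(self.df["stage"]) - set(STAGE_NAMES)
        if bad:
            raise ValueError(f"unknown stage names: {sorted(bad)}")
        if self.df.duplicated(["image_id", "expert_id"]).any():
            raise ValueError("each (image, expert) pair may carry only one grade")

    @property
    def experts(self) -> list[str]:
        return sorted(self.df["expert_id"].unique())

    def codes(self, expert: str | None = None) -> np.ndarray:
        """Coded labels (1-10), optionally restricted to one expert."""
        df = self.df if expert is None else self.df[self.df["expert_id"] == expert]
        if expert is not None and df.empty:
            raise KeyError(f"unknown expert {expert!r}")
        return df["stage"].map(STAGE_CODES).to_numpy()

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, int]]) -> "GradingTable":
        """Expand per-expert stage counts into synthetic per-image records."""
        rows = []
        for expert, stage_counts in counts.items():
            i = 0
            for stage in STAGE_NAMES:
                for _ in range(int(stage_counts.get(stage, 0))):
                    rows.append((f"{expert}_img{i:04d}", expert, stage))
                    i += 1
        return cls(pd.DataFrame(rows, columns=["image_id", "expert_id", "stage"]))

    @classmethod
    def from_csv(cls, path) -> "GradingTable":
        return cls(pd.read_csv(path, dtype={"image_id": str, "expert_id": str, "stage": str}))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def reference_table() -> GradingTable:
    """The 1800-record (3 experts x 600 images) reference grading table."""
    return GradingTable.from_counts(EXPERT_COUNTS)


def consensus_table() -> GradingTable:
    """The 600-image consensus grading table (single pseudo-expert)."""
    return GradingTable.from_counts({"consensus": CONSENSUS_COUNTS})


def pooled_label_stats(t: GradingTable) -> tuple[float, float]:
    """Mean and sample SD of the coded labels pooled over all experts."""
    codes = t.codes()
    if codes.size == 0:
        raise ValueError("grading table is empty")
    sd = float(codes.std(ddof=1)) if codes.size >= 2 else 0.0
    return float(codes.mean()), sd


def categorise(stage: str, scheme: str = "I") -> str:
    """Map a 10-stage grade into one of the coarser categorisation schemes.

    Scheme I: disease-free vs any retinopathy.  Scheme II: disease-free /
    non-proliferative / proliferative / advanced disease.  Scheme III: the
    identity (all ten stages).
    """
    if stage not in STAGE_NAMES:
        raise ValueError(f"unknown retinopathy stage {stage!r}")
    if scheme == "I":
        return "No DR" if stage == "No DR" else "DR"
    if scheme == "II":
        if stage == "No DR":
            return "No DR"
        if stage == "ADED":
            return "ADED"
        if stage.startswith("PDR"):
            return "Proliferative DR"
        return "Non-proliferative DR"
    if scheme == "III":
        return stage
    raise ValueError(f"unknown categorisation scheme {scheme!r}")


def categorise_counts(counts: Mapping[str, int], scheme: str = "I") -> dict[str, int]:
    """Aggregate stage counts under a categorisation scheme (order-preserving)."""
    out: dict[str, int] = {}
    for stage in STAGE_NAMES:
        if stage not in counts:
            continue
        cat = categorise(stage, scheme)
        out[cat] = out.get(cat, 0) + int(counts[stage])
    return out


def _tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """(q1, median, q3) by the median-of-halves rule; the median belongs to
    both halves when n is odd."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    med = float(np.median(x))
    half = (n + 1) // 2
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return q1, med, q3


def five_number_summary(t: GradingTable, expert: str) -> tuple[float, float, float, float, float]:
    """Boxplot statistics (min, q1, median, q3, max) of one expert's coded labels."""
    codes = t.codes(expert)
    q1, med, q3 = _tukey_hinges(codes)
    return float(codes.min()), q1, med, q3, float(codes.max())


@dataclass(frozen=True)
class CrosstabResult:
    counts: pd.DataFrame
    percentages: pd.DataFrame
    chi2: float
    p: float
    dof: int


def crosstab_chi_square(t: GradingTable) -> CrosstabResult:
    """Stage-by-expert contingency table with a Pearson chi-square test.

    Returns the count table (stages in scale order), per-expert column
    percentages rounded to 1 decimal place, and the chi-square statistic,
    p value and degrees of freedom.  Zero-margin rows/columns are dropped
    (with a warning) before the test.
    """
    experts = t.experts
    if len(experts) < 2:
        raise ValueError("chi-square needs at least two experts")
    counts = pd.crosstab(t.df["stage"], t.df["expert_id"]).reindex(
        index=list(STAGE_NAMES), columns=experts, fill_value=0
    )
    pct = (counts / counts.sum(axis=0) * 100).round(1)
    trimmed = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if trimmed.shape != counts.shape:
        warn("dropping zero-margin rows/columns before the chi-square test")
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2x2 table after trimming")
    chi2, p, dof, _ = stats.chi2_contingency(trimmed.to_numpy(), correction=False)
    return CrosstabResult(counts, pct, float(chi2), float(p), int(dof))


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p_overall: float
    pairwise: dict[tuple[str, str], float]


def one_way_anova(t: GradingTable, adjustment: str = "bonferroni") -> AnovaResult:
    """One-way ANOVA of coded labels across experts with post-hoc pairwise tests.

    Pairwise comparisons use pooled-MSE t tests (the classical post-hoc
    construction) with Bonferroni adjustment, capped at 1.0.
    """
    experts = t.experts
    if len(experts) < 2:
        raise ValueError("ANOVA needs at least two experts")
    groups = [t.codes(e).astype(float) for e in experts]
    for e, g in zip(experts, groups):
        if g.size < 2:
            raise ValueError(f"expert {e!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*groups)

    n_total = sum(g.size for g in groups)
    df_within = n_total - len(groups)
    mse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups) / df_within
    n_pairs = len(groups) * (len(groups) - 1) // 2
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")

    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(experts)):
        for j in range(i + 1, len(experts)):
            gi, gj = groups[i], groups[j]
            se = np.sqrt(mse * (1 / gi.size + 1 / gj.size))
            if se == 0:
                p_raw = 1.0
            else:
                tval = (gi.mean() - gj.mean()) / se
                p_raw = 2.0 * stats.t.sf(abs(tval), df_within)
            if adjustment == "bonferroni":
                p_raw = min(1.0, p_raw * n_pairs)
            pairwise[(experts[i], experts[j])] = float(p_raw)
    return AnovaResult(float(f), float(p), pairwise)


def consensus_stage(stages: list[str], rule: str = "mean_round") -> str:
    """Combine several experts' grades for one image into a consensus stage.

    ``mean_round``: round the mean coded label to the nearest stage (half up).
    ``majority``: the most frequent stage, ties broken toward the lower code.
    """
    if not stages:
        raise ValueError("need at least one grade")
    codes = [STAGE_CODES[s] for s in stages]
    if rule == "mean_round":
        code = int(np.floor(np.mean(codes) + 0.5))
        return STAGE_NAMES[code - 1]
    if rule == "majority":
        best = min(sorted(set(codes)), key=lambda c: (-codes.count(c), c))
        return STAGE_NAMES[best - 1]
    raise ValueError(f"unknown consensus rule {rule!r}")
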