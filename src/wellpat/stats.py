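"""Patterning summary statistics and significance tests.

Definitions
-----------
localization efficiency
    100 x (nuclei inside well interiors) / (total nuclei), over the
    all-nuclei channel restricted to the sampled-well neighbourhood.
viability
    100 x (1 - dead / total), dead being red-channel nuclei, by default
    restricted to well interiors.
occupancy distribution
    Fractions of sampled wells holding 0, 1, 2, 3 or >=4 interior
    nuclei; single-cell occupancy is the 1-cell bin as a percentage.
fold increase
    Mean over seeding densities of the stencil/no-stencil efficiency
    ratio.

Two significance tests are provided: the pooled-variance two-sample
Student's t-test, and the Mann-Whitney U test with an exact
small-sample branch (full enumeration of rank assignments when
``n1 + n2 <= 12`` and there are no ties) and a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import OCCUPANCY_BINS
from .errors import DegenerateVarianceError, UndefinedStatisticError

EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class PatterningSummary:
    """Per-scene (or per-condition) summary of patterning performance."""

    condition: str
    n_wells_sampled: int
    n_cells_total: int
    n_cells_interior: int
    localization_efficiency_pct: float
    n_dead: int
    viability_pct: float
    occupancy_counts: dict[int, int] = field(default_factory=dict)
    single_cell_occupancy_pct: float = float("nan")

    def occupancy_percentages(self) -> dict[int, float]:
        total = sum(self.occupancy_counts.values())
        if total == 0:
            return {k: float("nan") for k in OCCUPANCY_BINS}
        return {k: 100.0 * v / total for k, v in self.occupancy_counts.items()}


@dataclass(frozen=True)
class StatTestResult:
    method: str  # "students_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    n1: int
    n2: int
    alternative: str = "two-sided"


def localization_efficiency(assignment: pd.DataFrame) -> float:
    """Percent of assigned nuclei classified interior.

    Rows flagged ``in_sampled_set=False`` (nuclei outside the sampled
    wells' neighbourhood) are excluded when the flag is present.
    """
    df = assignment
    if "in_sampled_set" in df.columns:
        df = df[df["in_sampled_set"].astype(bool)]
    total = len(df)
    if total == 0:
        raise UndefinedStatisticError("no assigned nuclei; efficiency undefined")
    interior = int((df["location"] == "interior").sum())
    return 100.0 * interior / total


def viability(
    assignment_all: pd.DataFrame,
    assignment_dead: pd.DataFrame,
    restrict_to_interior: bool = True,
) -> float:
    """Percent of (interior) nuclei not labeled dead/dying."""

    def _count(df: pd.DataFrame) -> int:
        if "in_sampled_set" in df.columns:
            df = df[df["in_sampled_set"].astype(bool)]
        if restrict_to_interior:
            df = df[df["location"] == "interior"]
        return len(df)

    total = _count(assignment_all)
    dead = _count(assignment_dead)
    if total == 0:
        raise UndefinedStatisticError("no nuclei in restricted set; viability undefined")
    return 100.0 * (1.0 - dead / total)


def occupancy_distribution(
    assignment: pd.DataFrame, sampled_well_ids: np.ndarray
) -> tuple[dict[int, int], float]:
    """Interior-nucleus occupancy of the sampled wells.

    Wells with zero nuclei are counted.  Counts of 4 or more share the
    open top bin.  Returns ``(counts_by_bin, single_cell_pct)``.
    """
    sampled = np.asarray(sampled_well_ids)
    n_wells = len(sampled)
    if n_wells == 0:
        raise UndefinedStatisticError("no sampled wells")
    df = assignment
    if "in_sampled_set" in df.columns:
        df = df[df["in_sampled_set"].astype(bool)]
    df = df[(df["location"] == "interior") & df["well_id"].isin(sampled)]
    per_well = df.groupby("well_id").size()
    counts = {k: 0 for k in OCCUPANCY_BINS}
    n_occupied = 0
    for c in per_well.to_numpy():
        counts[min(int(c), OCCUPANCY_BINS[-1])] += 1
        n_occupied += 1
    counts[0] = n_wells - n_occupied
    single_pct = 100.0 * counts[1] / n_wells
    return counts, single_pct


def fold_increase(
    eff_stencil_by_density: np.ndarray, eff_control_by_density: np.ndarray
) -> float:
    """Mean stencil/control efficiency ratio over matched densities."""
    a = np.asarray(eff_stencil_by_density, dtype=float)
    b = np.asarray(eff_control_by_density, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise UndefinedStatisticError("density series must match and be non-empty")
    if np.any(b == 0):
        raise UndefinedStatisticError(
            "control efficiency of 0 at some density; ratio undefined"
        )
    return float(np.mean(a / b))


def students_t(
    sample_a: np.ndarray, sample_b: np.ndarray, welch: bool = False
) -> StatTestResult:
    """Two-sample t-test, pooled-variance by default (Welch optional)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise UndefinedStatisticError("need n >= 2 per group")
    if welch:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return StatTestResult("welch_t", float(t), float(p), n1, n2)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        raise DegenerateVarianceError("pooled variance is zero")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df=n1 + n2 - 2)
    return StatTestResult("students_t", float(t), float(p), n1, n2)


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U1 (for a) and U2 via midranks."""
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def mann_whitney_u(sample_a: np.ndarray, sample_b: np.ndarray) -> StatTestResult:
    """Mann-Whitney U test, two-sided, U = min(U1, U2).

    Exact p by full enumeration of the C(n1+n2, n1) rank assignments
    when the pooled sample is small (<= 12) and tie-free; otherwise the
    normal approximation with midrank tie correction and a continuity
    correction of 1/2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise UndefinedStatisticError("need n >= 1 per group")
    u1, u2 = _u_statistics(a, b)
    u = min(u1, u2)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= EXACT_MWU_MAX_N and not has_ties:
        p = _exact_p(u, n1, n2)
        return StatTestResult("mann_whitney_u", float(u), p, n1, n2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return StatTestResult("mann_whitney_u", float(u), 1.0, n1, n2)
    z = (u - mu + 0.5) / math.sqrt(var)  # u <= mu, shift toward the mean
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return StatTestResult("mann_whitney_u", float(u), float(p), n1, n2)


def _exact_p(u_obs: float, n1: int, n2: int) -> float:
    """P(min(U1, U2) <= u_obs) over all equally likely rank assignments."""
    n = n1 + n2
    total = 0
    hits = 0
    base = n1 * (n1 + 1) // 2
    for combo in combinations(range(1, n + 1), n1):
        u1 = sum(combo) - base
        u = min(u1, n1 * n2 - u1)
        total += 1
        if u <= u_obs + 1e-12:
            hits += 1
    return hits / total
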