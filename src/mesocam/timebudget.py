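"""Diel time-budget analysis: selection ratios and random-use tests.

Given detection counts in the crepuscular, diurnal, and nocturnal periods and
the proportional availability of each period over the survey effort, the
selection ratio for period i is

    w_i = o_i / pi_i

with o_i the proportion of detections in period i and pi_i its availability.
w_i > 1 flags selection (used more than available), w_i < 1 avoidance.

Non-random use is screened with the chi-square goodness-of-fit test against
expected counts N * pi_i (df = 2).  Per-period direction and significance come
from a multinomial randomization test: detections are treated as a
multinomial(N, pi) draw, and the observed count in each period is compared to
its randomization distribution one-sidedly in the direction of the observed
deviation, with the add-one correction p = (1 + #{as or more extreme}) /
(n_reps + 1) so p is never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mesocam.errors import DataConsistencyError
from mesocam.solar import PERIODS, AvailabilityVector


@dataclass
class SelectionResult:
    """Selection ratios and random-use tests for one species-season."""
    counts: np.ndarray               # order: crepuscular, diurnal, nocturnal
    availability: np.ndarray
    use: np.ndarray                  # o_i
    ratios: np.ndarray               # w_i
    chi2: float | None = None
    df: int | None = None
    p_chi2: float | None = None
    rand_p: np.ndarray | None = None
    rand_direction: list | None = None   # "above" / "below" expectation
    n_reps: int | None = None
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def _as_availability(availability) -> np.ndarray:
    if isinstance(availability, AvailabilityVector):
        return availability.as_array()
    pi = np.asarray(availability, dtype=float)
    if pi.shape != (3,) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ValueError("availability must be 3 proportions summing to 1")
    return pi


def selection_ratios(counts, availability) -> SelectionResult:
    """Selection ratios w_i = (n_i/N) / pi_i per diel period.

    ``counts`` ordered (crepuscular, diurnal, nocturnal), matching
    :data:`mesocam.solar.PERIODS`.
    """
    n = np.asarray(counts, dtype=float)
    pi = _as_availability(availability)
    if n.shape != (3,) or (n < 0).any():
        raise ValueError("counts must be 3 non-negative values")
    total = n.sum()
    if total <= 0:
        raise ValueError("no detections: selection ratios undefined")
    if ((pi == 0) & (n > 0)).any():
        raise DataConsistencyError("detections in a period with zero availability")
    use = n / total
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(pi > 0, use / np.where(pi > 0, pi, 1.0), np.nan)
    return SelectionResult(n.astype(int), pi, use, w)


def chisq_random_use(counts, availability):
    """Chi-square goodness-of-fit of counts against availability (df = 2)."""
    n = np.asarray(counts, dtype=float)
    pi = _as_availability(availability)
    expected = n.sum() * pi
    if (expected <= 0).any():
        raise DataConsistencyError("zero expected count under availability")
    chi2 = float(((n - expected) ** 2 / expected).sum())
    df = len(n) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def randomization_test(counts, availability, n_reps: int = 10_000,
                       seed: int | None = None):
    """Per-period one-sided multinomial randomization p-values with direction.

    Simulates ``n_reps`` multinomial(N, pi) surveys.  For period i the
    reported tail follows the observed deviation from expectation N*pi_i:
    "above" uses p = (1 + #{sim_i >= n_i})/(n_reps+1), "below" the analogous
    lower tail.
    """
    n = np.asarray(counts, dtype=int)
    pi = _as_availability(availability)
    total = int(n.sum())
    if total <= 0:
        raise ValueError("no detections")
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(total, pi, size=n_reps)
    expected = total * pi
    pvals = np.empty(3)
    directions = []
    for i in range(3):
        if n[i] > expected[i]:
            pvals[i] = (1 + np.sum(sims[:, i] >= n[i])) / (n_reps + 1)
            directions.append("above")
        else:
            pvals[i] = (1 + np.sum(sims[:, i] <= n[i])) / (n_reps + 1)
            directions.append("below")
    return pvals, directions


def analyse_time_budget(counts, availability, n_reps: int = 10_000,
                        seed: int | None = None) -> SelectionResult:
    """Full time-budget analysis for one species-season (ratios + both tests)."""
    res = selection_ratios(counts, availability)
    res.chi2, res.df, res.p_chi2 = chisq_random_use(counts, availability)
    res.rand_p, res.rand_direction = randomization_test(counts, availability,
                                                        n_reps, seed)
    res.n_reps, res.seed = n_reps, seed
    return res


def selection_table(results: dict, min_n: int = 10) -> "pd.DataFrame":  # noqa: F821
    """Assemble per species-season selection results into a long table.

    ``results`` maps (species, season) to counts; rows below ``min_n`` total
    detections are skipped (too few for a stable test).
    """
    import pandas as pd

    rows = []
    for (species, season), res in results.items():
        if res.n_total < min_n:
            continue
        row = {"species": species, "season": season, "n": res.n_total,
               "chi2": res.chi2, "p_chi2": res.p_chi2}
        for j, per in enumerate(PERIODS):
            row[f"n_{per}"] = int(res.counts[j])
            row[f"w_{per}"] = res.ratios[j]
            if res.rand_p is not None:
                row[f"p_{per}"] = res.rand_p[j]
                row[f"dir_{per}"] = res.rand_direction[j]
        rows.append(row)
    return pd.DataFrame(rows)
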