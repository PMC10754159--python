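"""Susceptibility scoring of cell populations from CG1 dose trajectories.

A population's susceptibility to particulate-matter stress is scored
from the fraction of its cells in cluster-group 1 (the large, "healthy"
morphologies) at control, low, and high dose:

    S_SC = [(CG1_UL − CG1_C) − (CG1_UH − CG1_UL)] / (CG1_UH − CG1_C)

For a monotone decline with per-step drops a = CG1_C − CG1_UL and
b = CG1_UL − CG1_UH this equals (a − b)/(a + b): +1 when the whole shift
away from CG1 happens already at low dose (most susceptible), −1 when
it happens only at high dose (resilient), 0 for a linear decline.
Scores are reported relative to the parental population (parental = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedScoreError(ValueError):
    """CG1_UH equals CG1_C: the score's denominator is zero."""


@dataclass(frozen=True)
class SusceptibilityInput:
    """CG1 fractions of one population across the three-dose series."""

    population_id: str
    cg1_control: float
    cg1_low: float
    cg1_high: float

    def __post_init__(self) -> None:
        for v in (self.cg1_control, self.cg1_low, self.cg1_high):
            if not 0.0 <= v <= 1.0:
                raise ValueError("CG1 fractions must lie in [0, 1]")


@dataclass
class SusceptibilityResult:
    population_id: str
    score: float  # raw S_SC
    score_normalized: float | None = None  # S_SC − S_SC(parental)
    rank: int | None = None
    monotone: bool = True
    ci_low: float | None = None
    ci_high: float | None = None


def susceptibility_score(inp: SusceptibilityInput) -> SusceptibilityResult:
    """Raw susceptibility score S_SC of one population.

    Raises :class:`UndefinedScoreError` when the high-dose CG1 fraction
    equals the control fraction (zero denominator).  Non-monotone CG1
    trajectories are scored but flagged ``monotone=False``.
    """
    c, ul, uh = inp.cg1_control, inp.cg1_low, inp.cg1_high
    denom = uh - c
    if denom == 0:
        raise UndefinedScoreError(
            f"{inp.population_id}: CG1 fraction unchanged control→high; "
            "score undefined"
        )
    score = ((ul - c) - (uh - ul)) / denom
    monotone = c >= ul >= uh
    return SusceptibilityResult(inp.population_id, float(score), monotone=monotone)


def susceptibility_score_ab(a: float, b: float) -> float:
    """Closed form (a − b)/(a + b) for monotone per-step CG1 drops."""
    if a + b == 0:
        raise UndefinedScoreError("total CG1 drop is zero; score undefined")
    return (a - b) / (a + b)


def normalize_to_parental(
    results: list[SusceptibilityResult], parental_id: str = "parental"
) -> list[SusceptibilityResult]:
    """Subtract the parental score from every population's score.

    The parental maps to exactly 0; subtraction preserves the ordering.
    """
    by_id = {r.population_id: r for r in results}
    if parental_id not in by_id:
        raise ValueError(f"parental population {parental_id!r} missing")
    ref = by_id[parental_id].score
    for r in results:
        r.score_normalized = r.score - ref
    return results


def rank_populations(
    results: list[SusceptibilityResult],
) -> list[SusceptibilityResult]:
    """Order populations most-susceptible first (descending normalized
    score, raw score if none normalized); ties break by population id."""
    if len(results) < 2:
        raise ValueError("need at least 2 populations to rank")

    def key(r: SusceptibilityResult):
        s = r.score_normalized if r.score_normalized is not None else r.score
        return (-s, r.population_id)

    ordered = sorted(results, key=key)
    for i, r in enumerate(ordered):
        r.rank = i + 1
    return ordered


def score_table(results: list[SusceptibilityResult]) -> pd.DataFrame:
    """Scores as a flat table (ranked order)."""
    return pd.DataFrame(
        [
            {
                "population_id": r.population_id,
                "score": r.score,
                "score_normalized": r.score_normalized,
                "rank": r.rank,
                "monotone": r.monotone,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in results
        ]
    )


def score_from_cg_labels(
    population_id: str,
    cg_labels_by_dose: dict[str, np.ndarray],
    n_boot: int = 0,
    seed: int = 0,
) -> SusceptibilityResult:
    """Score a population from per-cell CG labels at each dose.

    ``cg_labels_by_dose`` maps "control"/"low"/"high" to arrays of
    per-cell cluster-group ids.  With ``n_boot > 0``, cells are
    resampled within each dose to attach a percentile bootstrap 95% CI
    (an extension beyond the point score).
    """
    for dose in ("control", "low", "high"):
        if dose not in cg_labels_by_dose:
            raise ValueError(f"missing dose {dose!r}")
    fr = {
        d: float((np.asarray(v) == 1).mean())
        for d, v in cg_labels_by_dose.items()
    }
    res = susceptibility_score(
        SusceptibilityInput(population_id, fr["control"], fr["low"], fr["high"])
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        arrs = {d: np.asarray(v) == 1 for d, v in cg_labels_by_dose.items()}
        for _ in range(n_boot):
            try:
                f = {
                    d: a[rng.integers(0, len(a), len(a))].mean()
                    for d, a in arrs.items()
                }
                reps.append(
                    susceptibility_score(
                        SusceptibilityInput(
                            population_id, f["control"], f["low"], f["high"]
                        )
                    ).score
                )
            except UndefinedScoreError:
                continue
        if reps:
            res.ci_low, res.ci_high = (
                float(np.percentile(reps, 2.5)),
                float(np.percentile(reps, 97.5)),
            )
    return res
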