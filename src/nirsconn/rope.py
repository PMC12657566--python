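"""Posterior decision layer: marginal predictions, HDIs and ROPE rules.

From posterior draws of the degree model this module derives average
marginal predictions per Group x Session cell, pairwise difference
distributions (Delta), their 89% highest density intervals, and the
region-of-practical-equivalence decision: with ROPE bounds at +/- 0.1
times the response SD, a difference is *rejected* (non-zero) when fewer
than 2.5% of its HDI draws fall inside the ROPE and *supported* (zero)
when more than 97.5% do; anything else — including an HDI straddling
both ROPE bounds — is *inconclusive*.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .glmm import GROUP_LEVELS, SESSION_LEVELS, PosteriorDraws, fixed_design

ROPE_SD_FRACTION = 0.1
HDI_MASS = 0.89
DECISION_LOW = 0.025
DECISION_HIGH = 0.975


@dataclass
class MarginalPredictions:
    """Draws of the posterior mean degree per Group x Session cell."""

    cell_draws: dict[tuple[str, str], np.ndarray]  # (group, session) -> (n_draws,)
    n_draws: int

    def __post_init__(self) -> None:
        for key, v in self.cell_draws.items():
            if np.any(v <= 0):
                raise ParameterError(f"cell {key} has non-positive mean-degree draws")


@dataclass
class PairwiseComparison:
    """A difference distribution with its HDI, ROPE overlap and decision."""

    label: str
    delta_draws: np.ndarray
    median: float | None = None
    hdi_low: float | None = None
    hdi_high: float | None = None
    rope_low: float | None = None
    rope_high: float | None = None
    rope_overlap: float | None = None
    decision: str | None = None


def hdi(samples: np.ndarray, mass: float = HDI_MASS) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws.

    Sorted-window algorithm: slide a window of ceil(mass * n) samples
    over the sorted draws and return the narrowest; ties break toward
    the lowest-start window.
    """
    x = np.sort(np.asarray(samples, float))
    n = x.size
    if n < 50:
        raise ParameterError("hdi needs at least 50 samples")
    if not 0.0 < mass < 1.0:
        raise ParameterError("mass must lie in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def marginal_predictions(
    draws: PosteriorDraws,
    data: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | None = None,
) -> MarginalPredictions:
    """Average marginal posterior predictions per Group x Session cell.

    For each retained posterior draw (a seeded subsample of ``n_draws``)
    the expected degree of every observed (participant, channel) unit is
    computed under each cell — keeping the unit's own random effects —
    and averaged across units, yielding one mean prediction per cell per
    draw.
    """
    total = draws.n_chains * draws.n_draws
    if n_draws > total:
        raise ParameterError(f"n_draws={n_draws} exceeds {total} retained draws")
    rng = np.random.default_rng(seed)
    take = np.sort(rng.choice(total, size=n_draws, replace=False))

    beta = draws.beta_draws()[take]          # (S, 9)
    u = draws.u_draws()[take]                # (S, C, 9)
    w = draws.w_draws()[take]                # (S, J, 3)

    # observed units: (participant, channel) pairs present in the table
    pmap = {p: i for i, p in enumerate(draws.participants)}
    cmap = {c: i for i, c in enumerate(draws.channels)}
    units = data[["participant", "channel"]].drop_duplicates()
    unit_p = units["participant"].map(pmap).to_numpy()
    unit_c = units["channel"].map(cmap).to_numpy()
    if np.any(pd.isna(unit_p)) or np.any(pd.isna(unit_c)):
        raise ParameterError("table contains units unseen by the fitted model")

    cells = {}
    for g in GROUP_LEVELS:
        for s in SESSION_LEVELS:
            row = pd.DataFrame({"group": [g], "session": [s]})
            xf = fixed_design(row.assign(participant="x", channel="x", degree=0))[0]
            xw = xf[[0, 3, 4]]
            a = beta @ xf                    # (S,)
            cu = np.einsum("sck,k->sc", u, xf)   # (S, C)
            pw = np.einsum("sjk,k->sj", w, xw)   # (S, J)
            eta = a[:, None] + cu[:, unit_c] + pw[:, unit_p]  # (S, n_units)
            cells[(g, s)] = np.exp(eta).mean(axis=1)
    return MarginalPredictions(cell_draws=cells, n_draws=n_draws)


def pairwise_differences(
    m: MarginalPredictions, axis: str
) -> list[PairwiseComparison]:
    """Difference distributions along one factor axis.

    ``axis="session-within-group"`` gives later-minus-earlier session
    contrasts within each group (3 per group); ``axis="group-within-
    session"`` gives first-listed-minus-second-listed group contrasts
    within each session (3 per session), with groups ordered DLPFC,
    VLPFC, Sham.
    """
    for g in GROUP_LEVELS:
        for s in SESSION_LEVELS:
            if (g, s) not in m.cell_draws:
                raise ParameterError(f"missing cell {(g, s)}")
    out = []
    if axis == "session-within-group":
        for g in GROUP_LEVELS:
            for earlier, later in combinations(SESSION_LEVELS, 2):
                delta = m.cell_draws[(g, later)] - m.cell_draws[(g, earlier)]
                out.append(PairwiseComparison(f"{g}: {later} - {earlier}", delta))
    elif axis == "group-within-session":
        display = ("DLPFC", "VLPFC", "Sham")
        for s in SESSION_LEVELS:
            for first, second in combinations(display, 2):
                delta = m.cell_draws[(first, s)] - m.cell_draws[(second, s)]
                out.append(PairwiseComparison(f"{s}: {first} - {second}", delta))
    else:
        raise ParameterError(f"unknown axis {axis!r}")
    return out


def rope_decision(
    c: PairwiseComparison,
    response_sd: float,
    mass: float = HDI_MASS,
    rope_fraction: float = ROPE_SD_FRACTION,
) -> PairwiseComparison:
    """Complete a comparison with HDI, ROPE overlap and decision.

    ROPE bounds are +/- ``rope_fraction`` * ``response_sd``; the overlap
    is the fraction of Delta draws inside the HDI that also fall inside
    the ROPE.  Decision: rejected if overlap < 0.025, supported if
    overlap > 0.975, otherwise inconclusive; an HDI crossing both ROPE
    bounds is inconclusive regardless of overlap.
    """
    if response_sd <= 0:
        raise ParameterError("response_sd must be positive")
    lo, hi = hdi(c.delta_draws, mass)
    rope_high = rope_fraction * response_sd
    rope_low = -rope_high
    d = c.delta_draws
    in_hdi = (d >= lo) & (d <= hi)
    n_hdi = int(in_hdi.sum())
    in_rope = in_hdi & (d >= rope_low) & (d <= rope_high)
    overlap = float(in_rope.sum() / n_hdi) if n_hdi else 0.0

    if lo < rope_low and hi > rope_high:
        decision = "inconclusive"
    elif overlap < DECISION_LOW:
        decision = "rejected"
    elif overlap > DECISION_HIGH:
        decision = "supported"
    else:
        decision = "inconclusive"

    return PairwiseComparison(
        label=c.label,
        delta_draws=c.delta_draws,
        median=float(np.median(d)),
        hdi_low=lo,
        hdi_high=hi,
        rope_low=rope_low,
        rope_high=rope_high,
        rope_overlap=overlap,
        decision=decision,
    )


def compare_all(
    draws: PosteriorDraws,
    data: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | None = None,
    response_sd: float | None = None,
    mass: float = HDI_MASS,
    rope_fraction: float = ROPE_SD_FRACTION,
) -> list[PairwiseComparison]:
    """All 18 pairwise decisions (9 per-group, 9 per-session contrasts).

    ``response_sd`` defaults to the empirical SD of the analyzed degree
    column.
    """
    if response_sd is None:
        response_sd = float(data["degree"].std(ddof=1))
    m = marginal_predictions(draws, data, n_draws=n_draws, seed=seed)
    comps = pairwise_differences(m, "session-within-group")
    comps += pairwise_differences(m, "group-within-session")
    return [rope_decision(c, response_sd, mass, rope_fraction) for c in comps]


def comparisons_to_frame(comps: list[PairwiseComparison]) -> pd.DataFrame:
    """Tabular report of completed comparisons."""
    return pd.DataFrame(
        {
            "comparison": [c.label for c in comps],
            "median": [c.median for c in comps],
            "hdi_low": [c.hdi_low for c in comps],
            "hdi_high": [c.hdi_high for c in comps],
            "rope_overlap": [c.rope_overlap for c in comps],
            "decision": [c.decision for c in comps],
        }
    )
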