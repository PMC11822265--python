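"""Cost-effectiveness statistics over PSA iterations.

Aggregates per-iteration microsimulation means into the standard outputs of
a cost-utility analysis: per-strategy means and SDs, the dominance / ICER
frontier, net monetary benefit (NMB = QALYs x WTP - cost), the share of
iterations in which each strategy is optimal, cost-effectiveness
acceptability curves (CEAC), and confidence ellipses on the incremental
cost-effectiveness plane.

Dominance vocabulary: a strategy is *absolutely dominated* if some other
strategy costs no more and yields no fewer QALYs (with at least one strict
inequality); a frontier strategy is *extended dominated* when the pairwise
ICERs along the cost-sorted frontier are non-monotone, i.e. a mixture of
its neighbours delivers QALYs more cheaply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IterationResult",
    "CEARow",
    "CEATable",
    "CEACCurve",
    "Ellipse",
    "results_frame",
    "aggregate_psa",
    "nmb",
    "dominance_and_icers",
    "build_cea_table",
    "optimal_shares",
    "ceac",
    "crossover_wtp",
    "incremental_pairs",
    "confidence_ellipse",
    "nmb_curve",
    "write_cea_table",
    "write_ceac",
    "write_nmb_curve",
    "write_incremental_scatter",
    "write_ellipse",
]

UNDOMINATED = "undominated"
ABSOLUTE_DOMINATED = "absolute_dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass(frozen=True)
class IterationResult:
    """Per-strategy (mean cost, mean QALY) of one PSA iteration."""

    iteration: int
    costs: dict[str, float]
    qalys: dict[str, float]

    def __post_init__(self):
        if set(self.costs) != set(self.qalys):
            raise ValueError("costs and qalys must cover the same strategies")
        for name in self.costs:
            c, q = self.costs[name], self.qalys[name]
            if not (math.isfinite(c) and math.isfinite(q)) or c < 0 or q < 0:
                raise ValueError(
                    f"iteration {self.iteration}, strategy {name}: "
                    f"values must be finite and nonnegative (cost={c}, qaly={q})")


def results_frame(results: Sequence[IterationResult]) -> pd.DataFrame:
    """Long-format DataFrame (iteration, strategy, mean_cost, mean_qaly)."""
    rows = [
        {"iteration": r.iteration, "strategy": name,
         "mean_cost": r.costs[name], "mean_qaly": r.qalys[name]}
        for r in results for name in r.costs
    ]
    return pd.DataFrame(rows)


def _strategy_order(results: Sequence[IterationResult]) -> list[str]:
    return list(results[0].costs)


def aggregate_psa(results: Sequence[IterationResult]) -> pd.DataFrame:
    """Across-iteration mean and sample SD of cost and QALY per strategy."""
    if len(results) < 2:
        raise ValueError(f"need at least 2 iterations, got {len(results)}")
    order = _strategy_order(results)
    out = {}
    for name in order:
        costs = np.array([r.costs[name] for r in results])
        qalys = np.array([r.qalys[name] for r in results])
        out[name] = {"mean_cost": costs.mean(), "sd_cost": costs.std(ddof=1),
                     "mean_qaly": qalys.mean(), "sd_qaly": qalys.std(ddof=1)}
    return pd.DataFrame.from_dict(out, orient="index").loc[order]


def nmb(mean_cost: float, mean_qaly: float, wtp: float) -> float:
    """Net monetary benefit: QALYs valued at WTP minus cost."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return mean_qaly * wtp - mean_cost


@dataclass(frozen=True)
class CEARow:
    strategy: str
    mean_cost: float
    sd_cost: float
    mean_qaly: float
    sd_qaly: float
    dominance_label: str
    incremental_cost: Optional[float]  # None for the reference (cheapest) row
    incremental_effect: Optional[float]
    icer: Optional[float]  # relative to the cheapest strategy, as printed
    nmb: float
    pct_iterations_optimal: Optional[float] = None


@dataclass(frozen=True)
class CEATable:
    """Rows sorted by mean cost plus the frontier ICER chain."""

    rows: tuple[CEARow, ...]
    wtp: float
    frontier_icers: tuple[tuple[str, str, float], ...] = ()

    def row(self, strategy: str) -> CEARow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(strategy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _absolute_dominated(means: Mapping[str, tuple[float, float]]) -> set[str]:
    out = set()
    for a, (ca, qa) in means.items():
        for b, (cb, qb) in means.items():
            if a == b:
                continue
            if cb <= ca and qb >= qa and (cb < ca or qb > qa):
                out.add(a)
                break
    return out


def _extended_dominated(means: Mapping[str, tuple[float, float]],
                        candidates: list[str]) -> set[str]:
    """Frontier points whose pairwise ICER chain is non-monotone."""
    out: set[str] = set()
    frontier = sorted(candidates, key=lambda n: (means[n][0], means[n][1], n))
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = _pairwise_icer(means[lo], means[mid])
            icer_hi = _pairwise_icer(means[mid], means[hi])
            if icer_lo is not None and icer_hi is not None and icer_lo > icer_hi:
                out.add(mid)
                frontier.pop(i)
                changed = True
                break
    return out


def _pairwise_icer(lo: tuple[float, float],
                   hi: tuple[float, float]) -> Optional[float]:
    dq = hi[1] - lo[1]
    if dq == 0:
        return None
    return (hi[0] - lo[0]) / dq


def dominance_and_icers(means: Mapping[str, tuple[float, float]],
                        wtp: float,
                        sds: Mapping[str, tuple[float, float]] | None = None,
                        shares: Mapping[str, float] | None = None) -> CEATable:
    """Classify strategies and compute incremental statistics.

    ``means`` maps strategy -> (mean_cost, mean_qaly).  Rows are sorted by
    mean cost (ties by name); incremental columns and per-row ICERs are
    relative to the cheapest strategy, while ``frontier_icers`` chains
    successive undominated strategies.
    """
    if len(means) < 2:
        raise ValueError("need at least 2 strategies")
    order = sorted(means, key=lambda n: (means[n][0], n))
    absolute = _absolute_dominated(means)
    extended = _extended_dominated(means, [n for n in order if n not in absolute])

    cheapest = order[0]
    c0, q0 = means[cheapest]
    rows = []
    for name in order:
        c, q = means[name]
        if name in absolute:
            label = ABSOLUTE_DOMINATED
        elif name in extended:
            label = EXTENDED_DOMINATED
        else:
            label = UNDOMINATED
        if name == cheapest:
            inc_c = inc_q = icer = None
        else:
            inc_c, inc_q = c - c0, q - q0
            icer = inc_c / inc_q if inc_q != 0 else None
        sd_c, sd_q = (sds or {}).get(name, (0.0, 0.0))
        rows.append(CEARow(
            strategy=name, mean_cost=c, sd_cost=sd_c, mean_qaly=q, sd_qaly=sd_q,
            dominance_label=label, incremental_cost=inc_c,
            incremental_effect=inc_q, icer=icer,
            nmb=nmb(c, q, wtp),
            pct_iterations_optimal=(shares or {}).get(name)))

    frontier = [n for n in order if n not in absolute and n not in extended]
    chain = []
    for lo, hi in zip(frontier, frontier[1:]):
        icer = _pairwise_icer(means[lo], means[hi])
        if icer is not None:
            chain.append((lo, hi, icer))
    return CEATable(rows=tuple(rows), wtp=wtp, frontier_icers=tuple(chain))


def _matrices(results: Sequence[IterationResult]):
    order = _strategy_order(results)
    costs = np.array([[r.costs[n] for n in order] for r in results])
    qalys = np.array([[r.qalys[n] for n in order] for r in results])
    return order, costs, qalys


def _winner_indices(costs: np.ndarray, qalys: np.ndarray, wtp: float,
                    name_rank: np.ndarray) -> np.ndarray:
    """Per-iteration index of the NMB-maximal strategy.

    Exact NMB ties are broken by lower cost, then by name order.
    """
    nmb_mat = qalys * wtp - costs
    tied = nmb_mat >= nmb_mat.max(axis=1, keepdims=True)
    cost_of_tied = np.where(tied, costs, np.inf)
    tied &= cost_of_tied <= cost_of_tied.min(axis=1, keepdims=True)
    rank = np.where(tied, name_rank, np.iinfo(np.int64).max)
    return rank.argmin(axis=1)


def optimal_shares(results: Sequence[IterationResult],
                   wtp: float) -> dict[str, float]:
    """Percent of iterations in which each strategy has maximal NMB.

    Ties go to the lower-cost strategy, then to the lexicographically
    smaller name.  Shares sum to 100.
    """
    order, costs, qalys = _matrices(results)
    name_rank = np.array([sorted(order).index(n) for n in order])
    winners = _winner_indices(costs, qalys, wtp, name_rank)
    counts = np.bincount(winners, minlength=len(order))
    return {name: 100.0 * counts[k] / len(results)
            for k, name in enumerate(order)}


def build_cea_table(results: Sequence[IterationResult], wtp: float) -> CEATable:
    """Full results table from PSA iterations (means, SDs, dominance,
    incrementals, NMB at ``wtp``, and % iterations optimal)."""
    agg = aggregate_psa(results)
    means = {n: (float(agg.loc[n, "mean_cost"]), float(agg.loc[n, "mean_qaly"]))
             for n in agg.index}
    sds = {n: (float(agg.loc[n, "sd_cost"]), float(agg.loc[n, "sd_qaly"]))
           for n in agg.index}
    shares = optimal_shares(results, wtp)
    return dominance_and_icers(means, wtp, sds=sds, shares=shares)


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is optimal as a function of WTP."""

    wtps: np.ndarray
    probabilities: pd.DataFrame  # index = wtp, columns = strategies

    def probability(self, strategy: str) -> np.ndarray:
        return self.probabilities[strategy].to_numpy()


def ceac(results: Sequence[IterationResult],
         wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curves on a WTP grid.

    At each WTP the share of iterations in which each strategy attains the
    maximal NMB (ties to lower cost); shares sum to 1 at every grid point.
    """
    wtps = np.asarray(list(wtp_grid), dtype=float)
    if wtps.size < 1:
        raise ValueError("wtp_grid must contain at least one value")
    order, costs, qalys = _matrices(results)
    name_rank = np.array([sorted(order).index(n) for n in order])
    probs = np.zeros((wtps.size, len(order)))
    for j, wtp in enumerate(wtps):
        winners = _winner_indices(costs, qalys, float(wtp), name_rank)
        probs[j] = np.bincount(winners, minlength=len(order)) / len(results)
    return CEACCurve(wtps=wtps,
                     probabilities=pd.DataFrame(probs, index=wtps, columns=order))


def crossover_wtp(curve: CEACCurve, s1: str, s2: str) -> Optional[float]:
    """WTP at which ``s1`` first becomes more likely optimal than ``s2``.

    Scans the grid for the first point where P(s1 optimal) exceeds
    P(s2 optimal); the crossing is linearly interpolated between the
    bracketing grid points.  Returns None when the curves never cross.
    """
    p1 = curve.probability(s1)
    p2 = curve.probability(s2)
    diff = p1 - p2
    idx = np.flatnonzero(diff > 0)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(curve.wtps[0])
    w_lo, w_hi = curve.wtps[i - 1], curve.wtps[i]
    d_lo, d_hi = diff[i - 1], diff[i]
    if d_hi == d_lo:
        return float(w_hi)
    return float(w_lo + (0.0 - d_lo) / (d_hi - d_lo) * (w_hi - w_lo))


def incremental_pairs(results: Sequence[IterationResult], s1: str,
                      s2: str) -> np.ndarray:
    """Per-iteration (cost(s1)-cost(s2), qaly(s1)-qaly(s2)) as an (n, 2) array."""
    return np.array([[r.costs[s1] - r.costs[s2], r.qalys[s1] - r.qalys[s2]]
                     for r in results])


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse of a bivariate sample (cost on axis 0)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float  # orientation of the major axis
    level: float
    degenerate: bool

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        pts = np.atleast_2d(points) - np.asarray(self.center)
        c, s = math.cos(self.angle_rad), math.sin(self.angle_rad)
        rot = np.array([[c, s], [-s, c]])  # rotate into the ellipse frame
        local = pts @ rot.T
        a, b = self.semi_axes
        if a == 0 or b == 0:
            return np.zeros(len(pts), dtype=bool)
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


def confidence_ellipse(pairs: np.ndarray, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of incremental (cost, effect) pairs.

    Center is the sample mean; the semi-axes are the square roots of the
    covariance eigenvalues scaled by sqrt(chi2.ppf(level, 2)) (about 2.4477
    at the 95% level), oriented along the eigenvectors.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need an (n, 2) array with n >= 3")
    center = pairs.mean(axis=0)
    cov = np.cov(pairs, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    scale = math.sqrt(stats.chi2.ppf(level, df=2))
    degenerate = bool(eigvals[0] <= 1e-12 * max(eigvals[1], 1.0))
    major = eigvecs[:, 1]
    angle = math.atan2(major[1], major[0])
    semi = (float(np.sqrt(max(eigvals[1], 0.0)) * scale),
            float(np.sqrt(max(eigvals[0], 0.0)) * scale))
    return Ellipse(center=(float(center[0]), float(center[1])),
                   semi_axes=semi, angle_rad=angle, level=level,
                   degenerate=degenerate)


def nmb_curve(results: Sequence[IterationResult],
              wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Mean NMB per strategy at each WTP (long format)."""
    agg = aggregate_psa(results)
    rows = []
    for wtp in wtp_grid:
        for name in agg.index:
            rows.append({"wtp": float(wtp), "strategy": name,
                         "nmb": nmb(float(agg.loc[name, "mean_cost"]),
                                    float(agg.loc[name, "mean_qaly"]),
                                    float(wtp))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# CSV writers (plain machine-readable CSV: header row, no thousands separators)

def write_cea_table(table: CEATable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_ceac(curve: CEACCurve, path) -> None:
    long = (curve.probabilities
            .rename_axis("wtp")
            .reset_index()
            .melt(id_vars="wtp", var_name="strategy", value_name="probability"))
    long.to_csv(path, index=False)


def write_nmb_curve(results: Sequence[IterationResult], wtp_grid,
                    path) -> None:
    nmb_curve(results, wtp_grid).to_csv(path, index=False)


def write_incremental_scatter(results: Sequence[IterationResult], s1: str,
                              s2: str, path) -> None:
    pairs = incremental_pairs(results, s1, s2)
    pd.DataFrame({"iteration": [r.iteration for r in results],
                  "incremental_cost": pairs[:, 0],
                  "incremental_qaly": pairs[:, 1]}).to_csv(path, index=False)


def write_ellipse(ellipse: Ellipse, path) -> None:
    pd.DataFrame([{
        "center_cost": ellipse.center[0],
        "center_effect": ellipse.center[1],
        "semi_axis_major": ellipse.semi_axes[0],
        "semi_axis_minor": ellipse.semi_axes[1],
        "angle_rad": ellipse.angle_rad,
        "level": ellipse.level,
        "degenerate": ellipse.degenerate,
    }]).to_csv(path, index=False)
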