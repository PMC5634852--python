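"""Global sensitivity analysis: Latin hypercube sampling + partial rank
correlation coefficients (PRCC).

The kinetic constants are drawn from uniform ranges (one stratified draw per
equal-probability interval and parameter, columns independently permuted),
the model's steady state is computed for every draw at a fixed Dvl level
from epithelial-basin initial conditions, and each parameter's influence on
each output is summarized by the correlation of their rank transforms after
removing the rank-linear effect of all other parameters.  A pair is called
significant when |rho| > 0.45 with p < 0.05 (effect-size threshold in place
of multiple-testing correction).

Two deliberate range restrictions keep the outputs monotone, which PRCC
requires: the basal beta-catenin production ranges start at alpha2 = 0.01
(dimensional) and A2 = 1 (nondimensional) because below these the
beta-catenin balance admits negative steady states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.stats import qmc

from .model import (
    DimensionalParams,
    Frame,
    NondimParams,
    _rhs_dim,
    _rhs_nondim,
)
from .simulate import Equilibrium, find_equilibria

logger = logging.getLogger(__name__)

#: Effect-size threshold of the significance rule.
RHO_THRESHOLD = 0.45

#: p-value threshold of the significance rule.
P_THRESHOLD = 0.05

#: Output column names per frame.
OUTPUTS = {"dimensional": ("E", "B", "S"), "nondimensional": ("e", "b", "s")}


@dataclass(frozen=True)
class SamplingRange:
    """Uniform sampling range of one parameter."""

    name: str
    min: float
    max: float
    frame: Frame

    def __post_init__(self) -> None:
        if not (self.min < self.max):
            raise ValueError(f"range for {self.name!r} needs min < max")


@dataclass
class LHSDesign:
    """A stratified N x K sample: one draw per stratum per column."""

    names: list[str]
    samples: np.ndarray  # shape (N, K)
    ranges: list[SamplingRange]
    seed: int

    @property
    def N(self) -> int:
        return self.samples.shape[0]

    @property
    def K(self) -> int:
        return self.samples.shape[1]

    def frame(self) -> Frame:
        return self.ranges[0].frame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)


def lhs_sample(ranges: list[SamplingRange], N: int, seed: int) -> LHSDesign:
    """Latin hypercube over the given ranges with N strata per parameter.

    The sample-size constraint N > (4/3) K applies (for the 13-parameter
    dimensional system this demands at least 18 strata); violating it is an
    error, as are duplicate parameter names or mixed frames.
    """
    K = len(ranges)
    names = [r.name for r in ranges]
    if len(set(names)) != K:
        raise ValueError("duplicate parameter names in ranges")
    if len({r.frame for r in ranges}) != 1:
        raise ValueError("all ranges must share one frame")
    if not N > 4.0 / 3.0 * K:
        n_min = math.floor(4.0 / 3.0 * K) + 1
        raise ValueError(
            f"LHS requires N > (4/3)*K: with K = {K} at least {n_min} strata "
            f"are needed, got N = {N}"
        )
    engine = qmc.LatinHypercube(d=K, seed=int(seed))
    unit = engine.random(N)
    lows = np.array([r.min for r in ranges])
    highs = np.array([r.max for r in ranges])
    return LHSDesign(
        names=names, samples=qmc.scale(unit, lows, highs),
        ranges=list(ranges), seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Model evaluation per sample
# ---------------------------------------------------------------------------

def _build_params(row: dict[str, float], defaults, frame: Frame):
    base = {
        f: getattr(defaults, f)
        for f in defaults.__dataclass_fields__  # type: ignore[attr-defined]
    }
    base.update(row)
    cls = DimensionalParams if frame == "dimensional" else NondimParams
    return cls(**base)


def _epithelial_init(params, frame: Frame) -> np.ndarray:
    # "e = 10 equivalent": ten times the E-cadherin half-maximal scale
    if frame == "dimensional":
        return np.array([10.0 * params.IC_E, 0.0, 0.0])
    return np.array([10.0, 0.0, 0.0])


def _select_basin(
    params, dvl: float, frame: Frame, stable: list[Equilibrium]
) -> Equilibrium | None:
    """Pick the stable equilibrium reached from epithelial-basin initial
    conditions, by a short integration and nearest-in-b assignment."""
    if len(stable) == 1:
        return stable[0]
    rhs = _rhs_dim if frame == "dimensional" else _rhs_nondim
    y0 = _epithelial_init(params, frame)
    if frame == "dimensional":
        rates = [params.beta1, params.beta2, params.beta3]
    else:
        rates = [params.C1, params.C2, params.C3]
    slowest = min(r for r in rates if r > 0)
    t_end = min(200.0 / slowest, 1e7)
    bs = np.array([eq.state.bcat for eq in stable])
    y = y0
    for _ in range(3):
        sol = solve_ivp(
            lambda t, yy: rhs(yy, params, dvl), (0.0, t_end), y,
            method="LSODA", rtol=1e-8, atol=1e-10,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            return None
        y = sol.y[:, -1]
        gaps = np.abs(y[1] - bs)
        order = np.argsort(gaps)
        if len(order) == 1 or gaps[order[0]] < 0.2 * gaps[order[1]]:
            return stable[int(order[0])]
        t_end *= 5
    return stable[int(np.argmin(np.abs(y[1] - bs)))]


def evaluate_outputs(
    design: LHSDesign,
    dvl: float,
    frame: Frame,
    defaults,
    n_scan: int = 4001,
) -> pd.DataFrame:
    """Steady-state outputs for every design row at a fixed Dvl level.

    Unsampled fields (in particular the Hill coefficients, which the ranges
    never include) come from ``defaults``.  The returned frame has one row
    per sample with the steady-state concentrations, a ``nonphysical`` flag
    for negative components (flagged, never dropped here) and a ``failed``
    flag for rows whose steady state could not be resolved; failures are
    excluded from PRCC downstream with a logged count.
    """
    out_names = OUTPUTS[frame]
    rows = []
    for i in range(design.N):
        sample = dict(zip(design.names, design.samples[i]))
        record = {name: np.nan for name in out_names}
        record["nonphysical"] = False
        record["failed"] = False
        try:
            params = _build_params(sample, defaults, frame)
            eqs = find_equilibria(params, dvl, frame=frame, n_scan=n_scan)
            stable = [e for e in eqs if e.stable]
            chosen = _select_basin(params, dvl, frame, stable)
            if chosen is None:
                raise RuntimeError("basin selection did not converge")
            y = chosen.state.as_array()
            record.update(dict(zip(out_names, y)))
            record["nonphysical"] = bool(np.any(y < 0))
        except Exception as exc:  # noqa: BLE001 -- per-row failures are data
            record["failed"] = True
            logger.debug("row %d failed: %s", i, exc)
        rows.append(record)
    df = pd.DataFrame(rows)
    n_failed = int(df["failed"].sum())
    if n_failed:
        logger.info("evaluate_outputs: %d/%d rows failed", n_failed, design.N)
    return df


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------

def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def _partial_corr_residual(X: np.ndarray, j: int, y: np.ndarray) -> float:
    """Correlation of x_j and y after regressing out the other columns."""
    others = np.delete(X, j, axis=1)
    Z = np.column_stack([np.ones(len(y)), others])
    beta_x, *_ = np.linalg.lstsq(Z, X[:, j], rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = X[:, j] - Z @ beta_x
    ry = y - Z @ beta_y
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return 0.0
    return float(np.clip(rx @ ry / denom, -1.0, 1.0))


def prcc(
    design: LHSDesign,
    outputs: pd.DataFrame,
    target: str,
    dvl: float | None = None,
    method: str = "partial",
) -> pd.DataFrame:
    """Rank correlation of every sampled parameter against one output column.

    With ``method="partial"`` (the default, standard PRCC) all columns are
    rank-transformed and each parameter's correlation with the output
    controls for the remaining parameters via the residual formulation.
    ``method="simple"`` gives the plain rank (Spearman) correlation without
    controlling for the other parameters -- the statistic under which the
    0.45 effect-size threshold separates the Dvl-on from the Dvl-off
    significance sets (partial correlations concentrate far more of the
    monotone signal into single parameters; see the methods note).

    The p-value uses the large-sample t statistic
    rho * sqrt((N - 2 - g) / (1 - rho^2)) with g controlled parameters
    (g = 0 for the simple statistic).  Failed rows are dropped (logged);
    ties beyond half a column trigger a degeneracy warning.
    """
    if method not in ("partial", "simple"):
        raise ValueError(f"method must be 'partial' or 'simple', got {method!r}")
    valid = ~outputs["failed"].to_numpy(dtype=bool)
    n_valid = int(valid.sum())
    if n_valid < design.K + 3:
        raise ValueError(
            f"need at least K + 3 = {design.K + 3} valid rows, have {n_valid}"
        )
    if n_valid < design.N:
        logger.info("prcc: excluding %d failed rows", design.N - n_valid)
    X = design.samples[valid]
    y = outputs.loc[valid, target].to_numpy(dtype=float)
    for j, name in enumerate(design.names):
        if len(np.unique(X[:, j])) < 0.5 * n_valid:
            logger.warning("prcc: column %r is >50%% ties (degenerate input)", name)
    if len(np.unique(y)) < 0.5 * n_valid:
        logger.warning("prcc: output %r is >50%% ties (degenerate input)", target)

    Xr = _rank(X)
    yr = _rank(y)
    g = design.K - 1 if method == "partial" else 0
    records = []
    for j, name in enumerate(design.names):
        if method == "partial":
            rho = _partial_corr_residual(Xr, j, yr)
        else:
            rho = float(np.corrcoef(Xr[:, j], yr)[0, 1])
        df_t = n_valid - 2 - g
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt(df_t / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), df_t)
        records.append(
            {
                "parameter": name,
                "output": target,
                "prcc": rho,
                "p_value": p,
                "significant": bool(abs(rho) > RHO_THRESHOLD and p < P_THRESHOLD),
                "N": n_valid,
                "seed": design.seed,
                "dvl": dvl,
                "frame": design.frame(),
                "method": method,
            }
        )
    return pd.DataFrame(records)


def prcc_table(
    design: LHSDesign,
    outputs: pd.DataFrame,
    dvl: float | None = None,
    method: str = "partial",
) -> pd.DataFrame:
    """Rank-correlation table of every parameter against every state variable."""
    frames = [
        prcc(design, outputs, target, dvl=dvl, method=method)
        for target in OUTPUTS[design.frame()]
    ]
    return pd.concat(frames, ignore_index=True)


def significance_report(tables: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Compare significant (parameter, output) pairs across Dvl levels.

    One row per pair that is significant at any level, with a boolean column
    per level and gained/lost annotations relative to the lowest level.
    """
    levels = sorted(tables)
    pairs: set[tuple[str, str]] = set()
    sig: dict[float, set[tuple[str, str]]] = {}
    for lv in levels:
        tbl = tables[lv]
        s = {
            (r.parameter, r.output)
            for r in tbl.itertuples()
            if r.significant
        }
        sig[lv] = s
        pairs |= s
    base = levels[0]
    records = []
    for param, out in sorted(pairs):
        rec: dict[str, object] = {"parameter": param, "output": out}
        for lv in levels:
            rec[f"significant_at_{lv:g}"] = (param, out) in sig[lv]
        in_base = (param, out) in sig[base]
        in_last = (param, out) in sig[levels[-1]]
        rec["change"] = (
            "stable" if in_base == in_last else ("gained" if in_last else "lost")
        )
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def monotonicity_screen(
    design: LHSDesign,
    outputs: pd.DataFrame,
    n_bins: int = 20,
    tol: float = 0.02,
) -> pd.DataFrame:
    """Binned-median monotonicity verdict per (parameter, output) pair.

    Samples are binned by each parameter's quantiles; the output's median
    per bin must be monotone up to a noise tolerance of ``tol`` times the
    median range.  PRCC is only meaningful where this holds.
    """
    valid = ~outputs["failed"].to_numpy(dtype=bool)
    out_names = [c for c in OUTPUTS[design.frame()] if c in outputs]
    records = []
    for j, name in enumerate(design.names):
        x = design.samples[valid, j]
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        for out in out_names:
            y = outputs.loc[valid, out].to_numpy(dtype=float)
            med = np.array([
                np.median(y[idx == k]) for k in range(n_bins) if np.any(idx == k)
            ])
            span = np.ptp(med) if len(med) else 0.0
            diffs = np.diff(med)
            up = np.sum(diffs > tol * span)
            down = np.sum(diffs < -tol * span)
            records.append(
                {
                    "parameter": name,
                    "output": out,
                    "monotone": bool(up == 0 or down == 0),
                    "violations": int(min(up, down)),
                }
            )
    return pd.DataFrame(records)


def input_independence_check(design: LHSDesign) -> pd.DataFrame:
    """Pairwise partial rank correlations among the sampled columns.

    Independently permuted LHS columns should show only sampling noise here
    (|rho| well under 0.05 at N = 1e4); a duplicated column shows up as
    rho = 1.
    """
    Xr = _rank(design.samples)
    K = design.K
    M = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            rest = [k for k in range(K) if k not in (i, j)]
            if rest:
                Z = np.column_stack([np.ones(design.N), Xr[:, rest]])
                bi, *_ = np.linalg.lstsq(Z, Xr[:, i], rcond=None)
                bj, *_ = np.linalg.lstsq(Z, Xr[:, j], rcond=None)
                ri = Xr[:, i] - Z @ bi
                rj = Xr[:, j] - Z @ bj
            else:
                ri = Xr[:, i] - Xr[:, i].mean()
                rj = Xr[:, j] - Xr[:, j].mean()
            denom = np.linalg.norm(ri) * np.linalg.norm(rj)
            rho = 0.0 if denom == 0 else float(np.clip(ri @ rj / denom, -1, 1))
            M[i, j] = M[j, i] = rho
    return pd.DataFrame(M, index=design.names, columns=design.names)
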