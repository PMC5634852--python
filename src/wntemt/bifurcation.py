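"""Equilibrium-branch continuation against Dvl and two-parameter region maps.

The switch's concentration-response structure is a one-sided hysteresis: the
epithelial branch (high E-cadherin) exists from d = 0 up to a saddle-node
fold, while the mesenchymal branch persists for every d >= 0.  Branches are
traced by grid scanning with nearest-state linkage and the folds refined by
bisection on the equilibrium count -- the scalar reduction makes this both
cheap and robust, so no pseudo-arclength continuation is needed.

Region maps classify the (d, parameter) plane: Region I holds only the
epithelial state, Region III only the mesenchymal one, and Region II is the
bistable window between the two fold curves L1 (loss of the mesenchymal
state, moving left) and L2 (loss of the epithelial state, moving right).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import NondimParams
from .simulate import Equilibrium, find_equilibria

#: Bisection stops when the fold is bracketed tighter than this in d.
FOLD_TOL = 1e-4

#: Parameters that a region map may vary along its y axis.
VARIABLE_PARAMS = (
    "A1", "A2", "A3", "C1", "C2", "C3", "F1", "F2", "n1", "n2", "n3", "n4",
)


class FoldNotFoundError(RuntimeError):
    """The equilibrium count does not change inside the given bracket."""


@dataclass
class BifurcationBranch:
    """One equilibrium branch followed along a parameter sweep."""

    parameter: str
    values: list[float]
    equilibria: list[Equilibrium]
    identity: str  # epithelial | mesenchymal | saddle | unlabeled


@dataclass(frozen=True)
class FoldPoints:
    """Fold (saddle-node) locations bounding the bistable window in d.

    ``L1`` is where the mesenchymal branch is lost when d decreases (absent
    when that branch survives down to d = 0, clipping the window there);
    ``L2`` is where the epithelial branch is lost as d increases.
    """

    L1: float | None
    L2: float | None

    @property
    def window(self) -> tuple[float, float] | None:
        if self.L2 is None:
            return None
        return (max(self.L1 or 0.0, 0.0), self.L2)


@dataclass
class RegionMap:
    """Per-cell phenotypic regime over a (d, parameter) grid."""

    vary: str
    d_grid: np.ndarray
    y_grid: np.ndarray
    region: np.ndarray  # shape (len(y_grid), len(d_grid)), values 1|2|3
    L1: list[tuple[float, float]]  # (d, y) polyline, may be empty
    L2: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# Branch sweeps
# ---------------------------------------------------------------------------

def _physical_stable(eqs: list[Equilibrium]) -> list[Equilibrium]:
    return [e for e in eqs if e.stable and not e.nonphysical]


def sweep_branches(
    params: NondimParams,
    d_grid: np.ndarray,
    n_scan: int = 10001,
) -> list[BifurcationBranch]:
    """Trace every equilibrium branch over a monotone grid of Dvl levels.

    Equilibria at adjacent grid points are linked by nearest state in
    (e, b, s); where two candidates fall within 10% of each other's distance
    the grid is refined locally and linkage retried.  Branch identities come
    from the ordering at the first grid point (epithelial = highest e stable,
    mesenchymal = lowest e stable, saddle = unstable point between them).
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.ndim != 1 or len(d_grid) < 2 or np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be a monotone increasing 1-D grid")
    if d_grid[0] < 0:
        raise ValueError("d must be >= 0")

    first = find_equilibria(params, float(d_grid[0]), n_scan=n_scan)
    branches: list[BifurcationBranch] = []
    for eq in first:
        if not eq.stable:
            ident = "saddle"
        elif eq.phenotype != "unlabeled":
            ident = eq.phenotype
        else:
            ident = "unlabeled"
        branches.append(
            BifurcationBranch("d", [float(d_grid[0])], [eq], ident)
        )

    live = list(branches)
    for d in d_grid[1:]:
        eqs = find_equilibria(params, float(d), n_scan=n_scan)
        live = _link_step(live, eqs, float(d), params, n_scan)
    return branches


def _link_step(
    live: list[BifurcationBranch],
    eqs: list[Equilibrium],
    d: float,
    params: NondimParams,
    n_scan: int,
) -> list[BifurcationBranch]:
    """Attach each new equilibrium to the nearest live branch end."""
    states = np.array([eq.state.as_array() for eq in eqs])
    ends = np.array([br.equilibria[-1].state.as_array() for br in live])
    # distance in a log-ish metric so the e ~ 10 and e ~ 0.08 scales both count
    scale = np.maximum(1e-3, np.abs(ends).max(axis=0))
    dist = np.linalg.norm(
        (states[:, None, :] - ends[None, :, :]) / scale, axis=2
    )  # (n_new, n_live)
    still: list[BifurcationBranch] = []
    used: set[int] = set()
    for i in range(len(eqs)):
        order = np.argsort(dist[i])
        j = int(order[0])
        if len(order) > 1 and dist[i, order[1]] < 1.1 * dist[i, j]:
            # ambiguous linkage: resolve with a locally denser scan
            refined = find_equilibria(params, d, n_scan=4 * n_scan)
            if len(refined) == len(eqs):
                eqs[i] = refined[i]
                states_i = refined[i].state.as_array()
                dist_i = np.linalg.norm((states_i - ends) / scale, axis=1)
                j = int(np.argmin(dist_i))
        if j in used:
            # two new points claim one branch end: keep the closer, start none
            prev = next(b for b in still if b is live[j])
            k = prev.values.index(d)
            if dist[i, j] < np.linalg.norm(
                (prev.equilibria[k].state.as_array() - ends[j]) / scale
            ):
                prev.values.pop(k)
                prev.equilibria.pop(k)
            else:
                continue
        live[j].values.append(d)
        live[j].equilibria.append(eqs[i])
        used.add(j)
        if live[j] not in still:
            still.append(live[j])
    return still


def find_fold(
    params: NondimParams,
    bracket: tuple[float, float],
    which_branch: str = "epithelial",
    tol: float = FOLD_TOL,
    n_scan: int = 10001,
) -> float:
    """Locate the saddle-node where a branch is lost, by bisection on the
    number of coexisting equilibria inside ``bracket``.

    The result is cross-checked by requiring a near-fold root pair (merging
    roots of the scalar residual, i.e. vanishing g'(b)) close to the
    returned d.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    n_lo = len(find_equilibria(params, lo, n_scan=n_scan))
    n_hi = len(find_equilibria(params, hi, n_scan=n_scan))
    if n_lo == n_hi:
        raise FoldNotFoundError(
            f"equilibrium count is {n_lo} at both ends of [{lo:g}, {hi:g}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        n_mid = len(find_equilibria(params, mid, n_scan=n_scan))
        if n_mid == n_lo:
            lo = mid
        else:
            hi = mid
    d_fold = 0.5 * (lo + hi)

    # cross-check: just inside the bistable side the merging root pair of
    # g(b) must be close together (g' -> 0 at the fold)
    inside = lo if n_lo == 3 else hi
    eqs = find_equilibria(params, inside, n_scan=n_scan)
    if len(eqs) == 3:
        gaps = [
            abs(eqs[i + 1].state.bcat - eqs[i].state.bcat) for i in range(2)
        ]
        if min(gaps) > 0.5:
            raise FoldNotFoundError(
                f"no merging root pair near d = {d_fold:g}; "
                "count change is not a simple fold"
            )
    return d_fold


def hysteresis_window(
    params: NondimParams, d_max: float = 6.0, n_coarse: int = 121, n_scan: int = 10001
) -> FoldPoints:
    """Fold points bounding the bistable window over d in [0, d_max].

    L2 is found from the loss of the epithelial branch as d grows; L1 is
    absent whenever the mesenchymal branch survives at d = 0 (the window is
    then clipped at 0 -- one-sided hysteresis).  Monostable systems
    return both folds absent.
    """
    ds = np.linspace(0.0, d_max, n_coarse)
    counts = np.array([len(find_equilibria(params, float(d), n_scan=n_scan)) for d in ds])
    L1: float | None = None
    L2: float | None = None
    for i in range(len(ds) - 1):
        if counts[i] == counts[i + 1]:
            continue
        d_fold = find_fold(params, (float(ds[i]), float(ds[i + 1])), n_scan=n_scan)
        if counts[i] < counts[i + 1]:  # bistability appears: mesenchymal fold
            L1 = d_fold
        else:  # bistability lost upward: epithelial fold
            L2 = d_fold
    return FoldPoints(L1=L1, L2=L2)


# ---------------------------------------------------------------------------
# Region maps
# ---------------------------------------------------------------------------

def _continue_label(
    stable_states, bistable_cells, iy: int, id_: int, params, d_grid
) -> int:
    """Region label (1 or 3) of a monostable cell in a row with no bistable
    interval, by matching its unique stable state to the epithelial /
    mesenchymal pair of the nearest bistable cell (same d column preferred)."""
    state = stable_states[iy][id_][0]
    if len(bistable_cells):
        same_col = bistable_cells[bistable_cells[:, 1] == id_]
        pool = same_col if len(same_col) else bistable_cells
        dist = np.abs(pool - [iy, id_]).sum(axis=1)
        ry, rd = pool[int(np.argmin(dist))]
        pair = stable_states[ry][rd]
    else:
        # no bistable cell anywhere on the map: anchor on the unvaried
        # parameters at d = 0 if those are bistable
        eqs = find_equilibria(params, float(d_grid[0]))
        pair = [e.state.as_array() for e in _physical_stable(eqs)]
        if len(pair) != 2:
            raise RuntimeError(
                "monostable everywhere and no bistable anchor available; "
                "cannot assign Region I/III labels by continuation"
            )
    # epithelial anchor = higher-e member of the pair
    pair = sorted(pair, key=lambda y: y[0])
    mes_anchor, epi_anchor = pair[0], pair[1]
    scale = np.maximum(1e-3, np.maximum(np.abs(mes_anchor), np.abs(epi_anchor)))
    d_epi = np.linalg.norm((state - epi_anchor) / scale)
    d_mes = np.linalg.norm((state - mes_anchor) / scale)
    return 1 if d_epi < d_mes else 3


def region_map(
    params: NondimParams,
    vary: str,
    y_grid: np.ndarray,
    d_grid: np.ndarray,
    n_scan: int = 2001,
) -> RegionMap:
    """Classify the (d, ``vary``) plane into Regions I / II / III.

    For each y the named parameter is substituted and the count of stable
    *physical* (b >= 0) equilibria computed across the d grid: two stable
    states mean Region II.  Monostable cells in a row that has a bistable
    interval take their identity from which side of it they lie on (left of
    L1 -> I, right of L2 -> III).  Rows with no bistable cell are labeled by
    branch continuation: each cell's unique stable state is matched against
    the epithelial/mesenchymal pair of the nearest bistable cell (same d
    column preferred), so labels stay consistent where the absolute
    E-cadherin scale changes with the parameter -- no fixed concentration
    threshold is ever applied.
    """
    if vary not in VARIABLE_PARAMS:
        raise ValueError(f"cannot vary {vary!r}; choose one of {VARIABLE_PARAMS}")
    y_grid = np.asarray(y_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(np.diff(y_grid) <= 0) or np.any(np.diff(d_grid) <= 0):
        raise ValueError("grids must be strictly increasing")

    ny, nd = len(y_grid), len(d_grid)
    stable_count = np.zeros((ny, nd), dtype=int)
    stable_states: list[list[list[np.ndarray]]] = []
    for iy, y in enumerate(y_grid):
        q = replace(params, **{vary: float(y)})
        row_states: list[list[np.ndarray]] = []
        for id_, d in enumerate(d_grid):
            eqs = find_equilibria(q, float(d), n_scan=n_scan)
            phys = _physical_stable(eqs)
            if len(phys) > 2:
                raise RuntimeError(
                    f"{len(phys)} stable equilibria at {vary}={y:g}, d={d:g}: "
                    "outside this model class"
                )
            stable_count[iy, id_] = len(phys)
            if not phys:
                # only nonphysical stable states here: keep them for the
                # continuation metric, but they never count toward Region II
                phys = [e for e in eqs if e.stable]
            row_states.append([e.state.as_array() for e in phys])
        stable_states.append(row_states)

    region = np.zeros((ny, nd), dtype=int)
    region[stable_count == 2] = 2
    # fold interval per row: [first II cell, last II cell] in d-index space
    intervals: dict[int, tuple[int, int]] = {}
    for iy in range(ny):
        ii = np.flatnonzero(stable_count[iy] == 2)
        if len(ii):
            intervals[iy] = (int(ii[0]), int(ii[-1]))

    bistable_cells = np.argwhere(stable_count == 2)
    for iy in range(ny):
        if iy in intervals:
            # side rule relative to this row's own fold interval
            lo, hi = intervals[iy]
            for id_ in range(nd):
                if region[iy, id_] == 2:
                    continue
                if id_ < lo:
                    region[iy, id_] = 1
                elif id_ > hi:
                    region[iy, id_] = 3
                else:
                    region[iy, id_] = 1 if (id_ - lo) <= (hi - id_) else 3
        else:
            for id_ in range(nd):
                region[iy, id_] = _continue_label(
                    stable_states, bistable_cells, iy, id_, params, d_grid
                )

    L1_line: list[tuple[float, float]] = []
    L2_line: list[tuple[float, float]] = []
    for iy, (lo, hi) in sorted(intervals.items()):
        if lo > 0:
            L1_line.append((float(d_grid[lo]), float(y_grid[iy])))
        if hi < nd - 1:
            L2_line.append((float(d_grid[hi]), float(y_grid[iy])))
    return RegionMap(
        vary=vary, d_grid=d_grid, y_grid=y_grid, region=region,
        L1=L1_line, L2=L2_line,
    )
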