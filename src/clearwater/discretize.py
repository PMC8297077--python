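"""Min–max normalization and 3-state hierarchical discretization.

Each continuous variable is scaled to [0, 1] and cut into three ordered
states by divisive 1-D clustering: the pair of cut points minimizing total
within-bin variance (sum of squared deviations from bin means). The optimum
is found exactly by dynamic programming over the sorted values — for three
bins this coincides with exhaustive enumeration of all two-cut partitions —
so the mapping is deterministic for a fixed input. Equal-frequency binning
is available as a fallback dialect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DiscretizationError(ValueError):
    pass


@dataclass
class DiscretizationMap:
    """Bin edges for one variable plus the min/max used to normalize."""

    variable: str
    edges: tuple[float, ...]   # len = bins-1, strictly increasing, on the normalized scale
    vmin: float
    vmax: float

    @property
    def n_states(self) -> int:
        return len(self.edges) + 1

    def normalize(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.vmin) / (self.vmax - self.vmin)

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Map raw values to integer states 0..n_states-1."""
        return np.searchsorted(self.edges, self.normalize(values), side="right").astype(np.int8)


def minmax_normalize(values: np.ndarray, variable: str = "") -> tuple[np.ndarray, float, float]:
    """(x - min) / (max - min); raises naming the variable if constant."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise DiscretizationError(f"variable {variable!r}: no observed values")
    vmin, vmax = float(x.min()), float(x.max())
    if vmin == vmax:
        raise DiscretizationError(
            f"variable {variable!r} is constant and cannot be normalized"
        )
    return (np.asarray(values, dtype=float) - vmin) / (vmax - vmin), vmin, vmax


def _optimal_cuts(sorted_vals: np.ndarray, bins: int) -> list[int]:
    """Exact minimum-SSE partition of sorted values into ``bins`` contiguous
    groups (O(bins * m^2) dynamic program). Returns the start index of each
    bin after the first."""
    m = len(sorted_vals)
    pref = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    pref2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def sse(i: int, j: int) -> float:
        # SSE of sorted_vals[i:j]
        n = j - i
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / n

    INF = float("inf")
    cost = np.full((bins + 1, m + 1), INF)
    split = np.zeros((bins + 1, m + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, bins + 1):
        for j in range(k, m + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + sse(i, j)
                if c < best - 1e-15:   # strict improvement; ties keep leftmost
                    best, arg = c, i
            cost[k, j] = best
            split[k, j] = arg
    # recover bin starts
    starts = []
    j = m
    for k in range(bins, 0, -1):
        i = split[k, j]
        starts.append(i)
        j = i
    starts.reverse()
    return starts[1:]   # drop the leading 0


def hierarchical_discretize(
    values: np.ndarray,
    bins: int = 3,
    variable: str = "",
    method: str = "hierarchical",
) -> tuple[DiscretizationMap, np.ndarray]:
    """Discretize one variable into ``bins`` ordered states.

    Returns the DiscretizationMap and the state labels of the non-missing
    input values. ``method`` is "hierarchical" (variance-minimizing
    divisive clustering, the default) or "equal_frequency".
    """
    raw = np.asarray(values, dtype=float)
    norm, vmin, vmax = minmax_normalize(raw, variable)
    x = norm[~np.isnan(norm)]
    if len(np.unique(x)) < bins:
        raise DiscretizationError(
            f"variable {variable!r}: need >= {bins} distinct values"
        )
    xs = np.sort(x)
    if method == "hierarchical":
        starts = _optimal_cuts(xs, bins)
        edges = tuple((xs[i - 1] + xs[i]) / 2.0 for i in starts)
    elif method == "equal_frequency":
        qs = np.quantile(xs, [k / bins for k in range(1, bins)])
        edges = tuple(float(q) for q in qs)
        if len(set(edges)) != bins - 1:
            raise DiscretizationError(
                f"variable {variable!r}: ties defeat equal-frequency binning"
            )
    else:
        raise DiscretizationError(f"unknown method {method!r}")
    dmap = DiscretizationMap(variable=variable, edges=edges, vmin=vmin, vmax=vmax)
    return dmap, dmap.apply(raw[~np.isnan(raw)])


def discretize_frame(
    df: pd.DataFrame,
    variables: list[str] | None = None,
    bins: int = 3,
    method: str = "hierarchical",
) -> tuple[pd.DataFrame, dict[str, DiscretizationMap]]:
    """Complete-case discretization of the given columns.

    Rows with any missing modeled variable are dropped; each remaining
    column is min-max normalized and cut into ``bins`` states.
    """
    variables = variables or list(df.columns)
    sub = df[variables].dropna()
    states = {}
    maps = {}
    for v in variables:
        dmap, _ = hierarchical_discretize(
            sub[v].to_numpy(float), bins=bins, variable=v, method=method
        )
        maps[v] = dmap
        states[v] = dmap.apply(sub[v].to_numpy(float))
    return pd.DataFrame(states, index=sub.index), maps
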