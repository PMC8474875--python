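"""IsomiR co-expression network from Spearman correlation on non-zero
sample intersections, with the edge/node selection and group-enrichment
rules of the screening pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationEdge:
    key_a: str
    key_b: str
    rho: float
    n_overlap: int
    p: float
    z: float = math.nan
    selected: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def spearman_nonzero(
    vec_a: np.ndarray,
    vec_b: np.ndarray,
    min_overlap: int = 3,
) -> tuple[float, int, float]:
    """Spearman rho restricted to indices where both vectors are nonzero.

    Because zeros are dropped pairwise, different pairs are evaluated on
    different sample counts. Returns (rho, n_overlap, p); rho and p are
    NaN (flagged undefined, not an error) when the overlap is below
    ``min_overlap`` or either restricted vector is constant. The p-value
    uses the t approximation on n_overlap - 2 df.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    mask = (a != 0) & (b != 0)
    n = int(mask.sum())
    if n < min_overlap:
        return math.nan, n, math.nan
    ra = stats.rankdata(a[mask], method="average")
    rb = stats.rankdata(b[mask], method="average")
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        return math.nan, n, math.nan
    rho = float(np.corrcoef(ra, rb)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:  # exact rank agreement up to float error
        return float(np.sign(rho)), n, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, n, float(p)


def correlation_edges(
    matrix: pd.DataFrame,
    keys: list[str] | None = None,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """All pairwise non-zero-intersection Spearman correlations."""
    keys = list(keys) if keys is not None else list(matrix.index)
    rows = []
    data = {k: matrix.loc[k].to_numpy(dtype=float) for k in keys}
    for ka, kb in combinations(keys, 2):
        rho, n, p = spearman_nonzero(data[ka], data[kb], min_overlap)
        rows.append({"key_a": ka, "key_b": kb, "rho": rho, "n_overlap": n, "p": p})
    return pd.DataFrame(rows, columns=["key_a", "key_b", "rho", "n_overlap", "p"])


def classify_pairs_correlation(
    edges: pd.DataFrame,
    classes: dict[str, str],
    z_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize rho over the evaluated pair set and test group enrichment.

    z = (rho - mean rho) / sd rho over all defined edges passed in.
    Significant-positive edges have z > z_threshold, significant-negative
    z < -z_threshold. For each group-pair label (derived from the two
    endpoint classes) the proportion of significant edges in each
    direction is tested against the pooled remainder by a right-tailed
    Fisher's exact test.
    """
    edges = edges.copy()
    defined = edges["rho"].notna()
    rho = edges.loc[defined, "rho"]
    if len(rho) < 2:
        raise ValueError("need at least 2 defined edges")
    sd = rho.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate edge set: all rho equal (sd = 0)")
    edges["z"] = (edges["rho"] - rho.mean()) / sd
    edges["sig_pos"] = defined & (edges["z"] > z_threshold)
    edges["sig_neg"] = defined & (edges["z"] < -z_threshold)

    def group_label(row) -> str:
        ca = classes.get(row["key_a"], "other")
        cb = classes.get(row["key_b"], "other")
        return "-".join(sorted([ca, cb]))

    edges["group_pair"] = edges.apply(group_label, axis=1)

    rows = []
    for grp, sub in edges[defined].groupby("group_pair"):
        rest = edges[defined & (edges["group_pair"] != grp)]
        row = {
            "group_pair": grp,
            "n_total": len(sub),
            "n_sig_pos": int(sub["sig_pos"].sum()),
            "n_sig_neg": int(sub["sig_neg"].sum()),
        }
        for direction in ("pos", "neg"):
            k_in = int(sub[f"sig_{direction}"].sum())
            k_out = int(rest[f"sig_{direction}"].sum()) if len(rest) else 0
            table = [[k_in, len(sub) - k_in], [k_out, len(rest) - k_out]]
            _, p = stats.fisher_exact(table, alternative="greater")
            row[f"fisher_p_{direction}"] = p
        rows.append(row)
    enrich = pd.DataFrame(
        rows,
        columns=["group_pair", "n_total", "n_sig_pos", "n_sig_neg", "fisher_p_pos", "fisher_p_neg"],
    )
    return edges, enrich


def select_edges(
    edges: pd.DataFrame,
    top_fraction: float = 0.05,
    min_degree: int = 2,
) -> nx.Graph:
    """Positive-rho edges in both top-fraction lists, degree-pruned.

    An edge survives when rho > 0 and it lies simultaneously in the top
    ``top_fraction`` of defined edges by largest rho and by smallest p
    (boundary ties included). Nodes with degree < ``min_degree`` are then
    removed iteratively to a fixed point, together with their edges.
    """
    g = nx.Graph()
    defined = edges[edges["rho"].notna()].copy()
    if defined.empty:
        return g
    k = max(1, math.ceil(top_fraction * len(defined)))
    rho_cut = defined["rho"].nlargest(k).iloc[-1]
    p_cut = defined["p"].nsmallest(k).iloc[-1]
    sel = defined[(defined["rho"] > 0) & (defined["rho"] >= rho_cut) & (defined["p"] <= p_cut)]
    for row in sel.itertuples(index=False):
        g.add_edge(row.key_a, row.key_b, rho=row.rho, p=row.p)
    while True:
        weak = [n for n, d in g.degree() if d < min_degree]
        if not weak:
            break
        g.remove_nodes_from(weak)
    return g
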