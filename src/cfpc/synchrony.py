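"""Population synchrony: pairwise correlation matrices, ROI merging, and the
synchrony-versus-mediolateral-distance relationship.

CF populations fire highly synchronously within a mediolateral imaging field,
with a weak decline of pairwise correlation over mediolateral separation. ROIs
that sit in the same parasagittal plane (~20 um mediolaterally) and correlate
above 0.85 are treated as fragments of one varicosity and merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import TraceMatrix, make_roi_table

__all__ = [
    "correlation_matrix",
    "merge_correlated_rois",
    "synchrony_vs_distance",
    "DistanceFit",
]


def correlation_matrix(z: TraceMatrix) -> pd.DataFrame:
    """Pearson correlation of every ROI pair over the full trace.

    Returns a symmetric DataFrame (unit diagonal) indexed by roi_id.
    """
    if z.n_rois < 2:
        raise ValueError("correlation_matrix needs >= 2 ROIs")
    sd = z.values.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance ROI trace(s): {[z.roi_ids[i] for i in bad]}")
    c = np.corrcoef(z.values)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=z.roi_ids, columns=z.roi_ids)


def merge_correlated_rois(
    z: TraceMatrix,
    rois: pd.DataFrame,
    r_thresh: float = 0.85,
    plane_window_um: float = 20.0,
) -> tuple[TraceMatrix, pd.DataFrame]:
    """Merge ROI fragments: pairs in the same parasagittal plane (mediolateral
    separation <= ``plane_window_um``) with correlation >= ``r_thresh`` are
    merged under transitive closure.

    The merged trace is the mean of the member traces re-z-scored; the merged
    centroid is the member mean. Input ROI order does not affect the grouping.
    """
    if z.n_rois != len(rois):
        raise ValueError("trace matrix and ROI table must describe the same ROIs")
    if z.n_rois == 1:
        return z, rois.copy()
    corr = correlation_matrix(z).to_numpy()
    x = rois["x_um"].to_numpy()
    adj = (corr >= r_thresh) & (np.abs(x[:, None] - x[None, :]) <= plane_window_um)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    new_vals, new_ids, xs, ys, rads = [], [], [], [], []
    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        mean_trace = z.values[members].mean(axis=0)
        sd = mean_trace.std()
        if sd == 0:
            raise ValueError("merged trace has zero variance")
        new_vals.append((mean_trace - mean_trace.mean()) / sd)
        new_ids.append("+".join(rois["roi_id"].iloc[members]))
        xs.append(float(rois["x_um"].iloc[members].mean()))
        ys.append(float(rois["y_um"].iloc[members].mean()))
        rads.append(float(rois["radius_um"].iloc[members].mean()))

    merged = TraceMatrix(np.vstack(new_vals), fs=z.fs, units="SD",
                         channel=z.channel, roi_ids=new_ids)
    table = make_roi_table(new_ids, np.array(xs), np.array(ys), np.array(rads),
                           channel=str(rois["channel"].iloc[0]))
    return merged, table


@dataclass
class DistanceFit:
    """OLS fit of pairwise correlation on mediolateral distance."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    degenerate: bool = False

    def summary(self) -> str:
        tag = " (zero-variance correlations; fit degenerate)" if self.degenerate else ""
        return (
            f"Synchrony vs mediolateral distance: n = {self.n_pairs} pairs, "
            f"slope = {self.slope:.3e} /um, intercept = {self.intercept:.3f}, "
            f"R^2 = {self.r_squared:.3f}{tag}"
        )


def synchrony_vs_distance(
    corr: pd.DataFrame, rois: pd.DataFrame
) -> tuple[pd.DataFrame, DistanceFit]:
    """Pair table (|mediolateral distance|, r) for every unordered ROI pair,
    with an ordinary least-squares fit of r on distance.

    Distance uses only the mediolateral (x) coordinate.
    """
    ids = list(corr.index)
    if len(ids) < 3:
        raise ValueError("synchrony_vs_distance needs >= 3 ROIs")
    xpos = rois.set_index("roi_id")["x_um"]
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append(
                {"roi_a": ids[i], "roi_b": ids[j],
                 "dist_um": abs(float(xpos[ids[i]]) - float(xpos[ids[j]])),
                 "r": float(corr.iloc[i, j])}
            )
    pairs = pd.DataFrame(rows)
    d = pairs["dist_um"].to_numpy()
    r = pairs["r"].to_numpy()
    if np.ptp(r) == 0 or np.ptp(d) == 0:
        fit = DistanceFit(0.0, float(r.mean()), 0.0, len(pairs), degenerate=True)
    else:
        res = stats.linregress(d, r)
        fit = DistanceFit(float(res.slope), float(res.intercept),
                          float(res.rvalue**2), len(pairs))
    return pairs, fit
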