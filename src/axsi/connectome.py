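"""Streamline weighting, connectome assembly, and callosal statistics.

Each tractography streamline is weighted by the mean eMAD of the voxels it
traverses; streamlines are then binned by the atlas labels of their
endpoints into symmetric node-by-node matrices weighted either by mean ADD
or by streamline count. Group averaging uses median-absolute-deviation
outlier exclusion per edge. The corpus-callosum layer segments a
midsagittal mask into the five Witelson-style sections (genu, anterior /
mid / posterior body, splenium) and compares sections with a
repeated-measures ANOVA plus Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ttest_rel
from statsmodels.stats.anova import AnovaRM

from axsi.maps import streamline_voxels

log = logging.getLogger(__name__)

#: MAD threshold in robust (1.4826-scaled) units
DEFAULT_MAD_THRESHOLD = 2.5

#: consistency factor making MAD estimate the normal sigma
MAD_SCALE = 1.4826

#: endpoints are matched to the nearest labeled atlas voxel within this (mm)
ENDPOINT_TOLERANCE_MM = 2.0

SECTION_NAMES = ("Genu", "Anterior Body", "Mid Body", "Posterior Body",
                 "Splenium")
#: anterior -> posterior fractional boundaries between the five sections
SECTION_BOUNDARIES = (1.0 / 3.0, 1.0 / 2.0, 2.0 / 3.0, 4.0 / 5.0)


@dataclass
class WeightedTractogram:
    """Streamlines with their per-streamline ADD (um) and endpoint labels."""

    streamlines: list
    add: np.ndarray                 # NaN where no traversed voxel had eMAD
    endpoint_labels: np.ndarray | None = None  # (n, 2) atlas ids, 0 = unassigned
    n_outside: int = 0              # streamlines entirely outside the volume


@dataclass
class ConnectomeMatrix:
    """Symmetric edge table over atlas nodes.

    add_weight holds the mean streamline ADD per node pair and is NaN where
    count_weight is 0; count_weight counts all connecting streamlines,
    including those whose own ADD was undefined.
    """

    labels: np.ndarray
    add_weight: np.ndarray
    count_weight: np.ndarray
    n_unassigned: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.add_weight, index=self.labels,
                            columns=self.labels)


def weight_streamlines(streamlines, emad_map: np.ndarray,
                       affine: np.ndarray) -> WeightedTractogram:
    """Average eMAD over each streamline's unique traversed voxel set.

    Revisited voxels count once; voxels with undefined eMAD are ignored in
    the average. A streamline entirely outside the volume (or meeting only
    undefined voxels) gets NaN.
    """
    shape = emad_map.shape
    add = np.full(len(streamlines), np.nan)
    n_outside = 0
    for i, sl in enumerate(streamlines):
        vox = streamline_voxels(sl, affine, shape)
        if not vox.size:
            n_outside += 1
            continue
        vals = emad_map[vox[:, 0], vox[:, 1], vox[:, 2]]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            add[i] = vals.mean()
    if n_outside:
        log.warning("%d streamlines entirely outside the volume", n_outside)
    return WeightedTractogram(streamlines=list(streamlines), add=add,
                              n_outside=n_outside)


def _assign_endpoints(streamlines, atlas: np.ndarray,
                      affine: np.ndarray,
                      tolerance_mm: float) -> np.ndarray:
    """Atlas label per streamline endpoint; 0 when no label within tolerance."""
    labeled = np.argwhere(atlas > 0)
    if not labeled.size:
        return np.zeros((len(streamlines), 2), dtype=int)
    centers = labeled @ affine[:3, :3].T + affine[:3, 3]
    tree = cKDTree(centers)
    ends = np.array([[sl[0], sl[-1]] for sl in streamlines], dtype=float)
    ends_flat = ends.reshape(-1, 3)
    dist, idx = tree.query(ends_flat, distance_upper_bound=tolerance_mm)
    labels = np.zeros(len(ends_flat), dtype=int)
    ok = np.isfinite(dist)
    vi = labeled[idx[ok]]
    labels[ok] = atlas[vi[:, 0], vi[:, 1], vi[:, 2]]
    return labels.reshape(-1, 2)


def build_connectome(tractogram: WeightedTractogram, atlas: np.ndarray,
                     affine: np.ndarray,
                     tolerance_mm: float = ENDPOINT_TOLERANCE_MM
                     ) -> ConnectomeMatrix:
    """Bin streamlines into node-pair edges by their endpoint atlas labels.

    Edges are weighted by the mean ADD of connecting streamlines (NaN-ADD
    streamlines are counted but excluded from the average) and by streamline
    count. Self-connections land on the diagonal. Streamlines with an
    unlabeled endpoint are tallied as unassigned.
    """
    atlas = np.asarray(atlas)
    labels = np.unique(atlas[atlas > 0])
    n = labels.size
    index = {int(lab): i for i, lab in enumerate(labels)}
    add_sum = np.zeros((n, n))
    add_cnt = np.zeros((n, n), dtype=int)
    count = np.zeros((n, n), dtype=int)
    ep = _assign_endpoints(tractogram.streamlines, atlas, affine, tolerance_mm)
    n_unassigned = 0
    for (la, lb), add in zip(ep, tractogram.add):
        if la == 0 or lb == 0:
            n_unassigned += 1
            continue
        i, j = index[int(la)], index[int(lb)]
        i, j = min(i, j), max(i, j)
        count[i, j] += 1
        if np.isfinite(add):
            add_sum[i, j] += add
            add_cnt[i, j] += 1
    count = count + np.triu(count, 1).T
    add_sum = add_sum + np.triu(add_sum, 1).T
    add_cnt = add_cnt + np.triu(add_cnt, 1).T
    add_weight = np.full((n, n), np.nan)
    has = add_cnt > 0
    add_weight[has] = add_sum[has] / add_cnt[has]
    if n_unassigned:
        log.info("%d streamlines unassigned to atlas nodes", n_unassigned)
    return ConnectomeMatrix(labels=labels, add_weight=add_weight,
                            count_weight=count, n_unassigned=n_unassigned)


def mad_outlier_mask(values: np.ndarray,
                     threshold: float = DEFAULT_MAD_THRESHOLD) -> np.ndarray:
    """Keep-mask from median-absolute-deviation outlier detection.

    Keeps x iff |x - median| <= threshold * 1.4826 * MAD. When MAD is 0 the
    rule degenerates: only values equal to the median are kept. With fewer
    than 3 finite values all finite values are kept (with a warning).
    Non-finite entries are never kept.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    keep = finite.copy()
    if finite.sum() < 3:
        log.warning("fewer than 3 finite values; MAD exclusion skipped")
        return keep
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    if mad == 0:
        keep &= (x == med)
    else:
        keep &= np.abs(x - med) <= threshold * MAD_SCALE * mad
    return keep


def group_average_connectome(connectomes: list[ConnectomeMatrix],
                             threshold: float = DEFAULT_MAD_THRESHOLD
                             ) -> ConnectomeMatrix:
    """Edge-wise group mean with MAD outlier exclusion.

    Per edge, subject values where the edge exists (count > 0 and ADD
    defined) are pooled, MAD-masked, and averaged; an edge defined in no
    subject stays undefined. Counts are summed across subjects.
    """
    if not connectomes:
        raise ValueError("need at least one connectome")
    labels = connectomes[0].labels
    for c in connectomes[1:]:
        if not np.array_equal(c.labels, labels):
            raise ValueError("connectomes use different node label sets")
    n = labels.size
    add = np.full((n, n), np.nan)
    stack = np.stack([c.add_weight for c in connectomes])       # (s, n, n)
    counts = np.stack([c.count_weight for c in connectomes])
    defined = np.isfinite(stack) & (counts > 0)
    for i in range(n):
        for j in range(i, n):
            vals = stack[defined[:, i, j], i, j]
            if not vals.size:
                continue
            kept = vals[mad_outlier_mask(vals, threshold)]
            if kept.size:
                add[i, j] = add[j, i] = kept.mean()
    return ConnectomeMatrix(labels=labels, add_weight=add,
                            count_weight=counts.sum(axis=0))


def node_mean_add(connectome: ConnectomeMatrix,
                  count_weighted: bool = False) -> np.ndarray:
    """Mean ADD of edges incident on each node (self-connections excluded).

    With ``count_weighted`` the mean is taken over streamlines rather than
    edges: each incident edge contributes with its streamline count.
    """
    A = connectome.add_weight
    C = connectome.count_weight
    n = A.shape[0]
    out = np.full(n, np.nan)
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        sel = off[i] & np.isfinite(A[i])
        if not sel.any():
            continue
        if count_weighted:
            w = C[i, sel].astype(float)
            if w.sum() > 0:
                out[i] = float((A[i, sel] * w).sum() / w.sum())
        else:
            out[i] = float(A[i, sel].mean())
    return out


def _ap_axis_from_affine(affine: np.ndarray) -> tuple[int, bool]:
    """Voxel axis most aligned with world anterior-posterior (+y = anterior).

    Returns (axis, anterior_is_high_index).
    """
    R = np.asarray(affine)[:3, :3]
    y_comp = R[1, :]
    axis = int(np.argmax(np.abs(y_comp)))
    return axis, bool(y_comp[axis] > 0)


def witelson_sections(cc_mask: np.ndarray,
                      affine: np.ndarray | None = None,
                      ap_axis: int | None = None,
                      anterior_is_high_index: bool = True) -> np.ndarray:
    """Segment a midsagittal corpus-callosum mask into 5 sections.

    Labels 1..5 (genu, anterior body, mid body, posterior body, splenium)
    are assigned by each voxel's fractional position along the
    anterior-posterior extent of the mask, with boundaries at 1/3, 1/2, 2/3
    and 4/5 of the extent. Intervals are half-open closed on the anterior
    side, so a voxel exactly on a boundary falls in the posterior section.
    The AP axis is read from the affine unless given explicitly.
    """
    cc_mask = np.asarray(cc_mask, dtype=bool)
    if not cc_mask.any():
        raise ValueError("empty corpus-callosum mask")
    if ap_axis is None:
        if affine is None:
            raise ValueError("need an affine or an explicit AP axis")
        ap_axis, anterior_is_high_index = _ap_axis_from_affine(affine)
    coords = np.argwhere(cc_mask)
    pos = coords[:, ap_axis].astype(float)
    lo, hi = pos.min(), pos.max()
    if hi - lo + 1 < 5:
        raise ValueError(
            f"mask spans only {int(hi - lo + 1)} voxels along the AP axis; "
            "need at least 5")
    frac = (hi - pos) / (hi - lo) if anterior_is_high_index \
        else (pos - lo) / (hi - lo)  # 0 = anterior, 1 = posterior
    section = np.searchsorted(SECTION_BOUNDARIES, frac, side="right") + 1
    out = np.zeros(cc_mask.shape, dtype=np.int16)
    out[tuple(coords.T)] = section
    return out


@dataclass
class SectionStats:
    """Repeated-measures ANOVA and paired post-hoc results over sections."""

    f_value: float
    p_value: float
    df_num: float
    df_den: float
    pairwise: pd.DataFrame  # columns: section_a, section_b, t, p_raw, p_bonferroni


def cc_section_stats(table: pd.DataFrame) -> SectionStats:
    """Compare eMAD across the five callosal sections within subjects.

    ``table`` is subjects x sections (one column per section, complete
    cases). Runs a one-way repeated-measures ANOVA over sections, then all
    C(5,2) = 10 paired t-tests with Bonferroni correction (p * 10, capped
    at 1). A positive t for the pair (a, b) means section a > section b.
    """
    if table.isna().any().any():
        raise ValueError("section table must be complete (no NaN)")
    sections = list(table.columns)
    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="section", value_name="value")
    if np.allclose(table.to_numpy().std(axis=0), 0) or \
            np.allclose(table.sub(table.mean(axis=1), axis=0).std(), 0):
        # degenerate: identical columns give a 0/0 F ratio
        f_val, p_val = 0.0, 1.0
        df_num = float(len(sections) - 1)
        df_den = float((len(table) - 1) * (len(sections) - 1))
    else:
        res = AnovaRM(long, depvar="value", subject="subject",
                      within=["section"]).fit()
        row = res.anova_table.iloc[0]
        f_val = float(row["F Value"])
        p_val = float(row["Pr > F"])
        df_num = float(row["Num DF"])
        df_den = float(row["Den DF"])

    n_pairs = len(list(combinations(sections, 2)))
    rows = []
    for a, b in combinations(sections, 2):
        diff = table[a] - table[b]
        if np.allclose(diff.std(), 0):
            t, p = 0.0, 1.0
        else:
            t, p = ttest_rel(table[a], table[b])
        rows.append({"section_a": a, "section_b": b, "t": float(t),
                     "p_raw": float(p),
                     "p_bonferroni": min(float(p) * n_pairs, 1.0)})
    return SectionStats(f_value=f_val, p_value=p_val, df_num=df_num,
                        df_den=df_den, pairwise=pd.DataFrame(rows))
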