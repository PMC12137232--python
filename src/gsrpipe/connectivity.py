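"""Functional connectivity: network-averaged series, Pearson matrices,
Fisher-Z transforms, and paired baseline-vs-unconscious edge contrasts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme
from .preprocess import PreprocessedRecording
from .bayes import jzs_bf_paired, bf10_from_t


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Pearson correlation matrix with zero diagonal."""

    values: np.ndarray
    labels: list[str]
    level: str                      # "network17" or "roi114"
    z_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("matrix/label shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if self.z_values is None:
            with np.errstate(divide="ignore"):
                z = np.arctanh(np.clip(v, -1.0, 1.0))
            np.fill_diagonal(z, 0.0)
            object.__setattr__(self, "z_values", z)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels
                     ).to_csv(path, sep="\t", float_format="%.6g")


def network_timeseries(pre: PreprocessedRecording, scheme: ParcellationScheme,
                       level: str = "network17") -> tuple[np.ndarray, list[str]]:
    """Average unit series into ROI (114) or network (17) series.

    Voxel labels 'ROI###_v#' collapse onto their ROI; ROI series collapse
    onto their network by unweighted means.
    """
    roi_labels = scheme.roi_labels
    roi_pos = {r: i for i, r in enumerate(roi_labels)}
    rois = pre.roi_of_unit
    unknown = sorted(set(rois) - set(roi_labels))
    if unknown:
        raise ValueError(f"unit labels outside the parcellation: {unknown[:5]}")
    n_t = pre.data.shape[0]
    roi_ts = np.zeros((n_t, len(roi_labels)))
    counts = np.zeros(len(roi_labels))
    for j, r in enumerate(rois):
        roi_ts[:, roi_pos[r]] += pre.data[:, j]
        counts[roi_pos[r]] += 1
    if np.any(counts == 0):
        empty = [r for r, c in zip(roi_labels, counts) if c == 0]
        raise ValueError(f"ROIs without any unit: {empty[:5]}")
    roi_ts /= counts
    if level == "roi114":
        return roi_ts, list(roi_labels)
    if level != "network17":
        raise ValueError("level must be 'network17' or 'roi114'")
    nets = scheme.networks
    net_of = scheme.network_of_roi()
    out = np.column_stack([
        roi_ts[:, [roi_pos[r] for r in roi_labels if net_of[r] == net]].mean(axis=1)
        for net in nets])
    return out, list(nets)


def fc_matrix(ts: np.ndarray, labels: list[str], level: str = "network17"
              ) -> FCMatrix:
    """Pearson correlation matrix of the columns, diagonal zeroed."""
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlations")
    sds = ts.std(axis=0)
    tiny = sds <= 1e-12 * (np.abs(ts).max(axis=0) + 1.0)
    if np.any(tiny):
        zero = [l for l, t in zip(labels, tiny) if t]
        raise ValueError(f"zero-variance series: {zero}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return FCMatrix(values=r, labels=list(labels), level=level)


def mean_fc(matrices: list[FCMatrix]) -> FCMatrix:
    """Group-average FC: mean on the Fisher-Z scale, back-transformed."""
    z = np.mean([m.z_values for m in matrices], axis=0)
    r = np.tanh(z)
    np.fill_diagonal(r, 0.0)
    return FCMatrix(values=r, labels=list(matrices[0].labels),
                    level=matrices[0].level)


def state_contrast(baseline: list[FCMatrix], unconscious: list[FCMatrix],
                   subject_ids: list[str] | None = None,
                   bf_threshold: float = 3.0, cauchy_scale: float = 0.707
                   ) -> pd.DataFrame:
    """Edge-wise paired contrast between states.

    Per edge: ``delta_r`` = mean baseline r minus mean unconscious r (on
    the correlation scale); the Bayes factor comes from the paired JZS
    test on the Fisher-Z values.  Rows are the upper-triangle edges.
    """
    if len(baseline) != len(unconscious):
        raise ValueError("states must have equal, paired subject counts")
    labels = baseline[0].labels
    for m in baseline + unconscious:
        if m.labels != labels:
            raise ValueError("all matrices must share labels")
    rb = np.stack([m.values for m in baseline])       # subj x k x k
    ru = np.stack([m.values for m in unconscious])
    zb = np.stack([m.z_values for m in baseline])
    zu = np.stack([m.z_values for m in unconscious])
    k = len(labels)
    rows = []
    n = rb.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            diffs = zb[:, i, j] - zu[:, i, j]
            if np.all(diffs == 0):
                # exactly identical states: null-favoring evidence at t = 0
                bf = bf10_from_t(0.0, n, cauchy_scale)
                row = {"t": 0.0, "bf10": bf, "delta_median": 0.0,
                       "ci_lo": 0.0, "ci_hi": 0.0,
                       "significant": bool(bf > bf_threshold)}
            else:
                res = jzs_bf_paired(zb[:, i, j], zu[:, i, j], r=cauchy_scale)
                row = {"t": res.t_stat, "bf10": res.bf10,
                       "delta_median": res.delta_median,
                       "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                       "significant": bool(res.bf10 > bf_threshold)}
            rows.append({
                "edge_i": labels[i], "edge_j": labels[j],
                "delta_r": float(rb[:, i, j].mean() - ru[:, i, j].mean()),
                **row})
    return pd.DataFrame(rows)
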