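"""Post-acquisition time-series preprocessing.

The chain mirrors a standard resting-state pipeline applied after image
reconstruction and registration: zero-phase band-pass filtering to the
0.01-0.1 Hz fluctuation band, removal of the first volumes, nuisance
regression (motion parameters, their derivatives, white-matter and CSF
series), optionally augmented with the global signal (the gray-matter mean
series), and per-unit z-scoring.  The two regression branches are the
*withGS* / *withoutGS* conditions compared throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import Recording

GS_CONDITIONS = ("withGS", "withoutGS")


@dataclass
class PreprocessedRecording:
    """Residual, z-scored time series and the provenance of how it got there."""

    subject_id: str
    group: str
    state: str
    gs_condition: str
    data: np.ndarray                 # time x units, z-scored residuals
    residuals: np.ndarray            # same, before z-scoring (for SD maps)
    gs_series: np.ndarray            # gray-matter mean that was (or would be) removed
    unit_labels: list[str]
    tr_s: float
    provenance: list[dict] = field(default_factory=list)

    @property
    def roi_of_unit(self) -> list[str]:
        return [u.split("_")[0] for u in self.unit_labels]


def bandpass(data: np.ndarray, tr_s: float, f_lo: float = 0.01,
             f_hi: float = 0.1, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass, column-wise.

    Forward-backward application (filtfilt) doubles the effective order
    and cancels phase distortion; odd-extension padding limits edge
    transients.
    """
    nyq = 0.5 / tr_s
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz must sit inside (0, {nyq}) Hz")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=1.0 / tr_s,
                        output="sos")
    padlen = 3 * (2 * order + 1)
    if data.shape[0] <= padlen:
        raise ValueError(f"need more than {padlen} rows for stable filtering")
    return signal.sosfiltfilt(sos, data, axis=0, padtype="odd")


def discard_initial(data: np.ndarray, n: int = 5) -> np.ndarray:
    """Drop the first ``n`` rows (scanner equilibration volumes)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= data.shape[0]:
        raise ValueError(f"cannot discard {n} of {data.shape[0]} rows")
    return data[n:]


def regress_confounds(data: np.ndarray, confounds: np.ndarray,
                      include_gs: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares removal of nuisance regressors from every column.

    The gray-matter mean series (global signal) is always computed and
    returned; it joins the design matrix only when ``include_gs``.
    Residuals are orthogonal to every regressor up to solver precision.
    """
    if confounds.shape[0] != data.shape[0]:
        raise ValueError("confounds and data must have equal row counts")
    gs = data.mean(axis=1)
    cols = [np.ones(data.shape[0]), confounds]
    if include_gs:
        cols.append(gs)
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns for the diagnostic
        names = (["intercept"] + [f"confound_{i}" for i in range(confounds.shape[1])]
                 + (["global_signal"] if include_gs else []))
        keep, bad = [], []
        basis = np.empty((design.shape[0], 0))
        for j in range(design.shape[1]):
            trial = np.column_stack([basis, design[:, j]])
            if np.linalg.matrix_rank(trial) > basis.shape[1]:
                basis = trial
                keep.append(j)
            else:
                bad.append(names[j])
        raise np.linalg.LinAlgError(
            f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    residuals = data - design @ beta
    return residuals, gs


def zscore(data: np.ndarray) -> np.ndarray:
    """Per-column standardization to mean 0, SD 1 (sample SD, ddof=1)."""
    centered = data - data.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a zero-variance column")
    return centered / sd


def preprocess(rec: Recording, gs_condition: str, *, f_lo: float = 0.01,
               f_hi: float = 0.1, n_discard: int = 5,
               filter_confounds: bool = True) -> PreprocessedRecording:
    """Full chain: band-pass -> discard -> nuisance regression (+/- GS) -> z-score.

    ``filter_confounds`` applies the identical band-pass to the confound
    table before regression so no out-of-band variance is reintroduced.
    """
    if gs_condition not in GS_CONDITIONS:
        raise ValueError(f"gs_condition must be one of {GS_CONDITIONS}")
    prov: list[dict] = []
    x = bandpass(rec.data, rec.tr_s, f_lo, f_hi)
    prov.append({"step": "bandpass", "f_lo": f_lo, "f_hi": f_hi,
                 "filter": "butterworth-order5-zero-phase"})
    x = discard_initial(x, n_discard)
    conf = rec.confounds.to_numpy(dtype=float)
    if filter_confounds:
        conf = bandpass(conf, rec.tr_s, f_lo, f_hi)
    conf = discard_initial(conf, n_discard)
    prov.append({"step": "discard_initial", "n": n_discard,
                 "confounds_filtered": filter_confounds})
    # "withGS" keeps the global signal in the data (confound-only
    # regression); "withoutGS" additionally regresses the GM mean out (GSR)
    include_gs = gs_condition == "withoutGS"
    residuals, gs = regress_confounds(x, conf, include_gs=include_gs)
    prov.append({"step": "regress_confounds", "gs_condition": gs_condition,
                 "gs_computed_after_bandpass": True,
                 "n_regressors": conf.shape[1] + 1 + int(include_gs)})
    z = zscore(residuals)
    prov.append({"step": "zscore", "per": "unit", "ddof": 1})
    return PreprocessedRecording(
        subject_id=rec.subject_id, group=rec.group, state=rec.state,
        gs_condition=gs_condition, data=z, residuals=residuals,
        gs_series=gs, unit_labels=list(rec.unit_labels), tr_s=rec.tr_s,
        provenance=prov)
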