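"""Temporal-variability and low-frequency amplitude indices.

Three subject-level summaries of a preprocessed recording:

* SD of the gray-matter average series — how much the whole cortex
  fluctuates coherently; under global-signal regression this collapses
  towards zero by construction.
* voxel-wise (unit-wise) SD — the map of residual temporal variability.
  Because the final pipeline step standardizes every unit, this is
  informative only on the *pre-z-score* residuals, which is where the
  pipeline evaluates it.
* ALFF — the mean amplitude (square root of power) of the Fourier
  spectrum inside the low-frequency band, min-max normalized to [0, 1]
  across units within the subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PreprocessedRecording


@dataclass(frozen=True)
class FluctuationSummary:
    sd_gm_average: float
    mean_voxel_sd: float
    mean_norm_alff: float
    per_unit_sd: np.ndarray
    per_unit_alff_norm: np.ndarray


def sd_gm_average(data: np.ndarray) -> float:
    """Sample SD (ddof=1) of the row-mean (gray-matter average) series."""
    if data.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    return float(data.mean(axis=1).std(ddof=1))


def voxelwise_sd(data: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-unit sample SD and its mean across units."""
    if data.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    per_unit = data.std(axis=0, ddof=1)
    return per_unit, float(per_unit.mean())


def alff(data: np.ndarray, tr_s: float, f_lo: float = 0.01, f_hi: float = 0.1
         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Amplitude of low-frequency fluctuations, raw and min-max normalized.

    Per unit: one-sided FFT, amplitude = sqrt(power) per bin, averaged
    over the bins inside [f_lo, f_hi] (bin averaging keeps the index
    invariant to zero padding).  Normalized values are min-max rescaled
    across units so the least-fluctuating unit maps to 0 and the most to 1.
    """
    n = data.shape[0]
    if n < 64:
        raise ValueError("need at least 64 time points for a stable spectrum")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any():
        raise ValueError("frequency band contains no Fourier bins")
    spec = np.fft.rfft(data, axis=0)
    amplitude = (2.0 / n) * np.abs(spec)       # sinusoid of amplitude A -> A
    raw = amplitude[band].mean(axis=0)
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        norm = (raw - lo) / (hi - lo)
    else:
        norm = np.zeros_like(raw)
    return raw, norm, float(norm.mean())


def parseval_residual(data: np.ndarray) -> float:
    """Relative gap between time-domain energy and summed spectral power.

    An internal FFT sanity check: |sum x^2 - sum |X|^2 / n| / sum x^2.
    """
    energy_t = float(np.sum(data ** 2))
    spec = np.fft.fft(data, axis=0)
    energy_f = float(np.sum(np.abs(spec) ** 2) / data.shape[0])
    return abs(energy_t - energy_f) / energy_t


def summarize(pre: PreprocessedRecording, f_lo: float = 0.01,
              f_hi: float = 0.1) -> FluctuationSummary:
    """Subject-level summary on the pipeline's conventions.

    The GM-average SD and ALFF are computed on the z-scored data; the
    unit-wise SD on the pre-z-score residuals (after standardization it is
    identically 1).
    """
    per_sd, mean_sd = voxelwise_sd(pre.residuals)
    _, norm, mean_norm = alff(pre.data, pre.tr_s, f_lo, f_hi)
    return FluctuationSummary(
        sd_gm_average=sd_gm_average(pre.data),
        mean_voxel_sd=mean_sd,
        mean_norm_alff=mean_norm,
        per_unit_sd=per_sd,
        per_unit_alff_norm=norm)
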