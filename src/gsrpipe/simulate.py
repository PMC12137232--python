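"""Synthetic BOLD cohort generator with closed-form connectivity oracles.

The generator emulates a two-arm anesthesia study: two drug groups (7 and 6
subjects), each subject recorded in a *baseline* and an *unconscious* state
for 540 s.  Every ROI signal is a linear mixture of independent latent
processes:

    x_i(t) = g_s * G(t) + b_s * B(t) + w_s * N_k(t)
             + s_w * S(t) + lam * c(t) + sigma * eps_i(t)

where ``G`` is a shared low-frequency global component whose amplitude
``g_s`` drops in the unconscious state, ``B`` a shared between-network
component, ``N_k`` the latent of ROI *i*'s functional network, ``S`` a
subject-specific component shared by both states of a subject (the paired
random effect), ``c`` a motion-confound composite that leaks into the
signal, and ``eps_i`` white unit noise.  ``G``, ``B``, ``N_k``, ``S`` and
``c`` are Gaussian processes band-limited to 0.01-0.1 Hz and are
orthonormalized in-sample (QR), so the population correlation structure
implied by the mixing weights is exact for the structural part; only the
white-noise terms contribute O(1/sqrt(T)) sampling error.

The mixing weights are solved from *correlation targets*: the user states
the wanted within-network and between-network ROI correlations per state
(plus the global-signal amplitude), and the generator back-computes
``w_s`` and ``b_s``.  :func:`expected_fc` returns the implied population
ROI correlation matrix in closed form, which downstream parameter-recovery
tests use as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme, make_parcellation

STATES = ("baseline", "unconscious")
GROUPS = ("drugA", "drugB")

MOTION_NAMES = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
CONFOUND_NAMES = MOTION_NAMES + tuple(f"{m}_derivative" for m in MOTION_NAMES) + (
    "white_matter", "csf")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters of the synthetic cohort.

    Correlation targets are per-state ``{"baseline": ..., "unconscious": ...}``
    mappings.  Defaults encode the study conditions: a strong global
    component and block-structured coupling at baseline, both attenuated
    after loss of consciousness.
    """

    n_subjects_per_group: tuple[int, int] = (7, 6)
    scan_duration_s: float = 540.0
    tr_s: float = 2.0
    n_voxels_per_roi: int = 5
    gs_amplitude: dict = field(default_factory=lambda: {
        "baseline": 0.6, "unconscious": 0.35})
    coupling_within: dict = field(default_factory=lambda: {
        "baseline": 0.50, "unconscious": 0.40})
    coupling_between: dict = field(default_factory=lambda: {
        "baseline": 0.25, "unconscious": 0.10})
    confound_leak: float = 0.2
    noise_sd: float = 1.0
    voxel_noise_sd: float = 0.5
    subject_effect: float = 0.15
    wm_csf_gs_corr: float = 0.5
    band: tuple[float, float] = (0.01, 0.1)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimulationConfig requires an explicit seed")
        if self.n_timepoints < 60:
            raise ValueError("scan too short: need at least 60 time points")
        if self.noise_sd <= 0 or self.voxel_noise_sd < 0:
            raise ValueError("noise SDs must be positive (voxel noise >= 0)")
        if self.confound_leak < 0 or self.subject_effect < 0:
            raise ValueError("variance contributions must be non-negative")
        for state in STATES:
            # raises if the targets imply a non-PSD covariance
            self.mixing_weights(state)

    @property
    def n_timepoints(self) -> int:
        return int(np.floor(self.scan_duration_s / self.tr_s))

    def mixing_weights(self, state: str) -> dict[str, float]:
        """Solve the latent mixing weights for one state.

        With latent-part variance ``T0 = sigma^2 / (1 - r_w)`` the network
        weight is ``w^2 = (r_w - r_b) * T0`` and the shared between-network
        weight ``b^2 = r_b * T0 - g^2``; ``b^2 < 0`` means the requested
        global amplitude exceeds what the between-network correlation
        target can accommodate (non-PSD implied covariance).
        """
        r_w = float(self.coupling_within[state])
        r_b = float(self.coupling_between[state])
        g = float(self.gs_amplitude[state])
        if not (0 <= r_b <= r_w < 1):
            raise ValueError(f"need 0 <= between <= within < 1, got "
                             f"within={r_w}, between={r_b} ({state})")
        sigma2 = self.noise_sd ** 2
        t0 = sigma2 / (1.0 - r_w)
        w2 = (r_w - r_b) * t0
        b2 = r_b * t0 - g ** 2
        if b2 < -1e-12:
            raise ValueError(
                f"implied covariance not PSD in state '{state}': "
                f"gs_amplitude^2={g**2:.4f} exceeds the between-network "
                f"covariance budget {r_b * t0:.4f}")
        return {"g": g, "b": float(np.sqrt(max(b2, 0.0))),
                "w": float(np.sqrt(w2)), "sigma": self.noise_sd,
                "lam": self.confound_leak, "s": self.subject_effect}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        for key in ("n_subjects_per_group", "band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Recording:
    """One subject x state time-series matrix plus its confound table."""

    subject_id: str
    group: str
    state: str
    data: np.ndarray            # time x units
    unit_labels: list[str]
    tr_s: float
    confounds: pd.DataFrame     # time x 14 named regressors

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.unit_labels):
            raise ValueError("data must be time x units matching unit_labels")
        if len(self.confounds) != self.data.shape[0]:
            raise ValueError("confound rows must match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        sds = self.data.std(axis=0)
        if np.any(sds == 0):
            raise ValueError("every unit needs nonzero variance")

    @property
    def roi_of_unit(self) -> list[str]:
        """ROI label of each unit (voxel labels are 'ROI###_v#')."""
        return [u.split("_")[0] for u in self.unit_labels]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.data, columns=self.unit_labels).to_csv(
            path, sep="\t", index=False, float_format="%.6g")


def bandlimited_noise(rng: np.random.Generator, n: int, dt: float,
                      f_lo: float, f_hi: float, n_series: int = 1) -> np.ndarray:
    """Gaussian series with spectral support restricted to [f_lo, f_hi].

    Built by drawing iid complex Gaussian Fourier coefficients on the
    in-band bins and inverting; each column is z-scored to exact unit
    sample variance.
    """
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValueError("no Fourier bins inside the requested band")
    spec = np.zeros((len(freqs), n_series), dtype=complex)
    k = int(mask.sum())
    spec[mask] = rng.standard_normal((k, n_series)) + 1j * rng.standard_normal((k, n_series))
    x = np.fft.irfft(spec, n=n, axis=0)
    x -= x.mean(axis=0)
    x /= x.std(axis=0, ddof=1)
    return x


def _orthonormal_latents(raw: np.ndarray) -> np.ndarray:
    """QR-orthonormalize latent columns; rescale to unit sample variance."""
    n = raw.shape[0]
    if raw.shape[1] > n:
        raise ValueError("more latent processes than time points")
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))        # keep orientation of the raw draws
    q -= q.mean(axis=0)
    q /= q.std(axis=0, ddof=1)
    return q


def simulate_cohort(cfg: SimulationConfig,
                    scheme: ParcellationScheme | None = None) -> list[Recording]:
    """Generate the full two-group, two-state cohort. Seeded, bit-reproducible."""
    scheme = scheme or make_parcellation()
    networks = scheme.networks
    net_index = {net: i for i, net in enumerate(networks)}
    roi_net = [net_index[n] for n in scheme.network_of_roi()]
    n_roi = scheme.n_rois
    n_t = cfg.n_timepoints
    root = np.random.SeedSequence(cfg.seed)
    group_seeds = root.spawn(len(GROUPS))

    recordings: list[Recording] = []
    for group, n_subj, gseed in zip(GROUPS, cfg.n_subjects_per_group, group_seeds):
        subj_seeds = gseed.spawn(n_subj)
        for si, sseed in enumerate(subj_seeds):
            subj_rng = np.random.default_rng(sseed)
            state_rngs = [np.random.default_rng(s) for s in sseed.spawn(2)]
            # the subject random effect: one band-limited draw, reused in
            # both states so the two recordings are genuinely paired
            s_latent = bandlimited_noise(subj_rng, n_t, cfg.tr_s, *cfg.band)
            for state, rng in zip(STATES, state_rngs):
                rec = _simulate_recording(
                    cfg, scheme, roi_net, s_latent, rng,
                    subject_id=f"{group}_s{si + 1:02d}", group=group, state=state)
                recordings.append(rec)
    return recordings


def _simulate_recording(cfg: SimulationConfig, scheme: ParcellationScheme,
                        roi_net: list[int], s_latent: np.ndarray,
                        rng: np.random.Generator, *, subject_id: str,
                        group: str, state: str) -> Recording:
    n_t = cfg.n_timepoints
    n_roi = scheme.n_rois
    n_net = len(scheme.networks)
    wts = cfg.mixing_weights(state)

    # structural latents, column order [G, B, N_1..K, S, c]; orthonormalized
    # so the implied covariance of the structural part is exact in-sample
    fresh = bandlimited_noise(rng, n_t, cfg.tr_s, *cfg.band, n_series=3 + n_net)
    lat = _orthonormal_latents(
        np.column_stack([fresh[:, :2 + n_net], s_latent[:, 0], fresh[:, 2 + n_net]]))
    g_lat, b_lat = lat[:, 0], lat[:, 1]
    n_lat = lat[:, 2:2 + n_net]
    s_lat = lat[:, 2 + n_net]
    c_lat = lat[:, 3 + n_net]

    eps = rng.standard_normal((n_t, n_roi))
    eps -= eps.mean(axis=0)
    eps /= eps.std(axis=0, ddof=1)

    roi_sig = (wts["g"] * g_lat[:, None]
               + wts["b"] * b_lat[:, None]
               + wts["w"] * n_lat[:, roi_net]
               + wts["s"] * s_lat[:, None]
               + wts["lam"] * c_lat[:, None]
               + wts["sigma"] * eps)

    # voxel expansion: each ROI contributes n_voxels copies + white noise
    if cfg.n_voxels_per_roi > 1:
        v = cfg.n_voxels_per_roi
        vox = np.repeat(roi_sig, v, axis=1)
        vox = vox + cfg.voxel_noise_sd * rng.standard_normal(vox.shape)
        labels = [f"{r}_v{j + 1}" for r in scheme.roi_labels for j in range(v)]
        data = vox
    else:
        labels = list(scheme.roi_labels)
        data = roi_sig

    confounds = _make_confounds(cfg, rng, c_lat, g_lat, n_t)
    return Recording(subject_id=subject_id, group=group, state=state,
                     data=data, unit_labels=labels, tr_s=cfg.tr_s,
                     confounds=confounds)


def _make_confounds(cfg: SimulationConfig, rng: np.random.Generator,
                    c_lat: np.ndarray, g_lat: np.ndarray, n_t: int) -> pd.DataFrame:
    """Motion-like regressors spanning the leaked composite, plus WM/CSF.

    Each motion series mixes the leak composite ``c`` with an independent
    very-low-frequency process, so the 6-column motion block spans ``c``
    exactly and confound regression can remove the leak.  WM and CSF are
    partially correlated with the global component (coefficient
    ``wm_csf_gs_corr``) so that global-signal regression and confound-only
    regression genuinely differ.
    """
    slow = bandlimited_noise(rng, n_t, cfg.tr_s, 0.002,
                             min(0.05, 0.45 / cfg.tr_s), n_series=6)
    motion = 0.5 * c_lat[:, None] + np.sqrt(1 - 0.25) * slow
    deriv = np.gradient(motion, axis=0)
    rho = cfg.wm_csf_gs_corr
    extra = bandlimited_noise(rng, n_t, cfg.tr_s, *cfg.band, n_series=2)
    wm = rho * g_lat + np.sqrt(1 - rho ** 2) * extra[:, 0]
    csf = rho * g_lat + np.sqrt(1 - rho ** 2) * extra[:, 1]
    table = np.column_stack([motion, deriv, wm, csf])
    return pd.DataFrame(table, columns=list(CONFOUND_NAMES))


def expected_fc(cfg: SimulationConfig, state: str,
                scheme: ParcellationScheme | None = None) -> np.ndarray:
    """Closed-form population ROI correlation matrix implied by the config.

    Correlation of two ROIs = shared covariance (global + between
    component + same-network latent + subject effect + confound leak)
    over the total per-ROI variance.  Diagonal is 1.
    """
    scheme = scheme or make_parcellation()
    wts = cfg.mixing_weights(state)
    shared = wts["g"] ** 2 + wts["b"] ** 2 + wts["lam"] ** 2 + wts["s"] ** 2
    within = shared + wts["w"] ** 2
    total = within + wts["sigma"] ** 2
    nets = np.asarray([n for n in scheme.network_of_roi()])
    same = nets[:, None] == nets[None, :]
    fc = np.where(same, within / total, shared / total)
    np.fill_diagonal(fc, 1.0)
    return fc


def write_cohort(recordings: list[Recording], cfg: SimulationConfig,
                 out_dir: str | Path) -> Path:
    """Write every recording + confounds as TSV and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"tr_s": cfg.tr_s, "recordings": []}
    for rec in recordings:
        stem = f"{rec.subject_id}_{rec.state}"
        rec.to_tsv(out / f"{stem}_bold.tsv")
        rec.confounds.to_csv(out / f"{stem}_confounds.tsv", sep="\t",
                             index=False, float_format="%.6g")
        manifest["recordings"].append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "state": rec.state, "bold": f"{stem}_bold.tsv",
             "confounds": f"{stem}_confounds.tsv"})
    cfg.to_json(out / "config.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
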