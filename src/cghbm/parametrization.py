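"""PM-SNR calibration of the prior scale parameter.

The prior-over-measurement signal-to-noise ratio (PM-SNR) expresses the
weight of the conditionally Gaussian prior relative to the measurement noise,
balanced by the size of the source space.  It fixes the per-source scale
``theta0`` through

    PM-SNR = 10*log10( theta0 * N * A^2 / (sigma^2 * |Jp|^2) )
           = 20*log10( sqrt(theta0 * N) * A / (sigma * |Jp|) ),

where N is the number of source *positions*, A the signal amplitude (the
l2-norm of the measurement; 1 after normalization), sigma the relative noise
std and |Jp| the a-priori dipole strength (10 nAm by default).  PM-SNR = 0 dB
means the total prior fluctuation sqrt(theta0*N) exactly matches the
noise-induced level sigma*|Jp|/A.

This particular reading of the definition is fixed by three mutually
consistent requirements: (a) at fixed PM-SNR, theta0 is inversely
proportional to N (a 1/100 sparse space has a 100x larger theta0); (b) a
+10 dB step multiplies theta0 by exactly 10; and (c) the 0 dB matching
condition sqrt(theta0) = sigma*|Jp|/(A*sqrt(N)).

The relation between the per-source and the total (per-distribution) scale is

    theta0 = theta0_tot * sigma^2 * A^2 / N,

following from the additivity of Gaussian variances over nearby sources.

Latent (unmodeled) noise enters through a factor s >= 1 on the known noise
std, sigma = s * sigma_bar; by construction this shifts PM-SNR additively by
the amplitude-dB of s (+20 dB for s = 10).  Epoch averaging of n epochs
relative to a reference count scales the noise amplitude by
sqrt(reference/n), i.e. +10*log10(reference/n) dB (+6 dB for 300 of 1200).

Two calibration paths coexist and must not be conflated:

* the *formula* path above, which converts PM-SNR <-> theta0 from the actual
  noise model and amplitude of a dataset; and
* the *anchored preset* path (:func:`preset_table`), which reproduces the
  reference preset grid from its literal 0 dB anchor (dense theta0 = 1e-14,
  sparse = 1e-12).  Plugging the nominal constants (A = 1e-6 V, sigma = 0.03,
  |Jp| = 1e-8 Am, N ~ 7.6e4) into the formula gives ~1e-12, not 1e-14 — a
  factor-~100 mismatch in the reference absolute anchor that the package
  deliberately surfaces rather than hides (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .constants import (JP_REF_AM, REFERENCE_EPOCHS, SIGMA_DEFAULT,
                        db_amplitude, db_power, from_db_power)
from .hyperprior import HyperpriorSpec

__all__ = [
    "NoiseModel",
    "theta0_from_total",
    "total_from_theta0",
    "pm_snr",
    "theta0_from_pm_snr",
    "latent_correction",
    "epoch_noise_shift_db",
    "mean_referenced_correction",
    "sigma_from_covariance",
    "preset_table",
    "PRESET_ANCHOR_THETA0_DENSE",
    "PRESET_ANCHOR_THETA0_SPARSE",
]

#: Literal preset anchors: per-source theta0 at PM-SNR = 0 dB.
PRESET_ANCHOR_THETA0_DENSE = 1.0e-14
PRESET_ANCHOR_THETA0_SPARSE = 1.0e-12


@dataclass(frozen=True)
class NoiseModel:
    """Relative measurement-noise model sigma = s * sigma_bar * sqrt(n_ref/n).

    ``sigma_known`` is the a-priori known relative noise std (sigma_bar) at
    the reference epoch count; ``latent_factor`` (s >= 1) inflates it for
    unmodeled errors (forward-model, conductivity, segmentation);
    ``epochs``/``reference_epochs`` apply central-limit scaling of the
    evoked-average noise.
    """

    sigma_known: float = SIGMA_DEFAULT
    latent_factor: float = 1.0
    epochs: int = REFERENCE_EPOCHS
    reference_epochs: int = REFERENCE_EPOCHS

    def __post_init__(self):
        if self.sigma_known <= 0:
            raise ValueError("sigma_known must be positive")
        if self.epochs <= 0 or self.reference_epochs <= 0:
            raise ValueError("epoch counts must be positive integers")
        if self.latent_factor < 1.0:
            warnings.warn("latent_factor < 1 is nonstandard (it deflates the "
                          "known noise level)", stacklevel=2)

    @property
    def sigma_epoch(self) -> float:
        """Known noise std at the actual epoch count (excludes latent factor)."""
        return self.sigma_known * np.sqrt(self.reference_epochs / self.epochs)

    @property
    def sigma_effective(self) -> float:
        """Total effective noise std s * sigma_bar * sqrt(n_ref/n)."""
        return self.latent_factor * self.sigma_epoch


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be positive")


def theta0_from_total(theta0_tot: float, n_positions: int, sigma: float,
                      amplitude: float = 1.0) -> float:
    """Per-source scale from the total scale: theta0 = theta0_tot*sigma^2*A^2/N."""
    _check_positive(theta0_tot=theta0_tot, n_positions=n_positions,
                    sigma=sigma, amplitude=amplitude)
    return theta0_tot * sigma**2 * amplitude**2 / n_positions


def total_from_theta0(theta0: float, n_positions: int, sigma: float,
                      amplitude: float = 1.0) -> float:
    """Total scale from the per-source scale: theta0_tot = theta0*N/(sigma^2*A^2)."""
    _check_positive(theta0=theta0, n_positions=n_positions, sigma=sigma,
                    amplitude=amplitude)
    return theta0 * n_positions / (sigma**2 * amplitude**2)


def pm_snr(theta0: float, n_positions: int, noise: NoiseModel,
           amplitude: float = 1.0, jp_ref: float = JP_REF_AM) -> float:
    """PM-SNR in dB from the per-source scale theta0.

    Power-dB of the total scale: 10*log10(theta0*N*A^2/(sigma^2*|Jp|^2)),
    using the known (non-latent) noise std at the actual epoch count — the
    latent factor is represented *through* PM-SNR itself, so it must not also
    enter the conversion (see :func:`latent_correction`).
    """
    _check_positive(theta0=theta0, n_positions=n_positions,
                    amplitude=amplitude, jp_ref=jp_ref)
    sigma = noise.sigma_epoch
    return float(db_power(theta0 * n_positions * amplitude**2
                          / (sigma**2 * jp_ref**2)))


def theta0_from_pm_snr(pm_snr_db: float, n_positions: int, noise: NoiseModel,
                       amplitude: float = 1.0, jp_ref: float = JP_REF_AM) -> float:
    """Per-source scale from PM-SNR: theta0 = 10^(PM/10)*sigma^2*|Jp|^2/(A^2*N).

    Exact inverse of :func:`pm_snr`; sigma is the known noise std at the
    actual epoch count (latent factor excluded, as it is carried by
    ``pm_snr_db`` itself).
    """
    _check_positive(n_positions=n_positions, amplitude=amplitude,
                    jp_ref=jp_ref)
    sigma = noise.sigma_epoch
    return float(from_db_power(pm_snr_db) * sigma**2 * jp_ref**2
                 / (amplitude**2 * n_positions))


def latent_correction(pm_snr_bar_db: float, latent_factor: float) -> float:
    """PM-SNR = PM-SNR_bar + 20*log10(s): latent noise strengthens the prior."""
    if latent_factor < 1.0:
        warnings.warn("latent_factor < 1 is nonstandard", stacklevel=2)
    _check_positive(latent_factor=latent_factor)
    return float(pm_snr_bar_db + db_amplitude(latent_factor))


def epoch_noise_shift_db(reference_epochs: int, epochs: int) -> float:
    """Noise-amplitude increase from epoch averaging, in dB.

    Under sqrt(n) averaging the relative noise amplitude grows by
    sqrt(reference/epochs), i.e. 20*log10(sqrt(ref/n)) = 10*log10(ref/n) dB:
    +6 dB for 300 of 1200 epochs, +10.8 dB for 100 of 1200.
    """
    _check_positive(reference_epochs=reference_epochs, epochs=epochs)
    return float(db_power(reference_epochs / epochs))


def mean_referenced_correction(spec: HyperpriorSpec) -> float:
    """dB shift from scale-referenced to hyperprior-mean-referenced PM-SNR.

    The hyperprior mean is beta*theta0 (G) or theta0/(beta-1) (IG), so
    referencing PM-SNR to the mean instead of the scale shifts it by the
    power-dB of that variance factor: +10*log10(beta) for G (+5 dB at
    beta = 3) and -10*log10(beta-1) for IG (-3 dB at beta = 3).
    """
    if spec.family == "G":
        return float(db_power(spec.beta))
    if spec.beta <= 1:
        raise ValueError("IG mean undefined for beta <= 1")
    return float(-db_power(spec.beta - 1.0))


def sigma_from_covariance(cov) -> float:
    """Relative noise std for a non-diagonal noise covariance.

    The generalization of sigma^2 to correlated noise is the largest
    eigenvalue (l2-norm) of the covariance matrix.
    """
    cov = np.asarray(cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    return float(np.sqrt(np.linalg.eigvalsh(cov)[-1]))


_PRESET_KEYS = {"data", "modality", "estimate", "family", "pm_snr_db",
                "density"}

#: The reference preset grid: (data, modality, estimate, family, PM-SNR dB).
STANDARD_PRESETS: tuple[dict, ...] = tuple(
    dict(data=d, modality=m, estimate=e, family=f, pm_snr_db=p)
    for d, m, e, f, p in [
        ("measured", "EEG", "MAP", "G", 20), ("measured", "EEG", "MAP", "IG", 30),
        ("measured", "EEG", "CM", "G", 20), ("measured", "EEG", "CM", "IG", 20),
        ("measured", "MEG", "MAP", "G", 20), ("measured", "MEG", "MAP", "IG", 30),
        ("measured", "MEG", "CM", "G", 20), ("measured", "MEG", "CM", "IG", 20),
        ("synthetic", "EEG", "MAP", "G", 20), ("synthetic", "EEG", "MAP", "IG", 30),
        ("synthetic", "EEG", "CM", "G", 0), ("synthetic", "EEG", "CM", "IG", 0),
        ("synthetic", "MEG", "MAP", "G", 30), ("synthetic", "MEG", "MAP", "IG", 30),
        ("synthetic", "MEG", "CM", "G", 0), ("synthetic", "MEG", "CM", "IG", 0),
    ])


def preset_theta0(pm_snr_db: float, density: str) -> float:
    """Anchored preset theta0: anchor * 10^(PM-SNR/10).

    Anchors are literal reference values (dense 1e-14, sparse 1e-12 at 0 dB);
    this path is independent of the formula path on purpose.
    """
    if density == "dense":
        anchor = PRESET_ANCHOR_THETA0_DENSE
    elif density == "sparse":
        anchor = PRESET_ANCHOR_THETA0_SPARSE
    else:
        raise ValueError(f"unknown density {density!r}")
    return float(anchor * from_db_power(pm_snr_db))


def preset_table(configs: Sequence[dict] | None = None) -> pd.DataFrame:
    """Tabulate anchored presets: one row per run descriptor.

    Each descriptor names the data type, modality, estimator, hyperprior
    family and PM-SNR; the sparse and dense theta0 columns follow from the
    0 dB anchors.  With no argument the full reference grid is emitted.
    """
    if configs is None:
        configs = STANDARD_PRESETS
    rows = []
    for cfg in configs:
        unknown = set(cfg) - _PRESET_KEYS
        if unknown:
            raise ValueError(f"unknown preset descriptor keys: {sorted(unknown)}")
        missing = {"data", "modality", "estimate", "family", "pm_snr_db"} - set(cfg)
        if missing:
            raise ValueError(f"preset descriptor missing keys: {sorted(missing)}")
        p = float(cfg["pm_snr_db"])
        rows.append({
            "data": cfg["data"], "modality": cfg["modality"],
            "estimate": cfg["estimate"], "family": cfg["family"],
            "pm_snr_db": p,
            "theta0_sparse": preset_theta0(p, "sparse"),
            "theta0_dense": preset_theta0(p, "dense"),
        })
    return pd.DataFrame(rows)
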