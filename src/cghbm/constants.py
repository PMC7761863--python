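"""Shared numerical conventions.

Single source of truth for the decibel conventions used throughout the
package, so that the parametrization, inversion and reporting code cannot
silently diverge.

Decibel conventions
-------------------
Amplitude-like quantities (source strengths, noise std, the latent factor s)
use ``db_amplitude(x) = 20*log10(x)``.  Variance-like quantities (the prior
variances theta and their scale theta0) enter through their square root, so a
x10 change in theta0 corresponds to +10 dB; use ``db_power(x) = 10*log10(x)``
for those.  Every formula in :mod:`cghbm.parametrization` documents which of
the two it uses.
"""

from __future__ import annotations

import numpy as np

#: Brain conductivity used by the homogeneous-sphere EEG forward model [S/m].
BRAIN_CONDUCTIVITY_S_PER_M = 0.33

#: Vacuum permeability [T*m/A], used by the MEG forward model.
MU0 = 4.0e-7 * np.pi

#: A-priori dipolar source strength |Jp| [Am] — the typical 10 nAm cortical
#: dipole used as the PM-SNR reference level.
JP_REF_AM = 1.0e-8

#: Default relative measurement-noise standard deviation (3%).
SIGMA_DEFAULT = 0.03

#: Reference epoch count for the evoked-average noise model.
REFERENCE_EPOCHS = 1200


def db_amplitude(x):
    """20*log10(x): decibels of an amplitude-like quantity."""
    return 20.0 * np.log10(x)


def db_power(x):
    """10*log10(x): decibels of a power/variance-like quantity."""
    return 10.0 * np.log10(x)


def from_db_amplitude(db):
    """Inverse of :func:`db_amplitude`."""
    return 10.0 ** (np.asarray(db) / 20.0)


def from_db_power(db):
    """Inverse of :func:`db_power`."""
    return 10.0 ** (np.asarray(db) / 10.0)
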