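"""Hill-type muscle model.

The muscle force law combines an activation-scaled active term, shaped by
force-length and force-velocity factors, with a passive elastic term:

    F = f_max * (alpha * fl(l) * fv(ldot) + fp(l))

with ``alpha`` the activation in [0, 1], ``l`` the current length, ``ldot``
the lengthening velocity (positive = lengthening) and ``l0`` the resting
length.  ``fl`` is a quartic in l/l0 peaking near the resting length, ``fv``
a sigmoid in ldot/ldot_max that suppresses force during shortening and
boosts it slightly during lengthening, and ``fp`` an exponential toe curve.
The maximum contraction velocity is tied to the resting length,
``ldot_max = l0 / 0.1 s``.

All functions are vectorised over numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "F_MAX_DEFAULT",
    "FV_MAX",
    "force_length",
    "force_length_derivative",
    "force_velocity",
    "force_velocity_derivative",
    "passive_force",
    "passive_force_derivative",
    "passive_force_slack",
    "passive_force_slack_derivative",
    "muscle_force",
]

#: default maximum isometric force, N (identical for all ten trunk muscles)
F_MAX_DEFAULT = 800.0

#: supremum of the force-velocity factor, 0.1433 / 0.1074
FV_MAX = 0.1433 / 0.1074

# passive factor at the resting length, exp(-10.671 + 7.675)
_FP_AT_REST = float(np.exp(-10.671 + 7.675))


def _fl(r):
    v = 5.1 + r * (-29.0 + r * (56.0 + r * (-41.0 + 10.0 * r)))
    return np.maximum(v, 0.0)


def _dfl_dr(r):
    v = 5.1 + r * (-29.0 + r * (56.0 + r * (-41.0 + 10.0 * r)))
    d = -29.0 + r * (112.0 + r * (-123.0 + 40.0 * r))
    return np.where(v > 0.0, d, 0.0)


def _fv(x):
    z = np.clip(3.2 * x + 1.6, -25.0, 25.0)
    arg = np.clip(-1.409 * np.sinh(z), -700.0, 700.0)
    return 0.1433 / (0.1074 + np.exp(arg))


def _dfv_dx(x):
    z = np.clip(3.2 * x + 1.6, -25.0, 25.0)
    s = np.sinh(z)
    c = np.cosh(z)
    ex = np.exp(np.clip(-1.409 * s, -700.0, 700.0))
    a1 = ex / (0.1074 + ex)
    a2 = 1.0 / (0.1074 + ex)
    return 0.1433 * 1.409 * 3.2 * c * a1 * a2


def _fp(r):
    return np.exp(-10.671 + 7.675 * r)


def _fps(r):
    return np.maximum(np.exp(-10.671 + 7.675 * r) - _FP_AT_REST, 0.0)


def _ratio(l, l0):
    l = np.asarray(l, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    if np.any(l <= 0.0) or np.any(l0 <= 0.0):
        raise ValueError("muscle lengths must be strictly positive")
    return l / l0


def force_length(l, l0):
    """Active force-length factor, a quartic polynomial in l/l0.

    fl(l) = 5.1 - 29 r + 56 r^2 - 41 r^3 + 10 r^4,  r = l/l0,
    clamped at zero where the polynomial is negative so that activation can
    never push (the quartic has real roots outside the physiological range).
    """
    return _fl(_ratio(l, l0))


def force_length_derivative(l, l0):
    """d fl / dl, zero in the clamped (negative-polynomial) region."""
    return _dfl_dr(_ratio(l, l0)) / np.asarray(l0, dtype=float)


def force_velocity(l_dot, l_dot_max):
    """Force-velocity factor.

    fv(ldot) = 0.1433 / (0.1074 + exp(-1.409 sinh(3.2 x + 1.6))),
    x = ldot / ldot_max.  Strictly increasing; ~1.005 at x = 0; bounded in
    (0, 1.334).  The sinh argument is clipped far outside the physiological
    range purely to avoid floating overflow - the factor is already flat at
    machine precision there.
    """
    if np.any(np.asarray(l_dot_max, dtype=float) <= 0.0):
        raise ValueError("l_dot_max must be positive")
    return _fv(np.asarray(l_dot, dtype=float) / np.asarray(l_dot_max, dtype=float))


def force_velocity_derivative(l_dot, l_dot_max):
    """d fv / d ldot (zero in both saturated tails)."""
    l_dot_max = np.asarray(l_dot_max, dtype=float)
    return _dfv_dx(np.asarray(l_dot, dtype=float) / l_dot_max) / l_dot_max


def passive_force(l, l0):
    """Passive force-length factor, fp(l) = exp(-10.671 + 7.675 l/l0).

    Note fp(l0) ~= 0.0500: as printed, the parallel elastic element carries
    5% of f_max already at the resting length.
    """
    return _fp(_ratio(l, l0))


def passive_force_derivative(l, l0):
    return 7.675 * passive_force(l, l0) / np.asarray(l0, dtype=float)


def passive_force_slack(l, l0):
    """Slack variant of the passive factor: zero at and below the resting
    length, the exponential toe curve shifted to engage only under stretch,

        fp_slack(l) = max(0, fp(l) - fp(l0)).

    This is the conventional behaviour of a parallel elastic element (it
    cannot push and carries no tone in a shortened muscle) and is the
    default for the plant actuators; see the methods note for why.
    """
    return _fps(_ratio(l, l0))


def passive_force_slack_derivative(l, l0):
    r = _ratio(l, l0)
    v = np.exp(-10.671 + 7.675 * r)
    return np.where(v > _FP_AT_REST, 7.675 * v / np.asarray(l0, dtype=float), 0.0)


def muscle_force(l, l_dot, alpha, l0, f_max=F_MAX_DEFAULT, passive="eq"):
    """Total Hill muscle force in newtons.

    Parameters
    ----------
    l, l_dot : float or array
        Current length and lengthening velocity (same units as ``l0`` and
        ``l0`` per second respectively).
    alpha : float or array
        Activation, clipped into [0, 1].
    l0 : float or array
        Resting length; also sets ``l_dot_max = l0 / 0.1``.
    f_max : float
        Maximum isometric force, N.
    passive : {"eq", "slack", "none"}
        Passive-term convention: the exponential as printed, its slack
        (tension-only beyond rest) variant, or no passive term.
    """
    alpha = np.clip(np.asarray(alpha, dtype=float), 0.0, 1.0)
    l_dot_max = np.asarray(l0, dtype=float) / 0.1
    if passive == "eq":
        fp = passive_force(l, l0)
    elif passive == "slack":
        fp = passive_force_slack(l, l0)
    elif passive == "none":
        fp = 0.0
    else:
        raise ValueError(f"unknown passive mode {passive!r}")
    return f_max * (alpha * force_length(l, l0) * force_velocity(l_dot, l_dot_max) + fp)
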