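"""Tumour volume from paired mammographic dimensions.

A lesion is measured on a mammogram as two diameters in mm. The greater
dimension is treated as the "height" — the diameter of the semi-major
axis — and the smaller as the diameter of the semi-minor axis. Three
three-dimensional shape assumptions convert the pair into a volume:

* ``sphere``           V = (pi/6) * d^3 with d a single representative diameter
* ``cylinder``         V = pi * (minor/2)^2 * major  (height = greater dimension)
* ``oblate_spheroid``  V = (4/3) * pi * (major/2)^2 * (minor/2)

The sphere needs one diameter from two measurements; the default rule is
the arithmetic mean of the two dimensions, the most common mammographic
convention, with ``major``, ``minor`` and ``geometric_mean`` selectable
for sensitivity analysis.

All functions are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

SHAPES = ("sphere", "cylinder", "oblate_spheroid")
SPHERE_RULES = ("mean", "major", "minor", "geometric_mean")


def _check_dims(dim_major, dim_minor):
    dim_major = np.asarray(dim_major, dtype=float)
    dim_minor = np.asarray(dim_minor, dtype=float)
    if np.any(dim_major <= 0) or np.any(dim_minor <= 0):
        raise DomainError("lesion dimensions must be strictly positive")
    if np.any(dim_major < dim_minor):
        raise DomainError("dim_major must be >= dim_minor (reorder upstream)")
    return dim_major, dim_minor


def sphere_diameter(dim_major, dim_minor, rule: str = "mean"):
    """Single representative diameter feeding the sphere formula."""
    dim_major, dim_minor = _check_dims(dim_major, dim_minor)
    if rule == "mean":
        return (dim_major + dim_minor) / 2.0
    if rule == "major":
        return dim_major
    if rule == "minor":
        return dim_minor
    if rule == "geometric_mean":
        return np.sqrt(dim_major * dim_minor)
    raise ValueError(f"unknown sphere diameter rule {rule!r}; choose from {SPHERE_RULES}")


def lesion_volume(dim_major, dim_minor, shape: str, sphere_rule: str = "mean"):
    """Volume in mm^3 of a lesion with the given dimension pair (mm).

    Parameters
    ----------
    dim_major, dim_minor
        Greater and smaller mammographic diameters in mm (scalar or array).
    shape
        One of ``sphere``, ``cylinder``, ``oblate_spheroid``.
    sphere_rule
        How the sphere collapses two dimensions into one diameter.
    """
    dim_major, dim_minor = _check_dims(dim_major, dim_minor)
    if shape == "sphere":
        d = sphere_diameter(dim_major, dim_minor, sphere_rule)
        vol = (np.pi / 6.0) * d**3
    elif shape == "cylinder":
        vol = np.pi * (dim_minor / 2.0) ** 2 * dim_major
    elif shape == "oblate_spheroid":
        vol = (4.0 / 3.0) * np.pi * (dim_major / 2.0) ** 2 * (dim_minor / 2.0)
    else:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")
    return vol if vol.ndim else float(vol)


def dimensions_from_volume(volume, aspect_ratio, shape: str, sphere_rule: str = "mean"):
    """Invert :func:`lesion_volume`: recover a (major, minor) pair from a volume.

    Given a target volume (mm^3) and an aspect ratio ``a = major/minor >= 1``,
    returns the unique dimension pair reproducing the volume under ``shape``.
    Used by the synthetic cohort generator so that the geometry stage is
    exercised non-trivially; ``lesion_volume`` of the result round-trips
    exactly.
    """
    volume = np.asarray(volume, dtype=float)
    a = np.asarray(aspect_ratio, dtype=float)
    if np.any(volume <= 0):
        raise DomainError("volume must be strictly positive")
    if np.any(a < 1):
        raise DomainError("aspect ratio must be >= 1 (major/minor)")
    if shape == "sphere":
        d = (6.0 * volume / np.pi) ** (1.0 / 3.0)
        if sphere_rule == "mean":
            minor = 2.0 * d / (1.0 + a)
        elif sphere_rule == "major":
            minor = d / a
        elif sphere_rule == "minor":
            minor = d
        elif sphere_rule == "geometric_mean":
            minor = d / np.sqrt(a)
        else:
            raise ValueError(f"unknown sphere diameter rule {sphere_rule!r}")
    elif shape == "cylinder":
        minor = (4.0 * volume / (np.pi * a)) ** (1.0 / 3.0)
    elif shape == "oblate_spheroid":
        minor = (6.0 * volume / (np.pi * a**2)) ** (1.0 / 3.0)
    else:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")
    major = a * minor
    return major, minor
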