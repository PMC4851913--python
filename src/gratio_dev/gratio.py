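"""Voxel-wise myelin g-ratio index computation.

The aggregate g-ratio index combines a myelin water volume fraction map
(``vfm``, from multicomponent relaxometry) with NODDI volume fractions
(``nu_ic`` intracellular/neurite, ``nu_iso`` isotropic/free water):

    VF_A = (1 - VF_M) * (1 - nu_ISO) * nu_IC     (axon volume fraction)
    VF_F = VF_M + VF_A                           (total fiber volume fraction)
    g    = sqrt(1 - VF_M / VF_F)

``g`` is only defined where the fiber volume fraction is meaningfully
positive; voxels with ``VF_F <= eps`` are flagged undefined rather than
propagated as NaN surprises downstream.

No proportionality coefficient between VF_M and the true myelin volume
fraction is applied by default (``vfm_scale=1.0``); the scalar is exposed
for sensitivity analyses only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Fiber-volume-fraction floor below which the g-ratio index is undefined.
DEFAULT_EPS = 1e-6


class RangeError(ValueError):
    """An input volume fraction lies outside [0, 1] under the strict policy."""


def _check_range(name: str, arr: np.ndarray, policy: str) -> tuple[np.ndarray, int]:
    """Clamp or reject out-of-range fractions; returns (array, n_clamped)."""
    out_of_range = (arr < 0) | (arr > 1)
    n_bad = int(np.count_nonzero(out_of_range))
    if n_bad == 0:
        return arr, 0
    if policy == "strict":
        raise RangeError(f"{name}: {n_bad} voxel(s) outside [0, 1] under strict policy")
    if policy != "clamp":
        raise ValueError(f"unknown range policy {policy!r}; expected 'clamp' or 'strict'")
    log.warning("%s: clamped %d out-of-range voxel(s) into [0, 1]", name, n_bad)
    return np.clip(arr, 0.0, 1.0), n_bad


def axon_volume_fraction(vfm, nu_ic, nu_iso):
    """Axon volume fraction VF_A = (1 - VF_M)(1 - nu_ISO) nu_IC.

    Scalar or array inputs; all must be fractions in [0, 1].
    """
    vfm, nu_ic, nu_iso = np.asarray(vfm), np.asarray(nu_ic), np.asarray(nu_iso)
    for name, a in (("vfm", vfm), ("nu_ic", nu_ic), ("nu_iso", nu_iso)):
        if np.any((a < 0) | (a > 1)):
            raise RangeError(f"{name} outside [0, 1]")
    return (1.0 - vfm) * (1.0 - nu_iso) * nu_ic


def fiber_volume_fraction(vfm, vfa):
    """Total fiber volume fraction VF_F = VF_M + VF_A (myelin + axon)."""
    vfm, vfa = np.asarray(vfm), np.asarray(vfa)
    if np.any(vfm < 0) or np.any(vfa < 0):
        raise RangeError("volume fractions must be non-negative")
    return vfm + vfa


def g_index(vfm, vff, eps: float = DEFAULT_EPS):
    """g-ratio index g = sqrt(1 - VF_M / VF_F); NaN where VF_F <= eps.

    With VF_A from `axon_volume_fraction` and in-range inputs, VF_M <= VF_F
    always holds; a violating input raises, since it signals inconsistent
    upstream maps rather than a numerical edge case.
    """
    vfm, vff = np.asarray(vfm, dtype=float), np.asarray(vff, dtype=float)
    defined = vff > eps
    if np.any(vfm[defined] > vff[defined] * (1 + 1e-12)):
        raise ValueError("vfm > vff on defined voxels: inconsistent input maps")
    ratio = np.divide(vfm, vff, out=np.zeros_like(vff), where=defined)
    g = np.sqrt(np.clip(1.0 - ratio, 0.0, 1.0))
    g = np.where(defined, g, np.nan)
    if g.ndim == 0:
        return float(g)
    return g


@dataclass
class GRatioMaps:
    """Derived axon/fiber volume fraction and g-ratio index volumes."""

    vfa: np.ndarray
    vff: np.ndarray
    g: np.ndarray
    defined_mask: np.ndarray  # where g is computable (input mask & vff > eps)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_clamped: int = 0


def compute_gratio_maps(maps, policy: str = "clamp", eps: float = DEFAULT_EPS,
                        vfm_scale: float = 1.0) -> GRatioMaps:
    """Apply the three-step g-ratio computation voxel-wise over a mask.

    Parameters
    ----------
    maps
        A :class:`gratio_dev.cohort.ParameterMaps` (or any object with
        ``vfm``, ``nu_ic``, ``nu_iso``, ``mask`` arrays and an ``affine``).
    policy
        ``"clamp"`` (default) clips slightly out-of-range input fractions
        into [0, 1] with a logged count; ``"strict"`` raises instead.
    eps
        VF_F floor below which the index is undefined.
    vfm_scale
        Optional proportionality coefficient applied to VF_M before the
        computation (default 1.0, i.e. none).
    """
    vfm = np.asarray(maps.vfm, dtype=float) * vfm_scale
    nu_ic = np.asarray(maps.nu_ic, dtype=float)
    nu_iso = np.asarray(maps.nu_iso, dtype=float)
    if not (vfm.shape == nu_ic.shape == nu_iso.shape):
        raise ValueError("parameter map shapes differ")
    mask = np.asarray(maps.mask, dtype=bool)
    if mask.shape != vfm.shape:
        raise ValueError("mask shape differs from parameter maps")

    n_clamped = 0
    vfm, n = _check_range("vfm", vfm, policy)
    n_clamped += n
    nu_ic, n = _check_range("nu_ic", nu_ic, policy)
    n_clamped += n
    nu_iso, n = _check_range("nu_iso", nu_iso, policy)
    n_clamped += n

    vfa = axon_volume_fraction(vfm, nu_ic, nu_iso)
    vff = fiber_volume_fraction(vfm, vfa)
    g = g_index(vfm, vff, eps=eps)
    defined = mask & (vff > eps)
    g = np.where(defined, g, np.nan)
    affine = getattr(maps, "affine", np.eye(4))
    return GRatioMaps(vfa=vfa, vff=vff, g=g, defined_mask=defined,
                      affine=np.asarray(affine), n_clamped=n_clamped)
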