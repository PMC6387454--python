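"""Whole-volume parameter mapping.

:func:`fit_volume` runs any of the voxelwise estimators over the in-mask
voxels of a set of co-registered stacks, after correcting each stack for its
scanner intensity scale, and assembles 3-D parameter maps with NaN sentinels
outside the mask and at voxels that could not be fitted.
"""

from __future__ import annotations

import logging

import numpy as np

from .estimators import (
    Despot1HifiEstimator,
    IrseEstimator,
    R2StarEstimator,
    VfaEstimator,
)
from .io import ImageStack, check_congruent
from .sequences import SequenceKind

__all__ = ["fit_volume", "stack_signals"]

logger = logging.getLogger(__name__)

_ATTR_FOR_MAP = {"r1": "r1_", "k": "k_", "s0": "s0_", "r2star": "r2star_", "s_te0": "s_te0_"}


def stack_signals(stacks: list[ImageStack], mask: np.ndarray) -> np.ndarray:
    """Scale-correct and flatten stacks into an (n_voxels, n_meas) design.

    A 4-D (multi-echo) stack contributes one column per echo; 3-D stacks one
    column each.  Column order follows the stack order, echoes innermost.
    """
    mask = np.asarray(mask, dtype=bool)
    cols = []
    for st in stacks:
        arr = st.corrected()
        if arr.ndim == 3:
            cols.append(arr[mask][:, None])
        elif arr.ndim == 4:
            cols.append(arr[mask, :])
        else:
            raise ValueError(f"stack data must be 3-D or 4-D, got {arr.ndim}-D")
    return np.concatenate(cols, axis=1)


def _default_estimator(stacks: list[ImageStack]):
    kinds = {st.seq.kind for st in stacks}
    if kinds == {SequenceKind.ME_SGRE}:
        return R2StarEstimator(sequence=stacks[0].seq)
    if kinds == {SequenceKind.IR_SE}:
        return IrseEstimator(sequences=[st.seq for st in stacks], magnitude=True)
    if kinds == {SequenceKind.SGRE}:
        return VfaEstimator(sequences=[st.seq for st in stacks])
    return Despot1HifiEstimator(sequences=[st.seq for st in stacks])


def fit_volume(
    stacks: list[ImageStack],
    mask: np.ndarray,
    estimator=None,
) -> dict[str, np.ndarray]:
    """Fit parameter maps over the masked voxels of co-registered stacks.

    Parameters
    ----------
    stacks:
        Spatially congruent acquisitions (same grid and affine); each is
        corrected for its intensity scale factor before fitting.
    mask:
        Boolean volume selecting the voxels to fit.
    estimator:
        One of the voxelwise estimators; by default chosen from the stack
        sequence kinds (multi-echo → R2*, IR-SE → IRSE, sGRE only → VFA,
        mixed sGRE/IR-sGRE → DESPOT1-HIFI).

    Returns
    -------
    dict
        Float maps named after the estimator's parameters (e.g. ``r1``,
        ``k``, ``s0``), plus ``converged`` (bool); unfitted voxels are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = stacks[0].shape3
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match stacks {shape}")
    check_congruent(*stacks, (mask, stacks[0].affine))
    est = estimator if estimator is not None else _default_estimator(stacks)

    X = stack_signals(stacks, mask)
    logger.info(
        "fitting %d voxels with %s (%d measurements each)",
        X.shape[0], type(est).__name__, X.shape[1],
    )
    est.fit(X)

    maps: dict[str, np.ndarray] = {}
    for name in est.map_names_:
        vol = np.full(shape, np.nan, dtype=float)
        vol[mask] = getattr(est, _ATTR_FOR_MAP[name])
        maps[name] = vol
    conv = np.zeros(shape, dtype=bool)
    conv[mask] = est.converged_
    maps["converged"] = conv
    n_bad = int(np.sum(~est.converged_))
    if n_bad:
        logger.warning("%d of %d voxels did not converge", n_bad, X.shape[0])
    return maps
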