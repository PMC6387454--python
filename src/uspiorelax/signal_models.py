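"""Steady-state MR signal models for the relaxometry protocol.

Implements closed-form signal predictions for every sequence in the protocol:

* :func:`sgre_signal` — spoiled gradient echo (Ernst equation), the basis of
  variable-flip-angle R1 mapping.
* :func:`irsgre_signal_simplified` — inversion-prepared spoiled gradient echo
  under the assumption that the low-angle readout train does not perturb the
  recovery of longitudinal magnetisation.
* :func:`irsgre_signal_brix` — the full pulse-by-pulse periodic steady state
  of the IR-sGRE sequence: perfect inversion, free recovery to the train,
  N excitation pulses of angle kβ spaced by τ (each scaling Mz by cos kβ and
  followed by recovery over τ), then free recovery to the next inversion.
  Solved exactly by composing the affine Bloch maps over one TR cycle.
* :func:`irsgre_signal_deichmann` — the closed-form approximation in which the
  pulse train drives Mz toward an effective equilibrium M0* with an effective
  relaxation rate R1* = R1 − ln(cos kβ)/τ; accounts for the train's effect on
  recovery (unlike the simplified model) without explicit pulse-by-pulse
  stepping.
* :func:`multiecho_signal` — mono-exponential R2* decay across echoes.
* :func:`irse_signal` — inversion-recovery spin echo (signed or magnitude),
  the gold standard for R1.

All functions broadcast over numpy arrays of tissue parameters, so a whole
parameter map can be pushed through a model in one call.  Flip-angle scale
``k`` is the ratio of actual to nominal flip angle (B1 inhomogeneity and slab
profile); ``k = 1`` means the nominal angle was achieved.

T2*/T2 decay at the (short) echo time is neglected for sGRE and IR-sGRE, and
the echo-time factor of the IRSE sequence is absorbed into s0; both are
constant multipliers that do not affect R1 estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import SequenceKind, SequenceParams

__all__ = [
    "VoxelParams",
    "sgre_signal",
    "irsgre_signal_simplified",
    "irsgre_signal_brix",
    "irsgre_signal_brix_iterative",
    "irsgre_signal_deichmann",
    "irsgre_signal",
    "multiecho_signal",
    "irse_signal",
    "predict_signal",
    "IRSGRE_MODELS",
]


@dataclass
class VoxelParams:
    """Ground-truth or fitted per-voxel parameters.

    ``s0`` is the maximum possible signal (fully recovered magnetisation times
    receive sensitivity), ``r1`` the longitudinal relaxation rate in s⁻¹ and
    ``k`` the flip-angle scale.  ``s_te0`` and ``r2star`` describe the
    multi-echo decay: signal at zero echo time and effective transverse
    relaxation rate in s⁻¹.  Fields may be scalars or broadcastable arrays.
    """

    s0: float | np.ndarray | None = None
    r1: float | np.ndarray | None = None
    k: float | np.ndarray = 1.0
    s_te0: float | np.ndarray | None = None
    r2star: float | np.ndarray | None = None


def _require(seq: SequenceParams, kind: SequenceKind, fn: str) -> None:
    if seq.kind is not kind:
        raise ValueError(f"{fn} expects a {kind.value} sequence, got {seq.kind.value}")


# ---------------------------------------------------------------------------
# Spoiled gradient echo
# ---------------------------------------------------------------------------

def sgre_signal(p: VoxelParams, seq: SequenceParams):
    """Steady-state spoiled-gradient-echo (Ernst) signal.

    ``s = s0 (1 − E) sin(kβ) / (1 − E cos(kβ))`` with ``E = exp(−r1·tr)``.
    """
    _require(seq, SequenceKind.SGRE, "sgre_signal")
    s0, r1, k = np.asarray(p.s0), np.asarray(p.r1), np.asarray(p.k)
    e1 = np.exp(-r1 * seq.tr)
    a = k * seq.flip_rad
    return s0 * (1.0 - e1) / (1.0 - e1 * np.cos(a)) * np.sin(a)


# ---------------------------------------------------------------------------
# IR-sGRE: simplified model
# ---------------------------------------------------------------------------

def irsgre_signal_simplified(p: VoxelParams, seq: SequenceParams):
    """IR-sGRE signal assuming the readout train does not perturb recovery.

    ``s = s0 (1 − 2 e^{−r1·TI_eff} + e^{−r1·TR}) / (1 + e^{−r1·TR}) sin(kβ)``
    with complete inversion assumed.
    """
    _require(seq, SequenceKind.IR_SGRE, "irsgre_signal_simplified")
    s0, r1, k = np.asarray(p.s0), np.asarray(p.r1), np.asarray(p.k)
    e_ti = np.exp(-r1 * seq.ti_eff)
    e_tr = np.exp(-r1 * seq.tr)
    return s0 * (1.0 - 2.0 * e_ti + e_tr) / (1.0 + e_tr) * np.sin(k * seq.flip_rad)


# ---------------------------------------------------------------------------
# IR-sGRE: full pulse-by-pulse (Brix) model
# ---------------------------------------------------------------------------

def _compose(a2, b2, a1, b1):
    """Compose affine maps: apply (a1, b1) first, then (a2, b2)."""
    return a2 * a1, a2 * b1 + b2


def _repeat_affine(a, b, n: int):
    """n-fold composition of the affine map Mz -> a·Mz + b (geometric series)."""
    an = a ** n
    # b·(1 + a + ... + a^{n-1}); stable where a ~ 1
    with np.errstate(divide="ignore", invalid="ignore"):
        series = np.where(np.isclose(a, 1.0), float(n), (1.0 - an) / (1.0 - a))
    return an, b * series


def _brix_affines(r1, k, seq: SequenceParams):
    """Affine cycle map and readout map for the pulse-by-pulse steady state.

    Returns ``(a_cyc, b_cyc, a_ro, b_ro)`` where the cycle map propagates Mz/M0
    (relative to equilibrium) across one full TR starting just before the
    inversion pulse, and the readout map propagates it from that same point to
    just before the pulse at ``readout_index``.
    """
    tau = seq.echo_spacing
    n = seq.train_length
    t1 = seq.inversion_to_train
    td = seq.post_train_delay
    cosa = np.cos(k * seq.flip_rad)

    e_t1 = np.exp(-r1 * t1)
    e_tau = np.exp(-r1 * tau)
    e_td = np.exp(-r1 * td)

    # segment maps on Mz/M0 (equilibrium = 1)
    inv = (-1.0, 0.0)                       # perfect inversion
    rel_t1 = (e_t1, 1.0 - e_t1)             # free recovery to train start
    seg = (cosa * e_tau, 1.0 - e_tau)       # pulse followed by recovery over τ
    pulse = (cosa, 0.0)
    rel_td = (e_td, 1.0 - e_td)             # post-train recovery

    a, b = inv
    a, b = _compose(*rel_t1, a, b)
    a_ro, b_ro = _compose(*_repeat_affine(*seg, seq.readout_index - 1), a, b)
    a, b = _compose(*_repeat_affine(*seg, n - 1), a, b)
    a, b = _compose(*pulse, a, b)
    a, b = _compose(*rel_td, a, b)
    return a, b, a_ro, b_ro


def irsgre_signal_brix(p: VoxelParams, seq: SequenceParams):
    """IR-sGRE signal from the exact pulse-by-pulse periodic steady state.

    The Bloch evolution of Mz over one TR cycle is affine, so the periodic
    steady state is obtained in closed form (geometric series over the train
    pulses).  The reported signal is ``sin(kβ)·Mz⁻`` just before the pulse at
    ``seq.readout_index`` (the k-space-centre pulse, by default the train
    midpoint).

    Raises
    ------
    FloatingPointError
        If the cycle map is non-contractive (|gain| >= 1), in which case no
        periodic steady state exists.
    """
    _require(seq, SequenceKind.IR_SGRE, "irsgre_signal_brix")
    s0, r1, k = np.asarray(p.s0), np.asarray(p.r1), np.asarray(p.k)
    a, b, a_ro, b_ro = _brix_affines(r1, k, seq)
    if np.any(np.abs(a) >= 1.0):
        raise FloatingPointError(
            "IR-sGRE cycle map is non-contractive (|gain| >= 1): "
            f"max |gain| = {np.max(np.abs(a)):.6g}; no periodic steady state"
        )
    mz_pre_inv = b / (1.0 - a)               # fixed point of the cycle
    mz_readout = a_ro * mz_pre_inv + b_ro
    return s0 * mz_readout * np.sin(k * seq.flip_rad)


def irsgre_signal_brix_iterative(
    p: VoxelParams, seq: SequenceParams, n_cycles: int = 10_000
):
    """Pulse-by-pulse steady state by fixed-point iteration (reference only).

    Iterates the explicit per-pulse recursion from Mz = M0 for ``n_cycles`` TR
    periods.  Slow; retained as an independent oracle for the closed-form
    solution.
    """
    _require(seq, SequenceKind.IR_SGRE, "irsgre_signal_brix_iterative")
    s0, r1, k = np.asarray(p.s0), np.asarray(p.r1), np.asarray(p.k)
    tau, n = seq.echo_spacing, seq.train_length
    t1, td = seq.inversion_to_train, seq.post_train_delay
    cosa = np.cos(k * seq.flip_rad)
    e_t1, e_tau, e_td = (np.exp(-r1 * t) for t in (t1, tau, td))

    mz = np.ones(np.broadcast(r1, k).shape)
    mz_ro = np.zeros_like(mz)
    for _ in range(n_cycles):
        mz = -mz
        mz = 1.0 + (mz - 1.0) * e_t1
        for i in range(1, n + 1):
            if i == seq.readout_index:
                mz_ro = mz.copy()
            mz = mz * cosa
            if i < n:
                mz = 1.0 + (mz - 1.0) * e_tau
        mz = 1.0 + (mz - 1.0) * e_td
    return s0 * mz_ro * np.sin(k * seq.flip_rad)


# ---------------------------------------------------------------------------
# IR-sGRE: Deichmann closed-form approximation
# ---------------------------------------------------------------------------

def irsgre_signal_deichmann(p: VoxelParams, seq: SequenceParams):
    """IR-sGRE signal from the effective-relaxation closed form.

    During the readout train the repeated low-angle pulses drive Mz toward an
    effective equilibrium with an effective rate:

    ``R1* = R1 − ln(cos kβ)/τ``,
    ``M0* = M0 (1 − e^{−R1 τ}) / (1 − e^{−R1 τ} cos kβ)``.

    The TR cycle — perfect inversion, free recovery for the delay to the
    train, effective recovery over the train window of duration N·τ, free
    recovery for the remainder of TR — is affine in Mz, and periodicity gives
    the steady state in closed form.  The signal is read at the k-space-centre
    pulse, ``(readout_index − 1)·τ`` into the train.

    Unlike the simplified model this accounts for the train's effect on
    recovery; it approximates the pulse-by-pulse model to well under 0.5% of
    s0 at protocol settings.
    """
    _require(seq, SequenceKind.IR_SGRE, "irsgre_signal_deichmann")
    s0, r1, k = np.asarray(p.s0), np.asarray(p.r1), np.asarray(p.k)
    tau, n = seq.echo_spacing, seq.train_length
    t1 = seq.inversion_to_train
    t_train = n * tau
    # residual delay; may be slightly negative when the last recovery interval
    # of the train overruns TR — an artifact of the continuous approximation
    td = seq.tr - t1 - t_train

    cosa = np.cos(k * seq.flip_rad)
    if np.any(cosa <= 0):
        raise ValueError("Deichmann model requires kβ < 90°")
    e_tau = np.exp(-r1 * tau)
    r1_eff = r1 - np.log(cosa) / tau
    m0_eff = (1.0 - e_tau) / (1.0 - e_tau * cosa)

    e_t1 = np.exp(-r1 * t1)
    e_train = np.exp(-r1_eff * t_train)
    e_ro = np.exp(-r1_eff * (seq.readout_index - 1) * tau)
    e_td = np.exp(-r1 * td)

    # affine cycle on Mz/M0, from just before the inversion pulse
    a, b = -1.0, 0.0
    a, b = _compose(e_t1, 1.0 - e_t1, a, b)                  # to train start
    a_ro, b_ro = _compose(e_ro, m0_eff * (1.0 - e_ro), a, b)  # to readout
    a, b = _compose(e_train, m0_eff * (1.0 - e_train), a, b)  # to train end
    a, b = _compose(e_td, 1.0 - e_td, a, b)                   # to next inversion
    mz_pre_inv = b / (1.0 - a)
    mz_readout = a_ro * mz_pre_inv + b_ro
    return s0 * mz_readout * np.sin(k * seq.flip_rad)


IRSGRE_MODELS = {
    "simplified": irsgre_signal_simplified,
    "deichmann": irsgre_signal_deichmann,
    "brix": irsgre_signal_brix,
}


def irsgre_signal(p: VoxelParams, seq: SequenceParams, model: str = "deichmann"):
    """Dispatch to one of the IR-sGRE models by name."""
    try:
        fn = IRSGRE_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown IR-sGRE model {model!r}; choose from {sorted(IRSGRE_MODELS)}"
        ) from None
    return fn(p, seq)


# ---------------------------------------------------------------------------
# Multi-echo gradient echo and IRSE
# ---------------------------------------------------------------------------

def multiecho_signal(p: VoxelParams, seq: SequenceParams):
    """Mono-exponential multi-echo decay ``s_i = s_TE0 · exp(−r2*·TE_i)``.

    Returns an array whose last axis runs over the echoes of ``seq.te_list``.
    ``r2star`` may be any real number (negative values model apparent signal
    growth and are permitted, matching the unconstrained fit).
    """
    _require(seq, SequenceKind.ME_SGRE, "multiecho_signal")
    s_te0, r2s = np.asarray(p.s_te0), np.asarray(p.r2star)
    te = np.asarray(seq.te_list)
    return s_te0[..., None] * np.exp(-r2s[..., None] * te)


def irse_signal(p: VoxelParams, seq: SequenceParams, magnitude: bool = False):
    """Inversion-recovery spin-echo signal.

    Signed: ``s = s0 (1 − 2 e^{−r1·TI} + e^{−r1·TR})``.  With
    ``magnitude=True`` the absolute value is returned, as recorded on
    magnitude images.
    """
    _require(seq, SequenceKind.IR_SE, "irse_signal")
    s0, r1 = np.asarray(p.s0), np.asarray(p.r1)
    s = s0 * (1.0 - 2.0 * np.exp(-r1 * seq.ti_eff) + np.exp(-r1 * seq.tr))
    return np.abs(s) if magnitude else s


def predict_signal(
    p: VoxelParams, seq: SequenceParams, irsgre_model: str = "brix"
):
    """Forward-model the signal for any sequence kind (simulation front door)."""
    if seq.kind is SequenceKind.SGRE:
        return sgre_signal(p, seq)
    if seq.kind is SequenceKind.IR_SGRE:
        return irsgre_signal(p, seq, model=irsgre_model)
    if seq.kind is SequenceKind.ME_SGRE:
        return multiecho_signal(p, seq)
    if seq.kind is SequenceKind.IR_SE:
        return irse_signal(p, seq, magnitude=True)
    raise ValueError(f"unknown sequence kind: {seq.kind}")
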