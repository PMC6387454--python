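"""Voxelwise parameter estimation as scikit-learn-style estimators.

Each estimator takes the acquisition parameters in its constructor and fits
tissue parameters from measured signals with ``fit(X)``, where ``X`` has shape
``(n_voxels, n_measurements)`` (a single 1-D voxel is accepted and treated as
one sample).  Fitted attributes carry a trailing underscore and are arrays of
length ``n_voxels``:

* :class:`Despot1HifiEstimator` — joint (s0, r1, k) estimation from multi-flip
  sGRE plus IR-sGRE data, robust to B1 inhomogeneity.  All three parameters
  are constrained positive.
* :class:`VfaEstimator` — variable-flip-angle R1 mapping from sGRE data alone
  with the flip-angle scale fixed at k = 1 (linearised DESPOT1 regression with
  optional nonlinear refinement); biased wherever the true k deviates from 1.
* :class:`R2StarEstimator` — mono-exponential (s_TE0, R2*) fit across echoes,
  unconstrained, with noise-floor exclusion of low-intensity points.
* :class:`IrseEstimator` — inversion-recovery spin-echo R1 (gold standard),
  with polarity restoration for magnitude data.

Functional wrappers (:func:`fit_despot1_hifi`, :func:`fit_vfa`,
:func:`fit_r2star`, :func:`fit_irse`) fit a single voxel and return a
:class:`FitResult`.

All fits are deterministic: fixed initialisation, no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .sequences import SequenceKind, SequenceParams
from .signal_models import VoxelParams, sgre_signal

__all__ = [
    "DegenerateInputError",
    "FitConfig",
    "FitResult",
    "Despot1HifiEstimator",
    "VfaEstimator",
    "R2StarEstimator",
    "IrseEstimator",
    "fit_despot1_hifi",
    "fit_vfa",
    "fit_r2star",
    "fit_irse",
]

_EPS = 1e-12


class DegenerateInputError(ValueError):
    """Raised when the input signals carry no information (e.g. all zero)."""


@dataclass
class FitConfig:
    """Options shared by the voxelwise fitters.

    ``model`` selects the IR-sGRE signal model for the HIFI fit.  The noise
    settings drive the R2* noise-floor exclusion: data points with intensity
    below ``noise_floor_factor * noise_sigma`` are dropped, and voxels with
    fewer than ``min_echoes`` surviving points are flagged not-fit.
    """

    model: str = "deichmann"
    max_iterations: int = 500
    tolerance: float = 1e-10
    initial_values: tuple[float, float, float] | None = None
    noise_sigma: float = 0.0
    noise_floor_factor: float = 3.0
    min_echoes: int = 2
    multistart_r1: tuple[float, ...] = (0.3, 1.0, 3.0)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.noise_floor_factor < 0:
            raise ValueError("noise_floor_factor must be >= 0")
        if self.min_echoes < 2:
            raise ValueError("min_echoes must be >= 2")


@dataclass
class FitResult:
    """Single-voxel fit outcome."""

    params: VoxelParams
    residual_sse: float
    n_points_used: int
    converged: bool


def _as_2d(X) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X[None, :], True
    if X.ndim != 2:
        raise ValueError(f"X must be 1-D or 2-D, got shape {X.shape}")
    return X, False


# ---------------------------------------------------------------------------
# Fast scalar signal predictions
#
# The voxelwise solvers evaluate the forward models thousands of times with
# scalar arguments; plain-math closures over precompiled per-sequence
# constants are an order of magnitude faster than the array signal models.
# They implement the same formulas and are pinned to the canonical models by
# an equivalence test.
# ---------------------------------------------------------------------------

def _scalar_predictor(seq: SequenceParams, model: str):
    """Return f(s0, r1, k) -> float for one sequence (sGRE or IR-sGRE)."""
    beta = seq.flip_rad
    tr = seq.tr
    if seq.kind is SequenceKind.SGRE:

        def f_sgre(s0, r1, k):
            e1 = math.exp(-r1 * tr)
            a = k * beta
            return s0 * (1.0 - e1) / (1.0 - e1 * math.cos(a)) * math.sin(a)

        return f_sgre

    if seq.kind is not SequenceKind.IR_SGRE:
        raise ValueError(f"no scalar predictor for sequence kind {seq.kind}")

    ti = seq.ti_eff
    if model == "simplified":

        def f_simpl(s0, r1, k):
            e_tr = math.exp(-r1 * tr)
            return (
                s0
                * (1.0 - 2.0 * math.exp(-r1 * ti) + e_tr)
                / (1.0 + e_tr)
                * math.sin(k * beta)
            )

        return f_simpl

    tau = seq.echo_spacing
    n = seq.train_length
    ic = seq.readout_index
    t1 = seq.inversion_to_train
    if model == "brix":
        td = seq.post_train_delay

        def f_brix(s0, r1, k):
            c = math.cos(k * beta)
            e_t1 = math.exp(-r1 * t1)
            e_tau = math.exp(-r1 * tau)
            e_td = math.exp(-r1 * td)
            g = c * e_tau
            h = 1.0 - e_tau
            # state just before the first train pulse, as affine in Mz_pre_inv
            a1, b1 = -e_t1, 1.0 - e_t1
            # repeated (pulse + recovery) segments: geometric series
            g_ro = g ** (ic - 1)
            s_ro = (ic - 1.0) if g == 1.0 else (1.0 - g_ro) / (1.0 - g)
            g_n = g ** (n - 1)
            s_n = (n - 1.0) if g == 1.0 else (1.0 - g_n) / (1.0 - g)
            a_ro, b_ro = g_ro * a1, g_ro * b1 + h * s_ro
            a, b = g_n * a1, g_n * b1 + h * s_n
            a, b = c * a, c * b                      # final pulse
            a, b = e_td * a, e_td * b + 1.0 - e_td   # post-train recovery
            mz = b / (1.0 - a)
            return s0 * (a_ro * mz + b_ro) * math.sin(k * beta)

        return f_brix

    if model == "deichmann":
        t_train = n * tau
        td2 = tr - t1 - t_train

        def f_deich(s0, r1, k):
            c = math.cos(k * beta)
            e_tau = math.exp(-r1 * tau)
            m0e = (1.0 - e_tau) / (1.0 - e_tau * c)
            r1e = r1 - math.log(c) / tau
            e_t1 = math.exp(-r1 * t1)
            e_tn = math.exp(-r1e * t_train)
            e_ro = math.exp(-r1e * (ic - 1) * tau)
            e_td = math.exp(-r1 * td2)
            a1, b1 = -e_t1, 1.0 - e_t1
            a_ro, b_ro = e_ro * a1, e_ro * b1 + m0e * (1.0 - e_ro)
            a, b = e_tn * a1, e_tn * b1 + m0e * (1.0 - e_tn)
            a, b = e_td * a, e_td * b + 1.0 - e_td
            mz = b / (1.0 - a)
            return s0 * (a_ro * mz + b_ro) * math.sin(k * beta)

        return f_deich

    raise ValueError(f"unknown IR-sGRE model {model!r}")


# ---------------------------------------------------------------------------
# DESPOT1-HIFI
# ---------------------------------------------------------------------------

class Despot1HifiEstimator(BaseEstimator):
    """Joint (s0, r1, k) estimation from sGRE + IR-sGRE signals.

    Minimises the sum of squared differences between measured and predicted
    signals per voxel, with all three parameters constrained positive.  The
    IR-sGRE prediction uses the model named by ``signal_model``
    (``'simplified'``, ``'deichmann'`` or ``'brix'``).

    Parameters
    ----------
    sequences:
        Acquisition descriptors, one per column of ``X``; at least two sGRE
        flip angles and one IR-sGRE scan are required.
    signal_model:
        IR-sGRE model used in the forward prediction.
    r1_init, k_init:
        Starting values; s0 starts from the largest measured signal divided by
        sin of that measurement's nominal flip angle.
    multistart_r1:
        Fallback r1 grid tried when the single-start fit fails to converge.
    max_iterations, tolerance:
        Solver limits (trust-region reflective least squares).

    Attributes
    ----------
    s0_, r1_, k_ : ndarray of shape (n_voxels,)
        Fitted parameters; NaN where the voxel could not be fitted.
    residual_sse_ : ndarray
        Sum of squared residuals per voxel.
    converged_ : ndarray of bool
    """

    def __init__(
        self,
        sequences: list[SequenceParams] | None = None,
        signal_model: str = "deichmann",
        r1_init: float = 1.0,
        k_init: float = 1.0,
        multistart_r1: tuple[float, ...] = (0.3, 1.0, 3.0),
        max_iterations: int = 500,
        tolerance: float = 1e-10,
    ):
        self.sequences = sequences
        self.signal_model = signal_model
        self.r1_init = r1_init
        self.k_init = k_init
        self.multistart_r1 = multistart_r1
        self.max_iterations = max_iterations
        self.tolerance = tolerance

    # -- model ------------------------------------------------------------
    def _check_sequences(self) -> list[SequenceParams]:
        seqs = self.sequences
        if seqs is None:
            from .sequences import hifi_protocol

            seqs = hifi_protocol()
        n_sgre = sum(s.kind is SequenceKind.SGRE for s in seqs)
        n_ir = sum(s.kind is SequenceKind.IR_SGRE for s in seqs)
        if n_sgre < 2 or n_ir < 1:
            raise ValueError(
                "DESPOT1-HIFI needs >=2 sGRE flip angles and >=1 IR-sGRE scan; "
                f"got {n_sgre} sGRE and {n_ir} IR-sGRE"
            )
        return seqs

    def _predict_voxel(self, theta: np.ndarray, seqs: list[SequenceParams]) -> np.ndarray:
        preds = getattr(self, "_predictors", None)
        if preds is None or len(preds) != len(seqs):
            preds = [_scalar_predictor(s, self.signal_model) for s in seqs]
            self._predictors = preds
        s0, r1, k = theta
        return np.array([f(s0, r1, k) for f in preds])

    def _fit_voxel(self, y: np.ndarray, seqs: list[SequenceParams]):
        # s0 start: strongest measurement back-projected through sin(beta) at k=1
        i_max = int(np.argmax(np.abs(y)))
        s0_init = max(np.abs(y[i_max]) / np.sin(seqs[i_max].flip_rad), _EPS)
        # k is bounded just below the point where the train flip reaches 90
        # deg (signal models undefined beyond); ~18 at a 5 deg nominal flip,
        # far outside the physical B1 range, so genuine fits are unaffected
        k_max = 0.999 * min(
            (np.pi / 2) / s.flip_rad
            for s in seqs
            if s.kind is SequenceKind.IR_SGRE
        )

        def run(x0):
            return least_squares(
                lambda th: self._predict_voxel(th, seqs) - y,
                np.minimum(x0, [np.inf, 999.0, k_max * 0.9]),
                bounds=([_EPS, _EPS, _EPS], [np.inf, 1000.0, k_max]),
                method="trf",
                xtol=self.tolerance,
                ftol=self.tolerance,
                gtol=self.tolerance,
                max_nfev=self.max_iterations * 3,
            )

        res = run(np.array([s0_init, self.r1_init, self.k_init]))
        if res.status <= 0:
            # one fallback multi-start over r1
            cands = [res] + [
                run(np.array([s0_init, r1, self.k_init])) for r1 in self.multistart_r1
            ]
            res = min(cands, key=lambda r: r.cost)
        return res.x, 2.0 * res.cost, res.status > 0

    def fit(self, X, y=None):
        seqs = self._check_sequences()
        X2, _ = _as_2d(X)
        if X2.shape[1] != len(seqs):
            raise ValueError(
                f"X has {X2.shape[1]} measurements per voxel but "
                f"{len(seqs)} sequences are configured"
            )
        n = X2.shape[0]
        self.s0_ = np.full(n, np.nan)
        self.r1_ = np.full(n, np.nan)
        self.k_ = np.full(n, np.nan)
        self.residual_sse_ = np.full(n, np.nan)
        self.converged_ = np.zeros(n, dtype=bool)
        for i in range(n):
            yv = X2[i]
            if not np.any(np.abs(yv) > 0):
                continue  # degenerate voxel: left as NaN sentinel
            theta, sse, ok = self._fit_voxel(yv, seqs)
            self.s0_[i], self.r1_[i], self.k_[i] = theta
            self.residual_sse_[i] = sse
            self.converged_[i] = ok
        self.n_features_in_ = X2.shape[1]
        return self

    def predict(self, X=None):
        """Predicted signals at the fitted parameters, shape (n_voxels, n_meas)."""
        seqs = self._check_sequences()
        out = np.empty((len(self.s0_), len(seqs)))
        for i in range(len(self.s0_)):
            out[i] = self._predict_voxel(
                np.array([self.s0_[i], self.r1_[i], self.k_[i]]), seqs
            )
        return out

    @property
    def map_names_(self) -> tuple[str, ...]:
        return ("r1", "k", "s0")


# ---------------------------------------------------------------------------
# Variable flip angle
# ---------------------------------------------------------------------------

class VfaEstimator(BaseEstimator):
    """Variable-flip-angle (DESPOT1) R1 fit with k fixed at unity.

    The sGRE equation is linear in ``y = S/sin β`` versus ``x = S/tan β`` with
    slope ``E1 = exp(−r1·tr)``; the fit is that regression, optionally refined
    by nonlinear least squares on the original signals (``refine=True``,
    the default — both agree on noiseless data).

    Attributes: ``s0_``, ``r1_``, ``residual_sse_``, ``converged_``.
    """

    def __init__(
        self,
        sequences: list[SequenceParams] | None = None,
        refine: bool = True,
        max_iterations: int = 500,
        tolerance: float = 1e-10,
    ):
        self.sequences = sequences
        self.refine = refine
        self.max_iterations = max_iterations
        self.tolerance = tolerance

    def _check_sequences(self) -> list[SequenceParams]:
        seqs = self.sequences
        if seqs is None:
            from .sequences import PROTOCOL_PRESETS

            seqs = [PROTOCOL_PRESETS[n] for n in ("sgre_fa12", "sgre_fa5", "sgre_fa3")]
        if any(s.kind is not SequenceKind.SGRE for s in seqs):
            raise ValueError("VFA fitting uses sGRE sequences only")
        if len(seqs) < 2:
            raise ValueError("VFA fitting needs >=2 flip angles")
        flips = [s.flip_deg for s in seqs]
        if len(set(flips)) < 2:
            raise np.linalg.LinAlgError(
                f"flip angles must be distinct for VFA fitting, got {flips}"
            )
        trs = {s.tr for s in seqs}
        if len(trs) != 1:
            raise ValueError("VFA fitting assumes a common tr across flip angles")
        return seqs

    def fit(self, X, y=None):
        seqs = self._check_sequences()
        X2, _ = _as_2d(X)
        if X2.shape[1] != len(seqs):
            raise ValueError("X columns must match the configured sequences")
        tr = seqs[0].tr
        alphas = np.array([s.flip_rad for s in seqs])
        yl = X2 / np.sin(alphas)
        xl = X2 / np.tan(alphas)
        xm = xl.mean(axis=1, keepdims=True)
        ym = yl.mean(axis=1, keepdims=True)
        var = ((xl - xm) ** 2).sum(axis=1)
        cov = ((xl - xm) * (yl - ym)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = cov / var
        slope = np.clip(slope, 1e-12, 1.0 - 1e-12)
        r1 = -np.log(slope) / tr
        s0 = (ym[:, 0] - slope * xm[:, 0]) / (1.0 - slope)

        n = X2.shape[0]
        conv = np.ones(n, dtype=bool)

        def predict(th):
            return np.array(
                [sgre_signal(VoxelParams(s0=th[0], r1=th[1], k=1.0), s) for s in seqs]
            )

        if self.refine:
            for i in range(n):
                if not np.any(np.abs(X2[i]) > 0):
                    r1[i] = np.nan
                    s0[i] = np.nan
                    conv[i] = False
                    continue
                res = least_squares(
                    lambda th, yv=X2[i]: predict(th) - yv,
                    np.array([max(s0[i], _EPS), max(r1[i], _EPS)]),
                    bounds=([_EPS, _EPS], [np.inf, np.inf]),
                    xtol=self.tolerance,
                    ftol=self.tolerance,
                    gtol=self.tolerance,
                    max_nfev=self.max_iterations * 2,
                )
                s0[i], r1[i] = res.x
                conv[i] = res.status > 0
        self.s0_, self.r1_ = s0, r1
        pred = np.stack(
            [
                sgre_signal(VoxelParams(s0=s0, r1=r1, k=1.0), s)
                for s in seqs
            ],
            axis=1,
        )
        self.residual_sse_ = np.nansum((pred - X2) ** 2, axis=1)
        self.converged_ = conv
        self.n_features_in_ = X2.shape[1]
        return self

    @property
    def map_names_(self) -> tuple[str, ...]:
        return ("r1", "s0")


# ---------------------------------------------------------------------------
# R2* mapping
# ---------------------------------------------------------------------------

class R2StarEstimator(BaseEstimator):
    """Unconstrained mono-exponential R2* fit with noise-floor exclusion.

    Points with intensity below ``noise_floor_factor * noise_sigma`` are
    excluded before fitting to avoid the positive bias of the magnitude-image
    (Rician) noise floor at long echo times.  Voxels retaining fewer than
    ``min_echoes`` points are flagged not-fit (NaN) rather than raising.

    ``method='nonlinear'`` (default) refines a log-linear start by
    unconstrained least squares on the magnitudes; ``method='loglinear'`` uses
    the signal-weighted log-linear regression alone (fast mode).

    Attributes: ``s_te0_``, ``r2star_``, ``n_points_used_``,
    ``residual_sse_``, ``converged_``.
    """

    def __init__(
        self,
        echo_times: tuple[float, ...] | None = None,
        sequence: SequenceParams | None = None,
        noise_sigma: float = 0.0,
        noise_floor_factor: float = 3.0,
        min_echoes: int = 2,
        method: str = "nonlinear",
        max_iterations: int = 500,
        tolerance: float = 1e-10,
    ):
        self.echo_times = echo_times
        self.sequence = sequence
        self.noise_sigma = noise_sigma
        self.noise_floor_factor = noise_floor_factor
        self.min_echoes = min_echoes
        self.method = method
        self.max_iterations = max_iterations
        self.tolerance = tolerance

    def _te(self) -> np.ndarray:
        if self.echo_times is not None:
            return np.asarray(self.echo_times, dtype=float)
        if self.sequence is not None:
            return np.asarray(self.sequence.te_list, dtype=float)
        from .sequences import PROTOCOL_PRESETS

        return np.asarray(PROTOCOL_PRESETS["me_sgre"].te_list)

    def _fit_voxel(self, te: np.ndarray, s: np.ndarray):
        keep = s >= self.noise_floor_factor * self.noise_sigma
        n_used = int(keep.sum())
        if n_used < self.min_echoes:
            return np.nan, np.nan, n_used, np.nan, False
        te_k, s_k = te[keep], s[keep]
        # log-linear start, weighted by s^2 (variance of log s ~ sigma^2/s^2)
        pos = s_k > 0
        if pos.sum() >= 2:
            w = s_k[pos] ** 2
            A = np.stack([np.ones(pos.sum()), -te_k[pos]], axis=1)
            b = np.log(s_k[pos])
            WA = A * w[:, None]
            coef = np.linalg.lstsq(WA.T @ A, WA.T @ b, rcond=None)[0]
            s_te0, r2s = np.exp(coef[0]), coef[1]
        else:
            s_te0, r2s = max(float(np.max(s_k)), _EPS), 0.0
        ok = True
        if self.method == "nonlinear":
            res = least_squares(
                lambda th: th[0] * np.exp(-th[1] * te_k) - s_k,
                np.array([s_te0, r2s]),
                method="lm",
                xtol=self.tolerance,
                ftol=self.tolerance,
                gtol=self.tolerance,
                max_nfev=self.max_iterations * 2,
            )
            s_te0, r2s = res.x
            sse = 2.0 * res.cost
            ok = res.status > 0
        else:
            sse = float(np.sum((s_te0 * np.exp(-r2s * te_k) - s_k) ** 2))
        return s_te0, r2s, n_used, sse, ok

    def fit(self, X, y=None):
        te = self._te()
        X2, _ = _as_2d(X)
        if X2.shape[1] != len(te):
            raise ValueError(
                f"X has {X2.shape[1]} echoes but {len(te)} echo times configured"
            )
        n = X2.shape[0]
        self.s_te0_ = np.full(n, np.nan)
        self.r2star_ = np.full(n, np.nan)
        self.n_points_used_ = np.zeros(n, dtype=int)
        self.residual_sse_ = np.full(n, np.nan)
        self.converged_ = np.zeros(n, dtype=bool)
        for i in range(n):
            out = self._fit_voxel(te, X2[i])
            (
                self.s_te0_[i],
                self.r2star_[i],
                self.n_points_used_[i],
                self.residual_sse_[i],
                self.converged_[i],
            ) = out
        self.n_features_in_ = X2.shape[1]
        return self

    def predict(self, X=None):
        te = self._te()
        return self.s_te0_[:, None] * np.exp(-np.outer(self.r2star_, te))

    @property
    def map_names_(self) -> tuple[str, ...]:
        return ("r2star", "s_te0")


# ---------------------------------------------------------------------------
# IRSE gold standard
# ---------------------------------------------------------------------------

class IrseEstimator(BaseEstimator):
    """Inversion-recovery spin-echo (s0, r1) fit.

    With ``magnitude=True`` the polarity of each point is unknown; the fitter
    restores it by trying every sign assignment consistent with a single
    zero-crossing along the (sorted) inversion times and keeping the best SSE.

    Attributes: ``s0_``, ``r1_``, ``residual_sse_``, ``converged_``.
    """

    def __init__(
        self,
        sequences: list[SequenceParams] | None = None,
        magnitude: bool = False,
        max_iterations: int = 500,
        tolerance: float = 1e-10,
    ):
        self.sequences = sequences
        self.magnitude = magnitude
        self.max_iterations = max_iterations
        self.tolerance = tolerance

    def _check_sequences(self) -> list[SequenceParams]:
        seqs = self.sequences
        if seqs is None:
            from .sequences import irse_series

            seqs = irse_series()
        if any(s.kind is not SequenceKind.IR_SE for s in seqs):
            raise ValueError("IRSE fitting expects IR-SE sequences")
        if len(seqs) < 3:
            raise ValueError("IRSE fitting needs >=3 inversion times")
        return seqs

    # coarse r1 grid for initialisation / polarity selection; s0 is profiled
    # out analytically (the model is linear in s0 at fixed r1)
    _R1_GRID = np.geomspace(0.05, 20.0, 48)

    def _recovery_matrix(self, ti: np.ndarray, tr: float) -> np.ndarray:
        g = (
            1.0
            - 2.0 * np.exp(-np.outer(self._R1_GRID, ti))
            + np.exp(-self._R1_GRID * tr)[:, None]
        )
        return g

    def _fit_voxel(self, ti: np.ndarray, tr: float, y: np.ndarray, G, Gsq):
        # candidate polarities: all sign assignments with a single
        # zero-crossing along the sorted inversion times (signed data: one)
        if self.magnitude:
            order = np.argsort(ti)
            patterns = []
            for j in range(len(ti) + 1):
                s = np.ones(len(ti))
                s[order[:j]] = -1.0
                patterns.append(s)
        else:
            patterns = [np.ones(len(ti))]

        best = None  # (sse_grid, ys, s0_init, r1_init)
        for signs in patterns:
            ys = signs * y
            num = G @ ys
            with np.errstate(invalid="ignore"):
                sse = ys @ ys - num**2 / Gsq
            j = int(np.argmin(sse))
            if best is None or sse[j] < best[0]:
                best = (sse[j], ys, num[j] / Gsq[j], float(self._R1_GRID[j]))
        _, ys, s0_init, r1_init = best

        res = least_squares(
            lambda th: th[0]
            * (1.0 - 2.0 * np.exp(-th[1] * ti) + np.exp(-th[1] * tr))
            - ys,
            np.array([max(s0_init, _EPS), r1_init]),
            method="lm",
            xtol=self.tolerance,
            ftol=self.tolerance,
            gtol=self.tolerance,
            max_nfev=self.max_iterations * 2,
        )
        return res.x, 2.0 * res.cost, res.status > 0

    def fit(self, X, y=None):
        seqs = self._check_sequences()
        ti = np.array([s.ti_eff for s in seqs])
        tr = seqs[0].tr
        X2, _ = _as_2d(X)
        if X2.shape[1] != len(seqs):
            raise ValueError("X columns must match the configured inversion times")
        n = X2.shape[0]
        self.s0_ = np.full(n, np.nan)
        self.r1_ = np.full(n, np.nan)
        self.residual_sse_ = np.full(n, np.nan)
        self.converged_ = np.zeros(n, dtype=bool)
        G = self._recovery_matrix(ti, tr)
        Gsq = (G**2).sum(axis=1)
        for i in range(n):
            if not np.any(np.abs(X2[i]) > 0):
                continue
            (s0, r1), sse, ok = self._fit_voxel(ti, tr, X2[i], G, Gsq)
            self.s0_[i], self.r1_[i] = s0, r1
            self.residual_sse_[i] = sse
            self.converged_[i] = ok
        self.n_features_in_ = X2.shape[1]
        return self

    @property
    def map_names_(self) -> tuple[str, ...]:
        return ("r1", "s0")


# ---------------------------------------------------------------------------
# Functional wrappers (single voxel)
# ---------------------------------------------------------------------------

def _single_result(est, names: dict[str, str], n_points: int) -> FitResult:
    p = VoxelParams(**{dst: float(getattr(est, src)[0]) for dst, src in names.items()})
    return FitResult(
        params=p,
        residual_sse=float(est.residual_sse_[0]),
        n_points_used=n_points,
        converged=bool(est.converged_[0]),
    )


def fit_despot1_hifi(
    signals, seqs: list[SequenceParams], cfg: FitConfig | None = None
) -> FitResult:
    """Single-voxel DESPOT1-HIFI fit; raises on all-zero input."""
    cfg = cfg or FitConfig()
    y = np.asarray(signals, dtype=float)
    if not np.any(np.abs(y) > 0):
        raise DegenerateInputError("all-zero signal vector cannot be fitted")
    init = cfg.initial_values or (None, 1.0, 1.0)
    est = Despot1HifiEstimator(
        sequences=seqs,
        signal_model=cfg.model,
        r1_init=init[1],
        k_init=init[2],
        multistart_r1=cfg.multistart_r1,
        max_iterations=cfg.max_iterations,
        tolerance=cfg.tolerance,
    ).fit(y)
    return _single_result(est, {"s0": "s0_", "r1": "r1_", "k": "k_"}, len(y))


def fit_vfa(signals, seqs: list[SequenceParams], cfg: FitConfig | None = None) -> FitResult:
    cfg = cfg or FitConfig()
    y = np.asarray(signals, dtype=float)
    est = VfaEstimator(
        sequences=seqs, max_iterations=cfg.max_iterations, tolerance=cfg.tolerance
    ).fit(y)
    res = _single_result(est, {"s0": "s0_", "r1": "r1_"}, len(y))
    res.params.k = 1.0
    return res


def fit_r2star(signals, seq: SequenceParams, cfg: FitConfig | None = None) -> FitResult:
    cfg = cfg or FitConfig()
    y = np.asarray(signals, dtype=float)
    est = R2StarEstimator(
        sequence=seq,
        noise_sigma=cfg.noise_sigma,
        noise_floor_factor=cfg.noise_floor_factor,
        min_echoes=cfg.min_echoes,
        max_iterations=cfg.max_iterations,
        tolerance=cfg.tolerance,
    ).fit(y)
    return _single_result(
        est, {"s_te0": "s_te0_", "r2star": "r2star_"}, int(est.n_points_used_[0])
    )


def fit_irse(
    signals,
    seq_list: list[SequenceParams],
    cfg: FitConfig | None = None,
    magnitude: bool = False,
) -> FitResult:
    cfg = cfg or FitConfig()
    y = np.asarray(signals, dtype=float)
    est = IrseEstimator(
        sequences=seq_list,
        magnitude=magnitude,
        max_iterations=cfg.max_iterations,
        tolerance=cfg.tolerance,
    ).fit(y)
    return _single_result(est, {"s0": "s0_", "r1": "r1_"}, len(y))
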