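"""Indel-spectrum decomposition of a break-site trace against a control.

An experimental chromatogram downstream of a double-strand break is modeled
as a non-negative mixture of copies of the control chromatogram shifted by
every candidate net indel size k in [-K, +K]: a net indel of k bases makes
sample position p read what the control reads at p - k.  Solving the
non-negative least-squares problem over a window that starts beyond the
largest modeled insertion (so no modeled position overlaps unknown inserted
bases) yields, after renormalization, the indel spectrum: the fraction of
molecules carrying each net indel.

Decomposition is deterministic given its inputs.  Quality control is a
pre-break background statistic (mean fraction of signal in non-called
channels); samples exceeding the background threshold are flagged and
refused by downstream classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .reference import ReferenceConstruct, locate_recognition_site
from .trace import BASES, TraceData


class RegistrationError(ValueError):
    """Sample trace could not be registered against the control."""


class DegenerateSignalError(ValueError):
    """The decomposition window carries no usable signal."""


class WindowConfigError(ValueError):
    """A decomposition/alignment window is out of bounds or ill-formed."""


@dataclass(frozen=True)
class DecompositionConfig:
    """Tunables for the mixture decomposition.

    ``align_window`` / ``decomp_window`` are absolute 1-based closed
    intervals; ``None`` selects the defaults relative to the break position
    and trace length: align on [break-100, break-20] (upstream, indel-free
    in every molecule) and decompose on [break+K+5, end-K-10] (downstream
    of the largest modeled insertion, with headroom so every shifted model
    stays within the control).
    """

    max_indel: int = 35
    align_window: tuple[int, int] | None = None
    decomp_window: tuple[int, int] | None = None
    background_threshold: float = 0.15
    nonneg_tol: float = 1e-9
    offset_search: int = 20
    min_align_corr: float = 0.8

    def __post_init__(self) -> None:
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")
        if not 0.0 <= self.background_threshold <= 1.0:
            raise ValueError("background_threshold must be in [0, 1]")

    def resolved_align_window(self, break_position: int) -> tuple[int, int]:
        if self.align_window is not None:
            lo, hi = self.align_window
        else:
            lo, hi = break_position - 100, break_position - 20
        if lo < 1 or hi <= lo or hi >= break_position:
            raise WindowConfigError(
                f"align window [{lo}, {hi}] must lie upstream of the break "
                f"at {break_position} and within the trace"
            )
        return lo, hi

    def resolved_decomp_window(
        self, break_position: int, control_end: int
    ) -> tuple[int, int]:
        K = self.max_indel
        if self.decomp_window is not None:
            lo, hi = self.decomp_window
        else:
            lo, hi = break_position + K + 5, control_end - K - 10
        if lo <= break_position + K:
            raise WindowConfigError(
                f"decomp window must start after break + K = {break_position + K}"
            )
        if hi <= lo:
            raise WindowConfigError(f"decomp window [{lo}, {hi}] is empty")
        if lo - K < 1 or hi + K > control_end:
            raise WindowConfigError(
                f"decomp window [{lo}, {hi}] overflows the control trace for "
                f"shifts up to +/-{K} (control ends at {control_end})"
            )
        return lo, hi


@dataclass(frozen=True)
class IndelSpectrum:
    """Normalized non-negative weights over shifts -K..+K with diagnostics."""

    weights: dict[int, float]
    r_squared: float
    background: float
    qc_pass: bool
    window_used: tuple[int, int]
    offset: int = 0
    t_stats: dict[int, float] = field(default_factory=dict)

    def weight(self, k: int) -> float:
        return self.weights.get(k, 0.0)

    @property
    def max_indel(self) -> int:
        return max(abs(k) for k in self.weights)


def estimate_offset(
    control: TraceData,
    sample: TraceData,
    cfg: DecompositionConfig,
    break_position: int,
) -> int:
    """Register the sample to the control upstream of the break.

    Returns the offset o maximizing the summed cross-channel correlation of
    sample[w + o] against control[w] over the alignment window, i.e. the o
    for which sample position p reads control position p - o.  Offsets in
    [-offset_search, +offset_search] are scanned exhaustively.
    """
    lo, hi = cfg.resolved_align_window(break_position)
    if lo < control.start or hi > control.end:
        raise WindowConfigError(
            f"align window [{lo}, {hi}] outside control bounds"
        )
    ref_block = control.rows(np.arange(lo, hi + 1)).ravel()
    if np.ptp(ref_block) == 0:
        raise RegistrationError("control alignment window is constant")
    best_offset, best_corr = None, -np.inf
    for o in range(-cfg.offset_search, cfg.offset_search + 1):
        if lo + o < sample.start or hi + o > sample.end:
            continue
        blk = sample.rows(np.arange(lo + o, hi + o + 1)).ravel()
        if np.ptp(blk) == 0:
            continue
        r = float(np.corrcoef(ref_block, blk)[0, 1])
        if r > best_corr:
            best_corr, best_offset = r, o
    if best_offset is None or best_corr < cfg.min_align_corr:
        raise RegistrationError(
            f"registration failed: best correlation {best_corr:.3f} < "
            f"{cfg.min_align_corr} (sample unusable)"
        )
    return best_offset


def build_shifted_models(
    control: TraceData,
    cfg: DecompositionConfig,
    break_position: int,
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model matrix of indel-shifted control signals over the window.

    Column j holds the stacked four-channel control intensities predicted
    under net indel k = shifts[j]: window position p maps to control
    position p - k.  Shifts are returned in fixed order -K..+K.
    """
    K = cfg.max_indel
    if window is None:
        window = cfg.resolved_decomp_window(break_position, control.end)
    lo, hi = window
    if lo - K < control.start or hi + K > control.end:
        raise WindowConfigError(
            f"window [{lo}, {hi}] with K={K} overflows control bounds "
            f"[{control.start}, {control.end}]"
        )
    positions = np.arange(lo, hi + 1)
    shifts = np.arange(-K, K + 1)
    A = np.empty((positions.size * 4, shifts.size), dtype=float)
    for j, k in enumerate(shifts):
        A[:, j] = control.rows(positions - k).ravel()
    return A, shifts


def background_qc(trace: TraceData, window: tuple[int, int]) -> float:
    """Mean fraction of per-position signal in non-called channels.

    Positions with zero total intensity are excluded from the mean; an
    all-zero window is an error.  N-called positions (argmax ties) use the
    max channel as the called intensity.
    """
    lo, hi = window
    if hi - lo + 1 < 1:
        raise WindowConfigError("background window is empty")
    block = trace.rows(np.arange(lo, hi + 1))
    called = trace.called_base[np.arange(lo, hi + 1) - trace.start]
    totals = block.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise DegenerateSignalError("background window has zero total intensity")
    called_idx = np.array(
        [BASES.index(b) if b in BASES else int(np.argmax(row)) for b, row in zip(called, block)]
    )
    called_intensity = block[np.arange(len(block)), called_idx]
    frac = (totals[keep] - called_intensity[keep]) / totals[keep]
    return float(frac.mean())


def _component_t_stats(
    A: np.ndarray, b: np.ndarray, w: np.ndarray, shifts: np.ndarray
) -> dict[int, float]:
    """Reporting-only t statistics for the fitted components (no gating)."""
    active = w > 0
    if not active.any():
        return {}
    Aa = A[:, active]
    resid = b - A @ w
    dof = max(1, A.shape[0] - int(active.sum()))
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.pinv(Aa.T @ Aa)
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        return {}
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    out: dict[int, float] = {}
    for k, wk, s in zip(shifts[active], w[active], se):
        out[int(k)] = float(wk / s) if s > 0 else float("inf")
    return out


def decompose(
    control: TraceData,
    sample: TraceData,
    ref: ReferenceConstruct | int,
    cfg: DecompositionConfig | None = None,
) -> IndelSpectrum:
    """Decompose a sample trace into its indel spectrum against the control.

    ``ref`` may be a construct (the break is located from its geometry) or
    an explicit 1-based break position.  The sample is first registered to
    the control over the upstream alignment window; the non-negative
    least-squares fit is then solved over the downstream decomposition
    window, truncated at ``nonneg_tol`` and renormalized to sum to one.
    """
    cfg = cfg or DecompositionConfig()
    break_position = ref if isinstance(ref, int) else locate_recognition_site(ref)
    offset = estimate_offset(control, sample, cfg, break_position)

    lo, hi = cfg.resolved_decomp_window(break_position, control.end)
    hi = min(hi, sample.end - offset)
    if hi <= lo:
        raise WindowConfigError(
            "sample trace too short to cover the decomposition window"
        )
    A, shifts = build_shifted_models(control, cfg, break_position, (lo, hi))
    b = sample.rows(np.arange(lo + offset, hi + offset + 1)).ravel()
    if not np.any(b > 0):
        raise DegenerateSignalError("all-zero sample decomposition window")

    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn(
            "shifted models are rank-deficient (repetitive control); the "
            "minimum-norm non-negative solution is reported",
            RuntimeWarning,
            stacklevel=2,
        )
    w, _ = scipy.optimize.nnls(A, b)

    fitted = A @ w
    ss_res = float(np.sum((b - fitted) ** 2))
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r_squared = 0.0 if ss_tot == 0 else float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    t_stats = _component_t_stats(A, b, w, shifts)

    w = np.where(w < cfg.nonneg_tol, 0.0, w)
    total = w.sum()
    if total <= 0:
        raise DegenerateSignalError("decomposition produced an all-zero spectrum")
    w /= total

    alo, ahi = cfg.resolved_align_window(break_position)
    background = background_qc(sample, (alo + offset, ahi + offset))
    return IndelSpectrum(
        weights={int(k): float(v) for k, v in zip(shifts, w)},
        r_squared=r_squared,
        background=background,
        qc_pass=background <= cfg.background_threshold,
        window_used=(lo, hi),
        offset=offset,
        t_stats=t_stats,
    )
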