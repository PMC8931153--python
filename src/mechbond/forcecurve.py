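"""Pulling force–time trace analysis.

Rupture force is read from the global maximum of the force spectrum; traces
whose rupture force exceeds a threshold (default 200 pN) are classified as
the high-strength dissociation pathway (type 1), the rest as type 2.
Clamp-window segmentation locates the plateau where the trace holds a
target force.  No smoothing is applied by default — the raw maximum is the
rupture force — but a centred moving average is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .structio import ForceTrace

__all__ = [
    "RuptureResult",
    "ClampWindow",
    "smooth",
    "rupture",
    "ramp_force_model",
    "clamp_windows",
    "PATHWAY_THRESHOLD_PN",
]

#: rupture-force threshold splitting the two dissociation pathways, pN
PATHWAY_THRESHOLD_PN = 200.0


@dataclass
class RuptureResult:
    rupture_force_pN: float
    rupture_time_ns: float
    pathway_type: str  # 'type1' | 'type2'


@dataclass
class ClampWindow:
    target_pN: float
    t_start_ns: float
    t_end_ns: float
    mean_force_pN: float
    found: bool


def smooth(trace: ForceTrace, window_ns: float) -> ForceTrace:
    """Centred moving average; endpoints use shrunken windows.

    ``window_ns`` below one sample spacing is an identity; a window larger
    than the trace span is an error.
    """
    span = trace.t_ns[-1] - trace.t_ns[0]
    if window_ns > span:
        raise ValueError("smoothing window larger than trace span")
    n = max(1, int(round(window_ns / trace.dt_ns)))
    if n % 2 == 0:
        n += 1
    if n == 1:
        return ForceTrace(trace.t_ns.copy(), trace.f_pN.copy())
    f = (
        pd.Series(trace.f_pN)
        .rolling(window=n, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return ForceTrace(trace.t_ns.copy(), f)


def rupture(
    trace: ForceTrace,
    smooth_window_ns: float | None = None,
    pathway_threshold_pN: float = PATHWAY_THRESHOLD_PN,
) -> RuptureResult:
    """Rupture force/time from the maximum of the (optionally smoothed) spectrum.

    Ties at the maximum resolve to the earliest time.  The pathway split is
    strict: only rupture forces *greater than* the threshold are type 1.
    """
    tr = trace if smooth_window_ns is None else smooth(trace, smooth_window_ns)
    k = int(np.argmax(tr.f_pN))  # argmax returns the first (earliest) maximum
    force = float(tr.f_pN[k])
    return RuptureResult(
        rupture_force_pN=force,
        rupture_time_ns=float(tr.t_ns[k]),
        pathway_type="type1" if force > pathway_threshold_pN else "type2",
    )


def ramp_force_model(
    t_ns: np.ndarray,
    extension_A: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    k_pN_per_A: float = 13.9,
    v_A_per_ns: float = 3.0,
) -> np.ndarray:
    """Virtual-spring force during constant-velocity pulling.

    F(t) = k · (v·t − x(t)) where x(t) is the attachment-point extension;
    a stalled attachment (x = 0) gives the stiff-spring ramp k·v·t.
    """
    t = np.asarray(t_ns, dtype=float)
    x = extension_A(t) if callable(extension_A) else np.asarray(extension_A, dtype=float)
    return k_pN_per_A * (v_A_per_ns * t - x)


def clamp_windows(
    trace: ForceTrace,
    target_forces_pN: Sequence[float],
    tolerance_pN: float,
) -> list[ClampWindow]:
    """Locate, per target, the longest contiguous window with |F − target| ≤ tol.

    A target the trace never holds yields a ``found=False`` window with NaN
    bounds.
    """
    targets = list(target_forces_pN)
    if sorted(targets) != targets:
        raise ValueError("target forces must be sorted ascending")
    out: list[ClampWindow] = []
    for tgt in targets:
        ok = np.abs(trace.f_pN - tgt) <= tolerance_pN
        best: tuple[int, int] | None = None
        start = None
        for idx, flag in enumerate(np.append(ok, False)):
            if flag and start is None:
                start = idx
            elif not flag and start is not None:
                if best is None or idx - start > best[1] - best[0]:
                    best = (start, idx)
                start = None
        if best is None:
            out.append(ClampWindow(tgt, float("nan"), float("nan"), float("nan"), False))
        else:
            lo, hi = best
            out.append(
                ClampWindow(
                    tgt,
                    float(trace.t_ns[lo]),
                    float(trace.t_ns[hi - 1]),
                    float(trace.f_pN[lo:hi].mean()),
                    True,
                )
            )
    return out
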