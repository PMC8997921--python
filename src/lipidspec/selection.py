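"""Variable selection for spectral calibration models.

Two procedures are implemented:

* :func:`region_retrain` — retrain on user-supplied regions of interest
  (axis windows) and keep the restricted model only if its cross-validated
  performance beats the full-spectrum baseline.  Typical for NIR, where the
  informative CH-overtone regions are known a priori.
* :func:`bottom_up_select` — forward selection over consecutive fixed-size
  channel blocks: evaluate each block alone by CV, keep the best, then
  repeatedly try adding each remaining block and keep the best addition as
  long as the minimum RMSECV keeps improving.  Typical for Raman, where a
  few narrow bands carry the signal.

"Performance" throughout is the minimum RMSECV over component counts; the
R²_cv trace is logged alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemometrics import CVResult, cross_validate


@dataclass
class SelectionResult:
    """Outcome of a variable-selection run.

    ``blocks`` lists accepted (start, stop) channel-index ranges
    (half-open) in acceptance order; ``trace`` holds the best RMSECV after
    each acceptance; ``selected`` is the final sorted channel index set.
    """

    blocks: list[tuple[int, int]]
    trace: list[float]
    r2_trace: list[float]
    selected: np.ndarray
    stopping_reason: str
    kept_restricted: bool | None = None
    cv: CVResult | None = None
    log: list[dict] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _channels_for_regions(axis: np.ndarray, regions: list[tuple[float, float]]) -> np.ndarray:
    keep = np.zeros(len(axis), dtype=bool)
    for lo, hi in regions:
        keep |= (axis >= lo) & (axis <= hi)
    return np.where(keep)[0]


def region_retrain(X: np.ndarray, y: np.ndarray, axis: np.ndarray,
                   regions: list[tuple[float, float]], a_max: int, k: int = 7,
                   baseline_cv: CVResult | None = None) -> SelectionResult:
    """Retrain on regions of interest; keep the restricted model iff better.

    The restricted model is kept only when its best RMSECV is strictly lower
    than the full-spectrum baseline's (ties keep the baseline).
    """
    X = np.asarray(X, dtype=float)
    axis = np.asarray(axis, dtype=float)
    channels = _channels_for_regions(axis, regions)
    if len(channels) == 0:
        raise ValueError("regions of interest select no channels")
    if baseline_cv is None:
        baseline_cv = cross_validate(X, y, min(a_max, X.shape[1]), k)
    restricted_cv = cross_validate(X[:, channels], y, min(a_max, len(channels)), k)
    keep = restricted_cv.best_rmsecv < baseline_cv.best_rmsecv
    if keep:
        selected = channels
        cv = restricted_cv
        reason = "restricted model improved RMSECV"
    else:
        selected = np.arange(X.shape[1])
        cv = baseline_cv
        reason = "baseline kept (regions did not improve RMSECV)"
    return SelectionResult(
        blocks=[(int(channels[0]), int(channels[-1]) + 1)] if keep else
               [(0, X.shape[1])],
        trace=[cv.best_rmsecv],
        r2_trace=[float(cv.r2cv[cv.best_a - 1])],
        selected=selected,
        stopping_reason=reason,
        kept_restricted=bool(keep),
        cv=cv,
        log=[{"baseline_rmsecv": baseline_cv.best_rmsecv,
              "restricted_rmsecv": restricted_cv.best_rmsecv,
              "kept_restricted": bool(keep)}],
    )


def _partition_blocks(p: int, block_size: int) -> list[tuple[int, int]]:
    """Consecutive half-open blocks of block_size; last block may be smaller."""
    return [(s, min(s + block_size, p)) for s in range(0, p, block_size)]


def bottom_up_select(X: np.ndarray, y: np.ndarray, block_size: int = 100,
                     k: int = 7, a_max: int = 20, tol: float = 0.0) -> SelectionResult:
    """Forward selection over consecutive channel blocks.

    Round 1 cross-validates each block alone and keeps the lowest-RMSECV
    block.  Each later round cross-validates the current selection plus
    every remaining block and accepts the best candidate iff it lowers the
    minimum RMSECV by more than ``tol``; otherwise the procedure stops.
    Component count is re-optimized by CV for every candidate; ties between
    candidates break to the lower block index.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < block_size:
        raise ValueError(f"need at least block_size={block_size} channels, got {p}")
    blocks = _partition_blocks(p, block_size)
    remaining = list(range(len(blocks)))
    accepted: list[tuple[int, int]] = []
    selected = np.array([], dtype=int)
    trace: list[float] = []
    r2_trace: list[float] = []
    log: list[dict] = []
    best_cv: CVResult | None = None
    current_best = np.inf
    reason = "no blocks accepted"
    for round_no in range(len(blocks)):
        round_scores = []
        for bi in remaining:
            lo, hi = blocks[bi]
            cand = np.union1d(selected, np.arange(lo, hi))
            cv = cross_validate(X[:, cand], y, min(a_max, len(cand)), k)
            round_scores.append((cv.best_rmsecv, bi, cand, cv))
        round_scores.sort(key=lambda t: (t[0], t[1]))
        best_score, best_bi, best_cand, best_cand_cv = round_scores[0]
        log.append({"round": round_no + 1,
                    "scores": {bi: float(s) for s, bi, _, _ in round_scores},
                    "accepted_block": best_bi if (round_no == 0 or
                                                  best_score < current_best - tol) else None})
        if round_no > 0 and not (best_score < current_best - tol):
            reason = "no candidate improved RMSECV beyond tol"
            break
        accepted.append(blocks[best_bi])
        remaining.remove(best_bi)
        selected = best_cand
        current_best = best_score
        best_cv = best_cand_cv
        trace.append(float(best_score))
        r2_trace.append(float(best_cand_cv.r2cv[best_cand_cv.best_a - 1]))
        if not remaining:
            reason = "all blocks accepted"
            break
        if np.isinf(tol):
            reason = "tol=inf: stopped after the first round"
            break
    return SelectionResult(blocks=accepted, trace=trace, r2_trace=r2_trace,
                           selected=selected, stopping_reason=reason,
                           cv=best_cv, log=log)


def blocks_to_axis_ranges(blocks: list[tuple[int, int]], axis: np.ndarray
                          ) -> list[tuple[float, float]]:
    """Accepted channel-index blocks expressed in axis units."""
    axis = np.asarray(axis, dtype=float)
    return [(float(axis[lo]), float(axis[hi - 1])) for lo, hi in blocks]
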