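"""Single-sample likelihood profiles and the dysfunction metrics built on them.

Given the per-timepoint log-likelihood curves of a test vector, the combined
likelihood curve is the truncated average

    log L_g(t) = (1/N_t) * sum_i max{log L_{g,i}(t), l_thresh},

whose argmax is the sample's internal phase T and whose maximum is ML.  The
likelihood ratio function (LRF) R_g(t) = L_g(t)/L_g(T) is compared with the
phase-shifted cosine reference

    C(t|T) = eta * (1 + eps + cos 2*pi*(t - T)/24)

to produce the dysfunction metric theta: the proportion of the day on which
the LRF lies strictly above C(t|T).  Peaks of the LRF, flat (floored)
regions, the likelihood-ratio statistic lambda, and the lowML / highTvar /
relTwrong dysfunction flags are all derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThetaConfig",
    "Peak",
    "LikelihoodProfile",
    "reference_curve",
    "combine_loglik",
    "estimate_phase",
    "theta",
    "find_peaks",
    "adjust_time_by_second_peak",
    "build_profile",
    "choose_lthresh",
    "classify_dysfunction",
]

_FLAT_TOL = 1e-9


@dataclass(frozen=True)
class ThetaConfig:
    """Parameters of the reference curve C(t|T) = eta*(1+eps+cos 2pi(t-T)/24).

    The admissible region is 0 < eta*eps < eta*(2+eps) < 1: the trough of C
    is positive and its crest stays below the LRF's maximum of 1, so theta
    is never degenerate by construction.
    """

    eta: float = 0.35
    eps: float = 0.15

    def __post_init__(self):
        lo = self.eta * self.eps
        hi = self.eta * (2.0 + self.eps)
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(
                f"invalid theta config: need 0 < eta*eps < eta*(2+eps) < 1, "
                f"got eta={self.eta}, eps={self.eps}"
            )


def reference_curve(grid_times: np.ndarray, T: float, cfg: ThetaConfig) -> np.ndarray:
    """C(t|T): scaled cosine with its maximum at the internal phase T."""
    return cfg.eta * (
        1.0 + cfg.eps + np.cos(2.0 * np.pi * (np.asarray(grid_times) - T) / 24.0)
    )


@dataclass
class Peak:
    time: float
    height: float
    prominence: float


@dataclass
class LikelihoodProfile:
    """Everything the model reports about one test sample."""

    grid_times: np.ndarray
    log_l: np.ndarray
    t: float
    ml: float
    log_ml: float
    lrf: np.ndarray
    theta: float
    peaks: list[Peak]
    flat_fraction: float
    lambda_stat: float | None = None
    flags: set = field(default_factory=set)
    sample_id: object = None
    t_adjusted: float | None = None
    l_thresh: float | None = None
    theta_config: ThetaConfig | None = None

    @property
    def second_peak_time(self) -> float | None:
        return self.peaks[1].time if len(self.peaks) > 1 else None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def combine_loglik(curves, l_thresh: float) -> np.ndarray:
    """Pointwise mean of per-timepoint log-likelihood curves floored at l_thresh."""
    arr = np.asarray(curves, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] == 0:
        raise ValueError("no per-timepoint curves to combine")
    return np.maximum(arr, l_thresh).mean(axis=0)


def estimate_phase(log_l: np.ndarray, grid_times: np.ndarray) -> tuple[float, float, set]:
    """Internal phase T (argmax, earliest on ties) and ML = exp(max).

    Returns ``(T, ML, flags)`` where flags may contain ``flat_curve`` (the
    curve is constant) or ``multimodal`` (several grid points tie for the
    maximum).
    """
    log_l = np.asarray(log_l, dtype=float)
    if log_l.size == 0:
        raise ValueError("empty likelihood curve")
    idx = int(np.argmax(log_l))
    mx = log_l[idx]
    flags: set = set()
    ties = np.flatnonzero(log_l >= mx - 1e-12)
    if len(ties) == log_l.size:
        flags.add("flat_curve")
    elif len(ties) > 1:
        flags.add("multimodal")
    return float(grid_times[idx]), float(np.exp(mx)), flags


def theta(lrf: np.ndarray, T: float, cfg: ThetaConfig, grid_times: np.ndarray) -> float:
    """Proportion of grid times where the LRF lies strictly above C(t|T)."""
    C = reference_curve(grid_times, T, cfg)
    return float(np.mean(np.asarray(lrf) > C))


def _circular_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Contiguous index runs of True in a circular boolean array."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, then find linear runs
    start = int(np.flatnonzero(~mask)[0])
    rolled = np.roll(mask, -start)
    runs = []
    in_run = False
    for k in range(n):
        if rolled[k] and not in_run:
            a = k
            in_run = True
        elif not rolled[k] and in_run:
            runs.append((np.arange(a, k) + start) % n)
            in_run = False
    if in_run:
        runs.append((np.arange(a, n) + start) % n)
    return runs


def find_peaks(
    lrf: np.ndarray,
    grid_times: np.ndarray,
    cfg: ThetaConfig,
    T: float | None = None,
    min_prominence: float = 0.0,
) -> list[Peak]:
    """Local maxima of the LRF on the circular grid, sorted by height.

    By default a candidate peak is significant when its height exceeds the
    reference curve C(t|T) at its own location; an additional numeric
    prominence threshold can be supplied.  Plateaus count once.  The
    returned list is sorted descending by height, so the element after the
    global peak (if any) carries the second-peak time.
    """
    v = np.asarray(lrf, dtype=float)
    n = len(v)
    if T is None:
        T = float(grid_times[int(np.argmax(v))])
    cand = (v >= np.roll(v, 1)) & (v >= np.roll(v, -1))
    peaks: list[tuple[int, float]] = []
    for run in _circular_runs(cand):
        k = run[int(np.argmax(v[run]))]
        # plateau interior points sharing both neighbours are swept into one run;
        # require the run to be a genuine max: neighbours outside run strictly lower
        left = (run[0] - 1) % n
        right = (run[-1] + 1) % n
        if len(run) == n or (v[k] > v[left] and v[k] > v[right]):
            peaks.append((int(k), float(v[k])))
    if not peaks:
        return []
    peaks.sort(key=lambda p: (-p[1], p[0]))
    C = reference_curve(grid_times, T, cfg)
    out: list[Peak] = []
    heights = np.array([h for _, h in peaks])
    for rank, (k, h) in enumerate(peaks):
        if rank == 0:
            prom = h - float(v.min())
        else:
            # saddle: highest of the two circular path minima toward any higher peak
            higher = [kk for (kk, hh) in peaks[:rank]]
            prom = h - _saddle_height(v, k, higher)
        if h > C[k] and prom >= min_prominence:
            out.append(Peak(time=float(grid_times[k]), height=h, prominence=float(prom)))
    return out


def _saddle_height(v: np.ndarray, k: int, higher: list[int]) -> float:
    n = len(v)
    best = -np.inf
    for target in higher:
        fwd = np.arange(k, k + (target - k) % n + 1) % n
        bwd = np.arange(target, target + (k - target) % n + 1) % n
        saddle = max(float(v[fwd].min()), float(v[bwd].min()))
        best = max(best, saddle)
    return best if np.isfinite(best) else float(v.min())


def adjust_time_by_second_peak(
    profile: LikelihoodProfile, window: tuple[float, float]
) -> float:
    """Re-time a sample by its second peak when T falls inside a window.

    Used for cohorts where the global peak is known to mistime a subset of
    samples (e.g. all samples timed before 7 am): if T lies in
    ``window = (start, end)`` (hours, circular) and a second peak exists,
    the second peak's time is returned and recorded on the profile;
    otherwise T is unchanged.
    """
    start, end = window
    t = profile.t
    in_window = (start <= t < end) if start <= end else (t >= start or t < end)
    if in_window and profile.second_peak_time is not None:
        profile.t_adjusted = float(profile.second_peak_time)
        profile.flags.add("second_peak_adjusted")
    else:
        profile.t_adjusted = t
        if in_window:
            profile.flags.add("no_second_peak")
    return profile.t_adjusted


def build_profile(
    per_timepoint_ll: np.ndarray,
    grid_times: np.ndarray,
    l_thresh: float,
    cfg: ThetaConfig,
    model=None,
    sample_id=None,
) -> LikelihoodProfile:
    """Assemble the full likelihood profile of one sample."""
    log_l = combine_loglik(per_timepoint_ll, l_thresh)
    T, ml, flags = estimate_phase(log_l, grid_times)
    log_ml = float(np.max(log_l))
    lrf = np.exp(log_l - log_ml)
    th = theta(lrf, T, cfg, grid_times)
    peaks = find_peaks(lrf, grid_times, cfg, T=T)
    flat = float(np.mean(log_l <= l_thresh + _FLAT_TOL))
    lam = None
    if model is not None:
        idx = int(np.argmax(log_l))
        lam = float(log_ml - model.max_log_density(idx))
    return LikelihoodProfile(
        grid_times=np.asarray(grid_times),
        log_l=log_l,
        t=T,
        ml=ml,
        log_ml=log_ml,
        lrf=lrf,
        theta=th,
        peaks=peaks,
        flat_fraction=flat,
        lambda_stat=lam,
        flags=flags,
        sample_id=sample_id,
        l_thresh=l_thresh,
        theta_config=cfg,
    )


def _flat_above_reference(profile: LikelihoodProfile) -> float:
    """Fraction of the grid where a floored (flat) region rises above C(t|T)."""
    cfg = profile.theta_config or ThetaConfig()
    C = reference_curve(profile.grid_times, profile.t, cfg)
    flat = profile.log_l <= (profile.l_thresh if profile.l_thresh is not None else -np.inf) + _FLAT_TOL
    return float(np.mean(flat & (profile.lrf > C)))


def choose_lthresh(
    training_profiles_at_candidates: dict,
    test_log_mls: dict,
    candidates,
    alpha: float = 0.05,
    beta: float = 0.90,
) -> tuple[float, pd.DataFrame]:
    """Recommend the largest l_thresh meeting the flatness and coverage rules.

    For each candidate threshold the caller supplies the training/control
    profiles recomputed at that threshold and the test samples' log-ML
    values.  The recommendation is the largest candidate such that

    (i)  at most ``alpha`` of training profiles have flat regions that
         intersect C(t|T) (i.e. floored stretches contributing to theta), and
    (ii) at least ``beta`` of test samples have log ML above the candidate.

    If no candidate satisfies both, the candidate maximising (ii) subject to
    (i) is returned (or maximising (ii) outright if none satisfies (i)),
    together with the full trade-off table.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("empty candidate list for l_thresh")
    rows = []
    for c in candidates:
        profs = training_profiles_at_candidates[c]
        frac_flat = float(np.mean([_flat_above_reference(p) > 0 for p in profs]))
        mls = np.asarray(test_log_mls[c], dtype=float)
        frac_above = float(np.mean(mls > c))
        rows.append((c, frac_flat, frac_above, frac_flat <= alpha, frac_above >= beta))
    table = pd.DataFrame(
        rows,
        columns=["l_thresh", "train_flat_fraction", "test_ml_above", "ok_flat", "ok_ml"],
    )
    both = table[table["ok_flat"] & table["ok_ml"]]
    if len(both):
        return float(both["l_thresh"].max()), table
    feasible = table[table["ok_flat"]]
    pool = feasible if len(feasible) else table
    best = pool.sort_values(["test_ml_above", "l_thresh"], ascending=[False, False]).iloc[0]
    return float(best["l_thresh"]), table


def classify_dysfunction(
    profile: LikelihoodProfile,
    training_summary: dict,
    q_low: float = 0.01,
    q_high: float = 0.99,
    error_threshold: float = 4.0,
    true_time: float | None = None,
) -> set:
    """Assign lowML / highTvar / relTwrong dysfunction flags to a profile.

    * ``lowML``: ML below the ``q_low`` quantile of the training MLs — the
      sample lies far from the training clock's manifold.
    * ``highTvar``: theta above the ``q_high`` training quantile with a
      non-flat contribution (secondary peaks or a broad main peak), i.e.
      genuinely imprecise or multimodal timing.
    * ``relTwrong``: a confidently wrong time — circular timing error beyond
      ``error_threshold`` hours while neither of the above holds.  Needs the
      true collection time; skipped (with a notice flag) when absent.
    """
    from .cohort import signed_circular_error

    flags = set()
    ml_cut = float(np.quantile(training_summary["ml"], q_low))
    th_cut = float(np.quantile(training_summary["theta"], q_high))
    if profile.ml < ml_cut:
        flags.add("lowML")
    nonflat = profile.theta - _flat_above_reference(profile)
    if profile.theta > th_cut and (len(profile.peaks) > 1 or nonflat > 0):
        flags.add("highTvar")
    if true_time is None:
        if error_threshold is not None:
            flags.add("relTwrong_skipped_no_true_time")
    else:
        err = abs(signed_circular_error(profile.t, true_time))
        if err > error_threshold and "lowML" not in flags and "highTvar" not in flags:
            flags.add("relTwrong")
    profile.flags |= flags
    return flags
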