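"""Cohort-level procedures built on single-sample phase estimates.

Leave-one-out cross-validation of a trained clock model, circular timing
errors and per-group timing displacements (the molecular chronotype),
cosinor rhythmometry, phase-displacement-plot (PDP) regression, theta-based
stratification with resampled differential-expression probabilities, and a
timestamp-free precision estimator for large unstamped cohorts.

All timing arithmetic is circular on a 24 h day: signed errors live in
(-12, 12] and group displacements are circular means via the resultant
vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionSet, GenePanel, extract_revs
from .normalize import intergene_normalise, self_timecourse_normalise

__all__ = [
    "signed_circular_error",
    "circular_mean_hours",
    "circular_sd_hours",
    "cosinor_fit",
    "leave_one_out",
    "timing_displacement",
    "pdp_regression",
    "theta_stratify_and_resample",
    "precision_without_timestamps",
    "StratificationResult",
]

_TWO_PI_OVER_24 = 2.0 * np.pi / 24.0


# ---------------------------------------------------------------------------
# circular arithmetic


def signed_circular_error(T, T_a):
    """Circular difference T - T_a mapped into (-12, 12] hours.

    +12 is preferred over -12 at the antipodal boundary.
    """
    e = (np.asarray(T, dtype=float) - np.asarray(T_a, dtype=float)) % 24.0
    out = np.where(e > 12.0, e - 24.0, e)
    return float(out) if np.isscalar(T) and np.isscalar(T_a) else out


def circular_mean_hours(hours, min_resultant: float = 0.0):
    """Circular mean of hour values via the resultant vector, in (-12, 12].

    Returns NaN when the mean resultant length falls below
    ``min_resultant`` (direction effectively undefined).
    """
    ang = np.asarray(hours, dtype=float) * _TWO_PI_OVER_24
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    if np.hypot(c, s) < min_resultant:
        return float("nan")
    h = np.arctan2(s, c) / _TWO_PI_OVER_24
    h = ((h + 12.0) % 24.0) - 12.0
    return 12.0 if h == -12.0 else float(h)


def circular_sd_hours(hours) -> float:
    """Circular standard deviation of hour values, in hours.

    Uses the resultant-length definition sqrt(-2 ln R), converted from
    radians to hours; 0 for perfectly aligned angles.
    """
    ang = np.asarray(hours, dtype=float) * _TWO_PI_OVER_24
    R = np.hypot(np.cos(ang).mean(), np.sin(ang).mean())
    R = min(R, 1.0)
    sd_rad = np.sqrt(max(0.0, -2.0 * np.log(R))) if R > 0 else np.inf
    return float(sd_rad / _TWO_PI_OVER_24)


# ---------------------------------------------------------------------------
# cosinor rhythmometry


def cosinor_fit(times, values, period: float = 24.0):
    """Least-squares cosinor fit y = M + A cos(2 pi (t - phi)/period).

    Fitted by the linearised cos/sin design.  Returns
    ``(mesor, amplitude, acrophase, p_rhythm)`` with amplitude >= 0,
    acrophase in [0, period), and p from the F-test of the two harmonic
    coefficients against the intercept-only model.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(t)
    if n < 4:
        raise ValueError("cosinor fit needs at least 4 samples")
    if len(np.unique(t % period)) < 3:
        raise ValueError("cosinor design is collinear: need >= 3 distinct times")
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("cosinor design is collinear")
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    mesor, a, b = beta
    amplitude = float(np.hypot(a, b))
    acrophase = float((np.arctan2(b, a) / w) % period)
    df2 = n - 3
    if rss1 <= 1e-300 * max(rss0, 1.0):
        p = 0.0 if rss0 > 0 else 1.0
    elif rss0 <= rss1:
        p = 1.0
    else:
        F = ((rss0 - rss1) / 2.0) / (rss1 / df2)
        p = float(stats.f.sf(F, 2, df2))
    return float(mesor), amplitude, acrophase, p


# ---------------------------------------------------------------------------
# cross-validation


def leave_one_out(
    es: ExpressionSet,
    panel: GenePanel | list | None = None,
    unit: str = "sample",
    model_params: dict | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validated timing errors for a training set.

    ``unit="sample"`` removes one sample (column) at a time and rebuilds the
    model without it; ``unit="instance"`` removes an entire tissue or
    individual's timecourse and scores all its samples against the model
    trained on the rest.  Normalisation is computed once on the full
    timecourses before the split (each instance standardised by its own
    series), matching how timecourse normalisation precedes model
    cross-validation; only the probability model itself is re-estimated per
    fold.

    Returns a table with one row per scored sample: estimated phase T,
    collection time, signed circular error, absolute error, ML and theta.
    """
    from .model import ClockModel

    params = dict(model_params or {})
    params.setdefault("compute_training_summary", False)
    mode = params.pop("normalisation", "timecourse")
    if panel is None:
        panel = GenePanel(list(es.gene_ids))
    elif not isinstance(panel, GenePanel):
        panel = GenePanel(list(panel))
    params["panel"] = panel
    params["normalisation"] = "none"
    revs = extract_revs(es, panel)
    g_norm = _self_normalise_per_instance(revs, es.instances, mode)
    es_norm = ExpressionSet(
        values=pd.DataFrame(g_norm, index=list(panel), columns=es.sample_ids),
        sample_times=es.sample_times,
        instances=es.instances,
    )
    rows = []
    if unit == "sample":
        counts = es.samples_per_timepoint()
        if len(set(counts)) == 1:
            warnings.warn(
                "leave-one-sample-out breaks the equal samples-per-timepoint "
                "layout; falling back to unequal-count tolerant fitting"
            )
        params["allow_unequal_ns"] = True
        for k in range(es.n_samples):
            keep = np.ones(es.n_samples, dtype=bool)
            keep[k] = False
            model = ClockModel(**params).fit(es_norm.subset_samples(keep))
            prof = model.score_samples(g_norm[:, [k]], already_normalised=True)[0]
            rows.append(_loo_row(es, k, prof))
    elif unit == "instance":
        for inst in pd.unique(es.instances):
            held = es.instances == inst
            model = ClockModel(**params).fit(es_norm.subset_samples(~held))
            profs = model.score_samples(g_norm[:, held], already_normalised=True)
            for prof, k in zip(profs, np.flatnonzero(held)):
                rows.append(_loo_row(es, k, prof))
    else:
        raise ValueError(f"unknown leave-one-out unit {unit!r}")
    return pd.DataFrame(rows)


def _self_normalise_per_instance(revs: np.ndarray, instances, mode: str) -> np.ndarray:
    """Normalise each instance's block by its own full timecourse statistics."""
    if mode == "none":
        return np.asarray(revs, dtype=float)
    if mode == "intergene":
        return intergene_normalise(revs)
    return self_timecourse_normalise(revs, instances, then_intergene=(mode == "both"))




def _loo_row(es: ExpressionSet, k: int, prof) -> dict:
    err = signed_circular_error(prof.t, es.sample_times[k])
    return {
        "sample_id": es.sample_ids[k],
        "instance": es.instances[k],
        "time": es.sample_times[k],
        "T": prof.t,
        "ml": prof.ml,
        "log_ml": prof.log_ml,
        "theta": prof.theta,
        "signed_error": err,
        "abs_error": abs(err),
    }


# ---------------------------------------------------------------------------
# timing displacement / chronotype


def timing_displacement(
    errors: pd.DataFrame, group_col: str = "instance", min_resultant: float = 0.1
):
    """Per-group circular-mean timing displacement and corrected errors.

    Returns ``(displacements, corrected, pairwise)``:

    * ``displacements`` — one row per group: circular-mean displacement in
      (-12, 12], sample count, circular SD of the errors, and a rank-sum
      p-value of that group's signed errors against all other groups' (NaN
      for singleton groups).
    * ``corrected`` — the input table with corrected signed/absolute errors,
      where the correction shifts the collection time by the group's
      displacement.
    * ``pairwise`` — two-sided Wilcoxon rank-sum p-values between all group
      pairs.
    """
    disp_rows = []
    corrected = errors.copy()
    corrected["corrected_signed_error"] = np.nan
    groups = list(pd.unique(errors[group_col]))
    for g in groups:
        m = errors[group_col] == g
        e = errors.loc[m, "signed_error"].to_numpy()
        disp = circular_mean_hours(e, min_resultant=min_resultant)
        sd = circular_sd_hours(e)
        if len(e) >= 2 and len(groups) > 1:
            other = errors.loc[~m, "signed_error"].to_numpy()
            p = float(stats.mannwhitneyu(e, other, alternative="two-sided").pvalue)
        else:
            p = np.nan
        disp_rows.append(
            {"group": g, "displacement": disp, "n": int(m.sum()), "dispersion": sd, "p_vs_rest": p}
        )
        if np.isfinite(disp):
            ce = signed_circular_error(
                errors.loc[m, "T"].to_numpy(), errors.loc[m, "time"].to_numpy() + disp
            )
            corrected.loc[m, "corrected_signed_error"] = ce
    corrected["corrected_abs_error"] = corrected["corrected_signed_error"].abs()
    pair_rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            ea = errors.loc[errors[group_col] == a, "signed_error"]
            eb = errors.loc[errors[group_col] == b, "signed_error"]
            if len(ea) >= 2 and len(eb) >= 2:
                p = float(stats.mannwhitneyu(ea, eb, alternative="two-sided").pvalue)
            else:
                p = np.nan
            pair_rows.append({"group_a": a, "group_b": b, "p": p})
    return (
        pd.DataFrame(disp_rows),
        corrected,
        pd.DataFrame(pair_rows, columns=["group_a", "group_b", "p"]),
    )


# ---------------------------------------------------------------------------
# PDP regression


def pdp_regression(
    phases: pd.DataFrame, displacements: pd.Series, unwrap_flag_spread: float = 6.0
) -> pd.DataFrame:
    """Regress per-gene acrophases on group timing displacements.

    ``phases`` is genes x groups (hours); ``displacements`` is indexed by
    group.  Phases are unwrapped by shifting each by a multiple of 24 to the
    representative nearest its gene's circular mean, then fitted by ordinary
    least squares.  A slope of 1 with high r-squared means the group
    differences are a coherent phase shift of the whole panel.

    Returns a per-gene table with slope, intercept, r2, F-test p-value of a
    non-zero slope, and an ``unwrap_ambiguous`` flag when the unwrapped
    phases still span more than ``unwrap_flag_spread`` hours.
    """
    groups = [g for g in phases.columns if g in displacements.index]
    if len(groups) < 3:
        raise ValueError("PDP regression needs at least 3 groups")
    x = displacements.loc[groups].to_numpy(dtype=float)
    rows = []
    for gene in phases.index:
        raw = phases.loc[gene, groups].to_numpy(dtype=float)
        centre = circular_mean_hours(raw)
        y = centre + signed_circular_error(raw, centre)
        flagged = bool(np.ptp(y) > unwrap_flag_spread)
        n = len(x)
        sx = x - x.mean()
        sy = y - y.mean()
        sxx = float(sx @ sx)
        if sxx == 0:
            raise ValueError("displacements are constant; slope undefined")
        slope = float(sx @ sy) / sxx
        intercept = float(y.mean() - slope * x.mean())
        syy = float(sy @ sy)
        r2 = 0.0 if syy == 0 else float((sx @ sy) ** 2 / (sxx * syy))
        if r2 >= 1.0 - 1e-15:
            p = 0.0
        else:
            F = (n - 2) * r2 / (1.0 - r2)
            p = float(stats.f.sf(F, 1, n - 2))
        rows.append(
            {
                "gene": gene,
                "slope": slope,
                "intercept": intercept,
                "r2": r2,
                "p_slope": p,
                "unwrap_ambiguous": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# theta stratification with resampled DE probabilities


@dataclass
class StratificationResult:
    """Output of the theta-stratified differential-expression resampling."""

    bcg_ids: list
    gcg_ids: list
    deg_list: list
    m_values: np.ndarray
    p_rand: np.ndarray
    p_rand_se: np.ndarray
    p_theta: np.ndarray
    p_theta_se: np.ndarray
    iters: int


def default_de_test(x_a: np.ndarray, x_b: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Per-gene two-sample rank-sum test with Benjamini-Hochberg at alpha.

    ``x_a``/``x_b`` are genes x samples blocks; returns indices of genes
    differentially expressed after BH adjustment.  Deliberately simple — not
    a reproduction of any moderated-statistics package.
    """
    pvals = np.ones(x_a.shape[0])
    for g in range(x_a.shape[0]):
        a, b = x_a[g], x_b[g]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            continue
        pvals[g] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return np.flatnonzero(reject)


def theta_stratify_and_resample(
    theta_of_lthresh,
    expr: np.ndarray,
    n_range: tuple[int, int],
    lthresh_range: tuple[float, float],
    de_test=None,
    iters: int = 200,
    seed: int | np.random.Generator = 0,
    sample_ids=None,
    m_max: int | None = None,
) -> StratificationResult:
    """Estimate p_rand(m) and p_theta(m) for theta-stratified DE discovery.

    ``theta_of_lthresh`` maps an l_thresh value to the per-sample theta
    array (so the ranking can be recomputed for randomly drawn thresholds);
    ``expr`` is a genes x samples matrix over which differential expression
    is tested.  Per iteration:

    * p_rand — a random group of size n (n drawn from ``n_range``) is
      compared against the rest, and the number of DEGs recorded;
    * p_theta — l_thresh is drawn uniformly from ``lthresh_range``, n from
      ``n_range``, the bad clock group (BCG) is the n samples with highest
      theta at that threshold, and DEGs are counted for BCG vs the rest.

    ``p(m)`` is the fraction of iterations yielding >= m DEGs; both curves
    come with binomial Monte-Carlo standard errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if de_test is None:
        de_test = default_de_test
    if iters < 1:
        raise ValueError("iters must be positive")
    expr = np.asarray(expr, dtype=float)
    n_samples = expr.shape[1]
    n_lo, n_hi = int(n_range[0]), int(n_range[1])
    if n_hi > n_samples // 2:
        raise ValueError("group size n must not exceed half the cohort")
    lt_lo, lt_hi = min(lthresh_range), max(lthresh_range)

    counts_rand = np.empty(iters, dtype=int)
    counts_theta = np.empty(iters, dtype=int)
    theta_cache: dict[float, np.ndarray] = {}
    for it in range(iters):
        n = int(rng.integers(n_lo, n_hi + 1))
        grp = rng.choice(n_samples, size=n, replace=False)
        mask = np.zeros(n_samples, dtype=bool)
        mask[grp] = True
        counts_rand[it] = len(de_test(expr[:, mask], expr[:, ~mask]))

        lt = float(rng.uniform(lt_lo, lt_hi))
        key = round(lt, 6)
        if key not in theta_cache:
            theta_cache[key] = np.asarray(theta_of_lthresh(lt), dtype=float)
        th = theta_cache[key]
        n2 = int(rng.integers(n_lo, n_hi + 1))
        bcg = np.argsort(-th, kind="stable")[:n2]
        mask = np.zeros(n_samples, dtype=bool)
        mask[bcg] = True
        counts_theta[it] = len(de_test(expr[:, mask], expr[:, ~mask]))

    top = int(max(counts_rand.max(), counts_theta.max(), 1)) if m_max is None else m_max
    m_values = np.arange(1, top + 1)
    p_rand = np.array([(counts_rand >= m).mean() for m in m_values])
    p_theta = np.array([(counts_theta >= m).mean() for m in m_values])
    se = lambda p: np.sqrt(p * (1.0 - p) / iters)  # noqa: E731

    th_mid = np.asarray(theta_of_lthresh(0.5 * (lt_lo + lt_hi)), dtype=float)
    order = np.argsort(-th_mid, kind="stable")
    bcg_idx = order[:n_hi]
    gcg_idx = order[n_hi:]
    ids = list(range(n_samples)) if sample_ids is None else list(sample_ids)
    mask = np.zeros(n_samples, dtype=bool)
    mask[bcg_idx] = True
    deg = de_test(expr[:, mask], expr[:, ~mask])
    return StratificationResult(
        bcg_ids=[ids[k] for k in bcg_idx],
        gcg_ids=[ids[k] for k in gcg_idx],
        deg_list=list(deg),
        m_values=m_values,
        p_rand=p_rand,
        p_rand_se=se(p_rand),
        p_theta=p_theta,
        p_theta_se=se(p_theta),
        iters=iters,
    )


# ---------------------------------------------------------------------------
# timestamp-free precision


def precision_without_timestamps(
    revs: np.ndarray,
    T_values: np.ndarray,
    window: tuple[float, float],
    grid_points: int = 481,
    bandwidth: float | None = None,
    max_nonmonotone: float = 0.2,
):
    """Upper bound for the SD of P(T | g) without any time stamps.

    Within ``window`` (hours), the expression vectors are projected onto
    their first principal component, giving one scalar per sample.  A
    Gaussian-kernel local-linear smooth of that scalar against the
    estimated time T gives a mean curve (the degree-1 refinement of a
    Nadaraya-Watson smooth; it is free of the boundary bias that would
    otherwise distort the window edges); inverting it (nearest preimage on
    the window grid) assigns each sample a curve-predicted time, and the
    sample's horizontal deviation from the curve is T minus that time.  The
    sample SD of the deviations is the reported precision bound.

    Raises when fewer than 30 samples fall in the window, or when the
    smoothed curve is non-monotone over more than ``max_nonmonotone`` of it.
    """
    T_values = np.asarray(T_values, dtype=float)
    lo, hi = window
    if lo <= hi:
        m = (T_values >= lo) & (T_values <= hi)
    else:
        m = (T_values >= lo) | (T_values <= hi)
    if m.sum() < 30:
        raise ValueError(f"need at least 30 samples in the window, got {int(m.sum())}")
    X = np.asarray(revs, dtype=float)[:, m]
    T = T_values[m]
    if lo > hi:  # unwrap a seam-crossing window onto a linear axis
        T = np.where(T <= hi, T + 24.0, T)
        hi = hi + 24.0
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    g_tilde = U[:, 0] @ Xc

    n = len(T)
    if bandwidth is None:
        sd_t = T.std(ddof=1)
        bandwidth = 1.06 * sd_t * n ** (-0.2) if sd_t > 0 else 0.5
    grid = np.linspace(lo, hi, grid_points)
    dx = T[None, :] - grid[:, None]
    w = np.exp(-0.5 * (dx / bandwidth) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * dx).sum(axis=1)
    s2 = (w * dx * dx).sum(axis=1)
    wy = w @ g_tilde
    wxy = (w * dx) @ g_tilde
    denom = s0 * s2 - s1 * s1
    nw = wy / s0
    with np.errstate(invalid="ignore", divide="ignore"):
        ll = (s2 * wy - s1 * wxy) / denom
    # fall back to the degree-0 estimate where the local design degenerates
    mean_curve = np.where(denom > 1e-12 * np.maximum(s0 * s2, 1e-300), ll, nw)

    dg = np.diff(mean_curve)
    dominant = np.sign(np.median(dg[dg != 0])) if np.any(dg != 0) else 0.0
    frac_bad = float(np.mean(np.sign(dg) == -dominant)) if dominant != 0 else 1.0
    if frac_bad > max_nonmonotone:
        raise ValueError(
            "smoothed mean curve is non-monotone over "
            f"{frac_bad:.0%} of the window; use a narrower window"
        )
    inv_idx = np.argmin(np.abs(mean_curve[:, None] - g_tilde[None, :]), axis=0)
    deviations = T - grid[inv_idx]
    sd_estimate = float(np.std(deviations, ddof=1))
    return sd_estimate, deviations
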