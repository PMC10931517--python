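"""Synthetic circadian cohorts with the statistical structure the model assumes.

The generator draws genes with cosinor-shaped 24 h profiles (gene-specific
mesor, amplitude, acrophase, optional second harmonic), instance-specific
chronotype offsets, and correlated residual noise with a low-rank factor
plus diagonal structure — the rapidly decaying residual eigenvalues that
justify a 3-dimensional local projection.  Perturbation archetypes emulate
the canonical dysfunction signatures: a coherent phase shift, amplitude
collapse (lowML), a single-gene knockout, a per-gene phase scramble
(highTvar) and a frozen clock stuck at one phase (relTwrong).

A chronotype offset delta is an *advance* of the instance's internal clock:
its transcriptome at external time t is the reference clock's state at
t + delta, so estimated phases run ahead of collection times by delta and
the instance's fitted acrophases shift by -delta.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionSet, write_expression_set

__all__ = ["ClockSimConfig", "simulate_training", "perturb", "worked_example_bundle"]

PERTURB_KINDS = (
    "phase_shift",
    "amplitude_collapse",
    "gene_knockout",
    "frozen_clock",
    "phase_scramble",
)


@dataclass
class ClockSimConfig:
    """Generative parameters of a synthetic clock cohort.

    Defaults define the standard study conditions used throughout the test
    suite: 12 genes, 6 timepoints 4 h apart, 12 instances, amplitudes
    0.6-1.8 on a log-like scale, acrophases spread around the day, a 20%
    second harmonic, and moderate correlated noise (two shared factors at
    SD 0.10 plus diagonal SD 0.15).
    """

    n_genes: int = 12
    timepoints: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_instances: int = 12
    amplitudes: np.ndarray | None = None  # default linspace(0.6, 1.8)
    acrophases: np.ndarray | None = None  # default evenly spaced over 24 h
    mesors: np.ndarray | None = None  # default 7.0
    second_harmonic: float = 0.2  # fraction of the fundamental amplitude
    chronotype_offsets: np.ndarray | None = None  # hours of clock advance per instance
    n_factors: int = 2
    factor_sd: float = 0.10
    noise_sd: float = 0.15
    gene_phase_jitter_sd: float = 0.0  # per-(gene, instance) incoherent offsets
    phase_advance: float = 0.0  # global clock advance (hours)
    amplitude_scale: float = 1.0
    knockout: tuple | None = None  # (gene_index, level)
    frozen_at: float | None = None  # hours; overrides nominal sampling time
    seed: int = 0
    instance_prefix: str = "inst"

    def resolved(self):
        """Per-gene/per-instance parameter arrays with defaults filled in."""
        G = self.n_genes
        amp = (
            np.linspace(0.6, 1.8, G)
            if self.amplitudes is None
            else np.asarray(self.amplitudes, dtype=float)
        )
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")
        phi = (
            (np.arange(G) * 24.0 / G) % 24.0
            if self.acrophases is None
            else np.asarray(self.acrophases, dtype=float) % 24.0
        )
        mes = (
            np.full(G, 7.0)
            if self.mesors is None
            else np.asarray(self.mesors, dtype=float)
        )
        delta = (
            np.zeros(self.n_instances)
            if self.chronotype_offsets is None
            else np.asarray(self.chronotype_offsets, dtype=float)
        )
        if np.any((delta <= -12.0) | (delta > 12.0)):
            raise ValueError("chronotype offsets must lie in (-12, 12]")
        for name, arr, size in (
            ("amplitudes", amp, G),
            ("acrophases", phi, G),
            ("mesors", mes, G),
            ("chronotype_offsets", delta, self.n_instances),
        ):
            if len(arr) != size:
                raise ValueError(f"{name} must have length {size}")
        if self.n_factors < 0 or self.factor_sd < 0 or self.noise_sd < 0:
            raise ValueError("invalid residual covariance specification")
        return amp, phi, mes, delta


def _mean_expression(cfg: ClockSimConfig, internal_time, amp, phi, mes, jitter=None):
    """Deterministic expression (G,) of the reference clock at internal time."""
    w = 2.0 * np.pi / 24.0
    t = np.asarray(internal_time, dtype=float)
    ph = phi if jitter is None else phi + jitter
    arg = w * (t - ph)
    x = mes + cfg.amplitude_scale * amp * (
        np.cos(arg) + cfg.second_harmonic * np.cos(2.0 * arg)
    )
    return x


def simulate_training(cfg: ClockSimConfig) -> ExpressionSet:
    """Generate a full training cohort: one sample per (timepoint, instance).

    Reproducible from the seed; the returned ExpressionSet carries the
    config on its ``sim_config`` attribute so perturbations can regenerate
    from the same noise stream.
    """
    amp, phi, mes, delta = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    G, nt, ns = cfg.n_genes, len(cfg.timepoints), cfg.n_instances
    loadings = rng.normal(0.0, cfg.factor_sd, size=(G, cfg.n_factors))
    jitter = None
    if cfg.gene_phase_jitter_sd > 0:
        jitter = rng.normal(0.0, cfg.gene_phase_jitter_sd, size=(G, ns))

    values = np.empty((G, nt * ns))
    times = np.empty(nt * ns)
    instances = np.empty(nt * ns, dtype=object)
    ids = []
    col = 0
    for i, t in enumerate(cfg.timepoints):
        for j in range(ns):
            internal = (
                cfg.frozen_at
                if cfg.frozen_at is not None
                else t + delta[j] + cfg.phase_advance
            )
            jit = None if jitter is None else jitter[:, j]
            x = _mean_expression(cfg, internal, amp, phi, mes, jit)
            f = rng.normal(size=cfg.n_factors)
            e = rng.normal(0.0, cfg.noise_sd, size=G)
            x = x + loadings @ f + e
            if cfg.knockout is not None:
                k, level = cfg.knockout
                x[int(k)] = level + f @ loadings[int(k)] + e[int(k)]
            values[:, col] = x
            times[col] = t
            instances[col] = f"{cfg.instance_prefix}{j:02d}"
            ids.append(f"s_t{i}_{cfg.instance_prefix}{j:02d}")
            col += 1
    df = pd.DataFrame(values, index=[f"gene{k:02d}" for k in range(G)], columns=ids)
    es = ExpressionSet(values=df, sample_times=times, instances=instances)
    es.sim_config = cfg  # type: ignore[attr-defined]
    return es


def perturb(es: ExpressionSet, kind: str, params: dict | None = None) -> ExpressionSet:
    """Regenerate a cohort under one of the dysfunction archetypes.

    * ``phase_shift`` — advance every instance's clock by ``delta`` hours
      (coherent chronotype-like shift; timing displacement approx +delta).
    * ``amplitude_collapse`` — multiply all amplitudes by ``rho`` < 1
      (flattened rhythms; lowML signature).
    * ``gene_knockout`` — set ``gene`` (index or id) to arrhythmic noise at
      ``level`` (defaults to its mesor).
    * ``frozen_clock`` — every sample shows the clock state at ``t_frozen``
      hours plus noise, regardless of its nominal sampling time
      (relTwrong signature: confident, constant, wrong time).
    * ``phase_scramble`` — incoherent per-(gene, instance) phase offsets
      with SD ``sd`` hours (broad/multimodal likelihoods; highTvar).

    The perturbed cohort is regenerated from the source config with the
    same noise stream, so ``perturb(es, "phase_shift", {"delta": 0})``
    reproduces the input values exactly.
    """
    cfg = getattr(es, "sim_config", None)
    if cfg is None:
        raise ValueError("perturb needs an ExpressionSet produced by simulate_training")
    params = dict(params or {})
    if kind == "phase_shift":
        new = dataclasses.replace(cfg, phase_advance=cfg.phase_advance + float(params["delta"]))
    elif kind == "amplitude_collapse":
        rho = float(params["rho"])
        if not 0 <= rho < 1:
            raise ValueError("amplitude_collapse needs 0 <= rho < 1")
        new = dataclasses.replace(cfg, amplitude_scale=cfg.amplitude_scale * rho)
    elif kind == "gene_knockout":
        gene = params["gene"]
        amp, phi, mes, _ = cfg.resolved()
        if isinstance(gene, str):
            gene = int(gene.replace("gene", ""))
        level = float(params.get("level", mes[int(gene)]))
        new = dataclasses.replace(cfg, knockout=(int(gene), level))
    elif kind == "frozen_clock":
        new = dataclasses.replace(cfg, frozen_at=float(params["t_frozen"]))
    elif kind == "phase_scramble":
        new = dataclasses.replace(
            cfg,
            gene_phase_jitter_sd=float(params.get("sd", 4.0)),
            seed=int(params.get("seed", cfg.seed)),
        )
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}; one of {PERTURB_KINDS}")
    if "seed" in params:
        new = dataclasses.replace(new, seed=int(params["seed"]))
    return simulate_training(new)


# ---------------------------------------------------------------------------

BUNDLE_SEED = 1234


def worked_example_bundle(out_dir, seed: int = BUNDLE_SEED) -> dict:
    """Write the pinned small example dataset used by the docs walkthrough.

    A fixed-seed cohort (12 genes, 6 timepoints, 12 instances, moderate
    noise, one instance with a +2 h chronotype) is written as TSV matrix +
    metadata together with the generating config and SHA-256 checksums.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    offsets = np.zeros(12)
    offsets[3] = 2.0  # one advanced-chronotype individual
    cfg = ClockSimConfig(chronotype_offsets=offsets, seed=seed)
    es = simulate_training(cfg)
    matrix = out / "expression.tsv"
    meta = out / "metadata.tsv"
    write_expression_set(es, matrix, meta)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["chronotype_offsets"] = offsets.tolist()
    (out / "config.json").write_text(json.dumps(cfg_dict, sort_keys=True, indent=2))
    manifest = {
        "seed": seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in (matrix, meta)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return manifest
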