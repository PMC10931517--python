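"""Timecourse, intergene and combined normalisation of expression vectors.

Two complementary normalisations are supported, matching how multi-tissue
training timecourses are put on a common footing before model fitting:

* *timecourse*: each (instance, gene) training series is standardised to
  mean 0, SD 1; the per-series offsets and scales form a persisted
  :class:`NormalisationRecipe` so that test samples from a known instance
  can be normalised with the *training* statistics (timecourse-matched).
* *intergene*: each sample's expression vector over the panel is
  standardised across its G entries, mapping the vector onto its shape and
  making it invariant to per-sample affine distortions.
* *both*: timecourse first, then intergene per sample.

Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import ExpressionSet, GenePanel, extract_revs

__all__ = [
    "NormalisationRecipe",
    "fit_timecourse",
    "apply_timecourse_matched",
    "intergene_normalise",
    "normalise",
    "self_timecourse_normalise",
    "ClockNormalizer",
]

MODES = ("intergene", "timecourse", "both")


@dataclass
class NormalisationRecipe:
    """Per-(instance, gene) offsets/scales learned from training timecourses."""

    mode: str
    offsets: pd.DataFrame  # genes x instances, mean of the training series
    scales: pd.DataFrame  # genes x instances, sample SD of the training series

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown normalisation mode {self.mode!r}")

    @property
    def instances(self) -> list[str]:
        return list(self.offsets.columns)

    def to_table(self) -> pd.DataFrame:
        """Flat (instance, gene, offset, scale) table for archiving."""
        rows = []
        for inst in self.offsets.columns:
            for gene in self.offsets.index:
                rows.append(
                    (inst, gene, self.offsets.at[gene, inst], self.scales.at[gene, inst])
                )
        return pd.DataFrame(rows, columns=["instance", "gene", "offset", "scale"])

    @classmethod
    def from_table(cls, table: pd.DataFrame, mode: str) -> "NormalisationRecipe":
        offsets = table.pivot(index="gene", columns="instance", values="offset")
        scales = table.pivot(index="gene", columns="instance", values="scale")
        return cls(mode=mode, offsets=offsets, scales=scales)


def fit_timecourse(es: ExpressionSet, panel: GenePanel) -> NormalisationRecipe:
    """Learn per-(instance, gene) standardisation from training timecourses.

    Raises on a constant series (SD 0), naming the instance and gene.
    """
    genes = list(panel)
    insts = list(pd.unique(es.instances))
    offsets = pd.DataFrame(index=genes, columns=insts, dtype=float)
    scales = pd.DataFrame(index=genes, columns=insts, dtype=float)
    revs = extract_revs(es, panel)
    for inst in insts:
        m = es.instances == inst
        if m.sum() < 2:
            raise ValueError(f"instance {inst!r} has fewer than 2 samples")
        block = revs[:, m]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"constant training series for instance {inst!r}, gene {genes[bad[0]]!r}"
            )
        offsets[inst] = mu
        scales[inst] = sd
    return NormalisationRecipe(mode="timecourse", offsets=offsets, scales=scales)


def apply_timecourse_matched(
    rev_matrix: np.ndarray, instance_labels, recipe: NormalisationRecipe
) -> np.ndarray:
    """Normalise test vectors with the *training* offsets/scales.

    ``rev_matrix`` is G x N in the recipe's gene order.  Every test instance
    label must exist in the recipe: timecourse-matched normalisation is only
    defined for tissues/individuals with a training time-series.
    """
    labels = np.asarray(instance_labels, dtype=object)
    unknown = [l for l in pd.unique(labels) if l not in recipe.offsets.columns]
    if unknown:
        raise KeyError(
            f"instances {unknown} have no training timecourse in the recipe; "
            "use intergene normalisation for unseen instances"
        )
    out = np.empty_like(rev_matrix, dtype=float)
    for inst in pd.unique(labels):
        m = labels == inst
        mu = recipe.offsets[inst].to_numpy()[:, None]
        sd = recipe.scales[inst].to_numpy()[:, None]
        out[:, m] = (rev_matrix[:, m] - mu) / sd
    return out


def intergene_normalise(rev: np.ndarray) -> np.ndarray:
    """Standardise a vector (or G x N matrix, per column) across its entries.

    Maps each expression vector onto its shape: output has mean 0, sample SD
    1 over the G genes, and is invariant to positive affine rescaling of the
    input.  A constant vector has no shape and raises.
    """
    rev = np.asarray(rev, dtype=float)
    x = rev[:, None] if rev.ndim == 1 else rev
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant expression vector: intergene shape undefined")
    out = (x - mu) / sd
    return out[:, 0] if rev.ndim == 1 else out


def normalise(
    mode: str,
    rev_matrix: np.ndarray,
    instance_labels=None,
    recipe: NormalisationRecipe | None = None,
) -> np.ndarray:
    """Dispatch on mode; ``both`` applies timecourse first, then intergene.

    Mode ``"none"`` is an explicit passthrough for already-normalised data.
    """
    if mode == "none":
        return np.asarray(rev_matrix, dtype=float)
    if mode not in MODES:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if mode == "intergene":
        return intergene_normalise(rev_matrix)
    if recipe is None:
        raise ValueError(f"mode {mode!r} requires a fitted NormalisationRecipe")
    tc = apply_timecourse_matched(rev_matrix, instance_labels, recipe)
    if mode == "timecourse":
        return tc
    return intergene_normalise(tc)


def self_timecourse_normalise(
    rev_matrix: np.ndarray, instance_labels, then_intergene: bool = False
) -> np.ndarray:
    """Standardise each instance's block by its own timecourse statistics.

    For test data that form their own timecourse (a full series per tissue
    or individual), each (instance, gene) series is standardised by its own
    mean and sample SD instead of stored training statistics — the right
    choice when training and test series come from different platforms or
    batches, and the within-training analogue of the recipe-based
    normalisation.  Requires at least 2 samples per instance and rhythmic
    (non-constant) series; optionally followed by per-sample intergene
    normalisation.
    """
    revs = np.asarray(rev_matrix, dtype=float)
    labels = np.asarray(instance_labels, dtype=object)
    out = np.empty_like(revs)
    for inst in pd.unique(labels):
        m = labels == inst
        if m.sum() < 2:
            raise ValueError(f"instance {inst!r} has fewer than 2 samples")
        block = revs[:, m]
        sd = block.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"constant series for instance {inst!r}")
        out[:, m] = (block - block.mean(axis=1, keepdims=True)) / sd
    return intergene_normalise(out) if then_intergene else out


class ClockNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer facade over the normalisation recipes.

    Parameters
    ----------
    mode : {"intergene", "timecourse", "both"}
        Normalisation to apply.  Intergene needs no fit; the other modes
        learn a per-(instance, gene) recipe from a training ExpressionSet.
    panel : GenePanel or list of str
        Gene panel fixing row order.
    """

    def __init__(self, mode: str = "timecourse", panel=None):
        self.mode = mode
        self.panel = panel

    def _panel(self) -> GenePanel:
        return self.panel if isinstance(self.panel, GenePanel) else GenePanel(list(self.panel))

    def fit(self, X: ExpressionSet, y=None) -> "ClockNormalizer":
        if self.mode not in MODES:
            raise ValueError(f"unknown normalisation mode {self.mode!r}")
        if self.mode == "intergene":
            self.recipe_ = None
        else:
            self.recipe_ = fit_timecourse(X, self._panel())
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, ExpressionSet):
            revs = extract_revs(X, self._panel())
            labels = X.instances
        else:
            revs, labels = X
        return normalise(self.mode, revs, labels, getattr(self, "recipe_", None))
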