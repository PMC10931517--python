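"""Expression data containers, delimited-text I/O and gene-panel handling.

The central container is :class:`ExpressionSet`: a genes x samples matrix of
log-scale expression values together with per-sample metadata (collection
time in hours, an *instance* label identifying the tissue or individual the
sample came from, and an integer index grouping samples onto the training
timepoints).  Both training and test data are carried in this form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSet",
    "GenePanel",
    "RhythmicityRanking",
    "read_expression_set",
    "write_expression_set",
    "extract_revs",
    "rank_rhythmicity",
]

#: tolerance (hours) when grouping sample times onto training timepoints
TIMEPOINT_TOL = 0.25


def _reduce_times(times) -> np.ndarray:
    """Reduce times into the half-open interval [0, 24)."""
    t = np.asarray(times, dtype=float) % 24.0
    # -1e-9 % 24 can round to 24.0 exactly
    t[t >= 24.0] = 0.0
    return t


def _assign_timepoints(times: np.ndarray, tol: float = TIMEPOINT_TOL) -> np.ndarray:
    """Group sample times into integer timepoint indices.

    Times within ``tol`` hours of each other (circularly) share an index;
    indices are ordered by the representative time of each group.
    """
    reps: list[float] = []
    idx = np.empty(len(times), dtype=int)
    for k, t in enumerate(times):
        for g, r in enumerate(reps):
            d = abs(((t - r + 12.0) % 24.0) - 12.0)
            if d <= tol:
                idx[k] = g
                break
        else:
            reps.append(float(t))
            idx[k] = len(reps) - 1
    order = np.argsort(reps)
    remap = np.empty(len(reps), dtype=int)
    remap[order] = np.arange(len(reps))
    return remap[idx]


@dataclass
class ExpressionSet:
    """Genes x samples expression matrix with per-sample time/instance labels.

    Parameters
    ----------
    values : DataFrame
        Expression matrix, genes in rows (index = gene ids), samples in
        columns (columns = sample ids).  Log-like scale assumed.
    sample_times : array of float
        Collection time of each sample in hours, reduced into [0, 24).
    instances : array of str
        Tissue or individual label per sample.
    timepoint_index : array of int, optional
        Index i mapping each sample onto the training times t_i.  Derived
        from ``sample_times`` when omitted.
    """

    values: pd.DataFrame
    sample_times: np.ndarray
    instances: np.ndarray
    timepoint_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_times = _reduce_times(self.sample_times)
        self.instances = np.asarray(self.instances, dtype=object)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in expression matrix: {dup!r}")
        n = self.values.shape[1]
        if len(self.sample_times) != n or len(self.instances) != n:
            raise ValueError(
                "metadata length does not match the number of sample columns"
            )
        if self.timepoint_index is None:
            self.timepoint_index = _assign_timepoints(self.sample_times)
        else:
            self.timepoint_index = np.asarray(self.timepoint_index, dtype=int)

    # -- basic geometry -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def timepoint_times(self) -> np.ndarray:
        """Representative time (circular mean-free: first occurrence) of each timepoint index."""
        nt = self.timepoint_index.max() + 1 if len(self.timepoint_index) else 0
        out = np.empty(nt)
        for i in range(nt):
            out[i] = self.sample_times[self.timepoint_index == i][0]
        return out

    def subset_samples(self, mask) -> "ExpressionSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return ExpressionSet(
            values=self.values.iloc[:, cols].copy(),
            sample_times=self.sample_times[cols],
            instances=self.instances[cols],
        )

    def samples_per_timepoint(self) -> np.ndarray:
        return np.bincount(self.timepoint_index)


@dataclass
class GenePanel:
    """Ordered panel of clock-representative genes (the model's gene set).

    The panel order fixes the ordering of every expression vector the model
    sees; with a projection dimension of 3 the panel must contain at least
    four genes.
    """

    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = [str(g).strip() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene panel contains duplicates")
        if len(self.genes) < 4:
            raise ValueError(
                "gene panel needs at least 4 genes (projection dimension 3 "
                "must be strictly smaller than the panel size)"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class RhythmicityRanking:
    """Per-gene cosinor summaries used to rank candidate panel genes."""

    table: pd.DataFrame  # index gene; columns mesor, amplitude, acrophase, p_rhythm, phase_dispersion, rankable

    def sorted(self) -> pd.DataFrame:
        """Ranking: strong rhythm first, then tight cross-instance phase."""
        ok = self.table[self.table["rankable"]]
        return ok.sort_values(["p_rhythm", "phase_dispersion"])


# ---------------------------------------------------------------------------
# I/O


def read_expression_set(matrix_path, metadata_path, sep: str | None = None) -> ExpressionSet:
    """Read an expression matrix and its sample metadata from delimited text.

    The matrix file has a header row of sample ids and a first column of gene
    ids.  The metadata file needs columns ``sample_id``, ``time`` and
    ``instance``; its rows are aligned to the matrix columns by sample id.
    Times are reduced modulo 24.
    """
    sep_m = sep if sep is not None else _sniff_sep(matrix_path)
    mat = pd.read_csv(matrix_path, sep=sep_m, index_col=0)
    mat.index = mat.index.astype(str).str.strip()
    try:
        mat = mat.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric expression value in {matrix_path}: {e}") from e

    sep_d = sep if sep is not None else _sniff_sep(metadata_path)
    meta = pd.read_csv(metadata_path, sep=sep_d)
    required = {"sample_id", "time", "instance"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {sorted(missing_cols)}")
    meta = meta.set_index(meta["sample_id"].astype(str))
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = meta.loc[list(mat.columns)]
    return ExpressionSet(
        values=mat,
        sample_times=meta["time"].to_numpy(dtype=float),
        instances=meta["instance"].to_numpy(),
    )


def write_expression_set(es: ExpressionSet, matrix_path, metadata_path, sep: str = "\t") -> None:
    """Write an :class:`ExpressionSet` back to matrix + metadata text files."""
    es.values.to_csv(matrix_path, sep=sep, index_label="gene_id")
    meta = pd.DataFrame(
        {
            "sample_id": es.sample_ids,
            "time": es.sample_times,
            "instance": es.instances,
        }
    )
    meta.to_csv(metadata_path, sep=sep, index=False)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


# ---------------------------------------------------------------------------
# Panel operations


def extract_revs(es: ExpressionSet, panel: GenePanel) -> np.ndarray:
    """Extract the G x N matrix of expression vectors in panel order.

    A pure row selection/permutation: columns keep their order, rows follow
    the panel.  Raises if any panel gene is absent, naming the gene.
    """
    missing = [g for g in panel if g not in es.values.index]
    if missing:
        raise KeyError(f"panel genes absent from expression set: {missing}")
    return es.values.loc[list(panel)].to_numpy(dtype=float)


def rank_rhythmicity(es: ExpressionSet, candidate_genes: list[str]) -> RhythmicityRanking:
    """Rank candidate genes by 24 h rhythmicity and cross-instance synchrony.

    For each gene a cosinor is fitted to the pooled series (rhythmicity
    p-value, amplitude, acrophase) and per instance (acrophases whose
    circular SD measures how synchronised the gene's phase is across
    tissues/individuals).  Genes with fewer than 4 distinct sample times in
    some instance are flagged unrankable rather than dropped.
    """
    from .cohort import cosinor_fit, circular_sd_hours

    rows = []
    for gene in candidate_genes:
        gene = str(gene).strip()
        if gene not in es.values.index:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        y = es.values.loc[gene].to_numpy(dtype=float)
        t = es.sample_times
        rankable = True
        inst_phases = []
        for inst in pd.unique(es.instances):
            m = es.instances == inst
            if len(np.unique(t[m])) < 4:
                rankable = False
                break
            _, amp_i, phi_i, _ = cosinor_fit(t[m], y[m])
            inst_phases.append(phi_i)
        if not rankable or len(np.unique(t)) < 4:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        mesor, amp, phi, p = cosinor_fit(t, y)
        disp = circular_sd_hours(np.asarray(inst_phases)) if len(inst_phases) > 1 else 0.0
        rows.append((gene, mesor, amp, phi, p, disp, True))
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "mesor",
            "amplitude",
            "acrophase",
            "p_rhythm",
            "phase_dispersion",
            "rankable",
        ],
    ).set_index("gene")
    return RhythmicityRanking(table=table)
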