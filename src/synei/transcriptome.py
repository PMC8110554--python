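"""Transcriptional E/I ratio and gene-level screening on FPKM matrices.

The transcriptional E/I ratio for a subject is the raw, untransformed FPKM
ratio of DLG4 (encoding PSD-95) to GPHN (encoding gephyrin).  Around it,
this module implements the standard screening computations: an expression
filter (FPKM > 2 in at least three samples), a per-gene response screen by
simple linear regression against the DLG4/GPHN ratio, per-gene diagnosis
log2 fold changes as regression slopes of log2(FPKM + 0.1) on a binary
diagnosis, and summaries of user-supplied excitatory/inhibitory gene sets.

The matrix convention is genes as rows, subjects as columns (the usual TSV
layout of FPKM tables); metadata is a subject-indexed DataFrame with at
least a ``diagnosis`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_expressed",
    "transcriptional_ei",
    "transcriptional_ei_all",
    "response_screen",
    "diagnosis_log2fc",
    "module_fold_changes",
]

EXC_GENE = "DLG4"
INH_GENE = "GPHN"


def filter_expressed(matrix: pd.DataFrame, min_fpkm: float = 2.0,
                     min_samples: int = 3) -> pd.DataFrame:
    """Keep genes with FPKM strictly above ``min_fpkm`` in >= ``min_samples``
    subjects."""
    keep = (matrix > min_fpkm).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def transcriptional_ei(dlg4_fpkm: float, gphn_fpkm: float) -> float:
    """Raw FPKM(DLG4) / FPKM(GPHN); no transformation is applied."""
    if gphn_fpkm <= 0:
        raise ValueError("GPHN FPKM must be positive")
    return dlg4_fpkm / gphn_fpkm


def transcriptional_ei_all(matrix: pd.DataFrame,
                           exc_gene: str = EXC_GENE,
                           inh_gene: str = INH_GENE) -> pd.Series:
    """Per-subject transcriptional E/I ratios from a genes x subjects matrix."""
    for g in (exc_gene, inh_gene):
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} not present in the matrix")
    gphn = matrix.loc[inh_gene]
    if (gphn <= 0).any():
        raise ValueError("GPHN FPKM must be positive for every subject")
    return (matrix.loc[exc_gene] / gphn).rename("ei_ratio")


def response_screen(matrix: pd.DataFrame, ratios: pd.Series,
                    p_cutoff: float) -> pd.DataFrame:
    """Per-gene simple linear regression of expression on the E/I ratio.

    Returns, per gene: slope, Pearson r, two-sided p (t test on r with
    n - 2 df), Benjamini-Hochberg q, and a ``selected`` flag for
    positive-slope genes with raw p below ``p_cutoff``.  Selection uses raw
    p-values; the FDR column is reported alongside.  ``p_cutoff`` is a
    required choice (0.001 and 0.01 are both defensible conventions).
    """
    ratios = ratios.loc[matrix.columns].to_numpy(dtype=float)
    n = ratios.size
    if n < 3:
        raise ValueError("response screen needs at least 3 subjects")
    x = ratios - ratios.mean()
    sx = np.sqrt((x ** 2).sum())
    y = matrix.to_numpy(dtype=float)
    yc = y - y.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ x) / (sy * sx)
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)
        slope = (yc @ x) / sx ** 2
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "slope": slope, "r": r, "p": p, "q_fdr": q,
        "selected": (slope > 0) & (p < p_cutoff),
    }, index=matrix.index)
    return out.sort_values("p")


def diagnosis_log2fc(values: pd.Series | np.ndarray,
                     diagnosis: pd.Series | np.ndarray,
                     offset: float = 0.1) -> float:
    """Slope of log2(FPKM + offset) regressed on a 0/1 diagnosis code.

    For a binary regressor this equals the difference of group means of
    log2(FPKM + offset), i.e. an average log2 fold change.
    """
    v = np.log2(np.asarray(values, dtype=float) + offset)
    d = np.asarray(diagnosis, dtype=float)
    if set(np.unique(d)) - {0.0, 1.0}:
        raise ValueError("diagnosis must be coded 0/1")
    if len(np.unique(d)) < 2:
        raise ValueError("both diagnosis groups must be present")
    slope, _ = np.polyfit(d, v, 1)
    return float(slope)


def module_fold_changes(matrix: pd.DataFrame, gene_sets: dict[str, list[str]],
                        diagnosis: pd.Series,
                        offset: float = 0.1) -> dict[str, pd.DataFrame | pd.Series]:
    """Diagnosis log2 fold changes for user-supplied gene sets.

    ``gene_sets`` maps a set name (e.g. "excitatory", "inhibitory") to gene
    symbols.  Genes absent from the (already filtered) matrix are reported
    in the ``missing`` table rather than silently dropped.  Returns per-gene
    fold changes, a per-set mean summary, and the missing genes per set.
    """
    d = diagnosis.loc[matrix.columns]
    per_gene_rows = []
    missing_rows = []
    for set_name, genes in gene_sets.items():
        for g in genes:
            if g in matrix.index:
                fc = diagnosis_log2fc(matrix.loc[g], d, offset=offset)
                per_gene_rows.append({"set": set_name, "gene": g,
                                      "log2fc": fc})
            else:
                missing_rows.append({"set": set_name, "gene": g})
    per_gene = pd.DataFrame(per_gene_rows, columns=["set", "gene", "log2fc"])
    if len(per_gene):
        per_set = per_gene.groupby("set")["log2fc"].mean()
    else:
        per_set = pd.Series(dtype=float, name="log2fc")
    missing = pd.DataFrame(missing_rows, columns=["set", "gene"])
    return {"per_gene": per_gene, "per_set": per_set, "missing": missing}
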