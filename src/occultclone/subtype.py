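"""Per-cell transcriptional subtype assignment by highest average set expression.

PDAC transcriptional subtyping (basal-like vs classical) is defined by two
gene sets; each cell is labeled with the set showing the strictly highest
average expression over its genes (ties -> unassigned). Because single-cell
dropout can "force" a cell into a subtype on the strength of one or two
detected genes, every call carries its support — which winning-set genes
were actually detected — and per-sample summaries report admixture
(fractions per label) and per-cell hybrid flags (both programs expressed
above a threshold), distinguishing true subtype admixture between cells
from co-expression within cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

UNASSIGNED = "unassigned"


@dataclass
class SubtypeCalls:
    labels: np.ndarray  # per cell, set name or "unassigned"
    averages: pd.DataFrame  # cells x sets average expression
    barcodes: np.ndarray
    set_names: list[str]
    detected: dict[str, np.ndarray]  # set -> cells x set-genes boolean detection
    set_genes: dict[str, list[str]]  # resolvable genes per set, matrix order
    missing_genes: dict[str, list[str]]

    def winning_detected_fraction(self) -> np.ndarray:
        """Fraction of the winning set's genes detected, per cell (NaN if unassigned)."""
        out = np.full(len(self.labels), np.nan)
        for s in self.set_names:
            mask = self.labels == s
            if mask.any():
                out[mask] = self.detected[s][mask].mean(axis=1)
        return out


def _normalized_expression(counts: CountMatrix, normalization: str) -> np.ndarray:
    X = counts.matrix.T.astype(float).toarray()  # cells x genes
    if normalization == "raw":
        return X
    if normalization != "lognorm":
        raise ValueError(f"unknown normalization: {normalization!r}")
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(X / totals * 1e4)


def _resolve_sets(counts: CountMatrix, sets: dict[str, list[str]]):
    names = counts.gene_names if counts.gene_names is not None else counts.gene_ids
    pos = {}
    for i, g in enumerate(names):
        pos.setdefault(str(g), i)
    resolved, missing = {}, {}
    for sname, genes in sets.items():
        found = [g for g in genes if g in pos]
        if not found:
            raise ValueError(f"gene set {sname!r} has no genes in the matrix")
        resolved[sname] = found
        missing[sname] = [g for g in genes if g not in pos]
    return pos, resolved, missing


def assign_subtype(
    counts: CountMatrix,
    sets: dict[str, list[str]],
    normalization: str = "lognorm",
) -> SubtypeCalls:
    """Label each cell with the gene set of strictly highest average expression.

    The average is taken over the full set size: genes absent from the
    matrix contribute zero (and are recorded as missing). An exact tie
    between the top sets leaves the cell unassigned.
    """
    pos, resolved, missing = _resolve_sets(counts, sets)
    X = _normalized_expression(counts, normalization)
    raw = counts.matrix.T  # detection is on raw counts
    set_names = list(sets)
    avg = np.zeros((X.shape[0], len(set_names)))
    detected = {}
    for j, sname in enumerate(set_names):
        cols = [pos[g] for g in resolved[sname]]
        avg[:, j] = X[:, cols].sum(axis=1) / len(sets[sname])
        detected[sname] = np.asarray((raw[:, cols] > 0).todense())
    best = avg.argmax(axis=1)
    best_v = avg[np.arange(len(avg)), best]
    tied = (avg == best_v[:, None]).sum(axis=1) > 1
    labels = np.where(tied, UNASSIGNED, np.array(set_names, object)[best])
    averages = pd.DataFrame(avg, columns=set_names)
    return SubtypeCalls(
        labels.astype(object), averages, counts.barcodes, set_names, detected,
        resolved, missing,
    )


def assignment_support(
    calls: SubtypeCalls,
    sample_labels: np.ndarray,
    min_support_genes: int = 3,
) -> pd.DataFrame:
    """Which genes drive the calls, per sample and label.

    For each (sample, label), the detection frequency of every winning-set
    gene among the cells so labeled; rows whose cells detect fewer than
    ``min_support_genes`` winning-set genes on average raise a low-support
    flag — the signature of calls "forced" by one or two present genes.
    """
    sample_labels = np.asarray(sample_labels)
    rows = []
    for sample in sorted(set(sample_labels)):
        for sname in calls.set_names:
            mask = (sample_labels == sample) & (calls.labels == sname)
            if not mask.any():
                continue
            det = calls.detected[sname][mask]
            freq = det.mean(axis=0)
            genes = calls.set_genes[sname]
            mean_detected = float(det.sum(axis=1).mean())
            rows.append(
                {
                    "sample": sample,
                    "label": sname,
                    "n_cells": int(mask.sum()),
                    "mean_detected_genes": mean_detected,
                    "low_support": mean_detected < min_support_genes,
                    "driver_genes": ",".join(
                        g for g, f in sorted(zip(genes, freq), key=lambda t: -t[1]) if f > 0
                    ),
                }
            )
    return pd.DataFrame(rows)


def admixture_summary(
    calls: SubtypeCalls,
    sample_labels: np.ndarray,
    coexpr_threshold: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample label counts/fractions plus per-cell hybrid flags.

    A cell is a hybrid when every set's average expression exceeds
    ``coexpr_threshold`` — co-expression within the cell, as opposed to
    admixture of differently-labeled cells within the sample.
    """
    sample_labels = np.asarray(sample_labels)
    hybrid = (calls.averages.to_numpy() > coexpr_threshold).all(axis=1)
    rows = []
    for sample in sorted(set(sample_labels)):
        mask = sample_labels == sample
        n = int(mask.sum())
        for label in [*calls.set_names, UNASSIGNED]:
            cnt = int(((calls.labels == label) & mask).sum())
            rows.append(
                {
                    "sample": sample,
                    "label": label,
                    "count": cnt,
                    "fraction": cnt / n,
                    "hybrid_fraction": float(hybrid[mask].mean()),
                }
            )
    return pd.DataFrame(rows), hybrid
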