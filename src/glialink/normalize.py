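"""Count normalization: CPM, FPKM and their log2 transforms.

CPM(g, s)  = counts(g, s) / total(s) * 1e6
FPKM(g, s) = counts(g, s) * 1e9 / (length_bp(g) * total(s))

``total(s)`` is the raw library size, i.e. the column sum over all genes in
the matrix.  Log transforms are base 2 with a configurable pseudocount
(default 1) and may be applied exactly once.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CountMatrix, ExpressionMatrix, GeneAnnotation


def _library_sizes(counts: CountMatrix):
    totals = counts.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    return totals.astype(float)


def compute_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million; every output column sums to 1e6."""
    totals = _library_sizes(counts)
    values = counts.values.astype(float).div(totals, axis=1) * 1e6
    return ExpressionMatrix(values, transform="CPM", metadata=counts.metadata)


def compute_fpkm(counts: CountMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads."""
    missing = counts.genes.difference(ann.lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length(s): {missing.tolist()[:10]}")
    totals = _library_sizes(counts)
    lengths = ann.lengths.loc[counts.genes].astype(float)
    values = (
        counts.values.astype(float)
        .div(totals, axis=1)
        .div(lengths, axis=0)
        * 1e9
    )
    return ExpressionMatrix(values, transform="FPKM", metadata=counts.metadata)


def log_transform(
    expr: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(value + pseudocount); rejects an already-log matrix."""
    if expr.is_log:
        raise ValueError(
            f"matrix is already log-transformed ({expr.transform}); "
            "log of a log is rejected"
        )
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (expr.values.to_numpy() == 0).any():
        raise ValueError(
            "pseudocount 0 with zero entries would produce non-finite values"
        )
    values = np.log2(expr.values + pseudocount)
    transform = {"CPM": "log2CPM", "FPKM": "logFPKM"}[expr.transform]
    return ExpressionMatrix(
        values, transform=transform, pseudocount=pseudocount, metadata=expr.metadata
    )
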