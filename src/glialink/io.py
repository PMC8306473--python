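"""Tab-separated I/O for every table the pipeline exchanges.

Counts and expression matrices are written genes-as-rows with a header row
of sample ids; expression files carry a single comment line recording the
transform and pseudocount so the quantity is never ambiguous on re-read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, GeneAnnotation, LRPairTable


def write_counts(counts: CountMatrix, path) -> None:
    counts.values.rename_axis("gene").to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample").to_csv(path, sep="\t")


def read_counts(counts_path, metadata_path) -> CountMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(values, metadata)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation(path) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t")
    return GeneAnnotation(table.set_index("gene")["length_bp"])


def write_pairs(pairs: LRPairTable, path) -> None:
    pairs.pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> LRPairTable:
    return LRPairTable(pd.read_csv(path, sep="\t"))


def write_expression(expr: ExpressionMatrix, path) -> None:
    pseudo = "" if expr.pseudocount is None else repr(float(expr.pseudocount))
    with open(path, "w") as fh:
        fh.write(f"# transform={expr.transform} pseudocount={pseudo}\n")
        expr.values.rename_axis("gene").to_csv(fh, sep="\t")


def read_expression(path, metadata_path=None) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("# transform="):
        raise ValueError(f"{path}: missing transform header line")
    fields = dict(item.split("=", 1) for item in header[2:].split())
    pseudo = fields.get("pseudocount", "")
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    metadata = (
        pd.read_csv(metadata_path, sep="\t", index_col=0)
        if metadata_path is not None
        else None
    )
    return ExpressionMatrix(
        values,
        transform=fields["transform"],
        pseudocount=float(pseudo) if pseudo else None,
        metadata=metadata,
    )


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
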