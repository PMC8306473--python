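"""Ligand-receptor interaction scoring with a permutation null.

The score of a pair in one context is the mean of the ligand's average
log-FPKM over the OPC samples of that context and the receptor's average
log-FPKM over the microglia samples:

    score = (mean_s ligand(s) + mean_s receptor(s)) / 2

Significance comes from a one-sided permutation test: the null randomizes
which genes occupy the ligand and receptor roles, drawing both uniformly
from the expressed-gene universe and scoring them in the same context.
With 3-4 bulk replicates per group, sample-label permutation admits too
few arrangements to resolve small p-values, so gene-role randomization
(the bulk adaptation of the CellPhoneDB cluster-shuffling null) is the
default.  p-values use the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_perm), so p in (0, 1] with
granularity 1/(n_perm + 1); ties count as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, LRPairTable


class MissingGeneError(KeyError):
    """A pair's ligand or receptor is absent from its expression matrix."""


@dataclass
class InteractionContext:
    """Expression of one OPC (genotype, condition) group against one
    microglia condition; both matrices must be log-transformed and share
    no samples."""

    ligand_values: pd.DataFrame  # log expression, genes x OPC samples
    receptor_values: pd.DataFrame  # log expression, genes x microglia samples
    label: str

    def __post_init__(self) -> None:
        if self.ligand_values.shape[1] < 1 or self.receptor_values.shape[1] < 1:
            raise ValueError("each context matrix needs >= 1 sample")
        shared = set(self.ligand_values.columns) & set(self.receptor_values.columns)
        if shared:
            raise ValueError(f"context matrices share samples: {sorted(shared)[:5]}")

    def ligand_means(self) -> pd.Series:
        return self.ligand_values.mean(axis=1)

    def receptor_means(self) -> pd.Series:
        return self.receptor_values.mean(axis=1)


def pair_score(ligand_values, receptor_values) -> float:
    """Mean of the two per-gene average log expressions."""
    lig = np.asarray(ligand_values, dtype=float)
    rec = np.asarray(receptor_values, dtype=float)
    if lig.size == 0 or rec.size == 0:
        raise ValueError("ligand and receptor value vectors must be non-empty")
    if not (np.isfinite(lig).all() and np.isfinite(rec).all()):
        raise ValueError("expression values must be finite")
    return (lig.mean() + rec.mean()) / 2.0


def expressed_universe(
    context: InteractionContext, floor: float = 0.0
) -> list[str]:
    """Genes present in both matrices with mean log expression above the
    floor in each (the default null-draw universe)."""
    lig_mean = context.ligand_means()
    rec_mean = context.receptor_means()
    shared = lig_mean.index.intersection(rec_mean.index)
    ok = (lig_mean.loc[shared] > floor) & (rec_mean.loc[shared] > floor)
    return shared[ok].tolist()


def permutation_null(
    pair: tuple[str, str],
    context: InteractionContext,
    universe,
    n_perm: int,
    seed,
) -> tuple[float, np.ndarray]:
    """One-sided permutation p-value for one pair in one context.

    Each of the ``n_perm`` null draws assigns the ligand role and the
    receptor role independently and uniformly to universe genes and scores
    that random pair in the same context (the two roles are evaluated in
    different matrices, so a coincident draw is a valid assignment).
    Returns ``(p_value, null_scores)``; deterministic under ``seed``.
    """
    universe = list(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain >= 2 genes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    lig_means = context.ligand_means()
    rec_means = context.receptor_means()
    ligand, receptor = pair
    if ligand not in lig_means.index:
        raise MissingGeneError(f"ligand {ligand!r} absent from OPC matrix")
    if receptor not in rec_means.index:
        raise MissingGeneError(f"receptor {receptor!r} absent from microglia matrix")
    missing_u = [g for g in universe if g not in lig_means.index or g not in rec_means.index]
    if missing_u:
        raise ValueError(f"universe gene(s) absent from a matrix: {missing_u[:5]}")

    observed = (lig_means[ligand] + rec_means[receptor]) / 2.0

    rng = np.random.default_rng(seed)
    lig_pool = lig_means.loc[universe].to_numpy()
    rec_pool = rec_means.loc[universe].to_numpy()
    idx_l = rng.integers(0, len(universe), size=n_perm)
    idx_r = rng.integers(0, len(universe), size=n_perm)
    null_scores = (lig_pool[idx_l] + rec_pool[idx_r]) / 2.0

    p_value = (1.0 + np.count_nonzero(null_scores >= observed)) / (1.0 + n_perm)
    return p_value, null_scores


@dataclass
class InteractionResult:
    """Scored pairs per context plus any pairs skipped with a reason."""

    table: pd.DataFrame
    skipped: pd.DataFrame

    def top_pairs(self) -> pd.DataFrame:
        """Highest-scoring pair per context (the headline ranking)."""
        return (
            self.table.sort_values(["context", "score"], ascending=[True, False])
            .groupby("context", sort=True)
            .head(1)
            .reset_index(drop=True)
        )


def split_cell_types(
    expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split a combined matrix into its OPC and microglia sample blocks."""
    if expr.metadata is None:
        raise ValueError("splitting by cell type requires sample metadata")
    meta = expr.metadata.loc[expr.samples]
    out = []
    for cell_type in ("OPC", "microglia"):
        samples = meta[meta.cell_type == cell_type].index.tolist()
        if not samples:
            raise ValueError(f"no {cell_type} samples in the expression matrix")
        out.append(
            ExpressionMatrix(
                expr.values[samples],
                transform=expr.transform,
                pseudocount=expr.pseudocount,
                metadata=expr.metadata,
            )
        )
    return out[0], out[1]


def _default_contexts(
    opc_expr: ExpressionMatrix, mg_expr: ExpressionMatrix
) -> list[tuple[str, str, str]]:
    if opc_expr.metadata is None or mg_expr.metadata is None:
        raise ValueError("expression matrices need sample metadata to derive contexts")
    opc_meta = opc_expr.metadata.loc[opc_expr.samples]
    mg_meta = mg_expr.metadata.loc[mg_expr.samples]
    opc_groups = sorted(
        set(zip(opc_meta.genotype, opc_meta.condition)), key=str
    )
    mg_conditions = sorted(set(mg_meta.condition))
    return [
        (genotype, condition, mg_condition)
        for genotype, condition in opc_groups
        for mg_condition in mg_conditions
    ]


def build_context(
    opc_expr: ExpressionMatrix,
    mg_expr: ExpressionMatrix,
    genotype: str,
    opc_condition: str,
    mg_condition: str,
) -> InteractionContext:
    """Slice the two matrices down to one (genotype, condition) x condition cell."""
    opc_meta = opc_expr.metadata.loc[opc_expr.samples]
    mg_meta = mg_expr.metadata.loc[mg_expr.samples]
    opc_samples = opc_meta[
        (opc_meta.genotype == genotype) & (opc_meta.condition == opc_condition)
    ].index
    mg_samples = mg_meta[mg_meta.condition == mg_condition].index
    if len(opc_samples) == 0 or len(mg_samples) == 0:
        raise ValueError(
            f"no samples for context OPC {genotype}-{opc_condition} / MG {mg_condition}"
        )
    label = f"OPC {genotype}-{opc_condition} x MG {mg_condition}"
    return InteractionContext(
        ligand_values=opc_expr.values[opc_samples],
        receptor_values=mg_expr.values[mg_samples],
        label=label,
    )


def run_interaction_analysis(
    opc_expr: ExpressionMatrix,
    mg_expr: ExpressionMatrix,
    pairs: LRPairTable,
    contexts=None,
    n_perm: int = 1000,
    seed: int = 0,
    universe=None,
    expression_floor: float = 0.0,
) -> InteractionResult:
    """Score every pair in every context and attach permutation p-values.

    ``contexts`` is a list of (genotype, opc_condition, mg_condition)
    triples, or None for all combinations present in the metadata.  The
    universe defaults to the context's expressed genes (mean log value
    above ``expression_floor`` in both matrices).  Rows are sorted by
    context then descending score; p-values within a run share the same
    universe and ``n_perm`` and are therefore comparable.
    """
    if len(pairs) == 0:
        raise ValueError("pair table is empty")
    if not (opc_expr.is_log and mg_expr.is_log):
        raise ValueError("interaction scoring requires log-transformed matrices")

    pair_genes = set(pairs.pairs["ligand"]) | set(pairs.pairs["receptor"])
    if not (
        pair_genes & set(opc_expr.genes) or pair_genes & set(mg_expr.genes)
    ):
        raise ValueError("no pair-list genes found in either expression matrix")

    if contexts is None:
        contexts = _default_contexts(opc_expr, mg_expr)

    context_objs = [
        build_context(opc_expr, mg_expr, genotype, opc_cond, mg_cond)
        for genotype, opc_cond, mg_cond in contexts
    ]

    seeds = np.random.SeedSequence(seed).spawn(len(context_objs) * len(pairs))
    rows, skipped = [], []
    pair_rows = list(
        pairs.pairs[["ligand", "receptor", "name"]].itertuples(index=False)
    )
    k = 0
    for ctx in context_objs:
        ctx_universe = (
            list(universe)
            if universe is not None
            else expressed_universe(ctx, floor=expression_floor)
        )
        lig_means = ctx.ligand_means()
        rec_means = ctx.receptor_means()
        for ligand, receptor, name in pair_rows:
            child = seeds[k]
            k += 1
            try:
                p_value, _ = permutation_null(
                    (ligand, receptor), ctx, ctx_universe, n_perm, child
                )
            except MissingGeneError as exc:
                skipped.append((ctx.label, ligand, receptor, str(exc.args[0])))
                continue
            lm = float(lig_means[ligand])
            rm = float(rec_means[receptor])
            rows.append(
                (ctx.label, ligand, receptor, name, lm, rm, (lm + rm) / 2.0,
                 p_value, n_perm)
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "context", "ligand", "receptor", "pair", "ligand_mean",
            "receptor_mean", "score", "p_value", "n_permutations",
        ],
    ).sort_values(["context", "score"], ascending=[True, False], kind="mergesort")
    table = table.reset_index(drop=True)
    skipped_df = pd.DataFrame(
        skipped, columns=["context", "ligand", "receptor", "reason"]
    )
    return InteractionResult(table=table, skipped=skipped_df)


def export_dotplot_data(table: pd.DataFrame) -> pd.DataFrame:
    """Dot-plot coordinates: x = context, y = pair, colour = score,
    size = -log10(p) so lower p draws a bigger circle."""
    if len(table) == 0:
        raise ValueError("interaction table is empty")
    out = table[["context", "pair", "score", "p_value"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out[["context", "pair", "score", "neg_log10_p", "p_value"]]
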