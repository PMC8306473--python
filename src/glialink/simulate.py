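"""Synthetic bulk RNA-seq study generator.

Emulates a two-cell-type inflammatory-crosstalk design: oligodendrocyte
precursor cells (OPCs) of two genotypes (wild type and TNFR2 knockout),
each non-stimulated (NS) or stimulated (St) with a cytokine cocktail, and
spinal-cord microglia sampled naive or at acute EAE.  Counts follow a
negative binomial law with per-sample library-size variation, a planted set
of stimulation-responsive genes in OPCs, and planted ligand-receptor pairs
whose ligand is up-regulated in stimulated OPCs and whose receptor is
constitutively expressed (and EAE-boosted) in microglia.

Every planted effect is recorded in a :class:`~glialink.datatypes.GroundTruth`
so downstream stages can be tested for recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneAnnotation, GroundTruth, LRPairTable

#: OPC design cells: (genotype, condition).
OPC_GROUPS = (("WT", "NS"), ("WT", "St"), ("KO", "NS"), ("KO", "St"))
#: Microglia conditions (single genotype in vivo).
MG_CONDITIONS = ("naive", "EAE")

#: Readable aliases for the first planted pairs (chemokine / growth-factor
#: axes typical of OPC-microglia signalling).
KNOWN_PAIR_ALIASES = (("Ccl2", "Ccr5"), ("Csf1", "Csf1r"), ("Cx3cl1", "Cx3cr1"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Parameters
    ----------
    n_genes
        Number of simulated genes.
    n_replicates
        Biological replicates per cell type/condition group (3-4 in the
        emulated design).
    baseline_mean
        Negative-binomial mean count of a typical gene at library-size
        factor 1.
    dispersion
        NB size parameter; variance = mu + mu^2 / dispersion.
    n_de_up, n_de_down
        Planted stimulation-responsive genes per direction (applied to both
        genotypes' stimulated OPC groups).
    de_log2fc
        Planted effect size in log2 units.
    n_lr_pairs
        Rows of the emitted ligand-receptor reference list.
    n_active_pairs
        Pairs planted with ligand-up-in-stimulated-OPC and
        receptor-expressed-in-microglia structure (ligands are drawn from
        the planted up-genes, so requires ``n_active_pairs <= n_de_up``).
    gene_length_range
        Inclusive (min, max) transcript length in bp.
    seed
        Master seed; identical seeds give bit-identical outputs.
    gene_mean_sd_log2
        Between-gene spread (SD of log2 baseline means) around
        ``baseline_mean``.
    libsize_sd_log
        SD of the log-normal per-sample library-size factors.
    receptor_log2fc
        Constitutive elevation of active-pair receptor genes in microglia;
        defaults to ``de_log2fc``.
    eae_log2fc
        Additional up-regulation of active-pair receptors at EAE.
    alias_gene_names
        Rename the first planted pairs to Ccl2/Ccr5, Csf1/Csf1r,
        Cx3cl1/Cx3cr1 for readable fixtures.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    baseline_mean: float = 100.0
    dispersion: float = 10.0
    n_de_up: int = 300
    n_de_down: int = 250
    de_log2fc: float = 2.0
    n_lr_pairs: int = 200
    n_active_pairs: int = 5
    gene_length_range: tuple[int, int] = (1000, 3000)
    seed: int = 0
    gene_mean_sd_log2: float = 0.35
    libsize_sd_log: float = 0.1
    receptor_log2fc: float | None = None
    eae_log2fc: float = 1.0
    alias_gene_names: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("n_de_up", "n_de_down", "n_lr_pairs", "n_active_pairs"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be a non-negative count")
        for name in ("baseline_mean", "dispersion", "de_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_active_pairs > self.n_lr_pairs:
            raise ValueError("n_active_pairs exceeds n_lr_pairs")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("n_de_up + n_de_down exceeds n_genes")
        if self.n_active_pairs > 0 and self.n_active_pairs > self.n_de_up:
            raise ValueError(
                "n_active_pairs exceeds n_de_up (ligands are planted up-genes)"
            )
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("gene_length_range must satisfy 1 <= min <= max")
        if self.gene_mean_sd_log2 < 0 or self.libsize_sd_log < 0:
            raise ValueError("gene_mean_sd_log2 and libsize_sd_log must be >= 0")

    @property
    def receptor_effect(self) -> float:
        return self.de_log2fc if self.receptor_log2fc is None else self.receptor_log2fc


@dataclass
class _Plan:
    """Deterministic gene-role assignment derived from a config."""

    genes: list[str]
    de_up: list[str]
    de_down: list[str]
    ligands: list[str]
    receptors: list[str]
    alias: dict[str, str] = field(default_factory=dict)


def _plan(config: SimulationConfig) -> _Plan:
    """Assign planted roles to the first genes, then alias if requested.

    Roles are positional (no random choice) so that the three generator
    entry points agree on roles without sharing random state.
    """
    genes = [f"G{i:06d}" for i in range(1, config.n_genes + 1)]
    de_up = genes[: config.n_de_up]
    de_down = genes[config.n_de_up : config.n_de_up + config.n_de_down]
    ligands = de_up[: config.n_active_pairs]
    rest = genes[config.n_de_up + config.n_de_down :]
    if len(rest) < config.n_active_pairs:
        raise ValueError("not enough non-DE genes to host receptor roles")
    receptors = rest[: config.n_active_pairs]

    alias: dict[str, str] = {}
    if config.alias_gene_names:
        for (lname, rname), lig, rec in zip(KNOWN_PAIR_ALIASES, ligands, receptors):
            alias[lig] = lname
            alias[rec] = rname

    def a(gs: list[str]) -> list[str]:
        return [alias.get(g, g) for g in gs]

    return _Plan(a(genes), a(de_up), a(de_down), a(ligands), a(receptors), alias)


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for genotype, condition in OPC_GROUPS:
        for r in range(1, config.n_replicates + 1):
            rows.append(
                (f"OPC_{genotype}_{condition}_{r}", "OPC", genotype, condition)
            )
    for condition in MG_CONDITIONS:
        for r in range(1, config.n_replicates + 1):
            rows.append((f"MG_WT_{condition}_{r}", "microglia", "WT", condition))
    return pd.DataFrame(
        rows, columns=["sample", "cell_type", "genotype", "condition"]
    ).set_index("sample")


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the full count matrix and record every planted effect.

    Planted up/down genes shift their NB mean by ``de_log2fc`` in both
    genotypes' stimulated OPC groups, so they are differentially expressed
    in the two stimulation-versus-baseline comparisons.  Active-pair
    receptors are elevated in microglia (both conditions) and further
    boosted at EAE.
    """
    config.validate()
    plan = _plan(config)
    meta = _sample_table(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    n_genes, n_samples = config.n_genes, len(meta)
    base_log2 = np.log2(config.baseline_mean) + rng.normal(
        0.0, config.gene_mean_sd_log2, size=n_genes
    )
    size_factors = rng.lognormal(0.0, config.libsize_sd_log, size=n_samples)

    gene_pos = {g: i for i, g in enumerate(plan.genes)}
    # per-gene log2 offsets by design cell
    offsets = np.zeros((n_genes, n_samples))
    is_opc_stim = ((meta.cell_type == "OPC") & (meta.condition == "St")).to_numpy()
    is_mg = (meta.cell_type == "microglia").to_numpy()
    is_eae = (is_mg & (meta.condition == "EAE").to_numpy())

    up_idx = [gene_pos[g] for g in plan.de_up]
    down_idx = [gene_pos[g] for g in plan.de_down]
    rec_idx = [gene_pos[g] for g in plan.receptors]
    offsets[np.ix_(up_idx, np.where(is_opc_stim)[0])] += config.de_log2fc
    offsets[np.ix_(down_idx, np.where(is_opc_stim)[0])] -= config.de_log2fc
    offsets[np.ix_(rec_idx, np.where(is_mg)[0])] += config.receptor_effect
    offsets[np.ix_(rec_idx, np.where(is_eae)[0])] += config.eae_log2fc

    mu = np.exp2(base_log2[:, None] + offsets) * size_factors[None, :]
    p = config.dispersion / (config.dispersion + mu)
    counts = rng.negative_binomial(config.dispersion, p)

    values = pd.DataFrame(counts, index=pd.Index(plan.genes, name="gene"),
                          columns=meta.index)
    truth = _ground_truth(config, plan)
    return CountMatrix(values, meta), truth


def _ground_truth(config: SimulationConfig, plan: _Plan) -> GroundTruth:
    rows = []
    stim_comparisons = ("WT-St vs WT-NS", "KO-St vs KO-NS")
    for comp in stim_comparisons:
        rows += [(g, "up", config.de_log2fc, comp) for g in plan.de_up]
        rows += [(g, "down", -config.de_log2fc, comp) for g in plan.de_down]
    de = pd.DataFrame(rows, columns=["gene", "direction", "log2fc", "comparison"])
    active = list(zip(plan.ligands, plan.receptors))
    return GroundTruth(de_genes=de, active_pairs=active)


def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Draw one transcript length per gene, uniform on the configured range."""
    config.validate()
    plan = _plan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi, size=config.n_genes, endpoint=True)
    return GeneAnnotation(
        pd.Series(lengths, index=pd.Index(plan.genes, name="gene"), name="length_bp")
    )


def simulate_lr_reference(
    config: SimulationConfig,
) -> tuple[LRPairTable, GroundTruth]:
    """Emit the ligand-receptor pair list with the planted active pairs first.

    The remaining rows pair random distinct genes; rows are unique and the
    ground truth partitions them into active and null pairs.
    """
    config.validate()
    plan = _plan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    active = list(zip(plan.ligands, plan.receptors))
    seen = set(active)
    pairs = list(active)
    genes = plan.genes
    while len(pairs) < config.n_lr_pairs:
        lig, rec = rng.choice(genes, size=2, replace=False)
        if (lig, rec) not in seen:
            seen.add((lig, rec))
            pairs.append((lig, rec))

    table = LRPairTable(pd.DataFrame(pairs, columns=["ligand", "receptor"]))
    truth = GroundTruth(active_pairs=active, null_pairs=pairs[len(active):])
    return table, truth


def simulate_study(
    config: SimulationConfig,
) -> tuple[CountMatrix, GeneAnnotation, LRPairTable, GroundTruth]:
    """Convenience wrapper: counts + annotation + pair list + merged truth."""
    counts, truth_counts = simulate_counts(config)
    ann = simulate_annotation(config)
    pairs, truth_pairs = simulate_lr_reference(config)
    truth = GroundTruth(
        de_genes=truth_counts.de_genes,
        active_pairs=truth_pairs.active_pairs,
        null_pairs=truth_pairs.null_pairs,
    )
    return counts, ann, pairs, truth
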