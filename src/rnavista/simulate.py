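"""Synthetic experiment generator with planted, machine-readable truth.

Emits a complete input bundle — sample sheet, expression matrix,
differential tables, genome background, GMT gene sets and a TRRUST-style
regulator network — together with a truth manifest recording which genes
were planted differential (and with which cross-comparison profile),
which gene sets are enriched and which regulators are active.

Model: per-gene base log10 expression ~ Normal(1.5, 1); planted genes
receive per-group shifts encoding their differential profile (shift
magnitude = |log2fc| * log10(2)); iid Gaussian noise (sd 0.25 log10
units) per sample. The expression matrix is the antilog. Differential
tables are then computed *from the generated matrix* (never invented
independently) with a variance-moderated two-group location test on
log2 values: because the generator's noise is homoscedastic by
construction, the residual sd is pooled across all genes, giving a
z-test per gene; BH adjustment across genes. This keeps EM and DE files
self-consistent, so MA/volcano/fold-vs-fold views built from either
agree.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import (BackgroundAnnotation, ComparisonSpec, DifferentialTable,
                 ExpressionMatrix, GeneSetDatabase, RegulatorEdge,
                 RegulatorNetwork, SampleSheet)
from .stats import bh_adjust

LOG10_2 = math.log10(2.0)


@dataclass
class PlantedProfile:
    """A planted cross-comparison call profile shared by ``n_genes`` genes."""

    profile: tuple[str, ...]    # one of up/down/ns per comparison
    n_genes: int


@dataclass
class FixtureConfig:
    """Study design for one synthetic experiment.

    Defaults encode a moderate bulk design: 3 groups x 6 replicates,
    2000 genes, planted |log2fc| of 2 against log10-noise sd 0.25.
    """

    seed: int
    n_genes: int = 2000
    n_groups: int = 3
    reps_per_group: int = 6
    comparisons: list[tuple[int, int]] | None = None  # (test idx, ref idx)
    profiles: list[PlantedProfile] | None = None
    log2fc_magnitude: float = 2.0
    base_mean_log10: float = 1.5
    base_sd_log10: float = 1.0
    noise_sd_log10: float = 0.25
    adj_p_threshold: float = 0.05
    abs_log2fc_threshold: float = 1.0
    # gene-set database
    n_enriched_sets: int = 3
    n_null_sets: int = 20
    set_size: int = 50
    overlap_fraction: float = 0.75
    enriched_source_direction: str = "up"   # planted direction pool (comparison 0)
    # regulator network
    n_activated: int = 2
    n_inhibited: int = 2
    n_null_regulators: int = 10
    regulon_size: int = 20
    consistency_fraction: float = 0.9
    # annotation
    n_chromosomes: int = 5
    biased_chromosome: str | None = None    # gets every comparison-0 "up" gene
    invert: bool = False                    # flip every planted direction

    def __post_init__(self) -> None:
        if self.comparisons is None:
            self.comparisons = [(g + 1, g) for g in range(self.n_groups - 1)]
        if self.profiles is None:
            m = len(self.comparisons)
            base = [("up",), ("down",)] if m == 1 else [
                ("up",) + ("ns",) * (m - 1),
                ("ns",) * (m - 1) + ("up",),
                ("up", "down") + ("ns",) * (m - 2),
                ("down", "up") + ("ns",) * (m - 2),
            ]
            self.profiles = [PlantedProfile(p, 50) for p in base]
        n_planted = sum(p.n_genes for p in self.profiles)
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted gene count {n_planted} exceeds n_genes {self.n_genes}")
        for p in self.profiles:
            if len(p.profile) != len(self.comparisons):
                raise ValueError(
                    f"profile {p.profile} length != number of comparisons")
            if p.n_genes < 0 or not any(c != "ns" for c in p.profile):
                raise ValueError(f"invalid planted profile {p}")
        if self.reps_per_group < 2 or self.n_groups < 2:
            raise ValueError("need >= 2 groups with >= 2 replicates each")


@dataclass
class FixtureBundle:
    """In-memory synthetic bundle plus the planted truth manifest."""

    sheet: SampleSheet
    em: ExpressionMatrix
    background: BackgroundAnnotation
    comparisons: list[ComparisonSpec]
    gene_sets: GeneSetDatabase
    network: RegulatorNetwork
    truth: dict
    config: FixtureConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle in the pipeline's documented input formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        p = outdir / "sample_sheet.tsv"
        pd.DataFrame(self.sheet.samples, columns=["sample", "group"]).to_csv(
            p, sep="\t", index=False)
        paths["sample_sheet"] = p

        p = outdir / "expression_matrix.tsv"
        self.em.data.to_csv(p, sep="\t", index_label="gene_id")
        paths["expression_matrix"] = p

        for comp in self.comparisons:
            p = outdir / f"de_{comp.name}.tsv"
            df = comp.de_table.data.rename(columns={
                "log2fc": "log2FoldChange", "p": "pvalue", "adj_p": "padj"})
            df.to_csv(p, sep="\t", index_label="gene_id")
            paths[f"de_{comp.name}"] = p

        p = outdir / "background.tsv"
        self.background.data.to_csv(p, sep="\t", index_label="gene_id")
        paths["background"] = p

        p = outdir / "gene_sets.gmt"
        with open(p, "w") as fh:
            for name in self.gene_sets.sets:
                desc = self.gene_sets.descriptions.get(name, "synthetic")
                members = "\t".join(sorted(self.gene_sets.sets[name]))
                fh.write(f"{name}\t{desc}\t{members}\n")
        paths["gene_sets"] = p

        p = outdir / "regulators.tsv"
        with open(p, "w") as fh:
            for e in self.network.edges:
                fh.write(f"{e.regulator}\t{e.target}\t{e.mode}\tsynthetic\n")
        paths["regulators"] = p

        p = outdir / "truth_manifest.json"
        with open(p, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        paths["truth_manifest"] = p
        return paths


def _flip(call: str) -> str:
    return {"up": "down", "down": "up"}.get(call, call)


def generate_experiment(cfg: FixtureConfig) -> FixtureBundle:
    """Generate a synthetic bundle with planted ground truth (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    n_comp = len(cfg.comparisons)

    groups = [chr(ord("A") + g) for g in range(cfg.n_groups)]
    samples = [(f"{g}_{r + 1}", g) for g in groups for r in range(cfg.reps_per_group)]
    sheet = SampleSheet(samples=samples, group_order=groups)

    gene_ids = [f"gene_{i + 1:05d}" for i in range(cfg.n_genes)]
    symbols = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    # --- planted truth -----------------------------------------------------
    profiles: list[tuple[str, ...]] = []
    for p in cfg.profiles:
        prof = tuple(_flip(c) for c in p.profile) if cfg.invert else p.profile
        profiles.append(prof)
    gene_profile: dict[str, tuple[str, ...]] = {}
    gene_signature: dict[str, int] = {}
    idx = 0
    for sig_id, (planted, prof) in enumerate(zip(cfg.profiles, profiles), start=1):
        for _ in range(planted.n_genes):
            gene_profile[gene_ids[idx]] = prof
            gene_signature[gene_ids[idx]] = sig_id
            idx += 1
    ns_profile = ("ns",) * n_comp

    # per-gene per-group shifts in log10 units, solved from the profile by
    # walking the comparison list (test gets ref's shift +/- delta)
    delta = cfg.log2fc_magnitude * LOG10_2
    shifts = np.zeros((cfg.n_genes, cfg.n_groups))
    for i, gid in enumerate(gene_ids):
        prof = gene_profile.get(gid)
        if prof is None:
            continue
        for (test, ref), call in zip(cfg.comparisons, prof):
            if call == "up":
                shifts[i, test] = shifts[i, ref] + delta
            elif call == "down":
                shifts[i, test] = shifts[i, ref] - delta
            else:
                shifts[i, test] = shifts[i, ref]

    # --- expression matrix -------------------------------------------------
    base = rng.normal(cfg.base_mean_log10, cfg.base_sd_log10, size=cfg.n_genes)
    group_of = np.repeat(np.arange(cfg.n_groups), cfg.reps_per_group)
    log10_expr = (base[:, None] + shifts[:, group_of]
                  + rng.normal(0.0, cfg.noise_sd_log10,
                               size=(cfg.n_genes, len(samples))))
    em = ExpressionMatrix(data=pd.DataFrame(
        np.power(10.0, log10_expr), index=pd.Index(gene_ids, name="gene_id"),
        columns=[s for s, _ in samples]))

    # --- differential tables from the matrix -------------------------------
    log2_expr = log10_expr / LOG10_2
    # pooled residual sd across all genes and groups (noise is homoscedastic
    # by construction, so pooling is exact and gives a well-calibrated z-test)
    resid_ss = 0.0
    resid_df = 0
    for g in range(cfg.n_groups):
        cols = group_of == g
        sub = log2_expr[:, cols]
        resid_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum()
        resid_df += cfg.n_genes * (int(cols.sum()) - 1)
    pooled_sd = math.sqrt(resid_ss / resid_df)

    comparisons: list[ComparisonSpec] = []
    for (test, ref) in cfg.comparisons:
        t_cols, r_cols = group_of == test, group_of == ref
        n1, n2 = int(t_cols.sum()), int(r_cols.sum())
        l2fc = log2_expr[:, t_cols].mean(axis=1) - log2_expr[:, r_cols].mean(axis=1)
        se = pooled_sd * math.sqrt(1 / n1 + 1 / n2)
        z = l2fc / se
        p = 2.0 * _sps.norm.sf(np.abs(z))
        adj = bh_adjust(p)
        name = f"{groups[test]}_vs_{groups[ref]}"
        table = DifferentialTable(data=pd.DataFrame(
            {"log2fc": l2fc, "p": p, "adj_p": adj},
            index=pd.Index(gene_ids, name="gene_id")))
        comparisons.append(ComparisonSpec(
            name=name, test_group=groups[test], reference_group=groups[ref],
            de_table=table, adj_p_threshold=cfg.adj_p_threshold,
            abs_log2fc_threshold=cfg.abs_log2fc_threshold))

    # --- background annotation ---------------------------------------------
    chroms = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    chrom_col = [chroms[i % cfg.n_chromosomes] for i in range(cfg.n_genes)]
    if cfg.biased_chromosome is not None:
        biased_dir = "down" if cfg.invert else "up"
        for i, gid in enumerate(gene_ids):
            prof = gene_profile.get(gid)
            if prof is not None and prof[0] == biased_dir:
                chrom_col[i] = cfg.biased_chromosome
    background = BackgroundAnnotation(data=pd.DataFrame(
        {"symbol": symbols, "chromosome": chrom_col,
         "biotype": ["protein_coding"] * cfg.n_genes},
        index=pd.Index(gene_ids, name="gene_id")))

    sym_of = dict(zip(gene_ids, symbols))
    first_dir = cfg.enriched_source_direction
    if cfg.invert:
        first_dir = _flip(first_dir)
    pool_dir = [g for g, p in gene_profile.items() if p[0] == first_dir]
    planted_all = list(gene_profile)
    null_pool = [g for g in gene_ids if g not in gene_profile]

    # --- gene sets ----------------------------------------------------------
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    truth_sets: dict[str, bool] = {}
    for i in range(cfg.n_enriched_sets):
        n_hit = min(int(round(cfg.set_size * cfg.overlap_fraction)), len(pool_dir))
        hit = rng.choice(pool_dir, size=n_hit, replace=False)
        rest = rng.choice(null_pool, size=cfg.set_size - n_hit, replace=False)
        name = f"ENRICHED_SET_{i + 1}"
        sets[name] = {sym_of[g] for g in list(hit) + list(rest)}
        descriptions[name] = "planted enriched set"
        truth_sets[name] = True
    for i in range(cfg.n_null_sets):
        members = rng.choice(gene_ids, size=cfg.set_size, replace=False)
        name = f"NULL_SET_{i + 1:03d}"
        sets[name] = {sym_of[g] for g in members}
        descriptions[name] = "planted null set"
        truth_sets[name] = False
    gene_sets = GeneSetDatabase(name="synthetic", sets=sets,
                                descriptions=descriptions)

    # --- regulator network --------------------------------------------------
    up0 = [g for g, p in gene_profile.items() if p[0] == ("down" if cfg.invert else "up")]
    down0 = [g for g, p in gene_profile.items() if p[0] == ("up" if cfg.invert else "down")]
    edges: list[RegulatorEdge] = []
    truth_regs: dict[str, str] = {}

    def _regulon(name: str, cons_pool: list[str], incons_pool: list[str]) -> None:
        n_cons = int(round(cfg.regulon_size * cfg.consistency_fraction))
        n_cons = min(n_cons, len(cons_pool))
        n_inc = min(cfg.regulon_size - n_cons, len(incons_pool))
        cons = rng.choice(cons_pool, size=n_cons, replace=False)
        incons = rng.choice(incons_pool, size=n_inc, replace=False)
        for g in cons:
            edges.append(RegulatorEdge(name, sym_of[g], "Activation"))
        for g in incons:
            edges.append(RegulatorEdge(name, sym_of[g], "Activation"))

    for i in range(cfg.n_activated):
        name = f"ACTREG{i + 1:02d}"
        truth_regs[name] = "inhibited" if cfg.invert else "activated"
        _regulon(name, up0, down0)
    for i in range(cfg.n_inhibited):
        name = f"INHREG{i + 1:02d}"
        truth_regs[name] = "activated" if cfg.invert else "inhibited"
        _regulon(name, down0, up0)
    for i in range(cfg.n_null_regulators):
        name = f"NULLREG{i + 1:02d}"
        truth_regs[name] = "null"
        targets = rng.choice(gene_ids, size=cfg.regulon_size, replace=False)
        modes = rng.choice(["Activation", "Repression", "Unknown"],
                           size=cfg.regulon_size, p=[0.45, 0.45, 0.1])
        for g, m in zip(targets, modes):
            edges.append(RegulatorEdge(name, sym_of[g], str(m)))
    network = RegulatorNetwork(edges=edges)

    truth = {
        "genes": {g: {"profile": list(gene_profile.get(g, ns_profile)),
                      "signature": gene_signature.get(g)}
                  for g in gene_ids},
        "gene_sets": truth_sets,
        "regulators": truth_regs,
        "comparisons": [c.name for c in comparisons],
        "params": {
            "seed": cfg.seed, "n_genes": cfg.n_genes, "n_groups": cfg.n_groups,
            "reps_per_group": cfg.reps_per_group,
            "log2fc_magnitude": cfg.log2fc_magnitude,
            "noise_sd_log10": cfg.noise_sd_log10, "invert": cfg.invert,
        },
    }
    return FixtureBundle(sheet=sheet, em=em, background=background,
                         comparisons=comparisons, gene_sets=gene_sets,
                         network=network, truth=truth, config=cfg)


def generate_minimal_demo(seed: int = 0, outdir: str | Path | None = None,
                          ) -> FixtureBundle:
    """Small end-to-end demo bundle: 3 groups x 3 replicates, 2 comparisons,
    4 planted signature profiles, gene sets and regulators."""
    cfg = FixtureConfig(
        seed=seed, n_genes=800, n_groups=3, reps_per_group=3,
        profiles=[
            PlantedProfile(("up", "ns"), 50),
            PlantedProfile(("ns", "up"), 50),
            PlantedProfile(("up", "down"), 50),
            PlantedProfile(("down", "up"), 50),
        ],
        n_enriched_sets=3, n_null_sets=20, set_size=40,
        n_activated=2, n_inhibited=2, n_null_regulators=8,
    )
    bundle = generate_experiment(cfg)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
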