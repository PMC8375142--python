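"""Input readers, validation, and master gene table assembly.

The pipeline accepts five kinds of text input: a tab-delimited sample
sheet, a normalized expression matrix (genes x samples; FPKM/TPM/RLog —
any normalization), one differential table per comparison (DESeq2, EdgeR
or anything with mappable columns), a genome background/annotation table
(Biomart-style), gene-set databases in GMT format and a regulator network
in TRRUST format. All of them are validated here and joined into a single
master gene table that every downstream workflow reads.

Gene-id harmonization policy: expression, differential and background
tables are joined on gene_id exactly (case-sensitive). Gene *symbols* are
used only for matching against GMT / TRRUST databases and are matched
case-insensitively (databases conventionally use upper-case symbols).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("rnavista")


class ValidationError(ValueError):
    """Raised when an input file violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Ordered sample -> group mapping."""

    samples: list[tuple[str, str]]          # (sample_id, group_label)
    group_order: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {g: [] for g in self.group_order}
        for s, g in self.samples:
            out[g].append(s)
        return out

    def reorder_groups(self, order: list[str]) -> "SampleSheet":
        """Return a copy with a user-specified group order."""
        if sorted(order) != sorted(self.group_order):
            raise ValidationError(
                f"group order {order} does not match groups {self.group_order}")
        return SampleSheet(samples=list(self.samples), group_order=list(order))


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes x samples."""

    data: pd.DataFrame      # index: gene_id, columns: sample_id

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class DifferentialTable:
    """Per-gene differential statistics for one two-group contrast."""

    data: pd.DataFrame      # index: gene_id; columns: log2fc, p, adj_p

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class BackgroundAnnotation:
    """Genome background: gene_id, symbol, chromosome[, biotype]."""

    data: pd.DataFrame      # index: gene_id; columns: symbol, chromosome[, biotype]


@dataclass
class GeneSetDatabase:
    """Named gene sets (GMT); member symbols stored upper-case."""

    name: str
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class RegulatorEdge:
    regulator: str
    target: str
    mode: str               # Activation | Repression | Unknown


@dataclass
class RegulatorNetwork:
    """Signed regulator -> target network (TRRUST-style)."""

    edges: list[RegulatorEdge]

    def regulons(self) -> dict[str, dict[str, str]]:
        """regulator -> {target symbol: mode}."""
        out: dict[str, dict[str, str]] = {}
        for e in self.edges:
            out.setdefault(e.regulator, {})[e.target] = e.mode
        return out


@dataclass
class ComparisonSpec:
    """One differential contrast with its significance thresholds."""

    name: str
    test_group: str
    reference_group: str
    de_table: DifferentialTable
    adj_p_threshold: float = 0.05
    abs_log2fc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.adj_p_threshold <= 0 or self.abs_log2fc_threshold <= 0:
            raise ValidationError(f"thresholds must be > 0 in comparison {self.name}")


MODE_VOCAB = ("Activation", "Repression", "Unknown")
CALLS = ("up", "down", "ns", "untested")

# shipped column-name mappings for common differential-table producers
DE_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "deseq2": {"log2fc": "log2FoldChange", "p": "pvalue", "adj_p": "padj"},
    "edger": {"log2fc": "logFC", "p": "PValue", "adj_p": "FDR"},
    "generic": {"log2fc": "log2fc", "p": "p", "adj_p": "adj_p"},
}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a tab-delimited sample sheet (columns: sample, group, ...).

    Group order is the order of first appearance; extra columns are
    ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise ValidationError(f"sample sheet {path} has no rows")
    if df.shape[1] < 2:
        raise ValidationError(f"sample sheet {path} needs >= 2 columns (sample, group)")
    samples = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    ids = [s for s, _ in samples]
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValidationError(f"duplicate sample id(s) in {path}: {', '.join(dupes)}")
    if any(not s.strip() for s in ids):
        raise ValidationError(f"empty sample id in {path}")
    group_order: list[str] = []
    for _, g in samples:
        if g not in group_order:
            group_order.append(g)
    return SampleSheet(samples=samples, group_order=group_order)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read the expression matrix TSV (first column gene id, rest samples).

    Duplicate gene ids keep the first occurrence (logged); any negative or
    non-numeric cell is an error naming its coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"expression matrix {path} needs gene id + >=1 sample column")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    mat = df.apply(pd.to_numeric, errors="coerce")
    bad = mat.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric expression value {df.iloc[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r} in {path}")
    if mat.isna().to_numpy().any():
        r, c = np.argwhere(mat.isna().to_numpy())[0]
        raise ValidationError(
            f"missing expression value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}")
    if (mat.to_numpy() < 0).any():
        r, c = np.argwhere(mat.to_numpy() < 0)[0]
        raise ValidationError(
            f"negative expression value at gene {mat.index[r]!r}, "
            f"sample {mat.columns[c]!r} in {path}")
    if mat.index.duplicated().any():
        dup = sorted(set(mat.index[mat.index.duplicated()]))
        log.warning("duplicate gene ids in %s (first occurrence kept): %s",
                    path, ", ".join(map(str, dup[:10])))
        mat = mat[~mat.index.duplicated(keep="first")]
    mat.index = mat.index.astype(str)
    return ExpressionMatrix(data=mat.astype(float))


def read_differential_table(path: str | Path,
                            column_map: dict[str, str] | str | None = None,
                            gene_id_column: str | None = None) -> DifferentialTable:
    """Read a differential table with mappable column names.

    ``column_map`` may be a producer name ("deseq2", "edger", "generic"),
    an explicit mapping {log2fc/p/adj_p -> header}, or None to try the
    shipped producers in turn. Missing p / adj_p values (NA) are retained
    as NaN; genes with missing adj_p are later called "untested".
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise ValidationError(f"differential table {path} has no rows")
    if isinstance(column_map, str):
        maps = [DE_COLUMN_MAPS[column_map.lower()]]
    elif column_map is not None:
        maps = [column_map]
    else:
        maps = list(DE_COLUMN_MAPS.values())
    chosen = None
    for m in maps:
        if all(v in df.columns for v in m.values()):
            chosen = m
            break
    if chosen is None:
        wanted = maps[0] if len(maps) == 1 else DE_COLUMN_MAPS["generic"]
        missing = [v for v in wanted.values() if v not in df.columns]
        raise ValidationError(
            f"differential table {path} is missing required column(s): "
            f"{', '.join(missing)} (no shipped column mapping matched)")
    gene_col = gene_id_column or df.columns[0]
    out = pd.DataFrame({
        "log2fc": pd.to_numeric(df[chosen["log2fc"]], errors="coerce"),
        "p": pd.to_numeric(df[chosen["p"]], errors="coerce"),
        "adj_p": pd.to_numeric(df[chosen["adj_p"]], errors="coerce"),
    })
    out.index = df[gene_col].astype(str)
    out.index.name = "gene_id"
    for col in ("p", "adj_p"):
        vals = out[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            bad = vals[(vals < 0) | (vals > 1)].index[0]
            raise ValidationError(
                f"{col} out of [0, 1] for gene {bad!r} in {path}")
    n_na = int(out["adj_p"].isna().sum())
    if n_na:
        log.warning("%d gene(s) with missing adj_p in %s (will be 'untested')",
                    n_na, path)
    if out.index.duplicated().any():
        out = out[~out.index.duplicated(keep="first")]
        log.warning("duplicate gene ids in %s; first occurrence kept", path)
    return DifferentialTable(data=out)


def read_background(path: str | Path) -> BackgroundAnnotation:
    """Read a Biomart-style background table: gene_id, symbol, chromosome[, biotype]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 3:
        raise ValidationError(
            f"background {path} needs >= 3 columns (gene_id, symbol, chromosome)")
    cols = ["gene_id", "symbol", "chromosome"] + (
        ["biotype"] if df.shape[1] >= 4 else [])
    df = df.iloc[:, :len(cols)]
    df.columns = cols
    if df["gene_id"].duplicated().any():
        df = df[~df["gene_id"].duplicated(keep="first")]
        log.warning("duplicate gene ids in background %s; first kept", path)
    return BackgroundAnnotation(data=df.set_index("gene_id"))


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetDatabase:
    """Read a GMT gene-set database (name TAB description TAB members...)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: GMT line needs name + description")
            set_name, desc = parts[0], parts[1]
            members = {m.strip().upper() for m in parts[2:] if m.strip()}
            if not members:
                log.warning("%s:%d: gene set %r has no members; dropped",
                            path, lineno, set_name)
                continue
            if set_name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            sets[set_name] = members
            descriptions[set_name] = desc
    return GeneSetDatabase(name=name or path.stem, sets=sets,
                           descriptions=descriptions)


def read_trrust(path: str | Path) -> RegulatorNetwork:
    """Read a TRRUST-format network: regulator, target, mode, references.

    The reference column is ignored; unknown mode strings map to
    "Unknown" with a warning; duplicate (regulator, target) pairs are
    dropped keeping the first.
    """
    path = Path(path)
    edges: list[RegulatorEdge] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: TRRUST line needs regulator, target, mode")
            reg, tgt, mode = (parts[0].strip().upper(), parts[1].strip().upper(),
                              parts[2].strip().capitalize())
            if mode not in MODE_VOCAB:
                log.warning("%s:%d: unknown interaction mode %r -> Unknown",
                            path, lineno, parts[2])
                mode = "Unknown"
            if (reg, tgt) in seen:
                continue
            seen.add((reg, tgt))
            edges.append(RegulatorEdge(regulator=reg, target=tgt, mode=mode))
    return RegulatorNetwork(edges=edges)


# ---------------------------------------------------------------------------
# master gene table
# ---------------------------------------------------------------------------

@dataclass
class MasterGeneTable:
    """Per-gene join of expression, annotation and comparison statistics.

    One row per expression-matrix gene. Columns: symbol, chromosome,
    ``expr:<sample>`` raw values, ``mean:<group>`` group means,
    ``z:<sample>`` per-gene z-scores (over all samples; zero-variance
    genes get an all-zero z row), and per comparison ``<name>:log2fc``,
    ``<name>:p``, ``<name>:adj_p``, ``<name>:call`` in {up, down, ns,
    untested}.
    """

    data: pd.DataFrame
    sheet: SampleSheet
    comparisons: list[str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return self.sheet.sample_ids

    def expression(self) -> pd.DataFrame:
        cols = [f"expr:{s}" for s in self.sample_ids]
        out = self.data[cols].copy()
        out.columns = self.sample_ids
        return out

    def zscores(self) -> pd.DataFrame:
        cols = [f"z:{s}" for s in self.sample_ids]
        out = self.data[cols].copy()
        out.columns = self.sample_ids
        return out

    def group_means(self) -> pd.DataFrame:
        cols = [f"mean:{g}" for g in self.sheet.group_order]
        out = self.data[cols].copy()
        out.columns = self.sheet.group_order
        return out

    def calls(self, comparison: str) -> pd.Series:
        return self.data[f"{comparison}:call"]

    def significant_genes(self, comparison: str,
                          direction: str = "all") -> list[str]:
        """Gene ids called significant in a comparison (direction: all/up/down)."""
        calls = self.calls(comparison)
        if direction == "all":
            mask = calls.isin(["up", "down"])
        elif direction in ("up", "down"):
            mask = calls == direction
        else:
            raise ValueError(f"direction must be all/up/down, got {direction!r}")
        return list(calls.index[mask])

    def symbols_for(self, gene_ids) -> list[str]:
        """Upper-cased symbols for the given gene ids (empty symbols dropped)."""
        sub = self.data.loc[list(gene_ids), "symbol"]
        return [s.upper() for s in sub if isinstance(s, str) and s.strip()]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def build_master_table(sheet: SampleSheet, em: ExpressionMatrix,
                       comparisons: list[ComparisonSpec],
                       background: BackgroundAnnotation) -> MasterGeneTable:
    """Assemble the master gene table.

    Validates the sample sheet against the matrix columns, computes
    per-group means and per-gene z-scores (across all samples of the
    run), joins annotation, and computes significance calls per
    comparison: up iff adj_p < threshold and log2fc > +t; down iff
    adj_p < threshold and log2fc < -t; untested if the gene is absent
    from the differential table or has missing adj_p; else ns.
    """
    if set(em.sample_ids) != set(sheet.sample_ids):
        only_em = sorted(set(em.sample_ids) - set(sheet.sample_ids))
        only_sheet = sorted(set(sheet.sample_ids) - set(em.sample_ids))
        raise ValidationError(
            "expression matrix samples do not match the sample sheet "
            f"(matrix-only: {only_em}; sheet-only: {only_sheet})")
    for comp in comparisons:
        for g in (comp.test_group, comp.reference_group):
            if g not in sheet.group_order:
                raise ValidationError(
                    f"comparison {comp.name!r} references unknown group {g!r}")
        if not set(comp.de_table.gene_ids) & set(em.gene_ids):
            raise ValidationError(
                f"comparison {comp.name!r}: no genes shared between the "
                "expression matrix and the differential table")

    expr = em.data[sheet.sample_ids]
    ann = background.data.reindex(expr.index).fillna("")
    cols: dict[str, pd.Series | np.ndarray] = {
        "symbol": ann["symbol"].astype(str),
        "chromosome": ann["chromosome"].astype(str),
    }
    for s in sheet.sample_ids:
        cols[f"expr:{s}"] = expr[s]
    for g, members in sheet.groups.items():
        cols[f"mean:{g}"] = expr[members].mean(axis=1)

    vals = expr.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mu) / sd
    z[np.repeat(sd == 0, vals.shape[1], axis=1)] = 0.0
    for j, s in enumerate(sheet.sample_ids):
        cols[f"z:{s}"] = z[:, j]

    for comp in comparisons:
        de = comp.de_table.data.reindex(expr.index)
        cols[f"{comp.name}:log2fc"] = de["log2fc"]
        cols[f"{comp.name}:p"] = de["p"]
        cols[f"{comp.name}:adj_p"] = de["adj_p"]
        call = np.full(len(expr), "ns", dtype=object)
        untested = de["adj_p"].isna() | de["log2fc"].isna()
        sig = (de["adj_p"] < comp.adj_p_threshold) & ~untested
        call[(sig & (de["log2fc"] > comp.abs_log2fc_threshold)).to_numpy()] = "up"
        call[(sig & (de["log2fc"] < -comp.abs_log2fc_threshold)).to_numpy()] = "down"
        call[untested.to_numpy()] = "untested"
        cols[f"{comp.name}:call"] = call

    out = pd.DataFrame(cols, index=expr.index)
    out.index.name = "gene_id"
    return MasterGeneTable(data=out, sheet=sheet,
                           comparisons=[c.name for c in comparisons])


def read_master_table(path: str | Path, sheet: SampleSheet,
                      comparisons: list[str]) -> MasterGeneTable:
    """Re-read a master table written by :meth:`MasterGeneTable.to_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id",
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    for col in ("symbol", "chromosome"):
        df[col] = df[col].fillna("").astype(str)
    return MasterGeneTable(data=df, sheet=sheet, comparisons=list(comparisons))
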